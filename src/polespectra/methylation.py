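"""CpG methylation stratification of mutation burden.

CpG sites are partitioned into 12 bins by methylation fraction beta:
bin 1 holds exactly beta = 0, bins 2..11 are the half-open deciles
(0, 0.1], ..., (0.9, 1.0), and bin 12 holds exactly beta = 1.  Per-bin
burden is C>T mutations at the binned cytosines (a G>A call at the
paired guanine collapses onto the same CpG unit) per megabase of CpG
sites.  A pentanucleotide composition normalisation re-weights each
bin's mutated-context counts by the ratio of genome-wide to within-bin
context frequencies:

    C = sum_k N(k) * f(k) / F(k)

which equals the raw count sum exactly when the bin's composition
matches the genome-wide composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_context import MutationCatalog, ReferenceGenome

N_BINS = 12

BIN_LABELS = (
    "[0]", "(0,0.1]", "(0.1,0.2]", "(0.2,0.3]", "(0.3,0.4]", "(0.4,0.5]",
    "(0.5,0.6]", "(0.6,0.7]", "(0.7,0.8]", "(0.8,0.9]", "(0.9,1.0)", "[1]",
)


@dataclass
class MethylationTrack:
    """Per-CpG methylation fractions (position of the plus-strand C, 1-based)."""

    sites: pd.DataFrame  # columns: chrom, pos, beta[, coverage]

    def __post_init__(self):
        df = self.sites
        required = {"chrom", "pos", "beta"}
        if not required.issubset(df.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if ((df["beta"] < 0) | (df["beta"] > 1)).any():
            raise ValueError("methylation fraction outside [0, 1]")
        self.sites = df.reset_index(drop=True)

    def __len__(self):
        return len(self.sites)

    def validate_cpg(self, genome: ReferenceGenome) -> "MethylationTrack":
        """Keep only sites that are a C immediately followed by G on the plus strand."""
        keep = []
        for r in self.sites.itertuples(index=False):
            seq = genome.sequences.get(r.chrom, "")
            p = r.pos - 1
            keep.append(0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G")
        return MethylationTrack(self.sites[np.array(keep, dtype=bool)])

    def filter_coverage(self, min_coverage: int) -> "MethylationTrack":
        if "coverage" not in self.sites.columns:
            raise ValueError("track has no coverage column")
        return MethylationTrack(self.sites[self.sites["coverage"] > min_coverage])

    def mask_regions(self, regions: Mapping[str, list[tuple[int, int]]]) -> "MethylationTrack":
        """Restrict to sites inside 0-based half-open regions (e.g. a timing stratum)."""
        keep = np.zeros(len(self.sites), dtype=bool)
        for i, r in enumerate(self.sites.itertuples(index=False)):
            for s, e in regions.get(r.chrom, ()):
                if s <= r.pos - 1 < e:
                    keep[i] = True
                    break
        return MethylationTrack(self.sites[keep])


def read_methylation_bedgraph(path) -> MethylationTrack:
    """Read a bedGraph-like TSV: chrom, start (0-based), end, beta[, coverage].

    The C is taken at ``start``; a two-column variant (chrom, pos, beta)
    with 1-based pos is also accepted when the third column is a fraction.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] >= 4:
        out = pd.DataFrame({"chrom": df[0], "pos": df[1].astype(int) + 1, "beta": df[3].astype(float)})
        if df.shape[1] >= 5:
            out["coverage"] = df[4].astype(int)
    elif df.shape[1] == 3:
        out = pd.DataFrame({"chrom": df[0], "pos": df[1].astype(int), "beta": df[2].astype(float)})
    else:
        raise ValueError("need at least 3 columns")
    return MethylationTrack(out)


def methylation_bin(beta: np.ndarray) -> np.ndarray:
    """Bin index 1..12 per site: [0], (0,0.1], .., (0.9,1.0), [1]."""
    beta = np.asarray(beta, dtype=float)
    if ((beta < 0) | (beta > 1)).any():
        raise ValueError("beta outside [0, 1]")
    # guard against representation noise at the decile edges
    dec = np.ceil(np.round(beta * 10, 9)).astype(int)
    bins = np.clip(dec, 1, 10) + 1
    bins[beta == 0] = 1
    bins[beta == 1] = 12
    return bins


def bin_cpgs_by_methylation(track: MethylationTrack) -> dict[int, pd.DataFrame]:
    """Partition a validated track into the 12 methylation bins."""
    bins = methylation_bin(track.sites["beta"].to_numpy())
    out = {}
    for b in range(1, N_BINS + 1):
        out[b] = track.sites[bins == b].reset_index(drop=True)
    return out


def _cpg_ct_mutation_bins(catalog: MutationCatalog, site_bin: dict[tuple[str, int], int]) -> np.ndarray:
    """Per-bin counts of C>T mutations at binned CpGs (G>A at the paired G included)."""
    counts = np.zeros(N_BINS + 1, dtype=np.int64)
    for r in catalog.df.itertuples(index=False):
        if r.ref == "C" and r.alt == "T":
            b = site_bin.get((r.chrom, r.pos))
        elif r.ref == "G" and r.alt == "A":
            b = site_bin.get((r.chrom, r.pos - 1))
        else:
            continue
        if b is not None:
            counts[b] += 1
    return counts[1:]


@dataclass
class MethylBinProfile:
    """Per-bin CpG site counts, mutation counts and rates for one sample group."""

    group: str
    table: pd.DataFrame  # columns: bin, label, site_count, mutation_count, rate_per_mb

    @property
    def rates(self) -> np.ndarray:
        return self.table["rate_per_mb"].to_numpy()


def mutation_rate_per_bin(
    catalogs: Mapping[str, MutationCatalog],
    bins: dict[int, pd.DataFrame],
    per_sample_mean: bool = False,
) -> dict[str, MethylBinProfile]:
    """CpG C>T mutations per Mb of CpG sites, per methylation bin and group.

    Default pools each group's samples; ``per_sample_mean`` instead
    averages per-sample rates.  Empty bins get NaN rates.
    """
    site_bin: dict[tuple[str, int], int] = {}
    site_counts = np.zeros(N_BINS, dtype=np.int64)
    for b, df in bins.items():
        site_counts[b - 1] = len(df)
        for r in df.itertuples(index=False):
            site_bin[(r.chrom, r.pos)] = b

    out = {}
    for group, catalog in catalogs.items():
        if per_sample_mean:
            per = [
                _cpg_ct_mutation_bins(c, site_bin) for c in catalog.per_sample().values()
            ]
            muts = np.mean(per, axis=0) if per else np.zeros(N_BINS)
        else:
            muts = _cpg_ct_mutation_bins(catalog, site_bin)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(site_counts > 0, 1e6 * muts / site_counts, np.nan)
        out[group] = MethylBinProfile(
            group=group,
            table=pd.DataFrame(
                {
                    "bin": np.arange(1, N_BINS + 1),
                    "label": BIN_LABELS,
                    "site_count": site_counts,
                    "mutation_count": muts,
                    "rate_per_mb": rate,
                }
            ),
        )
    return out


def relative_burden(
    profiles: Mapping[str, MethylBinProfile], reference_group: str
) -> pd.DataFrame:
    """Per-bin rate ratios against a reference group (reference ratios all 1).

    Bins where the reference rate is zero or undefined come out NaN.
    """
    if reference_group not in profiles:
        raise KeyError(f"reference group {reference_group!r} absent")
    ref = profiles[reference_group].rates
    data = {"bin": np.arange(1, N_BINS + 1)}
    for g, prof in profiles.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            data[g] = np.where(ref > 0, prof.rates / ref, np.nan)
    return pd.DataFrame(data)


def _cpg_penta_contexts(sites: pd.DataFrame, genome: ReferenceGenome) -> pd.Series:
    """NNCGN pentanucleotide context per CpG site (plus strand, N windows dropped)."""
    out = []
    for r in sites.itertuples(index=False):
        seq = genome.sequences[r.chrom]
        p = r.pos - 1
        if 2 <= p <= len(seq) - 3:
            ctx = seq[p - 2 : p + 3]
            if "N" not in ctx:
                out.append(ctx)
    return pd.Series(out, dtype=str)


def context_composition_per_bin(
    bins: dict[int, pd.DataFrame], genome: ReferenceGenome
) -> pd.DataFrame:
    """Per-bin proportion of each NNCGN pentanucleotide context (sums to 1)."""
    cols = {}
    for b, sites in bins.items():
        ctx = _cpg_penta_contexts(sites, genome)
        cols[b] = ctx.value_counts(normalize=True) if len(ctx) else pd.Series(dtype=float)
    return pd.DataFrame(cols).fillna(0.0).sort_index()


@dataclass
class PentaNormalization:
    """Composition-normalised mutation value C for one methylation bin."""

    C: float
    raw: int  # sum of N(k)
    percent_change: float  # 100 * (C - raw) / raw

    @property
    def shrinks(self) -> bool:
        return self.C < self.raw


def penta_normalized_rate(
    bin_sites: pd.DataFrame,
    catalog: MutationCatalog,
    genome: ReferenceGenome,
    genome_weights: pd.Series | None = None,
    all_sites: pd.DataFrame | None = None,
) -> PentaNormalization:
    """Re-weight a bin's CpG C>T mutation count by context composition.

    ``genome_weights`` (f) are pentanucleotide frequencies over all CpG
    sites (sums to 1); provide them directly or via ``all_sites``.  The
    bin's own frequencies (F) come from ``bin_sites``.  Mutated contexts
    absent from the bin's composition (F=0, N>0) are an error.
    """
    if genome_weights is None:
        if all_sites is None:
            raise ValueError("need genome_weights or all_sites")
        genome_weights = _cpg_penta_contexts(all_sites, genome).value_counts(normalize=True)
    F = _cpg_penta_contexts(bin_sites, genome).value_counts(normalize=True)

    site_set = {(r.chrom, r.pos) for r in bin_sites.itertuples(index=False)}
    N: dict[str, int] = {}
    for r in catalog.df.itertuples(index=False):
        if r.ref == "C" and r.alt == "T":
            chrom, pos = r.chrom, r.pos
        elif r.ref == "G" and r.alt == "A":
            chrom, pos = r.chrom, r.pos - 1
        else:
            continue
        if (chrom, pos) in site_set:
            seq = genome.sequences[chrom]
            p = pos - 1
            if 2 <= p <= len(seq) - 3:
                ctx = seq[p - 2 : p + 3]
                if "N" not in ctx:
                    N[ctx] = N.get(ctx, 0) + 1

    C = 0.0
    for ctx, n in N.items():
        Fk = float(F.get(ctx, 0.0))
        if Fk == 0.0:
            raise ValueError(f"context {ctx} mutated in bin but absent from bin composition")
        C += n * float(genome_weights.get(ctx, 0.0)) / Fk
    raw = sum(N.values())
    pct = 100.0 * (C - raw) / raw if raw else 0.0
    return PentaNormalization(C=C, raw=raw, percent_change=pct)
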