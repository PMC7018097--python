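"""Recurrent-hotspot discovery and group-enrichment statistics.

A hotspot is an identical substitution (chrom, pos, ref, alt) carried by
at least ``min_recurrence`` distinct samples.  Enrichment of a hotspot
in a sample group is tested on 2x2 carriage tables with the two-sided
Fisher exact test (probability-mass convention) and Benjamini-Hochberg
FDR across hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome_context import MutationCatalog, ReferenceGenome


@dataclass
class HotspotTable:
    """Recurrent sites with per-site carrier sample sets."""

    table: pd.DataFrame  # chrom, pos, ref, alt, label, recurrence
    carriers: dict[tuple[str, int, str, str], frozenset[str]]

    def __len__(self):
        return len(self.table)


def find_hotspots(
    cohort: MutationCatalog | Mapping[str, MutationCatalog],
    min_recurrence: int = 20,
    labels: Mapping[tuple[str, int, str, str], str] | None = None,
) -> HotspotTable:
    """Sites carried by >= ``min_recurrence`` distinct samples.

    Carriage is counted once per sample regardless of how many times the
    sample's catalog lists the site.
    """
    if isinstance(cohort, Mapping):
        if not cohort:
            raise ValueError("empty cohort")
        df = pd.concat(
            [c.df.assign(sample_id=s) for s, c in cohort.items()], ignore_index=True
        )
    else:
        df = cohort.df
        if df.empty:
            raise ValueError("empty cohort")
    grp = df.groupby(["chrom", "pos", "ref", "alt"])["sample_id"].agg(lambda s: frozenset(s))
    carriers = {k: v for k, v in grp.items() if len(v) >= min_recurrence}
    rows = [
        (c, p, r, a, (labels or {}).get((c, p, r, a), f"{c}:{p}{r}>{a}"), len(v))
        for (c, p, r, a), v in sorted(carriers.items())
    ]
    return HotspotTable(
        table=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "label", "recurrence"]),
        carriers=carriers,
    )


def read_hotspot_tsv(path) -> pd.DataFrame:
    """Hotspot list TSV: chrom, pos, ref, alt, label."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "ref": str, "alt": str})


@dataclass
class HotspotContingency:
    """Per-group (carriers, non-carriers) counts for one hotspot."""

    hotspot: tuple[str, int, str, str]
    groups: list[str]
    carriers: dict[str, int]
    non_carriers: dict[str, int]

    def group_size(self, g: str) -> int:
        return self.carriers[g] + self.non_carriers[g]

    def row(self, g: str) -> tuple[int, int]:
        return self.carriers[g], self.non_carriers[g]


def contingency(
    groups: Mapping[str, str],
    hotspot: tuple[str, int, str, str],
    cohort: MutationCatalog,
    group_order: Sequence[str] | None = None,
) -> HotspotContingency:
    """Carriage-by-group table for one hotspot.

    ``groups`` maps every cohort sample to its group label; a cohort
    sample without a label is an error.  Group sizes come from the label
    map, so samples with zero retained mutations still count.
    """
    unlabeled = set(cohort.sample_ids) - set(groups)
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} cohort samples have no group label")
    chrom, pos, ref, alt = hotspot
    df = cohort.df
    hit = df[(df["chrom"] == chrom) & (df["pos"] == pos) & (df["ref"] == ref) & (df["alt"] == alt)]
    carrier_samples = set(hit["sample_id"])
    order = list(group_order) if group_order else sorted(set(groups.values()))
    carriers = {g: 0 for g in order}
    sizes = {g: 0 for g in order}
    for s, g in groups.items():
        if g not in sizes:
            continue
        sizes[g] += 1
        if s in carrier_samples:
            carriers[g] += 1
    return HotspotContingency(
        hotspot=hotspot,
        groups=order,
        carriers=carriers,
        non_carriers={g: sizes[g] - carriers[g] for g in order},
    )


def contingency_from_counts(
    counts: Mapping[str, tuple[int, int]], hotspot=("", 0, "", "")
) -> HotspotContingency:
    """Build a contingency object directly from (carriers, non-carriers) counts."""
    order = list(counts)
    return HotspotContingency(
        hotspot=tuple(hotspot),
        groups=order,
        carriers={g: int(c) for g, (c, _) in counts.items()},
        non_carriers={g: int(n) for g, (_, n) in counts.items()},
    )


def group_proportions(table: HotspotContingency, ndigits: int | None = None) -> dict[str, float]:
    """Percent carriage per group: 100*a/(a+b); empty groups are NaN."""
    out = {}
    for g in table.groups:
        a, b = table.row(g)
        p = 100.0 * a / (a + b) if a + b else float("nan")
        out[g] = round(p, ndigits) if ndigits is not None else p
    return out


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of non-negative ints.

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability is <= that of the observed table
    times (1 + 1e-7).  Odds ratio is a*d/(b*c) (+inf when b*c = 0 with
    a*d > 0, NaN for a degenerate margin).  A table with an all-zero
    margin has p = 1 by convention.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N, r1, c1 = a + b + c + d, a + b, a + c
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    if r1 == 0 or r1 == N or c1 == 0 or c1 == N:
        return odds, 1.0
    lo = max(0, c1 - (N - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    p = float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def _groupings(groups: list[str]):
    """All pairwise and one-vs-rest 2x2 groupings over >= 2 groups."""
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            yield f"{g1}_vs_{g2}", g1, (g2,)
        rest = tuple(g for g in groups if g != g1)
        if len(rest) > 1:
            yield f"{g1}_vs_rest", g1, rest


def enrichment_tests(tables: Sequence[HotspotContingency]) -> pd.DataFrame:
    """Fisher tests for every hotspot under every pairwise / one-vs-rest grouping.

    BH q-values are computed across hotspots within each grouping (the
    multiplicity is the number of hotspots tested).
    """
    rows = []
    for t in tables:
        label = f"{t.hotspot[0]}:{t.hotspot[1]}{t.hotspot[2]}>{t.hotspot[3]}"
        for gname, g1, rest in _groupings(t.groups):
            a, b = t.row(g1)
            c = sum(t.carriers[g] for g in rest)
            d = sum(t.non_carriers[g] for g in rest)
            odds, p = fisher_exact([[a, b], [c, d]])
            rows.append((label, gname, a, b, c, d, odds, p))
    df = pd.DataFrame(rows, columns=["hotspot", "grouping", "a", "b", "c", "d", "odds_ratio", "p"])
    df["q"] = np.nan
    for gname, sub in df.groupby("grouping"):
        df.loc[sub.index, "q"] = bh_fdr(sub["p"].to_numpy())
    return df


def ttcga_normalized_fraction(catalog: MutationCatalog, genome: ReferenceGenome) -> float:
    """Percent of CpG C>T mutations falling at TTCGA pentanucleotide sites.

    Numerator: distinct mutated sites whose collapsed pentanucleotide
    channel is TT[C>T]GA; denominator: all C>T mutations in an NNCGN
    (CpG) pentanucleotide context, both strands collapsed.
    """
    ttcga_sites = set()
    nncgn = 0
    for r in catalog.df.itertuples(index=False):
        if r.chrom not in genome.sequences:
            continue
        seq = genome.sequences[r.chrom]
        p = r.pos - 1
        if not 2 <= p <= len(seq) - 3:
            continue
        ctx = seq[p - 2 : p + 3]
        if "N" in ctx:
            continue
        if r.ref == "C" and r.alt == "T":
            pass
        elif r.ref == "G" and r.alt == "A":
            from ._channels import revcomp

            ctx = revcomp(ctx)
        else:
            continue
        if ctx[2] == "C" and ctx[3] == "G":
            nncgn += 1
            if ctx == "TTCGA":
                ttcga_sites.add((r.chrom, r.pos))
    return 100.0 * len(ttcga_sites) / nncgn if nncgn else float("nan")


def ttcga_fraction_from_counts(ttcga_mutated_sites: int, nncgn_mutations: int) -> float:
    """Same statistic from precomputed per-group counts (e.g. a published table)."""
    if nncgn_mutations <= 0:
        return float("nan")
    return 100.0 * ttcga_mutated_sites / nncgn_mutations
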