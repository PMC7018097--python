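"""Reference-genome and mutation-catalog I/O and sequence-context extraction.

Coordinate conventions: mutation positions are 1-based inclusive (MAF/VCF
convention); genomic intervals are 0-based half-open (BED convention).
The functions in this module are the only places where the two meet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._channels import (
    canonical_contexts,
    channel_of,
    context_index_array,
)

logger = logging.getLogger(__name__)

MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}

_VALID = frozenset("ACGT")


class FastaFormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


class BoundaryError(IndexError):
    """Requested window extends past a chromosome end."""


class MutationRecord(NamedTuple):
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class ReferenceGenome:
    """Uppercase in-memory genome with cached context-index arrays."""

    sequences: dict[str, str]
    _ctx_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def base(self, chrom: str, pos: int) -> str:
        """Plus-strand base at a 1-based position."""
        seq = self.sequences[chrom]
        if not 1 <= pos <= len(seq):
            raise BoundaryError(f"{chrom}:{pos} outside [1, {len(seq)}]")
        return seq[pos - 1]

    def context_indices(self, chrom: str, k: int) -> np.ndarray:
        """Cached per-position pyrimidine-collapsed context indices."""
        key = (chrom, k)
        if key not in self._ctx_cache:
            self._ctx_cache[key] = context_index_array(self.sequences[chrom], k)
        return self._ctx_cache[key]


def read_fasta(path) -> ReferenceGenome:
    """Load a (multi-record) FASTA into memory, uppercased."""
    try:
        fa = Fasta(str(path), rebuild=True, build_index=True)
    except Exception as exc:  # pyfaidx raises several types on malformed input
        raise FastaFormatError(f"cannot parse FASTA {path}: {exc}") from exc
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    if not seqs:
        raise FastaFormatError(f"no sequences in {path}")
    return ReferenceGenome(seqs)


class MutationCatalog:
    """Ordered catalog of single-base substitutions across samples.

    Backed by a DataFrame with columns sample_id, chrom, pos (1-based),
    ref, alt.  Duplicate (sample_id, chrom, pos) entries are dropped on
    construction, keeping the first.
    """

    COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]

    def __init__(self, records):
        if isinstance(records, pd.DataFrame):
            df = records[self.COLUMNS].copy()
        else:
            df = pd.DataFrame(list(records), columns=self.COLUMNS)
        df["pos"] = df["pos"].astype(np.int64)
        bad = ~(df["ref"].isin(_VALID) & df["alt"].isin(_VALID)) | (df["ref"] == df["alt"])
        if bad.any():
            raise ValueError(f"{int(bad.sum())} records are not valid single-base substitutions")
        df = df.drop_duplicates(subset=["sample_id", "chrom", "pos"], keep="first")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield MutationRecord(*row)

    @property
    def records(self) -> list[MutationRecord]:
        return list(self)

    @property
    def sample_ids(self) -> set[str]:
        return set(self.df["sample_id"].unique())

    def subset_samples(self, samples: Iterable[str]) -> "MutationCatalog":
        samples = set(samples)
        return MutationCatalog(self.df[self.df["sample_id"].isin(samples)])

    def per_sample(self) -> dict[str, "MutationCatalog"]:
        return {s: MutationCatalog(g) for s, g in self.df.groupby("sample_id", sort=True)}

    def merge(self, other: "MutationCatalog") -> "MutationCatalog":
        return MutationCatalog(pd.concat([self.df, other.df], ignore_index=True))

    def validate_against(self, genome: ReferenceGenome, strict: bool = False) -> "MutationCatalog":
        """Drop (or, with strict=True, reject) records whose ref mismatches the genome."""
        keep = np.ones(len(self.df), dtype=bool)
        for i, r in enumerate(self.df.itertuples(index=False)):
            if r.chrom not in genome.sequences or not 1 <= r.pos <= genome.lengths[r.chrom]:
                keep[i] = False
                continue
            keep[i] = genome.base(r.chrom, r.pos) == r.ref
        n_bad = int((~keep).sum())
        if n_bad:
            if strict:
                raise ValueError(f"{n_bad} records mismatch the reference genome")
            logger.warning("%d records mismatch the reference genome; dropped", n_bad)
        return MutationCatalog(self.df[keep])


def _read_maf_like(path, sample_id=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS.values() if c not in df.columns and c != "Tumor_Sample_Barcode"]
    if missing:
        raise SchemaError(f"missing required MAF columns: {missing}")
    if "Tumor_Sample_Barcode" not in df.columns:
        if sample_id is None:
            raise SchemaError("no Tumor_Sample_Barcode column and no sample_id given")
        df["Tumor_Sample_Barcode"] = sample_id
    out = pd.DataFrame({k: df[v] for k, v in MAF_COLUMNS.items()})
    out["pos"] = pd.to_numeric(out["pos"])
    return out


def _read_vcf_minimal(path, sample_id=None) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        default = sample_id or (vcf_samples[0] if vcf_samples else None)
        if default is None:
            raise SchemaError("VCF has no sample column; pass sample_id")
        for rec in vf:
            alts = rec.alts or ()
            rows.append((default, rec.chrom, rec.pos, rec.ref, ",".join(alts)))
    return pd.DataFrame(rows, columns=MutationCatalog.COLUMNS)


def read_mutations(path, dialect: str = "maf_like_tsv", sample_id: str | None = None) -> MutationCatalog:
    """Read an SNV catalog from a MAF-like TSV or a minimal VCF.

    Non-SNV rows (indels, MNVs, multi-allelic ALTs) are dropped and the
    count logged; duplicate (sample, chrom, pos) rows are deduplicated.
    """
    if dialect == "maf_like_tsv":
        df = _read_maf_like(path, sample_id)
    elif dialect == "vcf_minimal":
        df = _read_vcf_minimal(path, sample_id)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    is_snv = df["ref"].isin(_VALID) & df["alt"].isin(_VALID) & (df["ref"] != df["alt"])
    n_drop = int((~is_snv).sum())
    if n_drop:
        logger.info("%d non-SNV rows dropped from %s", n_drop, path)
    return MutationCatalog(df[is_snv])


def extract_context(genome: ReferenceGenome, chrom: str, pos: int, k: int) -> str:
    """Plus-strand sequence of length 2k+1 centred at a 1-based position."""
    seq = genome.sequences[chrom]
    if not (1 + k <= pos <= len(seq) - k):
        raise BoundaryError(f"{chrom}:{pos} too close to a sequence end for k={k}")
    return seq[pos - 1 - k : pos + k]


def collapse_channel(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Pyrimidine-stated (ref, alt, context) for a substitution in context."""
    return channel_of(ref, alt, context)


@dataclass
class ContextAbundance:
    """Counts of pyrimidine-collapsed contexts over a region set.

    Each genomic position with a full, N-free window is counted exactly
    once (plus and minus strand readings collapse onto one context).
    """

    k: int
    counts: dict[str, int]
    region_label: str = "genome"

    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        ctxs = canonical_contexts(self.k)
        return np.array([self.counts.get(c, 0) for c in ctxs], dtype=float)


def _region_mask(length: int, regions: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in regions:
        mask[max(0, start) : min(length, end)] = True
    return mask


def count_context_abundance(
    genome: ReferenceGenome,
    regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    k: int = 1,
    region_label: str = "genome",
) -> ContextAbundance:
    """Genome-wide (or region-restricted) context abundance.

    ``regions`` maps chromosome to 0-based half-open intervals; positions
    in overlapping intervals are still counted once.  Flanking bases of a
    window may extend beyond the region boundary (they come from the
    genome), but never beyond the chromosome.
    """
    ctxs = canonical_contexts(k)
    totals = np.zeros(len(ctxs), dtype=np.int64)
    for chrom, seq in genome.sequences.items():
        idx = genome.context_indices(chrom, k)
        if regions is not None:
            if chrom not in regions:
                continue
            sel = idx[_region_mask(len(seq), regions[chrom])]
        else:
            sel = idx
        sel = sel[sel >= 0]
        if len(sel):
            totals += np.bincount(sel, minlength=len(ctxs))
    return ContextAbundance(k=k, counts={c: int(n) for c, n in zip(ctxs, totals) if n}, region_label=region_label)
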