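"""Stacked mutation profiles around anchors and gene-part mutation density.

The expected-mutation model: over all anchor windows, each sequence
context gets a relative mutability f = M/A (mutations observed in that
context / abundance of the context in the windows).  Within one window
carrying m mutations, position p gets weight Wp = f(p) / sum_q f(q), so
the window's expected counts m*Wp redistribute exactly its own m
mutations by context.  Stacked over windows, sum(expected) equals
sum(observed) by construction — the model answers "where within the
window" and not "how many".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._channels import _BASE_CODE, canonical_contexts, channel_index, context_index
from .genome_context import MutationCatalog, ReferenceGenome

logger = logging.getLogger(__name__)

#: focus channels for promoter profiles: the POLE signature peaks
DEFAULT_TSS_CHANNELS = ("T[C>A]T", "T[C>T]G", "T[T>G]T")

GENE_PARTS = (
    "5UTR", "first_exon", "first_intron", "middle_exon",
    "middle_intron", "last_intron", "last_exon", "3UTR",
)


@dataclass
class AnchorSet:
    """Stranded anchor centres with a fixed flank; windows must fit the genome."""

    anchors: list[tuple[str, int, str]]  # (chrom, 1-based centre, strand)
    flank: int
    kind: str = "ctcf_motif"

    def __post_init__(self):
        if not self.anchors:
            raise ValueError("empty anchor set")

    def __len__(self):
        return len(self.anchors)

    def within(self, genome: ReferenceGenome) -> "AnchorSet":
        """Drop anchors whose window would cross a chromosome end."""
        kept = [
            (c, p, s)
            for c, p, s in self.anchors
            if c in genome.lengths and p - self.flank >= 1 and p + self.flank <= genome.lengths[c]
        ]
        if len(kept) < len(self.anchors):
            logger.info("%d anchors dropped at chromosome ends", len(self.anchors) - len(kept))
        return AnchorSet(kept, self.flank, self.kind)


def read_bed_anchors(path, flank: int, kind: str = "ctcf_motif") -> AnchorSet:
    """BED3/BED6 to anchors; the centre is the interval midpoint."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    anchors = []
    for r in df.itertuples(index=False):
        center = (int(r[1]) + int(r[2])) // 2 + 1  # 1-based
        strand = str(r[5]) if len(r) > 5 and str(r[5]) in "+-" else "+"
        anchors.append((str(r[0]), center, strand))
    return AnchorSet(anchors, flank=flank, kind=kind)


@dataclass
class PositionProfile:
    """Observed (and optionally expected) mutation counts per aligned offset."""

    flank: int
    observed: np.ndarray
    expected: np.ndarray | None = None
    n_windows: int = 0
    total_mutations: int = 0  # context-assignable mutations inside windows

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        d = {"offset": self.offsets, "observed": self.observed}
        if self.expected is not None:
            d["expected"] = self.expected
        return pd.DataFrame(d)


def _positions_by_chrom(catalog: MutationCatalog) -> dict[str, np.ndarray]:
    """Sorted 1-based mutation positions per chromosome (with multiplicity)."""
    return {
        chrom: np.sort(g["pos"].to_numpy())
        for chrom, g in catalog.df.groupby("chrom", sort=False)
    }


def stack_profile(catalog: MutationCatalog, anchors: AnchorSet) -> PositionProfile:
    """Observed mutation counts per offset, stacked over all anchor windows.

    A mutation under two overlapping windows counts once per window, at
    each window's own offset; minus-strand anchors flip offsets so +x is
    always 3' of the anchor.
    """
    f = anchors.flank
    obs = np.zeros(2 * f + 1, dtype=np.int64)
    bychrom = _positions_by_chrom(catalog)
    total = 0
    for chrom, center, strand in anchors.anchors:
        pos = bychrom.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, center - f, side="left")
        hi = np.searchsorted(pos, center + f, side="right")
        off = pos[lo:hi] - center
        if strand == "-":
            off = -off
        np.add.at(obs, off + f, 1)
        total += hi - lo
    return PositionProfile(flank=f, observed=obs, n_windows=len(anchors), total_mutations=total)


def expected_profile(
    catalog: MutationCatalog,
    anchors: AnchorSet,
    genome: ReferenceGenome,
    k: int = 1,
) -> PositionProfile:
    """Context-expected mutation counts per offset (plus observed).

    f = M/A is computed over the same windows (per window occurrence);
    each window's m context-assignable mutations are redistributed by
    Wp = f(p)/sum f(q).  Mutations at N/edge contexts are excluded from
    both M and m, so sum(expected) == sum(observed) at machine tolerance.
    """
    fl = anchors.flank
    W = 2 * fl + 1
    nctx = len(canonical_contexts(k))
    bychrom = _positions_by_chrom(catalog)

    windows = []  # (ctx array oriented 5'->3', observed offsets array)
    M = np.zeros(nctx, dtype=np.int64)
    A = np.zeros(nctx, dtype=np.int64)
    for chrom, center, strand in anchors.anchors:
        idx = genome.context_indices(chrom, k)
        lo0 = center - 1 - fl
        ctx = idx[lo0 : lo0 + W]
        pos = bychrom.get(chrom, np.empty(0, dtype=np.int64))
        a = np.searchsorted(pos, center - fl, side="left")
        b = np.searchsorted(pos, center + fl, side="right")
        mut_off = pos[a:b] - center  # genomic-orientation offsets
        mut_ctx = ctx[mut_off + fl]
        ok = mut_ctx >= 0
        mut_off = mut_off[ok]
        if strand == "-":
            ctx = ctx[::-1]
            mut_off = -mut_off
        valid = ctx >= 0
        A += np.bincount(ctx[valid], minlength=nctx)
        M += np.bincount(mut_ctx[ok], minlength=nctx)
        windows.append((ctx, mut_off))

    with np.errstate(divide="ignore", invalid="ignore"):
        frel = np.where(A > 0, M / np.maximum(A, 1), 0.0)

    obs = np.zeros(W, dtype=np.int64)
    exp = np.zeros(W, dtype=float)
    total = 0
    for ctx, mut_off in windows:
        m = len(mut_off)
        np.add.at(obs, mut_off + fl, 1)
        total += m
        if m == 0:
            continue
        w = np.where(ctx >= 0, frel[np.maximum(ctx, 0)], 0.0)
        s = w.sum()
        if s > 0:
            exp += m * w / s
    return PositionProfile(
        flank=fl, observed=obs, expected=exp, n_windows=len(anchors), total_mutations=total
    )


def tss_profile(
    catalog: MutationCatalog,
    tss_anchors: AnchorSet,
    genome: ReferenceGenome,
    focus_channels: Sequence[str] = DEFAULT_TSS_CHANNELS,
    bin_size: int = 100,
) -> dict[str, pd.DataFrame]:
    """Context-normalised per-offset rates of focus channels around TSSs.

    For each focus channel (e.g. ``T[C>T]G``), the per-offset rate is
    (mutations of that channel at the offset) / (occurrences of the
    channel's context at the offset across windows); offsets where the
    context never occurs are NaN, not zero.  A ``binned`` frame carries
    raw per-channel counts in ``bin_size``-bp bins.
    """
    k = 1
    fl = tss_anchors.flank
    W = 2 * fl + 1
    cidx = context_index(k)
    chidx = channel_index(k)
    targets = []
    for lab in focus_channels:
        l, rest = lab.split("[", 1)
        sub, r = rest.split("]", 1)
        ctx = l + sub[0] + r
        targets.append((lab, cidx[ctx], chidx[lab]))

    ctx_occ = np.zeros((len(targets), W), dtype=np.int64)
    mut_hits = np.zeros((len(targets), W), dtype=np.int64)

    df = catalog.df
    from ._channels import COMPLEMENT, channel_codes_for

    mut_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, g in df.groupby("chrom", sort=False):
        if chrom not in genome.sequences:
            continue
        idx = genome.context_indices(chrom, k)
        pos = g["pos"].to_numpy()
        inb = (pos >= 1) & (pos <= len(idx))
        pos = pos[inb]
        ctx = idx[pos - 1]
        refs = g["ref"].to_numpy()[inb]
        alts = g["alt"].to_numpy()[inb]
        alt_pyr = np.array(
            [_BASE_CODE[a if r in "CT" else COMPLEMENT[a]] for r, a in zip(refs, alts)]
        )
        ok = ctx >= 0
        chan = np.full(len(pos), -1, dtype=np.int64)
        chan[ok] = channel_codes_for(ctx[ok], alt_pyr[ok], k)
        order = np.argsort(pos, kind="stable")
        mut_by_chrom[chrom] = (pos[order], chan[order])

    for chrom, center, strand in tss_anchors.anchors:
        idx = genome.context_indices(chrom, k)
        ctx = idx[center - 1 - fl : center + fl]
        if strand == "-":
            ctx = ctx[::-1]
        for t, (_, ci, _) in enumerate(targets):
            ctx_occ[t] += ctx == ci
        pos, chan = mut_by_chrom.get(chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))
        a = np.searchsorted(pos, center - fl, side="left")
        b = np.searchsorted(pos, center + fl, side="right")
        off = pos[a:b] - center
        if strand == "-":
            off = -off
        for o, ch in zip(off, chan[a:b]):
            for t, (_, _, chi) in enumerate(targets):
                if ch == chi:
                    mut_hits[t, o + fl] += 1

    offsets = np.arange(-fl, fl + 1)
    out: dict[str, pd.DataFrame] = {}
    for t, (lab, _, _) in enumerate(targets):
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(ctx_occ[t] > 0, mut_hits[t] / np.maximum(ctx_occ[t], 1), np.nan)
        out[lab] = pd.DataFrame(
            {"offset": offsets, "mutations": mut_hits[t], "context_sites": ctx_occ[t], "rate": rate}
        )
    bin_id = (offsets + fl) // bin_size
    nb = int(bin_id.max()) + 1
    binned = {"bin_start": -fl + bin_size * np.arange(nb)}
    for t, (lab, _, _) in enumerate(targets):
        binned[lab] = np.bincount(bin_id, weights=mut_hits[t], minlength=nb).astype(int)
    out["binned"] = pd.DataFrame(binned)
    return out


@dataclass
class GeneModel:
    """One gene: exon blocks plus CDS span (half-open, 0-based)."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted genomic order
    cds_start: int
    cds_end: int


def read_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    genes = []
    for r in df.itertuples(index=False):
        chrom, start = str(r[0]), int(r[1])
        name, strand = str(r[3]), str(r[5])
        thick_s, thick_e = int(r[6]), int(r[7])
        sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(r[11]).rstrip(",").split(",")]
        exons = [(start + s, start + s + L) for s, L in zip(starts, sizes)]
        genes.append(GeneModel(name, chrom, strand, exons, thick_s, thick_e))
    return genes


def _clip(ivs: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    return [(max(s, lo), min(e, hi)) for s, e in ivs if min(e, hi) > max(s, lo)]


def _gene_parts(g: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals per part, each part in transcription order."""
    exons = sorted(g.exons)
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    coding = _clip(exons, g.cds_start, g.cds_end)
    utr_left = _clip(exons, 0, g.cds_start)
    utr_right = _clip(exons, g.cds_end, 10**15)
    fwd = g.strand == "+"
    parts: dict[str, list[tuple[int, int]]] = {p: [] for p in GENE_PARTS}
    parts["5UTR"] = utr_left if fwd else utr_right[::-1]
    parts["3UTR"] = utr_right if fwd else utr_left[::-1]
    tx_coding = coding if fwd else coding[::-1]
    tx_introns = introns if fwd else introns[::-1]
    if tx_coding:
        parts["first_exon"] = [tx_coding[0]]
        if len(tx_coding) > 1:
            parts["last_exon"] = [tx_coding[-1]]
        parts["middle_exon"] = tx_coding[1:-1]
    if tx_introns:
        parts["first_intron"] = [tx_introns[0]]
        if len(tx_introns) > 1:
            parts["last_intron"] = [tx_introns[-1]]
        parts["middle_intron"] = tx_introns[1:-1]
    return parts


@dataclass
class GenePartProfile:
    """Pooled mutations/Mb over 8 gene parts x 20 bins."""

    table: pd.DataFrame  # part, bin, bp, mutations, rate_per_mb
    n_bins: int = 20

    def part_mean_rate(self, part: str) -> float:
        sub = self.table[self.table["part"] == part]
        bp = sub["bp"].sum()
        return float(1e6 * sub["mutations"].sum() / bp) if bp else float("nan")


def gene_part_profile(
    catalog: MutationCatalog,
    genes: list[GeneModel],
    n_bins: int = 20,
    min_length: int = 20,
) -> GenePartProfile:
    """Mutation density per gene part and per 20-bin position within the part.

    Each gene's part (its intervals concatenated 5'->3') shorter than
    ``min_length`` bp is discarded; the rest is cut into ``n_bins``
    near-equal bins (widths differ by at most 1 bp) and pooled across
    genes by (part, bin index).
    """
    bychrom = _positions_by_chrom(catalog)
    bp = np.zeros((len(GENE_PARTS), n_bins), dtype=np.int64)
    muts = np.zeros((len(GENE_PARTS), n_bins), dtype=np.int64)
    pix = {p: i for i, p in enumerate(GENE_PARTS)}

    for g in genes:
        pos = bychrom.get(g.chrom, np.empty(0, dtype=np.int64))
        for part, ivs in _gene_parts(g).items():
            L = sum(e - s for s, e in ivs)
            if L < min_length:
                continue
            widths = np.full(n_bins, L // n_bins, dtype=np.int64)
            widths[: L % n_bins] += 1
            edges = np.concatenate([[0], np.cumsum(widths)])
            bp[pix[part]] += widths
            cum = 0
            for s, e in ivs:
                a = np.searchsorted(pos, s + 1, side="left")
                b = np.searchsorted(pos, e, side="right")
                if b > a:
                    pos0 = pos[a:b] - 1
                    off = (pos0 - s) if g.strand == "+" else (e - 1 - pos0)
                    tx_off = cum + off
                    bins = np.searchsorted(edges, tx_off, side="right") - 1
                    np.add.at(muts[pix[part]], bins, 1)
                cum += e - s
    rows = []
    for p, i in pix.items():
        for b in range(n_bins):
            rate = 1e6 * muts[i, b] / bp[i, b] if bp[i, b] else np.nan
            rows.append((p, b, int(bp[i, b]), int(muts[i, b]), rate))
    return GenePartProfile(
        table=pd.DataFrame(rows, columns=["part", "bin", "bp", "mutations", "rate_per_mb"]),
        n_bins=n_bins,
    )
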