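"""Replication-direction calling, strand asymmetry and timing strata.

Left- and right-replicating regions come from the sign of the derivative
of a (smoothed) replication-timing profile: the leading strand of a
left-replicating region is the plus strand read 5'->3', so a
proofreading-deficient leading-strand polymerase leaves complementary
substitution types unbalanced between the two region classes.  The
asymmetry of one pyrimidine-stated type is A = log2(N/n), with N the
count of the type as stated (e.g. C>A) and n its reverse complement
(G>T) within a region class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._channels import SUBSTITUTION_TYPES, COMPLEMENT
from .genome_context import MutationCatalog

logger = logging.getLogger(__name__)

#: the study's five timing-class boundaries, late to early (HepG2 profile units)
DEFAULT_TIMING_BOUNDARIES = (-4.51712, 30.8225, 44.19, 55.8262, 63.7717, 80.6964)


@dataclass
class TimingTrack:
    """Non-overlapping, sorted intervals with a real-valued timing signal."""

    intervals: pd.DataFrame  # chrom, start, end (0-based half-open), value

    def __post_init__(self):
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, g in df.groupby("chrom"):
            s, e = g["start"].to_numpy(), g["end"].to_numpy()
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping timing intervals on {chrom}")
        self.intervals = df


def read_timing_bedgraph(path) -> TimingTrack:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    return TimingTrack(df)


@dataclass
class ReplicationDirectionMap:
    """Directions ('left' / 'right' / 'undefined') over timing intervals."""

    regions: pd.DataFrame  # chrom, start, end, direction

    def regions_of(self, direction: str) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        sub = self.regions[self.regions["direction"] == direction]
        for r in sub.itertuples(index=False):
            out.setdefault(r.chrom, []).append((r.start, r.end))
        return out


def call_replication_direction(
    track: TimingTrack, smoothing_window: int = 100_000, tolerance: float = 1e-6
) -> ReplicationDirectionMap:
    """Sign of the smoothed profile derivative per interval.

    Values are averaged over ``smoothing_window`` bp around each interval
    midpoint before central finite differencing; |slope| below
    ``tolerance`` (units/bp) is 'undefined'.  Chromosomes with a single
    interval are entirely undefined.
    """
    rows = []
    for chrom, g in track.intervals.groupby("chrom", sort=True):
        g = g.sort_values("start")
        x = ((g["start"] + g["end"]) / 2).to_numpy(dtype=float)
        v = g["value"].to_numpy(dtype=float)
        n = len(g)
        if n < 2:
            for r in g.itertuples(index=False):
                rows.append((chrom, r.start, r.end, "undefined"))
            continue
        half = smoothing_window / 2
        lo = np.searchsorted(x, x - half, side="left")
        hi = np.searchsorted(x, x + half, side="right")
        cs = np.concatenate([[0.0], np.cumsum(v)])
        vs = (cs[hi] - cs[lo]) / (hi - lo)
        d = np.empty(n)
        d[1:-1] = (vs[2:] - vs[:-2]) / (x[2:] - x[:-2])
        d[0] = (vs[1] - vs[0]) / (x[1] - x[0])
        d[-1] = (vs[-1] - vs[-2]) / (x[-1] - x[-2])
        direction = np.where(d < -tolerance, "left", np.where(d > tolerance, "right", "undefined"))
        for r, dd in zip(g.itertuples(index=False), direction):
            rows.append((chrom, r.start, r.end, dd))
    return ReplicationDirectionMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"]))


def _assign_direction(catalog: MutationCatalog, dmap: ReplicationDirectionMap) -> pd.Series:
    """Direction label per catalog record ('none' outside covered intervals)."""
    labels = np.full(len(catalog.df), "none", dtype=object)
    by_chrom = {c: g.sort_values("start") for c, g in dmap.regions.groupby("chrom")}
    for chrom, g in catalog.df.groupby("chrom", sort=False):
        reg = by_chrom.get(chrom)
        if reg is None:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        dirs = reg["direction"].to_numpy()
        pos0 = g["pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.maximum(j, 0)])
        labels[g.index.to_numpy()[ok]] = dirs[j[ok]]
    return pd.Series(labels, index=catalog.df.index)


@dataclass
class StrandAsymmetryResult:
    mutation_type: str  # e.g. "C>A"
    direction: str
    N: int  # pyrimidine-stated occurrences (plus strand)
    n: int  # complementary (purine-stated) occurrences
    A: float  # log2(N/n); NaN when undefined


def strand_asymmetry(
    catalog: MutationCatalog,
    directions: ReplicationDirectionMap,
    mutation_type: str | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """A = log2(N/n) per substitution type and replication direction.

    With the default pseudocount of 0, a zero N or n leaves A undefined
    (NaN) and the counts are still reported.
    """
    lab = _assign_direction(catalog, directions)
    df = catalog.df
    types = (
        [tuple(mutation_type.split(">"))] if mutation_type else list(SUBSTITUTION_TYPES)
    )
    rows = []
    for direction in ("left", "right"):
        sel = df[lab == direction]
        for ref, alt in types:
            cref, calt = COMPLEMENT[ref], COMPLEMENT[alt]
            N = int(((sel["ref"] == ref) & (sel["alt"] == alt)).sum())
            nn = int(((sel["ref"] == cref) & (sel["alt"] == calt)).sum())
            Np, np_ = N + pseudocount, nn + pseudocount
            A = float(np.log2(Np / np_)) if Np > 0 and np_ > 0 else float("nan")
            rows.append((f"{ref}>{alt}", direction, N, nn, A))
    return pd.DataFrame(rows, columns=["mutation_type", "direction", "N", "n", "A"])


def timing_bins(
    track: TimingTrack,
    catalog: MutationCatalog | None = None,
    boundaries: tuple[float, ...] = DEFAULT_TIMING_BOUNDARIES,
) -> pd.DataFrame:
    """Assign covered bases to timing classes and compute mutation density.

    Bins are half-open [b_i, b_{i+1}) except the last, which is closed at
    the right end; interval values outside the union are excluded (the
    count is logged).  Density is 10^6 x mutations / bp per bin.
    """
    b = np.asarray(boundaries, dtype=float)
    if not (np.diff(b) > 0).all():
        raise ValueError("boundaries must be strictly increasing")
    nb = len(b) - 1
    iv = track.intervals
    v = iv["value"].to_numpy(dtype=float)
    binid = np.searchsorted(b, v, side="right") - 1
    binid[v == b[-1]] = nb - 1  # closed right end of the last bin
    outside = (binid < 0) | (binid >= nb)
    if outside.any():
        logger.info("%d timing intervals outside the bin union excluded", int(outside.sum()))

    bp = np.zeros(nb, dtype=np.int64)
    muts = np.zeros(nb, dtype=np.int64)
    lengths = (iv["end"] - iv["start"]).to_numpy()
    for i in range(nb):
        bp[i] = lengths[binid == i].sum()
    if catalog is not None:
        sub = iv[~outside]
        dmap_like = pd.DataFrame(
            {"chrom": sub["chrom"], "start": sub["start"], "end": sub["end"],
             "direction": binid[~outside].astype(str)}
        )
        lab = _assign_direction(catalog, ReplicationDirectionMap(dmap_like))
        for i in range(nb):
            muts[i] = int((lab == str(i)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(bp > 0, 1e6 * muts / np.maximum(bp, 1), np.nan)
    return pd.DataFrame(
        {"bin": np.arange(1, nb + 1), "lo": b[:-1], "hi": b[1:], "bp": bp,
         "mutations": muts, "rate_per_mb": rate}
    )
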