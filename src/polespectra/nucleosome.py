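"""Mutation-rate periodicity around nucleosome dyads.

Nucleosomal DNA (offsets -73..+73 around the dyad) alternates, with the
~10.3-bp helical period, between stretches whose minor groove faces the
histone core ("minor in") and stretches facing away ("minor out").  The
phase assignment per dyad offset is an editable configuration table; the
packaged default (``minor_groove_phase.synthetic.tsv``) is a synthetic
stand-in derived purely from the 10.3-bp period, not from structural
data, and users with a crystallography-derived table should supply it.

Observed per-phase rates are compared against the same context-expected
model used for anchor profiles (f = M/A over the dyad territory), giving
a relative increase observed/expected - 1 per phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._channels import canonical_contexts
from .genome_context import MutationCatalog, ReferenceGenome

NUCLEOSOME_HALF = 73
PHASES = ("minor_in", "minor_out")


def default_phase_map() -> dict[int, str]:
    """Packaged synthetic minor-groove phase table (offset -> phase)."""
    with resources.files("polespectra.data").joinpath(
        "minor_groove_phase.synthetic.tsv"
    ).open() as fh:
        return load_phase_map(fh)


def load_phase_map(path_or_handle) -> dict[int, str]:
    """Read a phase-map TSV with columns offset, phase."""
    df = pd.read_csv(path_or_handle, sep="\t")
    out = {}
    for r in df.itertuples(index=False):
        off = int(r.offset)
        if abs(off) > NUCLEOSOME_HALF:
            continue
        out[off] = str(r.phase)
    return out


@dataclass
class DyadSet:
    """Nucleosome dyad positions plus the offset -> phase assignment."""

    dyads: list[tuple[str, int]]  # (chrom, 1-based dyad position)
    phase_map: dict[int, str]

    def __post_init__(self):
        if not self.dyads:
            raise ValueError("empty dyad set")


def read_dyads_bed(path, phase_map: dict[int, str] | None = None) -> DyadSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    dyads = [(str(r[0]), (int(r[1]) + int(r[2])) // 2 + 1) for r in df.itertuples(index=False)]
    return DyadSet(dyads, phase_map or default_phase_map())


def assign_minor_groove_phase(dyads: DyadSet) -> dict[str, list[tuple[str, int]]]:
    """Genomic positions per phase, one entry per dyad occurrence.

    Positions under overlapping dyad footprints appear once per dyad,
    consistent with stacked profiling.
    """
    out: dict[str, list[tuple[str, int]]] = {p: [] for p in PHASES}
    for chrom, dpos in dyads.dyads:
        for off, phase in dyads.phase_map.items():
            if phase in out:
                out[phase].append((chrom, dpos + off))
    return out


@dataclass
class PeriodicityResult:
    table: pd.DataFrame  # phase, bp, observed, expected, obs_rate, exp_rate, relative_increase

    def relative_increase(self, phase: str) -> float:
        row = self.table[self.table["phase"] == phase]
        return float(row["relative_increase"].iloc[0])


def periodicity_rates(
    catalog: MutationCatalog,
    dyads: DyadSet,
    genome: ReferenceGenome,
    k: int = 1,
) -> PeriodicityResult:
    """Observed vs context-expected mutation rate per minor-groove phase.

    The expected model redistributes each dyad window's own mutations
    over its positions with weights proportional to f = M/A computed on
    the pooled dyad territory, then pools the per-position expectation
    by phase.
    """
    W = 2 * NUCLEOSOME_HALF + 1
    nctx = len(canonical_contexts(k))
    bychrom = {
        chrom: np.sort(g["pos"].to_numpy())
        for chrom, g in catalog.df.groupby("chrom", sort=False)
    }

    phase_of_col = np.full(W, "", dtype=object)
    for off, ph in dyads.phase_map.items():
        phase_of_col[off + NUCLEOSOME_HALF] = ph

    windows = []
    M = np.zeros(nctx, dtype=np.int64)
    A = np.zeros(nctx, dtype=np.int64)
    for chrom, dpos in dyads.dyads:
        if chrom not in genome.sequences:
            continue
        idx = genome.context_indices(chrom, k)
        lo0 = dpos - 1 - NUCLEOSOME_HALF
        if lo0 < 0 or lo0 + W > len(idx):
            continue
        ctx = idx[lo0 : lo0 + W]
        pos = bychrom.get(chrom, np.empty(0, dtype=np.int64))
        a = np.searchsorted(pos, dpos - NUCLEOSOME_HALF, side="left")
        b = np.searchsorted(pos, dpos + NUCLEOSOME_HALF, side="right")
        cols = pos[a:b] - dpos + NUCLEOSOME_HALF
        cols = cols[ctx[cols] >= 0]
        valid = ctx >= 0
        A += np.bincount(ctx[valid], minlength=nctx)
        M += np.bincount(ctx[cols], minlength=nctx)
        windows.append((ctx, cols))

    with np.errstate(divide="ignore", invalid="ignore"):
        frel = np.where(A > 0, M / np.maximum(A, 1), 0.0)

    obs_cols = np.zeros(W, dtype=np.int64)
    exp_cols = np.zeros(W, dtype=float)
    for ctx, cols in windows:
        np.add.at(obs_cols, cols, 1)
        m = len(cols)
        if m == 0:
            continue
        w = np.where(ctx >= 0, frel[np.maximum(ctx, 0)], 0.0)
        s = w.sum()
        if s > 0:
            exp_cols += m * w / s

    n_windows = len(windows)
    rows = []
    for ph in PHASES:
        sel = phase_of_col == ph
        bp = int(sel.sum()) * n_windows
        obs = int(obs_cols[sel].sum())
        exp = float(exp_cols[sel].sum())
        obs_rate = obs / bp if bp else float("nan")
        exp_rate = exp / bp if bp else float("nan")
        ri = obs / exp - 1.0 if exp > 0 else float("nan")
        rows.append((ph, bp, obs, exp, obs_rate, exp_rate, ri))
    return PeriodicityResult(
        pd.DataFrame(
            rows,
            columns=["phase", "bp", "observed", "expected", "obs_rate", "exp_rate", "relative_increase"],
        )
    )
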