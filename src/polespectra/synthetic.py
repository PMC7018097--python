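"""Seeded synthetic cohorts with the statistical structure of POLE-mutant genomes.

Every analysis input can be generated here with known ("planted") truth:
a random genome with CpG islands, per-CpG methylation fractions,
a sinusoidal replication-timing landscape with analytic left/right
breakpoints, gene models, CTCF-like motif anchors, nucleosome dyads, and
per-sample mutation catalogs drawn from a 96-channel signature with
optional effect modifiers (methylation dependence of CpG C>T, leading-
strand bias, depletion at motifs and exons, minor-groove-in excess, and
a plantable recurrent hotspot).  All randomness flows from one integer
seed through ``numpy.random.default_rng``; a fixed seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._channels import BASES, canonical_contexts, _channel_lut, channel_labels
from .genome_context import MutationCatalog, ReferenceGenome
from .methylation import MethylationTrack
from .nucleosome import DyadSet, default_phase_map
from .regional import AnchorSet, GeneModel
from .replication import ReplicationDirectionMap, TimingTrack

TIMING_LO, TIMING_HI = -4.51712, 80.6964  # range of the source timing profile


# ---------------------------------------------------------------------------
# signatures

def pole_like_signature(group: str, k: int = 1) -> np.ndarray:
    """A 96-channel signature emulating one mutant group's spectrum shape.

    Peaks follow the POLE proofreading-deficiency pattern (C>A at TCT,
    T>G at TTT, C>T at TCG); the V411L-like shape carries more CpG C>T,
    the P286R-like shape more TCT C>A.  ``flat`` is uniform.
    """
    labels = channel_labels(k)
    v = np.full(len(labels), 0.15 / len(labels))
    peaks = {
        "P286R": {"T[C>A]T": 0.34, "T[T>G]T": 0.26, "T[C>T]G": 0.05, "T[C>T]T": 0.06,
                  "A[C>T]G": 0.03, "C[C>T]G": 0.03, "G[C>T]G": 0.03, "T[C>A]A": 0.05},
        "V411L": {"T[C>A]T": 0.16, "T[T>G]T": 0.11, "T[C>T]G": 0.22, "A[C>T]G": 0.10,
                  "C[C>T]G": 0.08, "G[C>T]G": 0.08, "T[C>T]T": 0.05},
        "Other-Exo": {"T[C>A]T": 0.26, "T[T>G]T": 0.19, "T[C>T]G": 0.12, "A[C>T]G": 0.05,
                      "C[C>T]G": 0.04, "G[C>T]G": 0.04, "T[C>T]T": 0.05},
        "MSS": {"A[C>T]G": 0.07, "C[C>T]G": 0.07, "G[C>T]G": 0.07, "T[C>T]G": 0.07},
        "flat": {},
    }
    if group not in peaks:
        raise KeyError(f"unknown signature archetype {group!r}")
    idx = {lab: i for i, lab in enumerate(labels)}
    for lab, wt in peaks[group].items():
        v[idx[lab]] += wt
    return v / v.sum()


# ---------------------------------------------------------------------------
# configuration

@dataclass
class HotspotSpec:
    """A plantable recurrent site with per-group carriage probabilities."""

    carriage: dict[str, float]  # group -> Bernoulli carriage probability
    context: str = "TTCGA"  # site is the centre C of this pentanucleotide
    label: str = "hotspot"


@dataclass
class GroupSpec:
    name: str
    n_samples: int
    signature: str | np.ndarray = "flat"
    n_mutations: int = 20_000


@dataclass
class GeneratorConfig:
    """All the study-condition knobs, with defaults at the emulated scale."""

    seed: int = 0
    genome_length: int = 5_000_000
    gc_fraction: float = 0.41
    cpg_island_rate: float = 1 / 25_000  # islands per bp
    cpg_island_length: int = 300
    # methylation mixture: spikes at 0 and 1 plus a Beta body, so all 12
    # bins (including the degenerate [0] and [1] bins) are populated
    meth_spike0: float = 0.06
    meth_spike1: float = 0.14
    meth_beta_a: float = 4.0
    meth_beta_b: float = 1.6
    # landscape
    timing_step: int = 10_000
    timing_period: int = 2_000_000
    n_genes: int = 100
    motif_spacing: int = 50_000
    dyad_spacing: int = 5_000
    # effect knobs (defaults reproduce the study's qualitative structure)
    methylation_slope: float = 0.0  # 1.0 -> CpG C>T odds proportional to beta
    strand_bias: dict[str, float] = field(default_factory=dict)  # e.g. {"C>A": 4.0}
    ctcf_depletion: float = 1.0  # multiplicative factor within the radius
    ctcf_radius: int = 110  # bp around the motif centre
    exon_depletion: float = 1.0
    minor_in_excess: float = 1.0
    hotspot: HotspotSpec | None = None
    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("P286R", 5, "P286R"),
            GroupSpec("V411L", 5, "V411L"),
            GroupSpec("Other-Exo", 5, "Other-Exo"),
        ]
    )


# ---------------------------------------------------------------------------
# genome and methylation

def simulate_genome(config: GeneratorConfig, rng: np.random.Generator | None = None) -> ReferenceGenome:
    """IID bases at the configured GC fraction plus Poisson-placed CpG islands."""
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    if not (0 < config.gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=config.genome_length, p=probs)
    n_islands = rng.poisson(config.genome_length * config.cpg_island_rate)
    L = config.cpg_island_length
    if n_islands and config.genome_length > L + 2:
        starts = rng.integers(0, config.genome_length - L, size=n_islands)
        for s in np.sort(starts):
            # CpG-dense island: ~30% of dinucleotide slots forced to CG
            slots = np.arange(s, s + L - 1, 2)
            chosen = slots[rng.random(len(slots)) < 0.3]
            codes[chosen] = 1
            codes[chosen + 1] = 2
    seq = "".join(BASES[c] for c in codes)
    return ReferenceGenome({"chr1": seq})


def simulate_methylation(
    genome: ReferenceGenome,
    config: GeneratorConfig,
    rng: np.random.Generator,
    cold_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    cold_factor: float = 0.1,
) -> MethylationTrack:
    """Per-CpG beta from a {0}/{1}/Beta mixture; optional cold regions scale beta down."""
    frames = []
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        cpg = np.where((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]  # 0-based C
        u = rng.random(len(cpg))
        beta = rng.beta(config.meth_beta_a, config.meth_beta_b, size=len(cpg))
        beta[u < config.meth_spike0] = 0.0
        beta[(u >= config.meth_spike0) & (u < config.meth_spike0 + config.meth_spike1)] = 1.0
        if cold_regions and chrom in cold_regions:
            cold = np.zeros(len(arr), dtype=bool)
            for s, e in cold_regions[chrom]:
                cold[s:e] = True
            beta[cold[cpg]] *= cold_factor
        cov = rng.poisson(30, size=len(cpg)) + 1
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": cpg + 1, "beta": beta, "coverage": cov}
        ))
    return MethylationTrack(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# landscape

@dataclass
class Landscape:
    timing: TimingTrack
    direction_truth: ReplicationDirectionMap
    breakpoints: list[int]  # analytic extrema of the timing sinusoid
    genes: list[GeneModel]
    motifs: AnchorSet
    dyads: DyadSet


def simulate_landscape(genome: ReferenceGenome, config: GeneratorConfig,
                       rng: np.random.Generator) -> Landscape:
    """Sinusoidal timing (analytic breakpoints), genes, motifs and dyads."""
    chrom = next(iter(genome.sequences))
    L = genome.lengths[chrom]
    step, period = config.timing_step, config.timing_period
    if L < 5 * step:
        raise ValueError("genome too short for the timing step")
    mid, amp = (TIMING_LO + TIMING_HI) / 2, (TIMING_HI - TIMING_LO) / 2
    starts = np.arange(0, L - step + 1, step)
    x = starts + step / 2
    vals = mid + amp * np.sin(2 * np.pi * x / period)
    timing = TimingTrack(pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + step, "value": vals}
    ))
    # derivative of sin is cos: positive (right-replicating) on
    # (-period/4, period/4) mod period; extrema at period/4 + j*period/2
    slope = np.cos(2 * np.pi * x / period)
    direction = np.where(slope > 0, "right", "left")
    truth = ReplicationDirectionMap(pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + step, "direction": direction}
    ))
    breakpoints = [int(period / 4 + j * period / 2) for j in range(int(L / (period / 2)) + 1)
                   if period / 4 + j * period / 2 < L]

    genes: list[GeneModel] = []
    cursor = 2_000
    for i in range(config.n_genes):
        n_ex = int(rng.integers(3, 7))
        ex_lens = rng.integers(80, 400, size=n_ex)
        in_lens = rng.integers(400, 2_000, size=n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        if cursor + span + 2_000 > L:
            break
        exons = []
        p = cursor
        for j in range(n_ex):
            exons.append((p, p + int(ex_lens[j])))
            p += int(ex_lens[j]) + (int(in_lens[j]) if j < n_ex - 1 else 0)
        utr5 = min(60, int(ex_lens[0]) // 3)
        utr3 = min(60, int(ex_lens[-1]) // 3)
        strand = "+" if rng.random() < 0.5 else "-"
        cds_start = exons[0][0] + (utr5 if strand == "+" else utr3)
        cds_end = exons[-1][1] - (utr3 if strand == "+" else utr5)
        genes.append(GeneModel(f"gene{i}", chrom, strand, exons, cds_start, cds_end))
        cursor = exons[-1][1] + int(rng.integers(2_000, 8_000))

    n_motifs = max(2, int(L / config.motif_spacing))
    centers = np.sort(rng.integers(1_500, L - 1_500, size=n_motifs))
    strands = rng.choice(["+", "-"], size=n_motifs)
    motifs = AnchorSet([(chrom, int(c) + 1, str(s)) for c, s in zip(centers, strands)],
                       flank=1000, kind="ctcf_motif")

    dpos = np.arange(500, L - 500, config.dyad_spacing)
    dpos = dpos + rng.integers(-200, 200, size=len(dpos))
    dyads = DyadSet([(chrom, int(p)) for p in dpos if 100 < p < L - 100], default_phase_map())
    return Landscape(timing, truth, breakpoints, genes, motifs, dyads)


# ---------------------------------------------------------------------------
# mutation sampling

def _position_channel_weights(
    genome: ReferenceGenome,
    chrom: str,
    signature: np.ndarray,
    k: int,
    config: GeneratorConfig,
    methylation: MethylationTrack | None,
    landscape: Landscape | None,
    ctx_abundance: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(L, 3) channel weights per position plus the (L, 3) channel codes.

    Column j of the codes array holds the channel of the j-th alternative
    pyrimidine alt for the position's collapsed context (-1 at N/edge).
    Weights are the signature probability of each channel divided by the
    genome abundance of the channel's context, so that channel totals
    (not per-site odds) follow the signature.
    """
    ctx = genome.context_indices(chrom, k)
    lut = _channel_lut(k)  # (n_ctx, 4) -> channel or -1
    slots = np.array([[c for c in row if c >= 0] for row in lut], dtype=np.int64)  # (n_ctx, 3)
    valid = ctx >= 0
    codes = np.full((len(ctx), 3), -1, dtype=np.int64)
    codes[valid] = slots[ctx[valid]]
    w = np.zeros((len(ctx), 3), dtype=np.float64)
    w[valid] = signature[codes[valid]]
    if ctx_abundance is not None:
        denom = np.where(ctx_abundance > 0, ctx_abundance, 1.0)
        w[valid] /= denom[ctx[valid], None]

    seq = np.frombuffer(genome.sequences[chrom].encode(), dtype=np.uint8)
    is_pyr = (seq == ord("C")) | (seq == ord("T"))

    if methylation is not None and config.methylation_slope > 0:
        s = config.methylation_slope
        beta = np.full(len(seq), np.nan)
        sub = methylation.sites[methylation.sites["chrom"] == chrom]
        beta[sub["pos"].to_numpy() - 1] = sub["beta"].to_numpy()
        plus_c = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
        ct_col = _ct_slot_column(codes, ctx, k)
        # plus-strand CpG C: beta at own position; minus-strand CpG G: beta at p-1
        factor = np.ones(len(seq))
        pc = np.where(plus_c)[0]
        factor[pc] = (1 - s) + s * np.nan_to_num(beta[pc], nan=0.5)
        pg = pc + 1
        factor[pg] = (1 - s) + s * np.nan_to_num(beta[pc], nan=0.5)
        rows = np.where(factor != 1.0)[0]
        cols = ct_col[rows]
        ok = cols >= 0
        w[rows[ok], cols[ok]] *= factor[rows[ok]]

    if config.strand_bias and landscape is not None:
        left = np.zeros(len(seq), dtype=bool)
        right = np.zeros(len(seq), dtype=bool)
        for r in landscape.direction_truth.regions.itertuples(index=False):
            if r.chrom != chrom:
                continue
            if r.direction == "left":
                left[r.start : r.end] = True
            elif r.direction == "right":
                right[r.start : r.end] = True
        labels = channel_labels(k)
        for mtype, fac in config.strand_bias.items():
            ref, alt = mtype.split(">")
            chan_ids = np.array(
                [i for i, lab in enumerate(labels) if f"[{ref}>{alt}]" in lab]
            )
            target = np.isin(codes, chan_ids)  # (L, 3) slots of this type
            boost_left = left & is_pyr
            boost_right = right & ~is_pyr
            w[boost_left] = np.where(target[boost_left], w[boost_left] * fac, w[boost_left])
            w[boost_right] = np.where(target[boost_right], w[boost_right] * fac, w[boost_right])

    if landscape is not None and config.ctcf_depletion != 1.0:
        mask = np.zeros(len(seq), dtype=bool)
        for c, p, _ in landscape.motifs.anchors:
            if c == chrom:
                mask[max(0, p - 1 - config.ctcf_radius) : p + config.ctcf_radius] = True
        w[mask] *= config.ctcf_depletion

    if landscape is not None and config.exon_depletion != 1.0:
        mask = np.zeros(len(seq), dtype=bool)
        for g in landscape.genes:
            if g.chrom == chrom:
                for s0, e0 in g.exons:
                    mask[s0:e0] = True
        w[mask] *= config.exon_depletion

    if landscape is not None and config.minor_in_excess != 1.0:
        mask = np.zeros(len(seq), dtype=bool)
        offs = np.array([o for o, ph in landscape.dyads.phase_map.items() if ph == "minor_in"])
        for c, p in landscape.dyads.dyads:
            if c == chrom:
                cols = p - 1 + offs
                cols = cols[(cols >= 0) & (cols < len(seq))]
                mask[cols] = True
        w[mask] *= config.minor_in_excess

    return w, codes


def _ct_slot_column(codes: np.ndarray, ctx: np.ndarray, k: int) -> np.ndarray:
    """Per-position slot column holding the C>T channel (-1 where absent)."""
    labels = channel_labels(k)
    is_ct = np.array(["[C>T]" in lab for lab in labels] + [False])  # -1 -> False
    hit = is_ct[codes]  # (L, 3)
    col = np.full(len(codes), -1, dtype=np.int64)
    rows, cols = np.where(hit)
    col[rows] = cols
    return col


def simulate_mutations(
    genome: ReferenceGenome,
    signature: np.ndarray | str,
    n: int,
    seed: int | np.random.Generator,
    sample_id: str = "S0",
    config: GeneratorConfig | None = None,
    methylation: MethylationTrack | None = None,
    landscape: Landscape | None = None,
    k: int = 1,
) -> MutationCatalog:
    """Draw exactly ``n`` distinct-site SNVs from a signature with modifiers.

    Sites are sampled without replacement with probability proportional
    to the signature weight of their channel, multiplied by the active
    effect modifiers; the alt at each site follows the (modified)
    channel weights.  Raises when fewer than ``n`` sites have positive
    weight.
    """
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(signature, str):
        signature = pole_like_signature(signature, k)
    signature = np.asarray(signature, dtype=float)

    from .genome_context import count_context_abundance

    abundance = count_context_abundance(genome, k=k).as_array()
    records = []
    chrom_names = list(genome.sequences)
    weights_all, codes_all, bounds = [], [], [0]
    for chrom in chrom_names:
        w, codes = _position_channel_weights(
            genome, chrom, signature, k, config, methylation, landscape,
            ctx_abundance=abundance,
        )
        weights_all.append(w)
        codes_all.append(codes)
        bounds.append(bounds[-1] + len(w))
    W = np.vstack(weights_all)
    C = np.vstack(codes_all)
    tw = W.sum(axis=1)
    positive = np.where(tw > 0)[0]
    if len(positive) < n:
        raise ValueError(f"only {len(positive)} candidate sites with positive weight for n={n}")
    # Gumbel top-n gives a without-replacement weighted sample
    keys = np.log(tw[positive]) + rng.gumbel(size=len(positive))
    pick = positive[np.argpartition(-keys, n - 1)[:n]]
    u = rng.random(n)
    cum = np.cumsum(W[pick], axis=1)
    cum /= cum[:, -1:]
    slot = (u[:, None] > cum).sum(axis=1)
    chan = C[pick, slot]

    labels = channel_labels(k)
    alt_pyr = np.array([lab.split(">")[1][0] for lab in labels])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for gpos, ch in zip(pick, chan):
        ci = np.searchsorted(bounds, gpos, side="right") - 1
        chrom = chrom_names[ci]
        pos0 = int(gpos - bounds[ci])
        ref = genome.sequences[chrom][pos0]
        alt = alt_pyr[ch] if ref in "CT" else comp[alt_pyr[ch]]
        records.append((sample_id, chrom, pos0 + 1, ref, alt))
    records.sort(key=lambda r: (r[1], r[2]))
    return MutationCatalog(pd.DataFrame(records, columns=MutationCatalog.COLUMNS))


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticBundle:
    """Everything one run of the generator produced, plus the planted truth."""

    config: GeneratorConfig
    genome: ReferenceGenome
    methylation: MethylationTrack
    landscape: Landscape
    catalogs: dict[str, MutationCatalog]  # sample -> catalog
    groups: dict[str, str]  # sample -> group
    truth: dict

    def group_catalog(self, group: str) -> MutationCatalog:
        dfs = [c.df for s, c in self.catalogs.items() if self.groups[s] == group]
        return MutationCatalog(pd.concat(dfs, ignore_index=True))

    def cohort_catalog(self) -> MutationCatalog:
        return MutationCatalog(pd.concat([c.df for c in self.catalogs.values()], ignore_index=True))


def find_hotspot_site(genome: ReferenceGenome, context: str = "TTCGA") -> tuple[str, int, str, str]:
    """First occurrence of ``context``; the site is its centre C>T."""
    k = len(context) // 2
    for chrom, seq in genome.sequences.items():
        i = seq.find(context)
        if i >= 0:
            return (chrom, i + k + 1, context[k], "T")
    raise ValueError(f"context {context} absent from genome")


def simulate_cohort(config: GeneratorConfig) -> SyntheticBundle:
    """Full bundle: genome, tracks, landscape and per-sample catalogs."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    methylation = simulate_methylation(genome, config, rng)
    landscape = simulate_landscape(genome, config, rng)

    hotspot_site = None
    if config.hotspot is not None:
        hotspot_site = find_hotspot_site(genome, config.hotspot.context)

    catalogs: dict[str, MutationCatalog] = {}
    groups: dict[str, str] = {}
    carriers: dict[str, list[str]] = {}
    for gspec in config.groups:
        sig = (
            pole_like_signature(gspec.signature)
            if isinstance(gspec.signature, str)
            else np.asarray(gspec.signature, dtype=float)
        )
        carriers[gspec.name] = []
        for i in range(gspec.n_samples):
            sid = f"{gspec.name}_{i}"
            cat = simulate_mutations(
                genome, sig, gspec.n_mutations, rng, sample_id=sid,
                config=config, methylation=methylation, landscape=landscape,
            )
            if hotspot_site is not None:
                prob = config.hotspot.carriage.get(gspec.name, 0.0)
                if rng.random() < prob:
                    chrom, pos, ref, alt = hotspot_site
                    extra = pd.DataFrame(
                        [(sid, chrom, pos, ref, alt)], columns=MutationCatalog.COLUMNS
                    )
                    cat = MutationCatalog(pd.concat([extra, cat.df], ignore_index=True))
                    carriers[gspec.name].append(sid)
            catalogs[sid] = cat
            groups[sid] = gspec.name
    truth = {
        "seed": config.seed,
        "signatures": {g.name: (g.signature if isinstance(g.signature, str) else "custom")
                       for g in config.groups},
        "methylation_slope": config.methylation_slope,
        "strand_bias": dict(config.strand_bias),
        "ctcf_depletion": config.ctcf_depletion,
        "ctcf_radius": config.ctcf_radius,
        "exon_depletion": config.exon_depletion,
        "minor_in_excess": config.minor_in_excess,
        "breakpoints": landscape.breakpoints,
        "hotspot_site": hotspot_site,
        "hotspot_carriers": carriers,
    }
    return SyntheticBundle(config, genome, methylation, landscape, catalogs, groups, truth)


# ---------------------------------------------------------------------------
# writers (standard text formats)

def write_fasta(genome: ReferenceGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_maf(catalog: MutationCatalog, path) -> None:
    df = catalog.df.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode", "chrom": "Chromosome",
            "pos": "Start_Position", "ref": "Reference_Allele", "alt": "Tumor_Seq_Allele2",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_methylation_bedgraph(track: MethylationTrack, path) -> None:
    df = track.sites
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["pos"] - 1, "end": df["pos"], "beta": df["beta"]}
    )
    if "coverage" in df.columns:
        out["coverage"] = df["coverage"]
    out.to_csv(path, sep="\t", index=False, header=False)


def write_timing_bedgraph(track: TimingTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", index=False, header=False)


def write_anchors_bed(anchors: AnchorSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, center, strand in anchors.anchors:
            fh.write(f"{chrom}\t{center - 1}\t{center}\tanchor\t0\t{strand}\n")


def write_dyads_bed(dyads: DyadSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in dyads.dyads:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")


def write_genes_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons)
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.cds_start}\t{g.cds_end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def write_truth_json(bundle: SyntheticBundle, path) -> None:
    with open(path, "w") as fh:
        json.dump(bundle.truth, fh, indent=1, default=str)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Emit the bundle as the standard text formats the analyses read."""
    import os

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    write_fasta(bundle.genome, j("genome.fa"))
    write_maf(bundle.cohort_catalog(), j("mutations.maf"))
    write_methylation_bedgraph(bundle.methylation, j("methylation.bedgraph"))
    write_timing_bedgraph(bundle.landscape.timing, j("timing.bedgraph"))
    write_anchors_bed(bundle.landscape.motifs, j("motifs.bed"))
    write_dyads_bed(bundle.landscape.dyads, j("dyads.bed"))
    write_genes_bed12(bundle.landscape.genes, j("genes.bed"))
    pd.DataFrame(sorted(bundle.groups.items()), columns=["sample", "group"]).to_csv(
        j("groups.tsv"), sep="\t", index=False
    )
    write_truth_json(bundle, j("truth.json"))
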