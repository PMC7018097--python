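"""Calibration and recovery experiments on synthetic cohorts.

Each function here runs one self-contained experiment that scores an
analysis module against the generator's planted truth (or against an
exact independent computation), returning the measured quantity.  They
are the package's own validation battery: the synthetic data carry the
statistical structure the analyses assume, so these experiments check
that every estimator recovers what was planted, at the problem sizes a
single CPU handles in seconds to minutes.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .genome_context import MutationCatalog, count_context_abundance
from .hotspots import (
    bh_fdr,
    contingency_from_counts,
    enrichment_tests,
    fisher_exact,
    group_proportions,
)
from .methylation import bin_cpgs_by_methylation, mutation_rate_per_bin, penta_normalized_rate, relative_burden
from .regional import AnchorSet, expected_profile
from .replication import call_replication_direction, strand_asymmetry
from .spectrum import build_spectrum
from .synthetic import (
    GeneratorConfig,
    pole_like_signature,
    simulate_genome,
    simulate_landscape,
    simulate_methylation,
    simulate_mutations,
)

#: published colorectal-cohort carriage counts for the TP53 R213* hotspot
COLORECTAL_CARRIAGE = {"P286R": (10, 6), "other_POLE": (6, 25), "wild_type": (163, 7135)}
#: published endometrial-cohort carriage counts (POLE mutants)
ENDOMETRIAL_POLE_CARRIAGE = (11, 61)  # 11 of 72


def published_contingency_summary() -> dict[str, float]:
    """Carriage percentages and the P286R-vs-other-POLE Fisher p from the
    published colorectal / endometrial contingency counts."""
    t = contingency_from_counts(COLORECTAL_CARRIAGE)
    props = group_proportions(t)
    a, b = COLORECTAL_CARRIAGE["P286R"]
    c, d = COLORECTAL_CARRIAGE["other_POLE"]
    _, p = fisher_exact([[a, b], [c, d]])
    em = contingency_from_counts({"POLE": ENDOMETRIAL_POLE_CARRIAGE})
    return {
        "p286r_pct": props["P286R"],
        "other_pole_pct": props["other_POLE"],
        "wild_type_pct": props["wild_type"],
        "endometrial_pole_pct": group_proportions(em)["POLE"],
        "p286r_vs_other_pole_fisher_p": p,
    }


def expected_profile_conservation(seed: int, n_windows: int = 1000, flank: int = 100) -> dict:
    """Worst per-window |sum(expected) - sum(observed)| over random windows."""
    cfg = GeneratorConfig(seed=seed, genome_length=500_000)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(cfg, rng)
    cat = simulate_mutations(genome, "P286R", 20_000, seed=rng, config=cfg)
    L = genome.lengths["chr1"]
    centers = rng.integers(flank + 2, L - flank - 2, size=n_windows)
    strands = rng.choice(["+", "-"], size=n_windows)
    worst = 0.0
    for c, s in zip(centers, strands):
        prof = expected_profile(cat, AnchorSet([("chr1", int(c) + 1, str(s))], flank), genome)
        worst = max(worst, abs(prof.expected.sum() - prof.observed.sum()))
    stacked = expected_profile(
        cat, AnchorSet([("chr1", int(c) + 1, str(s)) for c, s in zip(centers, strands)], flank),
        genome,
    )
    worst = max(worst, abs(stacked.expected.sum() - stacked.observed.sum()))
    return {"max_abs_error": worst, "n": n_windows}


def _fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p by integer enumeration (rational arithmetic)."""
    N, r1, r2, c1 = a + b + c + d, a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    pa = nums[a - lo]
    total = sum(v for v in nums if v * 10**7 <= pa * (10**7 + 1))
    return float(Fraction(total, comb(N, c1)))


def fisher_exhaustive_equivalence(n_max: int = 60) -> dict:
    """Largest |p_impl - p_oracle| over every 2x2 table with total <= n_max."""
    worst = 0.0
    count = 0
    for N in range(0, n_max + 1):
        for a in range(N + 1):
            for b in range(N - a + 1):
                for c in range(N - a - b + 1):
                    d = N - a - b - c
                    _, p = fisher_exact([[a, b], [c, d]])
                    po = _fisher_enumeration_oracle(a, b, c, d)
                    worst = max(worst, abs(p - po))
                    count += 1
    return {"max_abs_diff": worst, "n": count}


def signature_roundtrip(seed: int, n: int = 100_000, genome_length: int = 5_000_000) -> dict:
    """Cosine similarity between a sampling signature and its re-estimate."""
    cfg = GeneratorConfig(seed=seed, genome_length=genome_length)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(cfg, rng)
    sig = pole_like_signature("P286R")
    cat = simulate_mutations(genome, sig, n, seed=rng, config=cfg)
    est = build_spectrum(cat, genome).proportions
    cos = float(np.dot(est, sig) / (np.linalg.norm(est) * np.linalg.norm(sig)))
    return {"cosine": cos, "n": n}


def penta_normalization_identity(seed: int) -> dict:
    """|C - sum(N)| when the bin's composition equals the genome-wide one."""
    cfg = GeneratorConfig(seed=seed, genome_length=100_000)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(cfg, rng)
    meth = simulate_methylation(genome, cfg, rng).validate_cpg(genome)
    cat = simulate_mutations(genome, "V411L", 3_000, seed=rng, config=cfg)
    res = penta_normalized_rate(meth.sites, cat, genome, all_sites=meth.sites)
    return {"abs_error": abs(res.C - res.raw), "n": res.raw}


def strand_asymmetry_recovery(seed: int, n: int = 10_000, bias: float = 4.0) -> dict:
    """Recover a planted leading-strand C>A bias as A ~ +/- log2(bias)."""
    cfg = GeneratorConfig(
        seed=seed, genome_length=1_000_000, timing_period=500_000,
        strand_bias={"C>A": bias},
    )
    rng = np.random.default_rng(seed)
    genome = simulate_genome(cfg, rng)
    landscape = simulate_landscape(genome, cfg, rng)
    cat = simulate_mutations(genome, "P286R", n, seed=rng, config=cfg, landscape=landscape)
    called = call_replication_direction(landscape.timing, smoothing_window=cfg.timing_step)
    res = strand_asymmetry(cat, called, "C>A").set_index("direction")
    return {"A_left": float(res.loc["left", "A"]), "A_right": float(res.loc["right", "A"]), "n": n}


def methylation_dependence_recovery(seed: int, n_per_group: int = 30_000) -> dict:
    """Planted beta-proportional CpG C>T rate: monotone bin rates and a flat
    cross-group rate ratio when both groups share the dependence."""
    cfg = GeneratorConfig(seed=seed, genome_length=1_000_000, methylation_slope=1.0)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(cfg, rng)
    meth = simulate_methylation(genome, cfg, rng).validate_cpg(genome)
    big = simulate_mutations(genome, "V411L", n_per_group, seed=rng, config=cfg,
                             methylation=meth, sample_id="big")
    small = simulate_mutations(genome, "V411L", n_per_group // 2, seed=rng, config=cfg,
                               methylation=meth, sample_id="small")
    bins = bin_cpgs_by_methylation(meth)
    profs = mutation_rate_per_bin({"big": big, "small": small}, bins)
    rates = profs["big"].rates[1:11]  # deciles (0,0.1] .. (0.9,1.0)
    rho = float(stats.spearmanr(np.arange(len(rates)), rates).statistic)
    ratios = relative_burden(profs, "big").loc[1:10, "small"].to_numpy()
    x = np.arange(len(ratios), dtype=float)
    ok = np.isfinite(ratios)
    fit = stats.linregress(x[ok], ratios[ok])
    return {
        "spearman_rho": rho,
        "ratio_slope": float(fit.slope),
        "ratio_slope_p": float(fit.pvalue),
        "n": n_per_group,
    }


def ctcf_null_calibration(seed: int, n_reps: int = 100, n_mut: int = 20_000,
                          pair_bin_bp: int = 10) -> dict:
    """Fraction of context-only replicates where the central observed-vs-
    expected paired test stays non-significant (alpha = 0.05).

    Paired differences are aggregated to ``pair_bin_bp`` resolution
    before the signed-rank test: at shallow stack depths the per-bp
    differences are Poisson-skewed, which by itself inflates the
    signed-rank rejection rate; summing to bins with a few counts each
    restores the symmetric null the test assumes.  The catalog size is
    hypermutant-scale so the stacks carry counts like the data the
    analysis targets.
    """
    cfg = GeneratorConfig(seed=seed, genome_length=300_000, motif_spacing=10_000)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(cfg, rng)
    landscape = simulate_landscape(genome, cfg, rng)
    anchors = landscape.motifs.within(genome)
    ok = 0
    for _ in range(n_reps):
        cat = simulate_mutations(genome, "P286R", n_mut, seed=rng, config=cfg)
        prof = expected_profile(cat, anchors, genome)
        fl = prof.flank
        centre = slice(fl - 110, fl + 111)
        diff = prof.observed[centre].astype(float) - prof.expected[centre]
        if pair_bin_bp > 1:
            nb = len(diff) // pair_bin_bp
            diff = diff[: nb * pair_bin_bp].reshape(nb, pair_bin_bp).sum(axis=1)
        p = stats.wilcoxon(diff).pvalue
        if p > 0.05:
            ok += 1
    return {"nonsignificant_fraction": ok / n_reps, "n": n_reps}


def hotspot_enrichment_recovery(seed: int, n_reps: int = 200, n_null_hotspots: int = 46) -> dict:
    """Fraction of cohort replicates where the planted hotspot group is
    flagged at q <= 0.10 (and ranks first) among all screened hotspots.

    Group sizes and carriage probabilities follow the published cohort
    shape: 16 / 31 / 7298 samples at carriage 0.625 / 0.194 / 0.022; the
    null hotspots carry at the background rate in every group.
    """
    sizes = {"P286R": 16, "other_POLE": 31, "wild_type": 7298}
    planted = {"P286R": 0.625, "other_POLE": 0.194, "wild_type": 0.022}
    background = 0.022
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        tables = []
        for h in range(n_null_hotspots + 1):
            carr = planted if h == 0 else {g: background for g in sizes}
            counts = {}
            for g, ng in sizes.items():
                a = int(rng.binomial(ng, carr[g]))
                counts[g] = (a, ng - a)
            tables.append(contingency_from_counts(counts, hotspot=("chr1", h + 1, "C", "T")))
        res = enrichment_tests(tables)
        sub = res[res["grouping"] == "P286R_vs_rest"].reset_index(drop=True)
        planted_row = sub[sub["hotspot"] == "chr1:1C>T"].iloc[0]
        top = sub.sort_values("p").iloc[0]
        if planted_row["q"] <= 0.10 and top["hotspot"] == "chr1:1C>T":
            hits += 1
    return {"recovery_fraction": hits / n_reps, "n": n_reps}
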