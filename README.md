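# polespectra

Mutational-spectrum and regional mutation-rate analysis for cancer genomes
carrying POLE exonuclease-domain mutations.

Tumours with a damaged POLE proofreading domain (hotspot variants such as
P286R and V411L) are hypermutated with a distinctive signature — C>A at
TCT, C>T at TCG and T>G at TTT trinucleotides. Different POLE variants
leave measurably different spectra, and those differences propagate into
which driver mutations a tumour is likely to acquire: the TP53 R213*
nonsense mutation arises from a C>T change in a TTCGA context that P286R
genomes mutate preferentially. This package provides the analysis toolkit
for that kind of study, for computational cancer-genomics researchers:

- **Spectra** — 96/1536-channel pyrimidine-collapsed mutation spectra,
  genome-context normalisation, cosine similarity, hierarchical sample
  clustering, non-negative least-squares signature fits.
- **Methylation** — CpG C>T burden across 12 methylation bins
  ([0], (0,0.1] … (0.9,1.0), [1]), cross-group relative burden, and the
  pentanucleotide composition normalisation C = Σ N(k)·f(k)/F(k).
- **Regional profiles** — stacked observed and context-expected mutation
  counts around CTCF motifs (expected at position p is m·W_p with
  W_p = f_p/Σf_q and f = M/A), context-normalised TSS profiles, and
  mutation density across 8 gene parts × 20 bins.
- **Replication** — left/right-replicating regions from the derivative of
  a timing profile, strand asymmetry A = log₂(N/n), five timing-class
  densities.
- **Nucleosomes** — minor-groove-in vs minor-groove-out mutation rates
  against a context-expected baseline.
- **Hotspots** — recurrent-site discovery (≥20 carriers), carriage
  contingency tables, two-sided Fisher exact tests (probability-mass
  convention) and Benjamini–Hochberg FDR.
- **Synthetic cohorts** — a seeded generator producing every input
  (genome, methylation, timing, genes, motifs, dyads, per-sample
  catalogs) with plantable effects, so each estimator is validated by
  recovering known truth.

## Worked example

Contingency arithmetic on the published colorectal TP53 R213* carriage
table (carriers, non-carriers per group):

```python
from polespectra import contingency_from_counts, group_proportions, fisher_exact

tab = contingency_from_counts(
    {"P286R": (10, 6), "other_POLE": (6, 25), "wild_type": (163, 7135)})
print("carriage %:", {g: round(p, 1) for g, p in group_proportions(tab).items()})
odds, p = fisher_exact([[10, 6], [6, 25]])
print(f"P286R vs other POLE: OR = {odds:.2f}, two-sided p = {p:.6f}")
```

prints

```
carriage %: {'P286R': 62.5, 'other_POLE': 19.4, 'wild_type': 2.2}
P286R vs other POLE: OR = 6.94, two-sided p = 0.007855
```

— 62.5% of P286R tumours carry the hotspot versus 19.4% of other POLE
mutants and 2.2% of POLE wild-type tumours, and the P286R excess over the
other mutants is unlikely under independence (p ≈ 0.008).

A full synthetic round trip — simulate a three-group cohort, rebuild the
spectra and recover the planted groups by clustering:

```python
from polespectra import (GeneratorConfig, GroupSpec, HotspotSpec,
                         simulate_cohort, build_spectrum, cluster_samples)

cfg = GeneratorConfig(
    seed=7, genome_length=1_000_000,
    groups=[GroupSpec("P286R", 4, "P286R", 10_000),
            GroupSpec("V411L", 4, "V411L", 10_000),
            GroupSpec("Other-Exo", 4, "Other-Exo", 10_000)],
    hotspot=HotspotSpec(carriage={"P286R": 0.625, "V411L": 0.1, "Other-Exo": 0.1}))
bundle = simulate_cohort(cfg)

specs = [build_spectrum(cat, bundle.genome, label=sid)
         for sid, cat in bundle.catalogs.items()]
labels = cluster_samples(specs, n_groups=3).labels
ct = {g: build_spectrum(bundle.group_catalog(g), bundle.genome)
        .substitution_fractions()["C>T"]
      for g in ("P286R", "V411L", "Other-Exo")}
print("C>T fraction per group:", {g: round(f, 3) for g, f in ct.items()})
```

prints

```
C>T fraction per group: {'P286R': 0.227, 'V411L': 0.577, 'Other-Exo': 0.364}
```

with the twelve samples falling into three flat clusters that coincide
exactly with the planted groups — the V411L-like archetype carries the
highest C>T fraction, the contrast the spectrum analysis is built to
resolve.

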