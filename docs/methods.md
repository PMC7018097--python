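# Methods

## Scope and model

`polespectra` re-implements, as a tested library, the bespoke computations
used to characterise the genomes of colorectal cancers carrying mutations in
the POLE exonuclease (proofreading) domain: context-resolved mutation
spectra, methylation-stratified and composition-normalised CpG mutation
rates, observed-versus-expected mutation profiles over regulatory and
structural genomic features, replication-strand asymmetry, and
driver-hotspot enrichment statistics. Every analysis can be exercised
end-to-end on seeded synthetic cohorts whose generative truth is known, so
each estimator is validated by parameter recovery rather than by comparison
to inaccessible patient data.

### Substitution channels

Every single-base substitution is stated with the mutated base read as a
pyrimidine: a purine-reference call is mapped onto the reverse-complement
strand, merging the two strand readings of one duplex event. With one
flanking base on each side this yields the standard 96 trinucleotide
channels (6 substitution types × 16 contexts); with two flanking bases,
1536 pentanucleotide channels. Channel order is fixed lexicographically by
(substitution type, context) so output files are bit-stable. Context
windows containing N, or running off a chromosome end, are excluded from
both numerators (mutation counts) and denominators (context abundance);
exclusions are tallied, never silently dropped.

Spectra are reported as counts, proportions, and optionally rates
normalised by genome-wide context abundance (count / abundance of the
channel's context). Sample similarity is the cosine of proportion vectors;
clustering is average-linkage agglomeration on 1 − cosine (ties broken by
input order, so the tree is deterministic). Signature contributions are fit
by non-negative least squares on proportions, reported renormalised to sum
to 1 alongside the residual norm; the signature matrix is user-supplied
input.

### Methylation stratification

CpG sites (validated against the reference as C followed by G on the plus
strand) are partitioned into 12 bins by methylation fraction β: bin 1 is
exactly β = 0, bins 2–11 are the right-closed deciles (0, 0.1] … (0.9, 1.0),
bin 12 is exactly β = 1. The degenerate end bins are kept separate because
fully unmethylated and fully methylated CpGs behave differently from their
neighbouring deciles. Per-bin burden counts C>T calls at binned cytosines —
a G>A call at the paired guanine collapses onto the same CpG unit — per
megabase of binned sites; groups pool samples by default (per-sample
averaging is available). Cross-group comparisons divide each group's
per-bin rate by a reference group's rate.

The pentanucleotide composition normalisation re-weights a bin's
mutated-context counts N(k) by the ratio of genome-wide CpG context
frequencies f(k) (Σf = 1) to the bin's own frequencies F(k) (ΣF = 1):

    C = Σ_k N(k) · f(k) / F(k)

C equals ΣN exactly when the bin's composition matches the genome-wide
composition (this identity is tested exactly), and shrinks bins inflated by
over-representation of hot contexts. A mutated context absent from the
bin's composition is impossible by construction (N is restricted to the
bin's own sites) and guarded as an error. Note that an NNCGN
pentanucleotide has 4³ = 64 realisations, since the fourth base is fixed
by the CpG.

### Expected-mutation model at anchors

For windows stacked around anchors (CTCF motif centres with ±1000 bp
flanks, nucleosome dyads with ±73 bp), each context receives a relative
mutability f = M/A — mutations observed in that context across all windows
divided by the context's abundance in the windows, both counted once per
window occurrence so overlapping windows stay consistent with stacking
semantics. Within one window carrying m context-assignable mutations,
position p gets weight W_p = f(p)/Σ_q f(q), and the window's expected
counts are m·W_p. The model therefore redistributes each window's own
mutations by context alone: Σ expected = Σ observed to machine precision,
which is the central conservation invariant and is tested per window and
stacked. Minus-strand anchors flip offsets so +x is always 3′ of the
anchor. The context width for f defaults to trinucleotide (matching the
96-channel framework); pentanucleotide is available via the `k` parameter.

TSS profiles are normalised differently: for each focus channel (defaults
are the POLE signature peaks T[C>A]T, T[C>T]G, T[T>G]T), the per-offset
rate is mutations of that channel at the offset divided by occurrences of
the channel's context at that offset across windows. Offsets where the
context never occurs are reported missing, not zero. Raw counts binned at
100 bp accompany the per-bp series.

### Gene parts

Each gene is split into eight parts — 5′UTR, first exon, first intron,
middle exon(s), middle intron(s), last intron, last exon, 3′UTR — from
BED12 exon blocks and the CDS span, ordered 5′→3′ on the transcribed
strand. All middle elements of a gene are pooled into one sequence per
part. Part sequences shorter than 20 bp are discarded; the rest are cut
into 20 near-equal bins (widths differ by at most 1 bp) and pooled across
genes by (part, bin), reporting mutations/Mb. Genes with fewer than three
exons contribute only to the parts they define.

### Replication direction, asymmetry and timing

Left/right-replicating regions are called from the sign of the derivative
of the replication-timing profile: values are averaged over a configurable
smoothing window (default 100 kb) around interval midpoints, centrally
differenced, and intervals with |slope| below 10⁻⁶ units/bp are left
undefined. Both knobs are parameters because the appropriate smoothing
depends on the profile's resolution. Strand asymmetry for a
pyrimidine-stated type is A = log₂(N/n) with N the count of the type as
stated and n its reverse complement within a region class; A is
antisymmetric under swapping, undefined (reported with counts) when either
count is zero, and no pseudocount is applied by default. Timing classes
default to the five late→early intervals of the source profile
([−4.51712, 30.8225), [30.8225, 44.19), [44.19, 55.8262),
[55.8262, 63.7717), [63.7717, 80.6964], last bin closed), with density in
mutations/Mb of covered sequence.

### Nucleosome periodicity

Offsets −73..+73 around each dyad are labelled minor-groove-in,
minor-groove-out or unassigned by an editable configuration table. The
packaged default, `minor_groove_phase.synthetic.tsv`, is a synthetic
stand-in derived purely from the 10.3-bp helical period (minor-in where
cos(2π·offset/10.3) ≥ 0.5, minor-out where ≤ −0.5); users with a
structure-derived table should supply their own. Observed per-phase rates
are compared with the same f = M/A expected model computed over the dyad
territory; the reported statistic is observed/expected − 1 per phase.
Positions under overlapping dyad footprints count once per dyad,
consistent with stacked profiling.

### Hotspot enrichment

A hotspot is an identical substitution carried by at least 20 distinct
samples (carriage counted once per sample). Carriage-by-group tables are
built from caller-supplied group labels; because the grouping behind the
published headline test is ambiguous, all pairwise and one-vs-rest 2×2
reductions are tested and reported explicitly. The Fisher exact test uses
the probability-mass two-sided convention (sum of hypergeometric
probabilities ≤ observed × (1 + 10⁻⁷)), implemented on
`scipy.stats.hypergeom` with explicit edge-case conventions (all-zero
margin → p = 1; odds ratio ad/bc, +∞ when bc = 0 with ad > 0) and verified
exhaustively against an exact integer-arithmetic enumeration for every 2×2
table with total ≤ 60. Benjamini–Hochberg q-values are computed across
hotspots within each grouping via `statsmodels`.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
human genome biology. A genome is i.i.d. bases at a configurable GC
fraction (default 0.41) with Poisson-placed CpG islands (300 bp, ~1 per
25 kb, ~30% of dinucleotide slots forced to CG). Methylation β per CpG is
drawn from a mixture — spikes at 0 (6%) and 1 (14%) plus a Beta(4, 1.6)
body — so all 12 bins, including the degenerate end bins, are populated,
matching the high-methylation skew of colon tissue. The replication
landscape is a sinusoid spanning the five default timing classes, with
analytically known extrema as direction breakpoints. Gene models have 3–6
exons with 5′/3′ UTRs; motif anchors and dyads are placed at configurable
densities.

Mutations are drawn per sample, without replacement within a sample,
with probability proportional to the signature weight of each site's
channel divided by the channel's context abundance — so expected channel
totals follow the signature vector itself and a spectrum built from the
catalog converges to it. Effect modifiers multiply site/alt weights:
CpG C>T odds scaled by (1−s) + s·β (s = 1 plants rate ∝ β); a per-type
strand bias applied to pyrimidine-stated events in left-replicating and
purine-stated events in right-replicating regions (a 4× bias yields
A = ±2); depletion factors within a radius of motif centres (default
110 bp) and in exons; a minor-groove-in excess; and a recurrent hotspot
planted by per-group Bernoulli carriage at a TTCGA site. Packaged
archetype signatures place the POLE proofreading-deficiency peaks
(C>A at TCT, T>G at TTT, C>T at TCG) with CpG-C>T mass highest in the
V411L-like archetype — the qualitative spectrum differences the analysis
is meant to resolve.

What the generator does not emulate: real chromatin context, repeat
structure, selection, clonal composition, indels/CNVs, or coverage
artefacts. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not performance on patient genomes.

## Numerical and procedural choices

- Coordinates: 1-based inclusive for mutations (MAF/VCF), 0-based
  half-open for intervals (BED); conversion happens only at readers.
- Duplicate (sample, chrom, pos) records are deduplicated keeping the
  first; multi-allelic VCF rows and non-SNVs are dropped with a logged
  count; reference mismatches warn-and-drop by default (strict mode
  raises).
- Empty spectra have undefined (NaN) proportions rather than zeros; empty
  methylation bins and zero-abundance contexts are NaN, never silently 0.
- Decile binning of β guards against representation noise by rounding
  10β to 9 decimals before taking the ceiling.
- The null calibration of the CTCF observed-vs-expected comparison
  aggregates paired differences to 10-bp bins before the Wilcoxon
  signed-rank test and uses hypermutant-scale catalogs (20k mutations over
  a 300-kb genome). At sub-count-per-bp stack depths the per-bp differences
  are Poisson-skewed, which inflates signed-rank rejection under a null
  where the expected model is demonstrably unbiased; a few counts per pair
  restore the symmetric null the test assumes. The planted-depletion test
  remains per-offset, where the signal dwarfs the skew.
- Validation problem sizes (a 300 kb–5 Mb genome, 10⁴–10⁵ mutations,
  100–200 replicates for calibration experiments) are chosen so the whole
  battery runs in minutes on one CPU while keeping sampling error well
  inside each tolerance.

## Known limitations

- The published headline Fisher p (0.0076) is not exactly reproduced by
  the standard probability-mass convention on the published carriage table
  ([[10,6],[6,25]] → 0.007855); the grouping/convention behind the printed
  value is not stated. The package reports its conventions explicitly.
- The published endometrial wild-type proportion ("0.006% (11/1973)") is
  internally inconsistent; the package reports computed proportions only.
- The minor-groove phase table is a synthetic stand-in (see above).
- Replication-direction calling is a derivative-sign heuristic; it does
  not model origin firing or termination zones beyond the profile's
  extrema.
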