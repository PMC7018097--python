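"""Stacked anchor profiles, the context-expected model, TSS and gene parts."""

import numpy as np
import pandas as pd
import pytest

from polespectra import (
    AnchorSet,
    GeneModel,
    MutationCatalog,
    ReferenceGenome,
    expected_profile,
    gene_part_profile,
    stack_profile,
    tss_profile,
)
from polespectra._channels import revcomp
from polespectra.synthetic import GeneratorConfig, simulate_mutations


def _cat(rows):
    return MutationCatalog(pd.DataFrame(rows, columns=MutationCatalog.COLUMNS))


class TestStackProfile:
    def test_single_center_mutation(self):
        anchors = AnchorSet([("chr1", 50, "+")], flank=5)
        prof = stack_profile(_cat([("s", "chr1", 50, "C", "T")]), anchors)
        assert prof.observed[prof.flank] == 1
        assert prof.observed.sum() == 1

    def test_overlapping_windows_count_per_window(self):
        anchors = AnchorSet([("chr1", 50, "+"), ("chr1", 52, "+")], flank=5)
        prof = stack_profile(_cat([("s", "chr1", 50, "C", "T")]), anchors)
        # offset 0 for the first window, offset -2 for the second
        assert prof.observed[5] == 1 and prof.observed[3] == 1
        assert prof.observed.sum() == 2

    def test_minus_strand_flips_offsets(self):
        anchors = AnchorSet([("chr1", 50, "-")], flank=10)
        prof = stack_profile(_cat([("s", "chr1", 55, "C", "T")]), anchors)
        # 5 bp 3' of a minus-strand centre in genome coords is offset -5,
        # flipped to +5 in anchor orientation... mutation at +5 genomic = -5 oriented
        assert prof.observed[10 - 5] == 1

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            AnchorSet([], flank=5)


def _oracle_expected(genome, catalog, anchors, k=1):
    """Direct evaluation of the m*f_p/sum(f_q) model by string matching."""
    from collections import Counter

    fl = anchors.flank
    windows = []
    M, A = Counter(), Counter()
    pos_list = [(r.chrom, r.pos) for r in catalog.df.itertuples(index=False)]
    for chrom, center, strand in anchors.anchors:
        seq = genome.sequences[chrom]
        ctxs, muts = [], []
        for off in range(-fl, fl + 1):
            p = center + off  # 1-based
            if p - k < 1 or p + k > len(seq):
                ctxs.append(None)
                continue
            c = seq[p - 1 - k : p + k]
            if "N" in c:
                ctxs.append(None)
                continue
            if c[k] not in "CT":
                c = revcomp(c)
            ctxs.append(c)
            A[c] += 1
        for chrom2, p in pos_list:
            if chrom2 == chrom and abs(p - center) <= fl:
                c = ctxs[p - center + fl]
                if c is not None:
                    M[c] += 1
                    muts.append(p - center)
        windows.append((strand, ctxs, muts))
    exp = np.zeros(2 * fl + 1)
    for strand, ctxs, muts in windows:
        f = [M[c] / A[c] if c is not None else 0.0 for c in ctxs]
        if strand == "-":
            f = f[::-1]
            muts = [-o for o in muts]
        s = sum(f)
        if s > 0 and muts:
            exp += len(muts) * np.array(f) / s
    return exp


class TestExpectedProfile:
    def test_uniform_context_window_gives_flat_expected(self):
        g = ReferenceGenome({"chr1": "A" * 101})
        anchors = AnchorSet([("chr1", 51, "+")], flank=10)
        cat = _cat([("s", "chr1", 48, "A", "C"), ("s2", "chr1", 51, "A", "G")])
        prof = expected_profile(cat, anchors, g)
        assert np.allclose(prof.expected, 2 / 21)

    def test_matches_hand_oracle_on_small_window(self, small_bundle):
        cfg, genome, _, _ = small_bundle
        anchors = AnchorSet(
            [("chr1", 5000, "+"), ("chr1", 5030, "-"), ("chr1", 9000, "+")], flank=25
        )
        cat = simulate_mutations(genome, "P286R", 3000, seed=7, config=cfg)
        prof = expected_profile(cat, anchors, genome)
        oracle = _oracle_expected(genome, cat, anchors)
        assert np.allclose(prof.expected, oracle, atol=1e-12)
        assert np.isclose(prof.expected.sum(), prof.observed.sum(), atol=1e-9)

    def test_conservation_sum_expected_equals_sum_observed(self, small_bundle):
        cfg, genome, _, landscape = small_bundle
        anchors = landscape.motifs.within(genome)
        cat = simulate_mutations(genome, "V411L", 5000, seed=8, config=cfg)
        prof = expected_profile(cat, anchors, genome)
        assert prof.expected.sum() == pytest.approx(prof.observed.sum(), abs=1e-9)

    def test_planted_central_depletion_detected(self, small_bundle):
        """Mutations thinned within ±110 bp of motif centres sit significantly
        below the context-expected profile in the centre."""
        from scipy.stats import wilcoxon

        cfg0, genome, meth, landscape = small_bundle
        cfg = GeneratorConfig(**{**cfg0.__dict__, "ctcf_depletion": 0.25})
        cat = simulate_mutations(genome, "P286R", 8000, seed=9, config=cfg,
                                 landscape=landscape)
        prof = expected_profile(cat, landscape.motifs.within(genome), genome)
        fl = prof.flank
        centre = slice(fl - 110, fl + 111)
        obs = prof.observed[centre]
        exp = prof.expected[centre]
        stat, p = wilcoxon(obs - exp, alternative="less")
        assert p < 1e-6
        assert obs.sum() < exp.sum()


class TestTssProfile:
    def test_rate_one_when_every_context_site_mutated(self):
        # TCG at positions 4..6 (1-based C at 5); anchor centred at 5
        g = ReferenceGenome({"chr1": "AAATCGAAAA" * 3})
        anchors = AnchorSet([("chr1", 5, "+")], flank=3, kind="tss")
        cat = _cat([("s", "chr1", 5, "C", "T")])
        prof = tss_profile(cat, anchors, g)
        row = prof["T[C>T]G"].set_index("offset").loc[0]
        assert row["rate"] == pytest.approx(1.0)

    def test_absent_context_offset_is_missing_not_zero(self):
        g = ReferenceGenome({"chr1": "AAATCGAAAA" * 3})
        anchors = AnchorSet([("chr1", 5, "+")], flank=3, kind="tss")
        prof = tss_profile(_cat([]), anchors, g)
        tbl = prof["T[T>G]T"].set_index("offset")
        assert np.isnan(tbl.loc[0, "rate"])  # no TTT context at the centre

    def test_minus_strand_anchor_counts_collapsed_context(self):
        # minus-strand TSS over the reverse complement of TCG (CGA on plus)
        g = ReferenceGenome({"chr1": "AAACGAAAAA" * 3})
        anchors = AnchorSet([("chr1", 5, "-")], flank=3, kind="tss")
        cat = _cat([("s", "chr1", 5, "G", "A")])  # G>A = C>T on minus strand
        prof = tss_profile(cat, anchors, g)
        tbl = prof["T[C>T]G"].set_index("offset")
        assert tbl["mutations"].sum() == 1


def _gene(strand="+", n_exons=3, exon_len=100, intron_len=200, utr=30, start=1000):
    exons = []
    p = start
    for _ in range(n_exons):
        exons.append((p, p + exon_len))
        p += exon_len + intron_len
    cds_start = exons[0][0] + utr
    cds_end = exons[-1][1] - utr
    return GeneModel("g", "chr1", strand, exons, cds_start, cds_end)


class TestGeneParts:
    def test_short_sequences_discarded(self):
        g = _gene(utr=19)  # 19-bp UTRs must be dropped
        prof = gene_part_profile(_cat([]), [g])
        tbl = prof.table
        assert tbl[tbl["part"] == "5UTR"]["bp"].sum() == 0
        assert tbl[tbl["part"] == "first_exon"]["bp"].sum() > 0

    def test_density_arithmetic(self):
        g = _gene(exon_len=1020, utr=20)  # first coding exon 1000 bp
        muts = [("s", "chr1", 1021 + i, "C", "T") for i in range(5)]  # inside coding
        prof = gene_part_profile(_cat(muts), [g])
        sub = prof.table[prof.table["part"] == "first_exon"]
        assert sub["bp"].sum() == 1000
        assert 1e6 * sub["mutations"].sum() / sub["bp"].sum() == pytest.approx(5000.0)

    def test_bin_widths_differ_by_at_most_one(self):
        g = _gene(exon_len=103, utr=21)
        prof = gene_part_profile(_cat([]), [g])
        for part in ("first_exon", "first_intron"):
            widths = prof.table[prof.table["part"] == part]["bp"].to_numpy()
            if widths.sum():
                assert widths.max() - widths.min() <= 1

    def test_gene_order_invariance(self, small_bundle):
        cfg, genome, _, landscape = small_bundle
        cat = simulate_mutations(genome, "Other-Exo", 3000, seed=10, config=cfg)
        genes = landscape.genes
        p1 = gene_part_profile(cat, genes).table
        p2 = gene_part_profile(cat, genes[::-1]).table
        pd.testing.assert_frame_equal(p1, p2)

    def test_two_exon_gene_has_no_middle_parts(self):
        g = _gene(n_exons=2, utr=30)
        prof = gene_part_profile(_cat([]), [g])
        tbl = prof.table
        assert tbl[tbl["part"] == "middle_exon"]["bp"].sum() == 0
        assert tbl[tbl["part"] == "middle_intron"]["bp"].sum() == 0
        assert tbl[tbl["part"] == "first_intron"]["bp"].sum() > 0

    def test_minus_strand_bins_run_five_prime_to_three_prime(self):
        g = _gene(strand="-", n_exons=3, exon_len=120, utr=20)
        # 5' end of a minus-strand gene is the genomic right end;
        # a mutation near the genomic end of the last exon lands in bin 0 of 5UTR
        utr5_start = g.exons[-1][1] - 20  # genomic left edge of the 5'UTR
        muts = [("s", "chr1", g.exons[-1][1], "C", "T")]  # genomic rightmost base
        prof = gene_part_profile(_cat(muts), [g], min_length=10)
        sub = prof.table[(prof.table["part"] == "5UTR") & (prof.table["mutations"] > 0)]
        assert list(sub["bin"]) == [0]
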