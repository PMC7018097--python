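"""Methylation binning, per-bin mutation rates, penta-context normalisation."""

import numpy as np
import pandas as pd
import pytest

from polespectra import (
    MutationCatalog,
    ReferenceGenome,
    bin_cpgs_by_methylation,
    context_composition_per_bin,
    methylation_bin,
    mutation_rate_per_bin,
    penta_normalized_rate,
    relative_burden,
)
from polespectra.methylation import MethylationTrack, read_methylation_bedgraph


def _track(rows):
    return MethylationTrack(pd.DataFrame(rows, columns=["chrom", "pos", "beta"]))


class TestBinning:
    @pytest.mark.parametrize("beta,expected", [
        (0.0, 1),    # exactly unmethylated
        (1.0, 12),   # exactly fully methylated
        (0.1, 2),    # deciles are right-closed
        (0.10000001, 3),
        (0.95, 11),
        (0.5, 6),
        (1e-9, 2),
    ])
    def test_bin_boundaries(self, beta, expected):
        assert methylation_bin([beta])[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            methylation_bin([1.2])

    def test_partition_is_exact_and_exhaustive(self):
        rng = np.random.default_rng(0)
        betas = np.concatenate([rng.random(500), [0.0, 1.0, 0.1, 0.9]])
        track = _track([("chr1", i + 1, b) for i, b in enumerate(betas)])
        bins = bin_cpgs_by_methylation(track)
        assert sum(len(df) for df in bins.values()) == len(betas)
        for b, df in bins.items():
            assert (methylation_bin(df["beta"].to_numpy()) == b).all()

    def test_validate_cpg_keeps_true_cpgs_only(self):
        g = ReferenceGenome({"chr1": "ACGTCGTTAA"})
        track = _track([("chr1", 2, 0.5), ("chr1", 5, 0.5), ("chr1", 9, 0.5)])
        ok = track.validate_cpg(g)
        assert list(ok.sites["pos"]) == [2, 5]

    def test_read_bedgraph_positions_are_one_based(self, tmp_path):
        p = tmp_path / "m.bedgraph"
        p.write_text("chr1\t1\t2\t0.8\t12\n")
        t = read_methylation_bedgraph(p)
        assert list(t.sites["pos"]) == [2]
        assert list(t.sites["coverage"]) == [12]


def _bins_one(chrom_pos, b=6):
    """All sites into one bin index for rate tests."""
    bins = {i: pd.DataFrame(columns=["chrom", "pos", "beta"]) for i in range(1, 13)}
    bins[b] = pd.DataFrame(chrom_pos, columns=["chrom", "pos"]).assign(beta=0.5)
    return bins


class TestRates:
    def test_rate_arithmetic(self):
        sites = [("chr1", 10 * i + 1) for i in range(1000)]
        bins = _bins_one(sites)
        cat = MutationCatalog(pd.DataFrame(
            [("s1", "chr1", 1, "C", "T"), ("s1", "chr1", 11, "C", "T")],
            columns=MutationCatalog.COLUMNS))
        prof = mutation_rate_per_bin({"g": cat}, bins)["g"]
        assert prof.table.loc[5, "rate_per_mb"] == pytest.approx(2000.0)

    def test_g_to_a_collapses_onto_cpg(self):
        bins = _bins_one([("chr1", 5)])
        cat = MutationCatalog(pd.DataFrame(
            [("s1", "chr1", 6, "G", "A")], columns=MutationCatalog.COLUMNS))
        prof = mutation_rate_per_bin({"g": cat}, bins)["g"]
        assert prof.table.loc[5, "mutation_count"] == 1

    def test_non_ct_mutations_ignored(self):
        bins = _bins_one([("chr1", 5)])
        cat = MutationCatalog(pd.DataFrame(
            [("s1", "chr1", 5, "C", "A")], columns=MutationCatalog.COLUMNS))
        prof = mutation_rate_per_bin({"g": cat}, bins)["g"]
        assert prof.table["mutation_count"].sum() == 0

    def test_empty_bin_rate_is_nan(self):
        bins = _bins_one([("chr1", 5)])
        cat = MutationCatalog(pd.DataFrame([], columns=MutationCatalog.COLUMNS))
        prof = mutation_rate_per_bin({"g": cat}, bins)["g"]
        assert np.isnan(prof.table.loc[0, "rate_per_mb"])
        assert prof.table.loc[5, "rate_per_mb"] == 0.0


class TestRelativeBurden:
    def _profiles(self, scale):
        sites = [("chr1", 2 * i + 1) for i in range(100)]
        bins = _bins_one(sites)
        ref = MutationCatalog(pd.DataFrame(
            [("r", "chr1", 2 * i + 1, "C", "T") for i in range(20)],
            columns=MutationCatalog.COLUMNS))
        other = MutationCatalog(pd.DataFrame(
            [("o", "chr1", 2 * i + 1, "C", "T") for i in range(int(20 * scale))],
            columns=MutationCatalog.COLUMNS))
        return mutation_rate_per_bin({"ref": ref, "other": other}, bins)

    def test_reference_against_itself_is_one(self):
        profs = self._profiles(1.0)
        ratios = relative_burden(profs, "ref")
        assert ratios.loc[5, "ref"] == pytest.approx(1.0)

    def test_half_rate_gives_half_ratio(self):
        ratios = relative_burden(self._profiles(0.5), "ref")
        assert ratios.loc[5, "other"] == pytest.approx(0.5)

    def test_zero_reference_bin_is_nan(self):
        ratios = relative_burden(self._profiles(0.5), "ref")
        assert np.isnan(ratios.loc[0, "other"])


class TestPentaNormalization:
    def test_identity_when_bin_matches_genome(self):
        """f == F makes the normalised value collapse to the raw count sum."""
        g = ReferenceGenome({"chr1": "ATTCGAGACGATTCGAGACGA"})
        sites = pd.DataFrame({"chrom": "chr1", "pos": [4, 9, 14, 19], "beta": 0.5})
        cat = MutationCatalog(pd.DataFrame(
            [("s", "chr1", 4, "C", "T"), ("s", "chr1", 9, "C", "T")],
            columns=MutationCatalog.COLUMNS))
        res = penta_normalized_rate(sites, cat, g, all_sites=sites)
        assert res.C == pytest.approx(res.raw, abs=1e-12)
        assert res.percent_change == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_reweighting(self):
        """Two contexts, N=(10,0), f=(0.5,0.5), F=(0.25,0.75) -> C = 20."""
        g = ReferenceGenome({"chr1": ("TTCGA" + "GACGA") * 60})
        # bin: 1 TTCGA site + 3 GACGA sites -> F = (0.25, 0.75)
        bin_sites = pd.DataFrame({"chrom": "chr1", "pos": [3, 8, 18, 28], "beta": 0.5})
        genome_w = pd.Series({"TTCGA": 0.5, "GACGA": 0.5})
        cat = MutationCatalog(pd.DataFrame(
            [(f"s{i}", "chr1", 3, "C", "T") for i in range(10)],
            columns=MutationCatalog.COLUMNS))
        res = penta_normalized_rate(bin_sites, cat, g, genome_weights=genome_w)
        assert res.C == pytest.approx(20.0)
        assert res.percent_change == pytest.approx(100.0)

    def test_hot_context_enrichment_shrinks(self):
        """A bin over-enriched in its mutated context gets C < raw."""
        g = ReferenceGenome({"chr1": ("TTCGA" + "GACGA") * 60})
        bin_sites = pd.DataFrame({"chrom": "chr1", "pos": [3, 13, 23, 8], "beta": 0.5})
        # bin is 75% TTCGA, genome-wide only 50%
        genome_w = pd.Series({"TTCGA": 0.5, "GACGA": 0.5})
        cat = MutationCatalog(pd.DataFrame(
            [(f"s{i}", "chr1", 3, "C", "T") for i in range(8)],
            columns=MutationCatalog.COLUMNS))
        res = penta_normalized_rate(bin_sites, cat, g, genome_weights=genome_w)
        assert res.C < res.raw
        assert res.shrinks

    def test_mutations_outside_bin_ignored(self):
        """Only mutations at the bin's own CpGs enter N, so a mutated
        context can never be missing from the bin's composition."""
        g = ReferenceGenome({"chr1": "ATTCGAGACGA" * 10})
        bin_sites = pd.DataFrame({"chrom": "chr1", "pos": [4], "beta": 0.5})
        cat = MutationCatalog(pd.DataFrame(
            [("s", "chr1", 9, "C", "T")], columns=MutationCatalog.COLUMNS))
        res = penta_normalized_rate(bin_sites, cat, g, all_sites=bin_sites)
        assert res.raw == 0
        assert res.C == 0.0


class TestComposition:
    def test_single_site_full_proportion(self):
        g = ReferenceGenome({"chr1": "ATTCGAGG"})
        bins = {1: pd.DataFrame({"chrom": ["chr1"], "pos": [4], "beta": [0.0]})}
        comp = context_composition_per_bin(bins, g)
        assert comp.loc["TTCGA", 1] == pytest.approx(1.0)

    def test_columns_sum_to_one(self):
        g = ReferenceGenome({"chr1": "ATTCGAGACGATACGTACGA" * 5})
        sites = [(p0 + 1) for p0, c in enumerate(g.sequences["chr1"][:-1])
                 if c == "C" and g.sequences["chr1"][p0 + 1] == "G"]
        bins = {1: pd.DataFrame({"chrom": "chr1", "pos": sites[:5], "beta": 0.0}),
                2: pd.DataFrame({"chrom": "chr1", "pos": sites[5:], "beta": 0.5})}
        comp = context_composition_per_bin(bins, g)
        assert comp[1].sum() == pytest.approx(1.0)
        assert comp[2].sum() == pytest.approx(1.0)
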