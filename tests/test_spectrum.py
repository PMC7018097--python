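"""Spectrum construction, normalisation, similarity, clustering, NNLS fits."""

import numpy as np
import pytest

from polespectra import (
    ReferenceGenome,
    SignatureMatrix,
    build_spectrum,
    cluster_samples,
    cosine_similarity,
    count_context_abundance,
    fit_signature_contributions,
    normalize_to_genome_frequency,
)
from polespectra.spectrum import ContextSpectrum
from polespectra._channels import channel_index, n_channels
from polespectra.synthetic import pole_like_signature, simulate_genome, simulate_mutations
from polespectra.synthetic import GeneratorConfig


def _spec_from(counts_by_label, k=1):
    v = np.zeros(n_channels(k), dtype=np.int64)
    ci = channel_index(k)
    for lab, n in counts_by_label.items():
        v[ci[lab]] = n
    return ContextSpectrum(k=k, counts=v)


class TestBuildSpectrum:
    def test_single_mutation_full_proportion(self, catalog_factory):
        g = ReferenceGenome({"chr1": "AACGT"})
        cat = catalog_factory([("s1", "chr1", 3, "C", "T")])
        spec = build_spectrum(cat, g, k=1)
        assert spec.total == 1
        assert spec.proportions[channel_index(1)["A[C>T]G"]] == 1.0

    def test_two_mutations_half_each(self, catalog_factory):
        g = ReferenceGenome({"chr1": "AACAATTTA"})
        cat = catalog_factory([
            ("s1", "chr1", 3, "C", "A"),   # A[C>A]A
            ("s1", "chr1", 7, "T", "G"),   # T[T>G]T
        ])
        spec = build_spectrum(cat, g, k=1)
        ci = channel_index(1)
        assert spec.proportions[ci["A[C>A]A"]] == 0.5
        assert spec.proportions[ci["T[T>G]T"]] == 0.5

    def test_empty_catalog_flags_undefined_proportions(self, catalog_factory):
        g = ReferenceGenome({"chr1": "AACGT"})
        spec = build_spectrum(catalog_factory([]), g, k=1)
        assert spec.total == 0
        assert np.isnan(spec.proportions).all()

    def test_boundary_records_excluded_and_counted(self, catalog_factory):
        g = ReferenceGenome({"chr1": "CGTAC"})
        cat = catalog_factory([("s1", "chr1", 1, "C", "T"), ("s1", "chr1", 3, "T", "G")])
        spec = build_spectrum(cat, g, k=1)
        assert spec.total == 1
        assert spec.n_excluded == 1

    def test_additivity_over_samples(self, small_bundle):
        cfg, genome, _, _ = small_bundle
        c1 = simulate_mutations(genome, "P286R", 500, seed=3, sample_id="a", config=cfg)
        c2 = simulate_mutations(genome, "V411L", 500, seed=4, sample_id="b", config=cfg)
        s1 = build_spectrum(c1, genome)
        s2 = build_spectrum(c2, genome)
        both = build_spectrum(c1.merge(c2), genome)
        assert (both.counts == s1.counts + s2.counts).all()

    def test_proportions_sum_to_one(self, small_bundle):
        cfg, genome, _, _ = small_bundle
        cat = simulate_mutations(genome, "Other-Exo", 2000, seed=5, config=cfg)
        spec = build_spectrum(cat, genome)
        assert spec.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert spec.total + spec.n_excluded == len(cat)


class TestNormalization:
    def test_rate_is_count_over_abundance(self):
        spec = _spec_from({"A[C>T]G": 10})
        g = ReferenceGenome({"chr1": "ACG" * 40})
        ab = count_context_abundance(g, k=1)
        norm = normalize_to_genome_frequency(spec, ab)
        i = channel_index(1)["A[C>T]G"]
        assert norm.normalized_rates[i] == pytest.approx(10 / ab.counts["ACG"])

    def test_k_mismatch_rejected(self):
        spec = _spec_from({"A[C>T]G": 1})
        g = ReferenceGenome({"chr1": "ACGT" * 10})
        with pytest.raises(ValueError):
            normalize_to_genome_frequency(spec, count_context_abundance(g, k=2))

    def test_rare_context_ranking_flips_after_normalization(self):
        """Most mutations in a common context, but the rare context has the
        higher per-site rate."""
        from polespectra.genome_context import ContextAbundance

        spec = _spec_from({"A[C>T]G": 30, "T[C>T]T": 10})
        ab = ContextAbundance(k=1, counts={"ACG": 1000, "TCT": 50})
        norm = normalize_to_genome_frequency(spec, ab)
        ci = channel_index(1)
        raw = spec.counts
        assert raw[ci["A[C>T]G"]] > raw[ci["T[C>T]T"]]
        assert norm.normalized_rates[ci["T[C>T]T"]] > norm.normalized_rates[ci["A[C>T]G"]]


class TestCosine:
    def test_identical_is_one(self):
        s = _spec_from({"A[C>T]G": 5, "T[T>G]T": 3})
        assert cosine_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        s1 = _spec_from({"A[C>T]G": 5})
        s2 = _spec_from({"T[T>G]T": 7})
        assert cosine_similarity(s1, s2) == pytest.approx(0.0)

    def test_half_overlap_closed_form(self):
        s1 = _spec_from({"A[C>A]A": 1, "A[C>A]C": 1})
        s2 = _spec_from({"A[C>A]A": 1})
        assert cosine_similarity(s1, s2) == pytest.approx(1 / np.sqrt(2))

    def test_empty_spectrum_rejected(self):
        s1 = _spec_from({"A[C>T]G": 1})
        with pytest.raises(ValueError):
            cosine_similarity(s1, _spec_from({}))


class TestClustering:
    def test_identical_pair_merges_first(self):
        a = _spec_from({"A[C>T]G": 10})
        b = _spec_from({"A[C>T]G": 10})
        c = _spec_from({"T[T>G]T": 10})
        res = cluster_samples([a, b, c], n_groups=2, names=["a", "b", "c"])
        assert res.labels[0] == res.labels[1] != res.labels[2]
        # first merge joins leaves 0 and 1
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_recovers_planted_archetypes(self, small_bundle):
        cfg, genome, _, _ = small_bundle
        specs, truth = [], []
        for gi, group in enumerate(["P286R", "V411L", "Other-Exo"]):
            for i in range(5):
                cat = simulate_mutations(genome, group, 10_000, seed=100 + 10 * gi + i,
                                         config=cfg)
                specs.append(build_spectrum(cat, genome))
                truth.append(group)
        res = cluster_samples(specs, n_groups=3)
        # planted groups map 1:1 onto recovered flat clusters
        mapping = {}
        for lab, t in zip(res.labels, truth):
            mapping.setdefault(t, set()).add(lab)
        assert all(len(v) == 1 for v in mapping.values())
        assert len(set().union(*mapping.values())) == 3

    def test_order_permutation_preserves_tree_heights(self):
        rng = np.random.default_rng(0)
        specs = [
            ContextSpectrum(k=1, counts=rng.integers(0, 50, size=96)) for _ in range(6)
        ]
        res1 = cluster_samples(specs)
        perm = [3, 1, 5, 0, 2, 4]
        res2 = cluster_samples([specs[i] for i in perm])
        assert np.allclose(np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2]))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples([_spec_from({"A[C>T]G": 1})])


class TestSignatureFit:
    def _sigs(self):
        m = np.zeros((96, 2))
        m[0:10, 0] = 0.1
        m[20:30, 1] = 0.1
        return SignatureMatrix(names=["sigA", "sigB"], matrix=m)

    def test_pure_signature_gets_weight_one(self):
        sigs = self._sigs()
        counts = (sigs.matrix[:, 0] * 1000).astype(int)
        fit = fit_signature_contributions(ContextSpectrum(k=1, counts=counts), sigs)
        assert fit.weights == pytest.approx([1.0, 0.0], abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_mixture_recovered(self):
        sigs = self._sigs()
        mix = 0.7 * sigs.matrix[:, 0] + 0.3 * sigs.matrix[:, 1]
        counts = np.round(mix * 10000).astype(int)
        fit = fit_signature_contributions(ContextSpectrum(k=1, counts=counts), sigs)
        assert fit.weights == pytest.approx([0.7, 0.3], abs=1e-6)

    def test_orthogonal_spectrum_all_zero_weights(self):
        sigs = self._sigs()
        counts = np.zeros(96, dtype=int)
        counts[50:60] = 100
        spec = ContextSpectrum(k=1, counts=counts)
        fit = fit_signature_contributions(spec, sigs)
        assert fit.raw_weights == pytest.approx([0.0, 0.0], abs=1e-12)
        assert fit.residual == pytest.approx(np.linalg.norm(spec.proportions))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_signature_contributions(
                _spec_from({"A[C>T]G": 1}),
                SignatureMatrix(names=[], matrix=np.zeros((96, 0))),
            )
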