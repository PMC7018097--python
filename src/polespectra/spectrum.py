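"""Mutation spectra over 96/1536 pyrimidine-collapsed channels.

A spectrum is a complete vector of counts over the canonical channel
ordering (substitution type, then context, both lexicographic), plus
derived proportions and, optionally, rates normalised by genome context
abundance.  Sample comparison uses cosine similarity on proportions;
clustering is average-linkage agglomeration on 1 - cosine; signature
contributions are fit by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from ._channels import (
    _BASE_CODE,
    COMPLEMENT,
    canonical_contexts,
    channel_codes_for,
    channel_labels,
    n_channels,
)
from .genome_context import ContextAbundance, MutationCatalog, ReferenceGenome


@dataclass
class ContextSpectrum:
    """Counts and proportions over the complete channel space for one k."""

    k: int
    counts: np.ndarray  # int array, length 96 (k=1) or 1536 (k=2)
    n_excluded: int = 0  # records dropped for N contexts / boundary
    normalized_rates: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        expected = n_channels(self.k)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (expected,):
            raise ValueError(f"expected {expected} channels, got {self.counts.shape}")

    @property
    def channels(self) -> tuple[str, ...]:
        return channel_labels(self.k)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Channel proportions; NaN vector when the spectrum is empty."""
        t = self.total
        if t == 0:
            return np.full_like(self.counts, np.nan, dtype=float)
        return self.counts / t

    def count_of(self, channel: str) -> int:
        return int(self.counts[self.channels.index(channel)])

    def substitution_fractions(self) -> dict[str, float]:
        """Fraction of mutations per six-type substitution class."""
        p = self.proportions
        block = len(p) // 6
        names = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
        return {nm: float(p[i * block : (i + 1) * block].sum()) for i, nm in enumerate(names)}


def build_spectrum(catalog: MutationCatalog, genome: ReferenceGenome, k: int = 1, label: str = "") -> ContextSpectrum:
    """Assign every SNV to its pyrimidine-collapsed channel.

    Records whose context window runs off the chromosome or contains N
    are excluded and tallied in ``n_excluded``.
    """
    counts = np.zeros(n_channels(k), dtype=np.int64)
    excluded = 0
    df = catalog.df
    for chrom, grp in df.groupby("chrom", sort=True):
        if chrom not in genome.sequences:
            excluded += len(grp)
            continue
        idx = genome.context_indices(chrom, k)
        pos0 = grp["pos"].to_numpy() - 1
        inb = (pos0 >= 0) & (pos0 < len(idx))
        excluded += int((~inb).sum())
        pos0 = pos0[inb]
        ctx = idx[pos0]
        refs = grp["ref"].to_numpy()[inb]
        alts = grp["alt"].to_numpy()[inb]
        # purine refs read the channel from the minus strand
        alt_pyr = np.array(
            [_BASE_CODE[a if r in "CT" else COMPLEMENT[a]] for r, a in zip(refs, alts)],
            dtype=np.int64,
        )
        ok = ctx >= 0
        excluded += int((~ok).sum())
        chan = channel_codes_for(ctx[ok], alt_pyr[ok], k)
        counts += np.bincount(chan, minlength=len(counts))
    return ContextSpectrum(k=k, counts=counts, n_excluded=excluded, label=label)


def normalize_to_genome_frequency(spectrum: ContextSpectrum, abundance: ContextAbundance) -> ContextSpectrum:
    """Divide channel counts by the abundance of each channel's context.

    Channels whose context never occurs get NaN rates.
    """
    if abundance.k != spectrum.k:
        raise ValueError(f"k mismatch: spectrum k={spectrum.k}, abundance k={abundance.k}")
    ctxs = canonical_contexts(spectrum.k)
    ab = np.repeat(abundance.as_array(), 1)  # per-context
    # channel order is (substitution, context); map context abundance to channels
    ctx_of_channel = []
    cidx = {c: i for i, c in enumerate(ctxs)}
    for lab in spectrum.channels:
        l, rest = lab.split("[", 1)
        sub, r = rest.split("]", 1)
        ctx_of_channel.append(cidx[l + sub[0] + r])
    denom = ab[np.array(ctx_of_channel)]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(denom > 0, spectrum.counts / denom, np.nan)
    return ContextSpectrum(
        k=spectrum.k,
        counts=spectrum.counts,
        n_excluded=spectrum.n_excluded,
        normalized_rates=rates,
        label=spectrum.label,
    )


def cosine_similarity(s1: ContextSpectrum, s2: ContextSpectrum) -> float:
    """Cosine similarity of two spectra's proportion vectors, in [0, 1]."""
    if s1.k != s2.k:
        raise ValueError("spectra have different context widths")
    p1, p2 = s1.proportions, s2.proportions
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if not np.isfinite(n1) or not np.isfinite(n2) or n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for an empty spectrum")
    return float(np.dot(p1, p2) / (n1 * n2))


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: np.ndarray  # flat cluster ids when n_groups requested
    sample_names: list[str]
    distance: np.ndarray = field(repr=False, default=None)

    def to_newick(self) -> str:
        """Dendrogram in Newick form (leaf names, branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.sample_names[node.id]
            l, r = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({l}:{dl:.6g},{r}:{dr:.6g})"

        return walk(tree) + ";"


def cluster_samples(
    spectra: list[ContextSpectrum],
    linkage: str = "average",
    n_groups: int | None = None,
    names: list[str] | None = None,
) -> ClusterResult:
    """Hierarchical clustering of spectra on 1 - cosine similarity.

    Deterministic given input order; with ``n_groups`` the tree is cut
    into that many flat groups.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to cluster")
    ks = {s.k for s in spectra}
    if len(ks) != 1:
        raise ValueError("spectra mix context widths")
    P = np.vstack([s.proportions for s in spectra])
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    U = P / norms
    D = 1.0 - U @ U.T
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    if n_groups is not None:
        labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    else:
        labels = np.arange(len(spectra))
    if names is None:
        names = [s.label or f"sample_{i}" for i, s in enumerate(spectra)]
    return ClusterResult(linkage=Z, labels=labels, sample_names=list(names), distance=D)


@dataclass
class SignatureMatrix:
    """Named 96-channel signature probability vectors (columns sum to 1)."""

    names: list[str]
    matrix: np.ndarray  # shape (96, n_signatures)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("signature matrix shape does not match names")
        if (self.matrix < 0).any():
            raise ValueError("signature entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature must sum to 1")


@dataclass
class SignatureFit:
    names: list[str]
    weights: np.ndarray  # normalised to sum 1 (all-zero if nothing fits)
    raw_weights: np.ndarray
    residual: float


def fit_signature_contributions(spectrum: ContextSpectrum, sigs: SignatureMatrix) -> SignatureFit:
    """Non-negative least squares of spectrum proportions on signatures."""
    if spectrum.k != 1:
        raise ValueError("signature fitting is defined on 96-channel spectra")
    if sigs.matrix.size == 0:
        raise ValueError("empty signature matrix")
    y = spectrum.proportions
    w, rnorm = nnls(sigs.matrix, y)
    total = w.sum()
    weights = w / total if total > 0 else w.copy()
    return SignatureFit(names=list(sigs.names), weights=weights, raw_weights=w, residual=float(rnorm))
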