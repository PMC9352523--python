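"""Alpha diversity, rarefaction, UniFrac distances and PCoA.

Shannon diversity is reported in nats (natural log), the convention of
vegan-style ecology software.  Beta diversity uses weighted or unweighted
UniFrac, which weight community differences by the phylogenetic branch
length separating the taxa; distances are computed through scikit-bio.
Principal coordinates analysis (classical metric scaling) embeds a
distance matrix into Euclidean axes by eigendecomposition of the
double-centered squared-distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import beta_diversity

from .io_formats import CountTable, PhyloTree, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.isfinite(self.d).all():
            raise ValidationError("distance matrix has non-finite entries")
        if (self.d < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.d[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class Ordination:
    """PCoA result: sample coordinates plus eigenvalue spectrum.

    ``coordinates`` holds the retained axes (samples x axes), ordered by
    decreasing eigenvalue.  ``proportion_explained`` is computed over the
    positive part of the spectrum only; negative eigenvalues are
    discarded, and ``negative_eigenvalue_warning`` is set when the most
    negative eigenvalue exceeds 5% of the largest positive one.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_warning: bool = False

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped (logged).  The
    per-taxon counts of each retained sample follow the multivariate
    hypergeometric distribution.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    depths = table.depths()
    keep = depths >= depth
    if not keep.any():
        raise ValidationError(f"no sample has >= {depth} reads; cannot rarefy")
    if (~keep).any():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        logger.info("rarefaction dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    rows = []
    ids = []
    for i, sample in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        if depths[i] == depth:
            rows.append(table.counts[i])
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        ids.append(sample)
    return CountTable(ids, list(table.taxon_ids), np.asarray(rows))


def default_rarefaction_depth(table: CountTable, floor: int = 1000) -> int:
    """Minimum retained depth after dropping samples below ``floor`` reads."""
    depths = table.depths()
    kept = depths[depths >= floor]
    if kept.size == 0:
        raise ValidationError(f"all samples below the {floor}-read floor")
    return int(kept.min())


def shannon_index(table: CountTable) -> pd.Series:
    """Per-sample Shannon diversity H = -sum(p * ln p), in nats."""
    p = table.relative_abundances()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids, name="shannon")


def observed_richness(table: CountTable) -> pd.Series:
    """Per-sample number of taxa with non-zero counts."""
    return pd.Series((table.counts > 0).sum(axis=1), index=table.sample_ids,
                     name="observed_richness")


def unifrac(table: CountTable, tree: PhyloTree, weighted: bool = True,
            normalized: bool = True) -> DistanceMatrix:
    """Pairwise UniFrac distances between all samples.

    Unweighted UniFrac is the fraction of branch length unique to either
    sample among branch length present in at least one; it depends only
    on presence/absence.  Weighted UniFrac weights each branch by the
    absolute difference in relative-abundance mass flowing through it;
    ``normalized=True`` rescales to [0, 1].
    """
    leaf_set = set(tree.leaf_names())
    missing = [t for t in table.taxon_ids if t not in leaf_set]
    if missing:
        raise ValidationError(f"taxa absent from the tree: {missing}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    dm = beta_diversity(metric, table.counts, ids=table.sample_ids,
                        taxa=table.taxon_ids, tree=tree.tree, validate=True,
                        **kwargs)
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -(1/2) J D^2 J."""
    a = -0.5 * np.asarray(d, dtype=float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix, n_axes: int) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposes the Gower-centered squared-distance matrix and keeps
    the top ``n_axes`` positive-eigenvalue axes; coordinates are
    eigenvectors scaled by sqrt(eigenvalue).  Proportions of variance
    explained are taken over the positive eigenvalues only.
    """
    n = d.n_samples
    if n_axes >= n:
        raise ValidationError(f"n_axes={n_axes} must be < n_samples={n}")
    g = gower_center(d.d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    n_pos = int(positive.sum())
    warning = False
    if n_pos and eigvals[-1] < 0 and abs(eigvals[-1]) > 0.05 * eigvals[0]:
        warning = True
        logger.warning("PCoA: most negative eigenvalue is %.3g (%.1f%% of largest); "
                       "negative part discarded", eigvals[-1],
                       100 * abs(eigvals[-1]) / eigvals[0])
    if n_pos == 0:
        # degenerate (e.g. all-zero distances): every embedding is at the origin
        return Ordination(list(d.sample_ids), np.zeros((n, n_axes)), eigvals,
                          np.zeros(n_axes), False)
    k = min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    pos_sum = eigvals[positive].sum()
    proportions = np.maximum(eigvals[:k], 0.0) / pos_sum
    return Ordination(list(d.sample_ids), coords, eigvals, proportions, warning)


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix rows and columns disagree")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))
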