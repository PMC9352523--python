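"""Distance-based variance partitioning and analyte association statistics.

PERMANOVA (permutational multivariate ANOVA) partitions the total sum of
squares of a distance matrix over model terms using the Gower-centered
inner-product matrix G = -(1/2) J D^2 J: the SS attributable to a design
block with hat matrix H is tr(H G), pseudo-F compares per-df explained
SS to residual SS, and significance comes from permuting sample labels
(rows/columns of G jointly).  Sequential mode attributes SS in term
order (terms + residual R^2 sum to 1); marginal mode tests each term
given all others.

The microbiota-to-cytokine variance-explained statistic represents the
community through the first few principal coordinates, runs a
sequential PERMANOVA of each analyte's one-dimensional Euclidean
distance matrix on those coordinate vectors, and sums the R^2 of axes
whose permutation p falls below a lenient threshold (default 0.2).  For
1-D Euclidean distances this R^2 coincides with the ordinary
least-squares R^2, which makes the statistic directly interpretable as
the fraction of analyte variance captured by community composition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix, Ordination, gower_center, pcoa
from .dmm import ClusterAssignment
from .io_formats import ResponsePanel, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PermanovaResult:
    """Per-term variance partition of a distance matrix."""

    table: pd.DataFrame  # rows: terms + Residual + Total; cols df/ss/r2/f/p
    n_permutations: int
    mode: str

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "r2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


@dataclass
class VarianceExplainedResult:
    """Per-analyte percentage of variance explained by ordination axes."""

    table: pd.DataFrame  # index analyte; explained_pct, contributing_axes, flagged
    axis_detail: pd.DataFrame  # one row per analyte x axis with r2 and p
    n_axes: int
    alpha: float
    n_permutations: int

    @property
    def explained_pct(self) -> pd.Series:
        return self.table["explained_pct"]


@dataclass
class GroupComparisonResult:
    """Per-analyte two-group comparison (rank-sum, optionally adjusted)."""

    table: pd.DataFrame


@dataclass
class ButyrateScore:
    """Per-sample summed relative abundance of butyrate-producing genera."""

    scores: pd.Series
    reference_id: str
    missing_genera: list[str]


# ---------------------------------------------------------------------------
# design-matrix helpers

_CATEGORICAL = {"group", "timepoint", "sex"}


def _term_block(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns (without intercept) for one metadata covariate."""
    if term not in meta.columns:
        raise ValidationError(f"unknown covariate {term!r}")
    col = meta[term]
    if col.isna().any():
        raise ValidationError(f"covariate {term!r} has missing values")
    if term in _CATEGORICAL or col.dtype == object:
        dummies = pd.get_dummies(col, drop_first=True)
        if dummies.shape[1] == 0:
            raise ValidationError(f"covariate {term!r} is constant")
        return dummies.to_numpy(dtype=float)
    values = col.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise ValidationError(f"covariate {term!r} is constant")
    return values[:, None]


def _hat(design: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of ``design``."""
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _permanova_blocks(g: np.ndarray, blocks: list[tuple[str, np.ndarray]],
                      n_perm: int, seed, mode: str,
                      factor: np.ndarray | None = None,
                      exhaustive: bool = False) -> pd.DataFrame:
    """Shared PERMANOVA engine over pre-built design blocks.

    ``factor``, when given, is a vector y with G = y yᵀ (the Gower
    matrix of 1-D Euclidean distances is rank one); the permutation
    loop then uses quadratic forms instead of permuting G, which is
    algebraically identical and much faster.
    """
    n = g.shape[0]
    names = [name for name, _ in blocks]
    intercept = np.ones((n, 1))
    cum = [intercept]
    hats = [_hat(intercept)]
    dfs = []
    rank_prev = 1
    for _, block in blocks:
        cum.append(block)
        design = np.hstack(cum)
        rank = np.linalg.matrix_rank(design)
        if rank == rank_prev:
            raise ValidationError("singular design: a term adds no rank")
        dfs.append(rank - rank_prev)
        rank_prev = rank
        hats.append(_hat(design))
    h_full = hats[-1]
    resid_proj = np.eye(n) - h_full
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    ss_total = float(np.trace(g))

    if mode == "sequential":
        projs = [hats[i + 1] - hats[i] for i in range(len(blocks))]
    elif mode == "marginal":
        projs = []
        for i in range(len(blocks)):
            others = [intercept] + [b for j, (_, b) in enumerate(blocks) if j != i]
            projs.append(h_full - _hat(np.hstack(others)))
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    proj_stack = np.stack(projs + [resid_proj])
    dfs_arr = np.asarray(dfs, dtype=float)
    eps = 1e-12 * max(abs(ss_total), 1.0)

    def f_from_ss(ss):
        """Pseudo-F per term; zero-SS terms get F=0, a zero residual
        (perfect fit) gives F=inf for any term with positive SS."""
        term_ss = np.where(np.abs(ss[..., :-1]) < eps, 0.0, ss[..., :-1])
        res_ss = np.where(ss[..., -1:] < eps, 0.0, ss[..., -1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (term_ss / dfs_arr) / (res_ss / df_res)
        return np.where(term_ss == 0.0, 0.0, f), term_ss, res_ss

    ss_obs = np.einsum("tij,ij->t", proj_stack, g)
    f_obs, ss_terms, ss_res = f_from_ss(ss_obs)
    ss_res = float(ss_res[0])

    if exhaustive:
        # all n! - 1 non-identity permutations; with the add-one
        # convention the p-value then equals exact enumeration over
        # distinct relabelings
        all_perms = np.array(list(itertools.permutations(range(n)))[1:])
        n_perm = len(all_perms)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(blocks))
    chunk = max(1, int(2**23 // max(n * n, 1)))  # ~64 MB of permuted G per chunk
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        if exhaustive:
            perms = all_perms[done:done + b]
        else:
            perms = np.stack([rng.permutation(n) for _ in range(b)])
        if factor is not None:
            y_perm = factor[perms]  # b x n; G_perm = y yᵀ of the permuted factor
            ss_p = np.stack([((y_perm @ p) * y_perm).sum(axis=1)
                             for p in proj_stack], axis=1)
        else:
            g_perm = g[perms[:, :, None], perms[:, None, :]]
            ss_p = np.einsum("tij,bij->bt", proj_stack, g_perm)
        f_p, _, _ = f_from_ss(ss_p)
        exceed += (f_p >= f_obs - 1e-12).sum(axis=0)
        done += b
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, name in enumerate(names):
        rows.append({"term": name, "df": dfs[i], "ss": float(ss_terms[i]),
                     "r2": float(ss_terms[i] / ss_total), "f": float(f_obs[i]),
                     "p": float(p_vals[i])})
    rows.append({"term": "Residual", "df": df_res, "ss": ss_res,
                 "r2": ss_res / ss_total, "f": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total, "r2": 1.0,
                 "f": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def permanova(d: DistanceMatrix, meta: SampleMetadata | pd.DataFrame, terms,
              n_perm: int = 9999, seed=None, mode: str = "sequential",
              exhaustive: bool = False) -> PermanovaResult:
    """PERMANOVA of a distance matrix on ordered metadata covariates.

    ``terms`` is an ordered list of metadata column names; categorical
    columns are dummy-encoded.  P-values use the add-one convention
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    df = meta.data if isinstance(meta, SampleMetadata) else meta
    df = df.loc[list(d.sample_ids)]
    blocks = [(t, _term_block(df, t)) for t in terms]
    g = gower_center(d.d)
    table = _permanova_blocks(g, blocks, n_perm, seed, mode,
                              exhaustive=exhaustive)
    return PermanovaResult(table=table, n_permutations=n_perm, mode=mode)


def permanova_vectors(d: DistanceMatrix, vectors: dict[str, np.ndarray],
                      n_perm: int = 999, seed=None, mode: str = "sequential",
                      _factor: np.ndarray | None = None) -> PermanovaResult:
    """PERMANOVA with explicit numeric regressors (e.g. ordination axes)."""
    n = d.n_samples
    blocks = []
    for name, vec in vectors.items():
        arr = np.asarray(vec, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise ValidationError(f"regressor {name!r} length does not match samples")
        blocks.append((name, arr))
    g = gower_center(d.d)
    table = _permanova_blocks(g, blocks, n_perm, seed, mode, factor=_factor)
    return PermanovaResult(table=table, n_permutations=n_perm, mode=mode)


def variance_partition(d: DistanceMatrix, meta: SampleMetadata | pd.DataFrame,
                       covariates, n_perm: int = 9999, seed=None) -> pd.DataFrame:
    """Single-term PERMANOVA per covariate (each fitted alone), sorted by R^2."""
    rng = np.random.default_rng(seed)
    rows = []
    for cov in covariates:
        res = permanova(d, meta, [cov], n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
        rows.append({"covariate": cov, "r2": res.r_squared(cov),
                     "p": res.p_value(cov), "df": int(res.table.loc[cov, "df"])})
    return (pd.DataFrame(rows).sort_values("r2", ascending=False)
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# cytokine variance explained


def cytokine_variance_explained(d: DistanceMatrix, panel: ResponsePanel,
                                n_axes: int = 4, alpha: float = 0.2,
                                n_perm: int = 999, seed=None,
                                ordination: Ordination | None = None) -> VarianceExplainedResult:
    """Fraction of each analyte's variance explained by community axes.

    The community is summarized by the first ``n_axes`` principal
    coordinates of ``d`` (computed on the samples shared with the
    panel).  For each analyte, a sequential PERMANOVA of the analyte's
    1-D Euclidean distance matrix on the ordered coordinate vectors is
    run, and the R^2 of axes with permutation p < ``alpha`` is summed.
    Analytes that are constant or entirely missing return 0, flagged.
    """
    shared = [s for s in d.sample_ids if s in set(panel.sample_ids)]
    if len(shared) < n_axes + 2:
        raise ValidationError("need at least n_axes + 2 shared samples")
    d_shared = d.select_samples(shared)
    if ordination is None:
        ordination = pcoa(d_shared, n_axes)
    n_positive = int((ordination.eigenvalues > 1e-10 *
                      max(abs(ordination.eigenvalues[0]), 1.0)).sum())
    if n_axes > n_positive:
        raise ValidationError(
            f"n_axes={n_axes} exceeds the {n_positive} positive PCoA eigenvalues")
    axes = ordination.coordinates[:, :n_axes]
    rng = np.random.default_rng(seed)
    values = panel.values.loc[shared]
    rows, detail = [], []
    for analyte in panel.analyte_names:
        y = values[analyte].to_numpy(dtype=float)
        ok = np.isfinite(y)
        sub_seed = int(rng.integers(2**31 - 1))
        if ok.sum() < n_axes + 2 or np.ptp(y[ok]) == 0:
            rows.append({"analyte": analyte, "explained_pct": 0.0,
                         "contributing_axes": "", "flagged": True})
            continue
        yv = y[ok]
        dy = DistanceMatrix([shared[i] for i in np.where(ok)[0]],
                            np.abs(yv[:, None] - yv[None, :]))
        vectors = {f"PCo{j + 1}": axes[ok, j] for j in range(n_axes)}
        res = permanova_vectors(dy, vectors, n_perm=n_perm, seed=sub_seed,
                                mode="sequential", _factor=yv - yv.mean())
        contributing = []
        total = 0.0
        for j in range(n_axes):
            term = f"PCo{j + 1}"
            r2 = res.r_squared(term)
            p = res.p_value(term)
            detail.append({"analyte": analyte, "axis": j + 1, "r2": r2, "p": p,
                           "included": p < alpha})
            if p < alpha:
                contributing.append(j + 1)
                total += r2
        rows.append({"analyte": analyte, "explained_pct": 100.0 * total,
                     "contributing_axes": ",".join(map(str, contributing)),
                     "flagged": False})
    table = pd.DataFrame(rows).set_index("analyte")
    axis_detail = pd.DataFrame(detail)
    return VarianceExplainedResult(table=table, axis_detail=axis_detail,
                                   n_axes=n_axes, alpha=alpha,
                                   n_permutations=n_perm)


def compare_explained(a: VarianceExplainedResult, b: VarianceExplainedResult,
                      paired: bool = False):
    """Compare per-analyte explained percentages between two conditions.

    Unpaired uses the two-sided Wilcoxon rank-sum (Mann-Whitney) test;
    paired uses the signed-rank test on shared analytes.
    """
    va = a.explained_pct.dropna()
    vb = b.explained_pct.dropna()
    if len(va) < 2 or len(vb) < 2:
        raise ValidationError("need at least 2 analytes per condition")
    if paired:
        shared = va.index.intersection(vb.index)
        diffs = va[shared] - vb[shared]
        if (diffs == 0).all():
            p = 1.0
        else:
            p = float(stats.wilcoxon(va[shared], vb[shared]).pvalue)
    else:
        if np.array_equal(np.sort(va), np.sort(vb)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
    summary = {
        "median_a": float(va.median()), "iqr_a": (float(va.quantile(0.25)),
                                                  float(va.quantile(0.75))),
        "median_b": float(vb.median()), "iqr_b": (float(vb.quantile(0.25)),
                                                  float(vb.quantile(0.75))),
        "p": p, "paired": paired,
    }
    return summary


# ---------------------------------------------------------------------------
# cluster-wise analyte comparisons


def _split_two_groups(values: pd.Series, assignment: ClusterAssignment):
    labels = pd.Series(assignment.labels, index=assignment.sample_ids)
    shared = values.index.intersection(labels.index)
    v = values.loc[shared]
    l = labels.loc[shared]
    ok = v.notna()
    v, l = v[ok], l[ok]
    groups = sorted(l.unique())
    return v, l, groups


def wilcoxon_group_compare(panel: ResponsePanel,
                           assignment: ClusterAssignment) -> GroupComparisonResult:
    """Per-analyte two-sided Wilcoxon rank-sum test between two clusters.

    Uses the exact null when the combined n is <= 25 without ties, the
    tie-corrected normal approximation otherwise.  An analyte for which
    a cluster is empty after missing-value removal is flagged with no p.
    """
    rows = []
    for analyte in panel.analyte_names:
        v, l, groups = _split_two_groups(panel.values[analyte], assignment)
        if len(groups) != 2:
            rows.append({"analyte": analyte, "p": np.nan, "flagged": True})
            continue
        g1, g2 = (v[l == g] for g in groups)
        has_ties = v.duplicated().any()
        method = "exact" if (len(v) <= 25 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
        rows.append({
            "analyte": analyte,
            "median_1": float(g1.median()), "iqr_1": (float(g1.quantile(0.25)),
                                                      float(g1.quantile(0.75))),
            "median_2": float(g2.median()), "iqr_2": (float(g2.quantile(0.25)),
                                                      float(g2.quantile(0.75))),
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "flagged": False,
        })
    return GroupComparisonResult(pd.DataFrame(rows).set_index("analyte"))


def adjusted_group_compare(panel: ResponsePanel, assignment: ClusterAssignment,
                           meta: SampleMetadata,
                           covariates=("age", "sex"),
                           transform: str | None = "rank") -> GroupComparisonResult:
    """Covariate-adjusted cluster effect on each analyte (linear model).

    Fits response ~ cluster + covariates by least squares after an
    optional transform ("rank", "log" or None) and reports the partial
    F-test p for the cluster term alongside the unadjusted rank-sum p.
    """
    import statsmodels.api as sm

    unadjusted = wilcoxon_group_compare(panel, assignment).table
    rows = []
    for analyte in panel.analyte_names:
        v, l, groups = _split_two_groups(panel.values[analyte], assignment)
        if len(groups) != 2:
            rows.append({"analyte": analyte, "p_adjusted": np.nan, "flagged": True})
            continue
        y = v.to_numpy(dtype=float)
        if transform == "rank":
            y = stats.rankdata(y)
        elif transform == "log":
            y = np.log1p(y)
        meta_sub = meta.data.loc[v.index]
        blocks = [(l == groups[1]).to_numpy(dtype=float)[:, None]]
        for cov in covariates:
            try:
                blocks.append(_term_block(meta_sub, cov))
            except ValidationError:
                # constant covariate in this subset carries no information
                continue
        design = np.hstack([np.ones((len(y), 1))] + blocks)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(f"collinear design for analyte {analyte!r}")
        full = sm.OLS(y, design).fit()
        reduced = sm.OLS(y, np.delete(design, 1, axis=1)).fit()
        f_res = full.compare_f_test(reduced)
        rows.append({"analyte": analyte, "p_adjusted": float(f_res[1]),
                     "f_cluster": float(f_res[0]), "flagged": False})
    adj = pd.DataFrame(rows).set_index("analyte")
    return GroupComparisonResult(unadjusted.join(adj, how="outer",
                                                 rsuffix="_adj"))


# ---------------------------------------------------------------------------
# butyrate producers


def butyrate_score(table, reference) -> ButyrateScore:
    """Summed relative abundance of a reference list of butyrate producers.

    Reference genera absent from the table contribute 0 (logged), so the
    score depends only on the proportions of the genera actually seen.
    """
    reference = list(reference)
    if not reference:
        raise ValidationError("butyrate reference list is empty")
    present = [g for g in reference if g in table.taxon_ids]
    missing = [g for g in reference if g not in table.taxon_ids]
    if missing:
        logger.info("butyrate reference genera absent from table: %s", missing)
    props = table.relative_abundances()
    if present:
        idx = [table.taxon_ids.index(g) for g in present]
        scores = props[:, idx].sum(axis=1)
    else:
        scores = np.zeros(table.n_samples)
    return ButyrateScore(pd.Series(scores, index=table.sample_ids,
                                   name="butyrate_score"),
                         reference_id=f"{len(reference)}-genus list",
                         missing_genera=missing)


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n)."""
    n = len(x_rank)
    perms = np.array(list(itertools.permutations(range(n))))
    y_perm = y_rank[perms]
    xc = x_rank - x_rank.mean()
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=1))
    rho = (yc @ xc) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def spearman_association(score, panel: ResponsePanel) -> pd.DataFrame:
    """Spearman correlation of a per-sample score with every analyte.

    Ties get average ranks.  Two-sided p is an exact permutation test
    for n <= 9 paired observations, the t approximation otherwise.
    Constant vectors leave rho undefined (flagged).
    """
    if isinstance(score, ButyrateScore):
        score = score.scores
    score = pd.Series(score)
    rows = []
    for analyte in panel.analyte_names:
        y = panel.values[analyte]
        shared = score.index.intersection(y.index)
        pairs = pd.DataFrame({"x": score.loc[shared], "y": y.loc[shared]}).dropna()
        if len(pairs) < 4:
            raise ValidationError(
                f"fewer than 4 paired observations for analyte {analyte!r}")
        x, yv = pairs["x"].to_numpy(), pairs["y"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(yv) == 0:
            rows.append({"analyte": analyte, "rho": np.nan, "p": np.nan,
                         "n": len(pairs), "flagged": True})
            continue
        xr, yr = stats.rankdata(x), stats.rankdata(yv)
        rho = float(np.corrcoef(xr, yr)[0, 1])
        if len(pairs) <= 9:
            p = _exact_spearman_p(xr, yr, rho)
        else:
            p = float(stats.spearmanr(x, yv).pvalue)
        rows.append({"analyte": analyte, "rho": rho, "p": p, "n": len(pairs),
                     "flagged": False})
    return pd.DataFrame(rows).set_index("analyte")
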