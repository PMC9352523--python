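"""Dirichlet-multinomial mixture (DMM) clustering of count communities.

Each mixture component k is a Dirichlet distribution over taxon
proportions with parameter vector alpha_k > 0; a sample's counts are
multinomial draws from component-specific proportions, so the marginal
per-component density is the Dirichlet-multinomial (DM).  Fitting is by
expectation-maximization: the E-step computes responsibilities
proportional to pi_k * DM(x_i | alpha_k), the M-step sets pi_k to the
mean responsibility and updates each alpha_k by responsibility-weighted
fixed-point iterations on the digamma stationarity condition (a
lower-bound ascent, so the observed-data log-likelihood never
decreases).

Model selection across the number of clusters K uses a Laplace
approximation of the negative log model evidence: the mixture
log-posterior at the EM mode plus a Gaussian-volume correction from the
Hessian in the log(alpha) parameterization.  Lower is better; the
scheme penalizes the K * n_taxa free Dirichlet parameters and thereby
trades fit against complexity.

Cluster robustness follows a leave-one-group-out design: samples are
split into ``n_folds`` groups, the mixture is refit on each 90% subset,
and every held-in sample's new label is compared (after optimal label
matching) with its full-data label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, logsumexp, polygamma
from sklearn.cluster import KMeans

from .io_formats import CountTable, ValidationError

logger = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-8
_PRIOR_SD = 10.0  # sd of the Gaussian prior on log(alpha); weakly informative


def trigamma(x):
    return polygamma(1, x)


@dataclass
class DmmModel:
    """Fitted Dirichlet-multinomial mixture.

    ``alpha`` has shape (K, n_taxa); ``pi`` is the mixture weight
    simplex; ``responsibilities`` is samples x K with rows summing to 1.
    ``laplace`` (negative log model evidence, lower = better) is filled
    in by :func:`laplace_evidence`.
    """

    k: int
    alpha: np.ndarray
    pi: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    sample_ids: list[str]
    taxon_ids: list[str]
    converged: bool
    n_iter: int
    loglik_history: np.ndarray
    n_reinits: int = 0
    laplace: float | None = None


@dataclass
class ClusterAssignment:
    """Hard cluster labels (1..K) with the posterior probability of each."""

    sample_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray

    def label_of(self, sample: str) -> int:
        return int(self.labels[self.sample_ids.index(sample)])


@dataclass
class LabelMatch:
    """Optimal one-to-one label mapping between two clusterings."""

    mapping: dict[int, int]  # label in b -> label in a
    n_agree: int
    n_total: int

    @property
    def agreement_pct(self) -> float:
        return 100.0 * self.n_agree / self.n_total


@dataclass
class ConcordanceResult:
    """Outcome of the n-fold re-clustering robustness procedure."""

    n_assignments: int
    n_discordant: int
    n_failed_folds: int = 0

    @property
    def concordance_pct(self) -> float:
        return 100.0 * (self.n_assignments - self.n_discordant) / self.n_assignments


# ---------------------------------------------------------------------------
# Dirichlet-multinomial density


def dm_log_pmf(counts, alpha) -> float:
    """Log Dirichlet-multinomial pmf of one count vector.

    log [ N! / prod(x_j!) * Gamma(A)/Gamma(N+A) * prod Gamma(x_j+a_j)/Gamma(a_j) ]
    with A = sum(alpha), N = sum(counts); evaluated via log-gamma.
    """
    x = np.asarray(counts, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if x.shape != a.shape:
        raise ValidationError("counts and alpha must have the same length")
    if (x < 0).any():
        raise ValidationError("negative counts")
    if (a <= 0).any():
        raise ValidationError("alpha must be strictly positive")
    n = x.sum()
    big_a = a.sum()
    coeff = gammaln(n + 1) - gammaln(x + 1).sum()
    return float(coeff + gammaln(big_a) - gammaln(n + big_a)
                 + (gammaln(x + a) - gammaln(a)).sum())


def _dm_log_pmf_rows(x: np.ndarray, alpha: np.ndarray, log_coeff: np.ndarray) -> np.ndarray:
    """Vectorized DM log pmf of every row of ``x`` under one alpha."""
    big_a = alpha.sum()
    depths = x.sum(axis=1)
    return (log_coeff + gammaln(big_a) - gammaln(depths + big_a)
            + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1))


def _multinomial_log_coeff(x: np.ndarray) -> np.ndarray:
    return gammaln(x.sum(axis=1) + 1) - gammaln(x + 1).sum(axis=1)


def _fit_alpha_weighted(x: np.ndarray, w: np.ndarray, alpha0: np.ndarray,
                        tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Weighted DM maximum likelihood for one component (fixed-point).

    Iterates a_j <- a_j * sum_i w_i [psi(x_ij+a_j)-psi(a_j)]
                       / sum_i w_i [psi(N_i+A)-psi(A)]
    which monotonically increases the weighted DM log-likelihood.
    """
    alpha = np.maximum(alpha0, _ALPHA_FLOOR).astype(float)
    depths = x.sum(axis=1)
    w_sum = w.sum()
    if w_sum <= 0:
        return alpha
    for _ in range(max_iter):
        big_a = alpha.sum()
        num = (w[:, None] * (digamma(x + alpha) - digamma(alpha))).sum(axis=0)
        den = (w * (digamma(depths + big_a) - digamma(big_a))).sum()
        if den <= 0:
            break
        new = alpha * num / den
        new = np.maximum(new, _ALPHA_FLOOR)
        if np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-6)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def _init_responsibilities(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means split of relative-abundance profiles, plus jitter."""
    n = x.shape[0]
    if k == 1:
        return np.ones((n, 1))
    props = x / x.sum(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=4,
                random_state=int(rng.integers(0, 2**31 - 1)))
    labels = km.fit_predict(props)
    resp = np.full((n, k), 0.05)
    resp[np.arange(n), labels] = 1.0
    resp += rng.uniform(0, 0.1, size=(n, k))
    return resp / resp.sum(axis=1, keepdims=True)


def fit_dmm(table: CountTable, k: int, seed: int | None = None,
            tol: float = 1e-6, max_iter: int = 500,
            n_restarts: int = 5) -> DmmModel:
    """Fit a K-component Dirichlet-multinomial mixture by EM.

    The best of ``n_restarts`` random initializations (k-means split of
    relative abundances plus jitter) is returned.  Convergence is
    declared when the relative change in log-likelihood falls below
    ``tol``; a run that exhausts ``max_iter`` is returned flagged
    ``converged=False`` rather than raising.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > table.n_samples:
        raise ValidationError(f"k={k} exceeds the number of samples ({table.n_samples})")
    x = table.counts.astype(float)
    log_coeff = _multinomial_log_coeff(x)
    rng = np.random.default_rng(seed)
    best: DmmModel | None = None
    restarts = 1 if k == 1 else max(1, n_restarts)
    for _ in range(restarts):
        model = _fit_dmm_once(x, k, rng, tol, max_iter, log_coeff,
                              table.sample_ids, table.taxon_ids)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def _fit_dmm_once(x, k, rng, tol, max_iter, log_coeff, sample_ids, taxon_ids) -> DmmModel:
    n, t = x.shape
    resp = _init_responsibilities(x, k, rng)
    props = x / x.sum(axis=1, keepdims=True)
    # moment-style start: responsibility-weighted mean proportions x precision 10
    alpha = np.empty((k, t))
    for j in range(k):
        w = resp[:, j]
        mean_p = (w[:, None] * props).sum(axis=0) / w.sum()
        alpha[j] = np.maximum(mean_p * 10.0, _ALPHA_FLOOR)
    pi = resp.mean(axis=0)

    history = []
    loglik = -np.inf
    converged = False
    n_reinits = 0
    for it in range(max_iter):
        # E-step
        log_dens = np.stack([_dm_log_pmf_rows(x, alpha[j], log_coeff)
                             for j in range(k)], axis=1)
        log_joint = log_dens + np.log(np.maximum(pi, 1e-300))
        log_norm = logsumexp(log_joint, axis=1)
        new_loglik = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        history.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * abs(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        # M-step
        pi = resp.mean(axis=0)
        empty = pi < 1.0 / (10.0 * n)
        if empty.any():
            # re-seed dead components from the worst-fit samples
            worst = np.argsort(log_norm)
            for idx, j in enumerate(np.where(empty)[0]):
                s = worst[idx % n]
                resp[s] = 0.0
                resp[s, j] = 1.0
                n_reinits += 1
            pi = resp.mean(axis=0)
            logger.info("reinitialized %d empty DMM component(s)", int(empty.sum()))
        for j in range(k):
            w = resp[:, j]
            mean_p = (w[:, None] * props).sum(axis=0) / max(w.sum(), 1e-12)
            start = alpha[j] if not empty[j] else np.maximum(mean_p * 10.0, _ALPHA_FLOOR)
            alpha[j] = _fit_alpha_weighted(x, w, start)
    return DmmModel(k=k, alpha=alpha, pi=pi, responsibilities=resp,
                    log_likelihood=loglik, sample_ids=list(sample_ids),
                    taxon_ids=list(taxon_ids), converged=converged,
                    n_iter=len(history), loglik_history=np.asarray(history),
                    n_reinits=n_reinits)


# ---------------------------------------------------------------------------
# Laplace model evidence


def laplace_evidence(model: DmmModel, table: CountTable) -> float:
    """Negative log model evidence via the Laplace approximation.

    Approximates -log integral of likelihood x prior by expanding the
    log-posterior around the EM mode in the log(alpha) parameterization:

        -[ log p(data, alpha*) + (d/2) ln(2 pi) - (1/2) ln det H ]

    with d = K * n_taxa free parameters and H the Hessian of the
    negative log posterior at the mode.  The Hessian is evaluated with
    responsibilities held at their converged values, which makes it
    block-diagonal across components; the prior on each log(alpha) entry
    is N(0, 10^2).  Lower values indicate better evidence.  A
    non-positive-definite block falls back to its diagonal (logged).
    """
    x = table.counts.astype(float)
    if model.alpha.shape[1] != x.shape[1]:
        raise ValidationError("model and table disagree on the number of taxa")
    k, t = model.alpha.shape
    lam = np.log(model.alpha)
    log_prior = float(-0.5 * (lam ** 2).sum() / _PRIOR_SD ** 2
                      - lam.size * np.log(_PRIOR_SD * np.sqrt(2 * np.pi)))
    d = k * t
    depths = x.sum(axis=1)
    log_det = 0.0
    for j in range(k):
        a = model.alpha[j]
        w = model.responsibilities[:, j]
        big_a = a.sum()
        grad = (w[:, None] * (digamma(big_a) - digamma(depths + big_a)[:, None]
                              + digamma(x + a) - digamma(a))).sum(axis=0)
        u = float((w * (trigamma(big_a) - trigamma(depths + big_a))).sum())
        v = (w[:, None] * (trigamma(x + a) - trigamma(a))).sum(axis=0)
        hess_a = np.full((t, t), u) + np.diag(v)
        hess_lam = (a[:, None] * a[None, :]) * hess_a + np.diag(a * grad)
        h = -hess_lam + np.eye(t) / _PRIOR_SD ** 2
        sign, block_logdet = np.linalg.slogdet(h)
        if sign <= 0 or not np.isfinite(block_logdet):
            diag = np.maximum(np.diag(h), 1e-12)
            block_logdet = float(np.log(diag).sum())
            logger.warning("Laplace Hessian block %d not positive definite; "
                           "using diagonal approximation", j)
        log_det += block_logdet
    evidence = -(model.log_likelihood + log_prior) - 0.5 * d * np.log(2 * np.pi) \
        + 0.5 * log_det
    model.laplace = float(evidence)
    return model.laplace


def select_k(table: CountTable, k_range, seeds, **fit_kwargs):
    """Choose the number of clusters by minimum Laplace evidence.

    ``seeds`` is either an iterable of integers or a count (distinct
    seeds 0..n-1).  For each K the best (lowest) evidence over seeds is
    kept; the selected K is the argmin over the scanned range.

    Returns ``(best_k, evidence)`` where ``evidence`` maps each feasible
    K to its best negative log evidence.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValidationError("k_range must be non-empty")
    if isinstance(seeds, (int, np.integer)):
        seeds = list(range(int(seeds)))
    evidence: dict[int, float] = {}
    for k in k_range:
        if k < 1 or k > table.n_samples:
            logger.warning("skipping infeasible K=%d", k)
            continue
        best = np.inf
        for s in seeds:
            model = fit_dmm(table, k, seed=s, **fit_kwargs)
            best = min(best, laplace_evidence(model, table))
        evidence[k] = best
    if not evidence:
        raise ValidationError("no feasible K in the requested range")
    best_k = min(evidence, key=evidence.get)
    return best_k, evidence


# ---------------------------------------------------------------------------
# assignments, matching, robustness


def hard_assignment(model: DmmModel) -> ClusterAssignment:
    """Hard labels (1..K) by maximum responsibility; ties go to the lower index."""
    labels = model.responsibilities.argmax(axis=1) + 1
    probs = model.responsibilities.max(axis=1)
    return ClusterAssignment(list(model.sample_ids), labels, probs)


def match_clusters(a: ClusterAssignment, b: ClusterAssignment) -> LabelMatch:
    """Optimal one-to-one label mapping from b's labels onto a's.

    Solves the assignment problem on the confusion matrix of the shared
    samples, maximizing the number of agreements.
    """
    shared = [s for s in b.sample_ids if s in set(a.sample_ids)]
    if not shared:
        raise ValidationError("no shared samples between the two clusterings")
    a_idx = {s: i for i, s in enumerate(a.sample_ids)}
    b_idx = {s: i for i, s in enumerate(b.sample_ids)}
    la = np.array([a.labels[a_idx[s]] for s in shared])
    lb = np.array([b.labels[b_idx[s]] for s in shared])
    labels_a = np.unique(np.concatenate([la, lb]))
    k = labels_a.max()
    confusion = np.zeros((k, k), dtype=int)
    for ya, yb in zip(la, lb):
        confusion[yb - 1, ya - 1] += 1
    rows, cols = linear_sum_assignment(-confusion)
    mapping = {int(r + 1): int(c + 1) for r, c in zip(rows, cols)}
    n_agree = int(confusion[rows, cols].sum())
    return LabelMatch(mapping=mapping, n_agree=n_agree, n_total=len(shared))


def fold_partition(n_samples: int, n_folds: int, seed: int | None = None) -> list[np.ndarray]:
    """Seeded random partition of sample indices into ``n_folds`` groups."""
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if n_samples < n_folds:
        raise ValidationError("need at least one sample per fold")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n_samples), n_folds)


def n_heldin_assignments(n_samples: int, n_folds: int = 10, seed: int | None = 0) -> int:
    """Number of held-in re-clustering events the n-fold procedure produces.

    Each fold's refit re-assigns the samples of the other folds, so every
    sample is re-clustered (n_folds - 1) times.
    """
    folds = fold_partition(n_samples, n_folds, seed)
    return int(sum(n_samples - fold.size for fold in folds))


def reclustering_concordance(table: CountTable, k: int, n_folds: int = 10,
                             seed: int | None = None,
                             **fit_kwargs) -> ConcordanceResult:
    """Leave-one-group-out DMM robustness check.

    Samples are randomly split into ``n_folds`` groups; for each group
    the mixture is refit on the remaining ~90% and every held-in
    sample's refit label is compared, after optimal label matching, with
    its label from the full-data clustering.  Folds whose refit fails to
    converge are excluded from the totals and counted.
    """
    rng = np.random.default_rng(seed)
    full = fit_dmm(table, k, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
    full_assign = hard_assignment(full)
    folds = fold_partition(table.n_samples, n_folds, int(rng.integers(2**31 - 1)))
    n_assignments = 0
    n_discordant = 0
    n_failed = 0
    for fold in folds:
        held_in = np.setdiff1d(np.arange(table.n_samples), fold)
        sub = table.select_samples([table.sample_ids[i] for i in held_in])
        refit = fit_dmm(sub, k, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
        if not refit.converged:
            n_failed += 1
            logger.warning("fold refit failed to converge; excluded from totals")
            continue
        match = match_clusters(full_assign, hard_assignment(refit))
        n_assignments += match.n_total
        n_discordant += match.n_total - match.n_agree
    if n_assignments == 0:
        raise ValidationError("every fold refit failed; no concordance computable")
    return ConcordanceResult(n_assignments=n_assignments,
                             n_discordant=n_discordant,
                             n_failed_folds=n_failed)
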