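"""Per-OTU differential-abundance tests with permutation nulls.

Each OTU is modelled as a binomial proportion: the OTU's read count out
of the sample total, after adding 2 to every count and 4 to every total
(two pseudo-successes and two pseudo-failures), fitted by a logistic
GLM.  Health status enters as a three-level fixed effect, or the
average gingivitis score of the sampled teeth as a continuous effect.

Because subgingival OTU proportions are tiny and overdispersed, p-values
are not taken from the GLM's asymptotic distribution.  Instead the
observed test statistic is referred to a permutation null built by
shuffling group labels (or scores), with

    p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations)

so p is always positive and valid.  The overall health-status statistic
is the deviance reduction of adding health to the intercept-only model;
pairwise contrasts use the squared Wald z of a two-group fit with labels
permuted among those two groups only, conditioning on the third group.
Benjamini-Hochberg adjustment is applied across OTUs separately within
each family of tests (overall, each contrast, trend).

The IRLS fitter is vectorised over permutation replicates, which is what
makes 1000-permutation nulls for hundreds of OTUs affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, xlogy

from .abundance import HEALTH_STATES, OtuTable, RARE_ID, check_samples_match

CONTRASTS = (
    ("H-vs-G", "health", "gingivitis"),
    ("G-vs-PD1", "gingivitis", "pd1"),
    ("H-vs-PD1", "health", "pd1"),
)

_PSEUDO_SUCC = 2.0
_PSEUDO_TOT = 4.0
# Numeric guard when comparing permuted statistics with the observed one:
# an exchangeable-null statistic recomputed under permutation can differ
# from the observed value by floating-point noise only.
_STAT_TOL = 1e-9


class DesignError(ValueError):
    """The design matrix is rank deficient or groups are degenerate."""


@dataclass
class GlmFit:
    """Maximum-likelihood binomial GLM fit (logit link)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    deviance: float
    fitted_proportions: np.ndarray
    converged: bool


@dataclass
class AssociationResult:
    """Health-status test result for one OTU."""

    otu_id: str
    overall_stat: float
    overall_perm_p: float
    contrast_estimates: dict[str, float]
    contrast_perm_p: dict[str, float]
    q_values: dict[str, float] = field(default_factory=dict)


@dataclass
class TrendResult:
    """Gingivitis-score trend test result for one OTU."""

    otu_id: str
    slope: float
    perm_p: float
    fit: GlmFit | None = None
    q_value: float | None = None


def _binomial_deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Deviance of batched fits; y, n, mu have shape (B, s)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * (
            xlogy(y, y) - xlogy(y, n * mu) + xlogy(n - y, n - y) - xlogy(n - y, n * (1.0 - mu))
        )
    return dev.sum(axis=-1)


def _batched_irls(
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """IRLS for B binomial-logit GLMs sharing one design matrix.

    X: (s, p); y, n: (B, s).  Returns (beta (B,p), cov (B,p,p),
    deviance (B,), mu (B,s), converged (B,)).
    """
    B, s = y.shape
    p = X.shape[1]
    phat = np.clip((y + 0.5) / (n + 1.0), 1e-6, 1.0 - 1e-6)
    eta = logit(phat)
    beta = np.zeros((B, p))
    dev = np.full(B, np.inf)
    converged = np.zeros(B, dtype=bool)
    A = np.zeros((B, p, p))
    for _ in range(max_iter):
        mu = expit(np.clip(eta, -30.0, 30.0))
        W = np.maximum(n * mu * (1.0 - mu), 1e-12)
        z = eta + (y - n * mu) / W
        A = np.einsum("si,bs,sj->bij", X, W, X, optimize=True)
        rhs = np.einsum("si,bs,bs->bi", X, W, z, optimize=True)
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
        eta = beta @ X.T
        new_dev = _binomial_deviance(y, n, expit(np.clip(eta, -30.0, 30.0)))
        converged = np.abs(dev - new_dev) < tol
        dev = new_dev
        if converged.all():
            break
    mu = expit(np.clip(eta, -30.0, 30.0))
    cov = np.linalg.inv(A)
    return beta, cov, dev, mu, converged


def fit_binomial_glm(
    successes: Sequence[float],
    totals: Sequence[float],
    design: np.ndarray,
) -> GlmFit:
    """Fit one binomial GLM with logit link by IRLS.

    ``design`` is the n x p model matrix (include the intercept column
    explicitly).  Convergence: deviance change < 1e-8 or 100 iterations;
    non-convergence is flagged on the returned fit, never silent.
    """
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    X = np.asarray(design, dtype=float)
    if y.ndim != 1 or y.shape != n.shape or X.shape[0] != y.shape[0]:
        raise DesignError("successes, totals and design rows must align")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= successes <= totals elementwise")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    beta, cov, dev, mu, converged = _batched_irls(X, y[None, :], n[None, :])
    return GlmFit(
        coefficients=beta[0],
        standard_errors=np.sqrt(np.diag(cov[0])),
        covariance=cov[0],
        deviance=float(dev[0]),
        fitted_proportions=mu[0],
        converged=bool(converged[0]),
    )


def perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    """p = (1 + #{permuted >= observed}) / (1 + B), with a float-noise guard."""
    permuted = np.asarray(permuted, dtype=float)
    guard = _STAT_TOL * max(1.0, abs(observed))
    exceed = int(np.sum(permuted >= observed - guard))
    return (1.0 + exceed) / (1.0 + permuted.size)


def _adjust(counts: np.ndarray, totals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return counts + _PSEUDO_SUCC, totals + _PSEUDO_TOT


def _null_deviance(y: np.ndarray, n: np.ndarray) -> float:
    mu = y.sum() / n.sum()
    return float(_binomial_deviance(y[None, :], n[None, :], np.full((1, len(y)), mu))[0])


def _group_design(labels: np.ndarray) -> np.ndarray:
    X = np.ones((len(labels), 3))
    X[:, 1] = labels == "gingivitis"
    X[:, 2] = labels == "pd1"
    return X


def health_status_test(
    counts: Sequence[int],
    totals: Sequence[int],
    health_labels: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    otu_id: str = "",
    contrasts: Sequence[str] | None = None,
    include_overall: bool = True,
) -> AssociationResult:
    """Permutation test of a health-status effect on one OTU's proportion.

    Counts/totals are raw; the 2/4 pseudo-count adjustment is applied
    internally.  The overall statistic permutes all labels jointly
    (implemented by permuting the (count, total) pairs, which leaves the
    invariant null deviance fixed); each pairwise contrast refits a
    two-group model with labels permuted within those two groups only.
    """
    labels = np.asarray(health_labels)
    c = np.asarray(counts, dtype=float)
    t = np.asarray(totals, dtype=float)
    if not (len(c) == len(t) == len(labels)):
        raise DesignError("counts, totals and labels must align")
    for state in HEALTH_STATES:
        if not np.any(labels == state):
            raise DesignError(f"health group {state!r} is empty")
    y, n = _adjust(c, t)
    rng = np.random.default_rng(seed)

    overall_stat = np.nan
    overall_p = np.nan
    if include_overall:
        X = _group_design(labels)
        d_null = _null_deviance(y, n)
        _, _, dev_obs, _, _ = _batched_irls(X, y[None, :], n[None, :])
        overall_stat = d_null - float(dev_obs[0])
        idx = np.tile(np.arange(len(y)), (n_perm, 1))
        idx = rng.permuted(idx, axis=1)
        _, _, dev_perm, _, _ = _batched_irls(X, y[idx], n[idx])
        overall_p = perm_pvalue(overall_stat, d_null - dev_perm)

    wanted = set(contrasts) if contrasts is not None else {k for k, _, _ in CONTRASTS}
    estimates: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for key, first, second in CONTRASTS:
        if key not in wanted:
            continue
        mask = (labels == first) | (labels == second)
        ys, ns = y[mask], n[mask]
        Xp = np.ones((mask.sum(), 2))
        Xp[:, 1] = labels[mask] == second
        beta, cov, _, _, _ = _batched_irls(Xp, ys[None, :], ns[None, :])
        coef = beta[0, 1]
        z2_obs = coef**2 / cov[0, 1, 1]
        estimates[key] = -coef  # logit(p_first) - logit(p_second)
        idx = np.tile(np.arange(len(ys)), (n_perm, 1))
        idx = rng.permuted(idx, axis=1)
        beta_p, cov_p, _, _, _ = _batched_irls(Xp, ys[idx], ns[idx])
        z2_perm = beta_p[:, 1] ** 2 / cov_p[:, 1, 1]
        pvals[key] = perm_pvalue(z2_obs, z2_perm)
    return AssociationResult(
        otu_id=otu_id,
        overall_stat=overall_stat,
        overall_perm_p=overall_p,
        contrast_estimates=estimates,
        contrast_perm_p=pvals,
    )


def gingivitis_trend_test(
    counts: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float],
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    otu_id: str = "",
) -> TrendResult:
    """Permutation test of a gingivitis-score trend in one OTU's proportion.

    The slope is the logit-scale change per unit of average gingivitis
    score; the permutation shuffles the score vector (equivalently the
    (count, total) pairs) and uses the deviance reduction of adding the
    score to an intercept-only model as the statistic.
    """
    c = np.asarray(counts, dtype=float)
    t = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (len(c) == len(t) == len(s)):
        raise DesignError("counts, totals and scores must align")
    if np.ptp(s) == 0:
        raise DesignError("scores are constant; trend is unidentifiable")
    y, n = _adjust(c, t)
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones_like(s), s])
    d_null = _null_deviance(y, n)
    beta, cov, dev_obs, mu, conv = _batched_irls(X, y[None, :], n[None, :])
    stat_obs = d_null - float(dev_obs[0])
    idx = np.tile(np.arange(len(y)), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    _, _, dev_perm, _, _ = _batched_irls(X, y[idx], n[idx])
    p = perm_pvalue(stat_obs, d_null - dev_perm)
    fit = GlmFit(
        coefficients=beta[0],
        standard_errors=np.sqrt(np.diagonal(cov[0])),
        covariance=cov[0],
        deviance=float(dev_obs[0]),
        fitted_proportions=mu[0],
        converged=bool(conv[0]),
    )
    return TrendResult(otu_id=otu_id, slope=float(beta[0, 1]), perm_p=p, fit=fit)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def predict_trend_curve(
    fit: GlmFit, score_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitted proportion curve with a pointwise 95% CI band.

    The band is the linear predictor +/- 1.96 SE mapped through the
    inverse logit, so its endpoints always lie in (0, 1) and it contains
    the curve pointwise.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to extrapolate")
    g = np.asarray(score_grid, dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    eta = X @ fit.coefficients
    se = np.sqrt(np.einsum("gi,ij,gj->g", X, fit.covariance, X))
    return expit(eta), expit(eta - 1.96 * se), expit(eta + 1.96 * se)


# ---------------------------------------------------------------------------
# Whole-table wrappers (per-OTU tests + per-family BH correction)
# ---------------------------------------------------------------------------


def health_status_tests(
    table: OtuTable,
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    include_rare: bool = False,
    contrasts: Sequence[str] | None = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Health-status permutation tests for every OTU in a table.

    Returns a long-format frame ``otu_id, contrast, estimate, perm_p,
    q_value`` where ``contrast`` is ``overall`` or a pairwise key; BH
    adjustment is applied across OTUs separately within each family.
    The pooled ``RARE`` row is excluded unless ``include_rare``.
    """
    check_samples_match(table, metadata)
    df = table.counts
    if not include_rare and RARE_ID in df.index:
        df = df.drop(index=RARE_ID)
    totals = table.counts.sum(axis=0)  # totals always include rare reads
    labels = metadata.loc[df.columns, "health_status"].to_numpy()
    children = np.random.SeedSequence(seed).spawn(len(df.index))
    results = [
        health_status_test(
            df.loc[otu].to_numpy(),
            totals.to_numpy(),
            labels,
            n_perm=n_perm,
            seed=child,
            otu_id=otu,
            contrasts=contrasts,
            include_overall=include_overall,
        )
        for otu, child in zip(df.index, children)
    ]
    rows = []
    families: list[str] = (["overall"] if include_overall else []) + [
        k for k, _, _ in CONTRASTS if contrasts is None or k in set(contrasts)
    ]
    for family in families:
        if family == "overall":
            ps = [r.overall_perm_p for r in results]
            ests = [np.nan] * len(results)
        else:
            ps = [r.contrast_perm_p[family] for r in results]
            ests = [r.contrast_estimates[family] for r in results]
        qs = bh_adjust(ps)
        for r, est, p, q in zip(results, ests, ps, qs):
            r.q_values[family] = float(q)
            rows.append(
                {
                    "otu_id": r.otu_id,
                    "contrast": family,
                    "estimate": est,
                    "perm_p": p,
                    "q_value": float(q),
                }
            )
    return pd.DataFrame(rows)


def gingivitis_trend_tests(
    table: OtuTable,
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    include_rare: bool = True,
) -> pd.DataFrame:
    """Score-trend permutation tests for every OTU (rare row included).

    Returns ``otu_id, slope, perm_p, q_value`` with BH across OTUs.
    """
    check_samples_match(table, metadata)
    df = table.counts
    if not include_rare and RARE_ID in df.index:
        df = df.drop(index=RARE_ID)
    totals = table.counts.sum(axis=0)
    scores = metadata.loc[df.columns, "avg_gingivitis_score"].to_numpy(dtype=float)
    children = np.random.SeedSequence(seed).spawn(len(df.index))
    results = [
        gingivitis_trend_test(
            df.loc[otu].to_numpy(),
            totals.to_numpy(),
            scores,
            n_perm=n_perm,
            seed=child,
            otu_id=otu,
        )
        for otu, child in zip(df.index, children)
    ]
    qs = bh_adjust([r.perm_p for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in results],
            "slope": [r.slope for r in results],
            "perm_p": [r.perm_p for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
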