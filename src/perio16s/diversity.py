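"""Alpha diversity, linear trait models, PCA and Jensen-Shannon PCoA.

Shannon index H = -sum p_i ln p_i (natural log) and species richness
(OTUs detected per sample) are compared across health states with
ordinary linear models (richness additionally adjusts for the sample's
total sequence count).  Sample ordination uses (a) PCA of the log10
pseudo-count-adjusted proportions and (b) classical-scaling PCoA of the
square-root Jensen-Shannon divergence, the metric form of JSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import rel_entr

from .abundance import HEALTH_STATES

_LN2 = np.log(2.0)


class OrdinationError(ValueError):
    """Input unsuitable for ordination (constant matrix, asymmetry...)."""


@dataclass
class Ordination:
    """Sample coordinates from PCA or PCoA."""

    coordinates: pd.DataFrame  # samples x axes
    explained_fraction: np.ndarray
    method: str  # "PCA" | "PCoA"
    eigenvalues: np.ndarray


@dataclass
class TraitModelResult:
    """Linear-model comparison of a per-sample trait across health states."""

    overall_f: float
    overall_p: float
    pairwise_estimates: dict[str, float]
    pairwise_p: dict[str, float]


def shannon_index(counts: Sequence[float]) -> float:
    """Shannon diversity H = -sum p ln p over positive counts (natural log)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one count must be positive")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts: Sequence[float]) -> int:
    """Number of OTUs with a positive count."""
    c = np.asarray(counts, dtype=float)
    return int(np.count_nonzero(c > 0))


_PAIRS = (("H-vs-G", "health", "gingivitis"),
          ("G-vs-PD1", "gingivitis", "pd1"),
          ("H-vs-PD1", "health", "pd1"))


def trait_linear_model(
    values: Sequence[float],
    health_labels: Sequence[str],
    covariate: Sequence[float] | None = None,
) -> TraitModelResult:
    """OLS of a trait on health status (plus an optional covariate).

    Overall health effect: F-test of the two group dummies; pairwise
    group differences: t contrasts.  Used with the Shannon index (no
    covariate) and species richness (total sequences as covariate).
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(health_labels)
    cols = [np.ones(len(y)),
            (labels == "gingivitis").astype(float),
            (labels == "pd1").astype(float)]
    names = ["intercept", "gingivitis", "pd1"]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
        names.append("covariate")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise OrdinationError("design is collinear")
    if len(y) <= X.shape[1]:
        raise ValueError("need more samples than parameters")
    if np.ptp(y) == 0.0:
        # Constant trait: no effect, define F = 0 / p = 1 rather than 0/0.
        zero = {k: 0.0 for k, _, _ in _PAIRS}
        one = {k: 1.0 for k, _, _ in _PAIRS}
        return TraitModelResult(overall_f=0.0, overall_p=1.0,
                                pairwise_estimates=zero, pairwise_p=one)
    model = sm.OLS(y, X).fit()
    restriction = np.zeros((2, X.shape[1]))
    restriction[0, 1] = 1.0
    restriction[1, 2] = 1.0
    ftest = model.f_test(restriction)
    # Group means on the linear predictor: health = b0, gingivitis =
    # b0+b1, pd1 = b0+b2 (covariate held fixed).
    L = {"health": 0.0, "gingivitis": 1, "pd1": 2}
    est, pv = {}, {}
    for key, first, second in _PAIRS:
        cvec = np.zeros(X.shape[1])
        if first != "health":
            cvec[L[first]] = 1.0
        if second != "health":
            cvec[L[second]] -= 1.0
        tt = model.t_test(cvec)
        est[key] = float(np.squeeze(tt.effect))
        pv[key] = float(np.squeeze(tt.pvalue))
    return TraitModelResult(
        overall_f=float(np.squeeze(ftest.fvalue)),
        overall_p=float(np.squeeze(ftest.pvalue)),
        pairwise_estimates=est,
        pairwise_p=pv,
    )


def diversity_frame(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index and richness from an OTU x sample frame."""
    return pd.DataFrame(
        {
            "shannon": counts.apply(lambda col: shannon_index(col.to_numpy())),
            "richness": counts.apply(lambda col: richness(col.to_numpy())),
            "total_reads": counts.sum(axis=0),
        }
    )


def pca_scores(log10_props: pd.DataFrame) -> Ordination:
    """PCA (covariance, via SVD) of a samples x OTUs log10-proportion matrix.

    Columns are centered; explained fractions are normalised squared
    singular values; the sign of each axis is fixed so the largest-
    magnitude OTU loading is positive.
    """
    X = log10_props.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise OrdinationError("need at least 2 samples and 2 OTUs")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise OrdinationError("matrix is constant; explained variance undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # Sign convention: largest-|loading| per axis positive.
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    explained = s**2 / np.sum(s**2)
    coords = pd.DataFrame(
        scores,
        index=log10_props.index,
        columns=[f"axis{k + 1}" for k in range(scores.shape[1])],
    )
    eigenvalues = s**2 / max(X.shape[0] - 1, 1)
    return Ordination(
        coordinates=coords,
        explained_fraction=explained,
        method="PCA",
        eigenvalues=eigenvalues,
    )


def jsd(p: Sequence[float], q: Sequence[float], base: str = "e") -> float:
    """Jensen-Shannon divergence between two distributions.

    JSD = KL(p||m)/2 + KL(q||m)/2 with m the midpoint mixture, natural
    log by default (range [0, ln 2]); ``base="2"`` rescales to [0, 1].
    Zero components follow the 0*ln(0) = 0 convention.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("distributions must each sum to 1 (within 1e-9)")
    m = 0.5 * (p + q)
    val = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    if base == "2":
        val = val / _LN2
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return float(val)


def jsd_distance_matrix(props: pd.DataFrame) -> pd.DataFrame:
    """Square matrix of sqrt-JSD distances between sample rows.

    ``props`` is samples x OTUs with rows summing to 1; the square root
    of the Jensen-Shannon divergence is a metric.
    """
    X = props.to_numpy(dtype=float)
    X = X / X.sum(axis=1, keepdims=True)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        pi = X[i]
        m = 0.5 * (pi[None, :] + X[i + 1 :])
        kl_p = rel_entr(np.broadcast_to(pi, m.shape), m).sum(axis=1)
        kl_q = rel_entr(X[i + 1 :], m).sum(axis=1)
        D[i, i + 1 :] = np.sqrt(np.maximum(0.5 * kl_p + 0.5 * kl_q, 0.0))
    D = D + D.T
    return pd.DataFrame(D, index=props.index, columns=props.index)


def pcoa(distance_matrix: pd.DataFrame | np.ndarray) -> Ordination:
    """Classical scaling (Gower double-centering + eigendecomposition).

    Axes with eigenvalue > 1e-10 are retained; negative eigenvalues are
    reported in ``eigenvalues`` but their axes dropped; explained
    fractions are over the positive eigenvalues.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        ids = distance_matrix.index
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        ids = pd.RangeIndex(D.shape[0])
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise OrdinationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise OrdinationError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12) or np.any(D < 0):
        raise OrdinationError("distances must be non-negative with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10
    pos_sum = eigval[eigval > 0].sum()
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    explained = eigval[keep] / pos_sum if pos_sum > 0 else np.zeros(keep.sum())
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"axis{k + 1}" for k in range(coords.shape[1])]
    )
    return Ordination(
        coordinates=frame,
        explained_fraction=explained,
        method="PCoA",
        eigenvalues=eigval,
    )
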