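"""Gram-stain and oxygen-requirement aggregate tests.

Per-OTU annotations (Gram positive/negative; aerobe/anaerobe/facultative
anaerobe) are summed to per-sample sequence counts per label, with
unannotated OTUs (including the pooled rare row) absorbed by an
``unknown`` label so reads are conserved exactly.  The proportion of a
label's reads is then tested for a health-status effect with a
quasi-binomial logistic regression: a binomial GLM whose dispersion
``phi`` is estimated as Pearson X^2 / df and used to scale standard
errors (overall effect: F-test on the deviance reduction scaled by phi;
pairwise contrasts: t-tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import HEALTH_STATES, OtuTable, RARE_ID
from .association import CONTRASTS, DesignError, _batched_irls, _group_design

GRAM_LABELS = ("gram_positive", "gram_negative", "unknown")
OXYGEN_LABELS = ("aerobe", "anaerobe", "facultative", "unknown")

_LABEL_ALIASES = {
    "gram_positive": "gram_positive",
    "positive": "gram_positive",
    "gram_negative": "gram_negative",
    "negative": "gram_negative",
    "aerobe": "aerobe",
    "aerobic": "aerobe",
    "anaerobe": "anaerobe",
    "anaerobic": "anaerobe",
    "facultative": "facultative",
    "facultative_anaerobe": "facultative",
    "unknown": "unknown",
}


class LabelError(ValueError):
    """An annotation label token is not recognised."""


@dataclass
class AggregateTable:
    """Per-sample read counts per annotation label (labels x samples)."""

    counts: pd.DataFrame
    label_set: tuple[str, ...]

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class OverdispersionResult:
    """Quasi-binomial health-status test for one label's proportion."""

    label: str
    overall_p: float
    overall_f: float
    pairwise_p: dict[str, float]
    pairwise_estimates: dict[str, float]
    dispersion: float
    group_means_pct: dict[str, float]


def aggregate_counts(
    table: OtuTable,
    otu_labels: Mapping[str, str],
    label_set: Sequence[str],
) -> AggregateTable:
    """Sum per-OTU counts into per-sample counts per annotation label.

    OTUs absent from ``otu_labels`` (and the ``RARE`` pooled row) fall
    into ``unknown``.  Unrecognised label tokens raise
    :class:`LabelError`.  Label counts sum to the sample totals exactly.
    """
    label_set = tuple(label_set)
    if "unknown" not in label_set:
        label_set = label_set + ("unknown",)
    resolved = {}
    for otu in table.otu_ids:
        if otu == RARE_ID:
            resolved[otu] = "unknown"
            continue
        raw = otu_labels.get(otu, "unknown")
        token = _LABEL_ALIASES.get(str(raw).strip().lower())
        if token is None:
            raise LabelError(f"unrecognised label {raw!r} for OTU {otu!r}")
        if token not in label_set:
            raise LabelError(
                f"label {token!r} for OTU {otu!r} not in label set {label_set}"
            )
        resolved[otu] = token
    groups = pd.Series(resolved, name="label")
    summed = table.counts.groupby(groups).sum()
    summed = summed.reindex(list(label_set), fill_value=0)
    summed.index.name = "label"
    return AggregateTable(counts=summed, label_set=label_set)


def overdispersed_proportion_test(
    agg: AggregateTable,
    label: str,
    health_labels: Sequence[str],
    denominator: str = "labelled",
) -> OverdispersionResult:
    """Quasi-binomial test of a health-status effect on one label's share.

    ``denominator`` is ``labelled`` (reads with a known label for this
    annotation axis; the default) or ``total`` (all reads including
    unknown).  The dispersion ``phi = Pearson X^2 / (n - p)`` scales the
    overall F statistic and the contrast standard errors.
    """
    if label not in agg.counts.index:
        raise LabelError(f"label {label!r} not present in aggregate table")
    if denominator not in ("labelled", "total"):
        raise ValueError("denominator must be 'labelled' or 'total'")
    labels = np.asarray(health_labels)
    y = agg.counts.loc[label].to_numpy(dtype=float)
    if denominator == "labelled":
        n = (agg.counts.sum(axis=0) - agg.counts.loc["unknown"]).to_numpy(dtype=float)
    else:
        n = agg.counts.sum(axis=0).to_numpy(dtype=float)
    if len(labels) != len(y):
        raise DesignError("health labels must align with samples")
    for state in HEALTH_STATES:
        if not np.any(labels == state):
            raise DesignError(f"health group {state!r} is empty")
    n_samples = len(y)
    n_params = 3
    df_resid = n_samples - n_params
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")

    X = _group_design(labels)
    beta, cov, dev_full, mu, _ = _batched_irls(X, y[None, :], n[None, :])
    beta, cov, mu = beta[0], cov[0], mu[0]
    pearson = float(np.sum((y - n * mu) ** 2 / (n * mu * (1.0 - mu))))
    phi = pearson / df_resid

    X0 = np.ones((n_samples, 1))
    _, _, dev_null, _, _ = _batched_irls(X0, y[None, :], n[None, :])
    f_stat = ((float(dev_null[0]) - float(dev_full[0])) / (n_params - 1)) / phi
    overall_p = float(stats.f.sf(f_stat, n_params - 1, df_resid))

    # Group logits from the treatment-coded fit: health = b0,
    # gingivitis = b0+b1, pd1 = b0+b2.
    L = {"health": np.array([1.0, 0.0, 0.0]),
         "gingivitis": np.array([1.0, 1.0, 0.0]),
         "pd1": np.array([1.0, 0.0, 1.0])}
    pairwise_p = {}
    pairwise_est = {}
    for key, first, second in CONTRASTS:
        cvec = L[first] - L[second]
        est = float(cvec @ beta)
        se = float(np.sqrt(cvec @ cov @ cvec * phi))
        tval = est / se
        pairwise_est[key] = est
        pairwise_p[key] = float(2.0 * stats.t.sf(abs(tval), df_resid))

    group_means = {
        state: float(100.0 * np.mean(y[labels == state] / n[labels == state]))
        for state in HEALTH_STATES
    }
    return OverdispersionResult(
        label=label,
        overall_p=overall_p,
        overall_f=float(f_stat),
        pairwise_p=pairwise_p,
        pairwise_estimates=pairwise_est,
        dispersion=float(phi),
        group_means_pct=group_means,
    )


def aggregate_tests(
    table: OtuTable,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    denominator: str = "labelled",
) -> pd.DataFrame:
    """Run the quasi-binomial test for every Gram and oxygen label.

    ``annotations`` has columns ``gram`` and ``oxygen`` indexed by OTU.
    Returns a tidy frame with one row per (axis, label, contrast).
    """
    labels = metadata.loc[table.sample_ids, "health_status"].to_numpy()
    rows = []
    for axis, label_set in (("gram", GRAM_LABELS), ("oxygen", OXYGEN_LABELS)):
        mapping = annotations[axis].to_dict()
        agg = aggregate_counts(table, mapping, label_set)
        for label in label_set:
            if label == "unknown":
                continue
            res = overdispersed_proportion_test(agg, label, labels, denominator)
            rows.append(
                {
                    "axis": axis,
                    "label": label,
                    "contrast": "overall",
                    "estimate": np.nan,
                    "p_value": res.overall_p,
                    "dispersion": res.dispersion,
                    **{f"mean_pct_{s}": res.group_means_pct[s] for s in HEALTH_STATES},
                }
            )
            for key, _, _ in CONTRASTS:
                rows.append(
                    {
                        "axis": axis,
                        "label": label,
                        "contrast": key,
                        "estimate": res.pairwise_estimates[key],
                        "p_value": res.pairwise_p[key],
                        "dispersion": res.dispersion,
                        **{f"mean_pct_{s}": res.group_means_pct[s] for s in HEALTH_STATES},
                    }
                )
    return pd.DataFrame(rows)
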