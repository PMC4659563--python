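"""Tiered core-microbiota classification (health vs mild periodontitis).

An OTU is *core-eligible* in a group when its raw relative abundance
reaches the abundance threshold (default 0.5%) in at least the
prevalence threshold (default 50%) of that group's samples.  Gingivitis
samples are excluded: the comparison is health vs mild periodontitis
(PD1).  Eligibility in only one group assigns the OTU to that group's
core; eligibility in both makes it shared unless one group dominates
both qualifying prevalence and mean abundance by the skew ratio
(default 1.5-fold), in which case the OTU moves to that group's core.

Tiers within the assigned group (shared OTUs tier on their
higher-prevalence group):

* tier 1 - highly prevalent (>= 2/3 of samples) and highly abundant
  (mean >= 2% of reads);
* tier 2 - highly prevalent, mean abundance < 2%;
* tier 3 - prevalence in [1/2, 2/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import OtuTable, RARE_ID, check_samples_match


@dataclass
class CoreClassification:
    otu_id: str
    category: str  # shared_core | health_core | disease_core | none
    tier: int | None  # 1 | 2 | 3 | None
    prevalence_health: float
    prevalence_pd1: float
    mean_abundance_health: float  # percent
    mean_abundance_pd1: float  # percent


def _tier(prevalence: float, mean_abund_pct: float,
          tier_prevalence: float, tier_abundance: float) -> int:
    if prevalence >= tier_prevalence:
        return 1 if mean_abund_pct >= tier_abundance else 2
    return 3


def classify_core(
    table: OtuTable,
    metadata: pd.DataFrame,
    abundance_threshold: float = 0.005,
    prevalence_threshold: float = 0.5,
    tier_prevalence: float = 2.0 / 3.0,
    tier_abundance: float = 2.0,
    skew_ratio: float = 1.5,
) -> list[CoreClassification]:
    """Classify every OTU into shared/health/disease core with a tier.

    ``abundance_threshold`` is a fraction of reads (0.005 = 0.5%);
    ``tier_abundance`` is in percent (2.0 = 2% of reads).  The pooled
    ``RARE`` row, if present, is ignored.
    """
    check_samples_match(table, metadata)
    counts = table.counts
    if RARE_ID in counts.index:
        counts = counts.drop(index=RARE_ID)
    props = table.counts.div(table.counts.sum(axis=0), axis=1).loc[counts.index]

    groups = {}
    for state in ("health", "pd1"):
        samples = metadata.index[metadata["health_status"] == state]
        if len(samples) == 0:
            raise ValueError(f"group {state!r} has no samples")
        groups[state] = props[samples]

    out: list[CoreClassification] = []
    for otu in counts.index:
        stats = {}
        for state, sub in groups.items():
            row = sub.loc[otu].to_numpy(dtype=float)
            stats[state] = {
                "prevalence": float(np.mean(row >= abundance_threshold)),
                "mean_pct": float(100.0 * row.mean()),
            }
        prev_h, prev_p = stats["health"]["prevalence"], stats["pd1"]["prevalence"]
        mean_h, mean_p = stats["health"]["mean_pct"], stats["pd1"]["mean_pct"]
        eligible_h = prev_h >= prevalence_threshold
        eligible_p = prev_p >= prevalence_threshold

        if not eligible_h and not eligible_p:
            category, tier = "none", None
        elif eligible_h and not eligible_p:
            category = "health_core"
            tier = _tier(prev_h, mean_h, tier_prevalence, tier_abundance)
        elif eligible_p and not eligible_h:
            category = "disease_core"
            tier = _tier(prev_p, mean_p, tier_prevalence, tier_abundance)
        else:
            if prev_h >= skew_ratio * prev_p and mean_h >= skew_ratio * mean_p:
                category = "health_core"
                tier = _tier(prev_h, mean_h, tier_prevalence, tier_abundance)
            elif prev_p >= skew_ratio * prev_h and mean_p >= skew_ratio * mean_h:
                category = "disease_core"
                tier = _tier(prev_p, mean_p, tier_prevalence, tier_abundance)
            else:
                category = "shared_core"
                # Tier on the higher-prevalence group; prevalence ties go
                # to the group with the higher mean abundance, then health.
                if (prev_p, mean_p) > (prev_h, mean_h):
                    tier = _tier(prev_p, mean_p, tier_prevalence, tier_abundance)
                else:
                    tier = _tier(prev_h, mean_h, tier_prevalence, tier_abundance)
        out.append(
            CoreClassification(
                otu_id=otu,
                category=category,
                tier=tier,
                prevalence_health=prev_h,
                prevalence_pd1=prev_p,
                mean_abundance_health=mean_h,
                mean_abundance_pd1=mean_p,
            )
        )
    return out


def core_frame(classifications: Sequence[CoreClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [c.otu_id for c in classifications],
            "category": [c.category for c in classifications],
            "tier": [c.tier if c.tier is not None else "none" for c in classifications],
            "prevalence_health": [c.prevalence_health for c in classifications],
            "prevalence_pd1": [c.prevalence_pd1 for c in classifications],
            "mean_abund_health": [c.mean_abundance_health for c in classifications],
            "mean_abund_pd1": [c.mean_abundance_pd1 for c in classifications],
        }
    )
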