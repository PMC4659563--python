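"""End-to-end pipeline: simulate -> filter -> annotate -> associate ->
aggregate -> diversity/ordination -> core -> report.

Every stage writes a plain TSV into the output directory and the final
report re-tallies headline numbers (non-rare OTU count, significant OTUs
per contrast, phylum-level abundance per group, Gram/oxygen means) from
those stage outputs, so the bundle is self-consistent.  Reruns with the
same configuration and seed are byte-identical; logging goes to standard
error, results never do.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    HEALTH_STATES,
    RARE_ID,
    OtuTable,
    adjusted_proportions,
    classify_rare,
    raw_proportions,
)
from .aggregates import aggregate_tests
from .association import gingivitis_trend_tests, health_status_tests
from .core import classify_core, core_frame
from .diversity import (
    diversity_frame,
    jsd_distance_matrix,
    pca_scores,
    pcoa,
    trait_linear_model,
)
from .synthetic import (
    SimulationConfig,
    simulate_dataset,
    simulate_reference_db,
    write_dataset,
    write_reference_set,
)
from .taxonomy import assign_all, write_assignments

logger = logging.getLogger("perio16s")


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a full pipeline run.

    Defaults equal the study's stated values: rare cutoff 0.05% /
    2 samples, 2/4 pseudo-counts (fixed in the association module),
    1000 permutations, alpha 0.05, annotation cascade 99/99 with 98/95
    demotion (fixed in the taxonomy module), core thresholds
    0.5% / 50% / 2-3 / 2%.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rare_prop_threshold: float = 0.0005
    rare_min_samples: int = 2
    n_perm: int = 1000
    alpha: float = 0.05
    core_abundance_threshold: float = 0.005
    core_prevalence_threshold: float = 0.5
    core_tier_prevalence: float = 2.0 / 3.0
    core_tier_abundance: float = 2.0
    core_skew_ratio: float = 1.5
    aggregate_denominator: str = "labelled"
    seed: int = 0
    outdir: str = "perio16s_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["n_samples_per_group"] = dict(
            d["simulation"]["n_samples_per_group"]
        )
        d["simulation"]["effect_otus"] = [
            list(e) for e in d["simulation"]["effect_otus"]
        ]
        return d

    def config_hash(self) -> str:
        # Hash the scientific configuration only; where the bundle is
        # written must not change the reported hash.
        payload = self.to_dict()
        payload.pop("outdir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_logging() -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                              datefmt="%Y-%m-%dT%H:%M:%S")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the report bundle, return the summary dict."""
    _setup_logging()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "perio16s %s seed=%d config=%s", __version__, config.seed,
        config.config_hash(),
    )
    logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True, default=str))

    # --- simulate ---------------------------------------------------------
    sim = config.simulation
    dataset = simulate_dataset(sim)
    write_dataset(dataset, outdir)
    logger.info(
        "simulated %d OTUs x %d samples", len(dataset.counts.otu_ids),
        len(dataset.counts.sample_ids),
    )

    # --- rare filtering ---------------------------------------------------
    filtered = classify_rare(
        dataset.counts,
        dataset.metadata,
        prop_threshold=config.rare_prop_threshold,
        min_samples=config.rare_min_samples,
    )
    _write(filtered.retained.counts, outdir / "filtered_counts.tsv",
           index_label="otu_id")
    retained_ids = [o for o in filtered.retained.otu_ids if o != RARE_ID]
    logger.info(
        "rare filtering: %d retained, %d rare", len(retained_ids),
        len(filtered.rare_otu_ids),
    )

    # --- taxonomy ---------------------------------------------------------
    # One representative sequence per retained OTU: reference-db queries
    # are generated with the same seed and identified with the OTUs.
    ref_sim = SimulationConfig(
        **{**sim.__dict__, "n_queries": len(retained_ids)}
    )
    refset = simulate_reference_db(ref_sim)
    qids = list(refset.queries)
    refset.queries = {
        otu: refset.queries[q] for otu, q in zip(retained_ids, qids)
    }
    refset.truth = {
        otu: refset.truth[q] for otu, q in zip(retained_ids, qids)
    }
    write_reference_set(refset, outdir)
    databases = {"FOMD": refset.fomd, "COMD": refset.comd, "SILVA": refset.silva}
    assignments = assign_all(refset.queries, databases)
    write_assignments(assignments, outdir / "assignments.tsv")
    logger.info("taxonomy: %d OTUs annotated", len(assignments))

    # --- association ------------------------------------------------------
    assoc = health_status_tests(
        filtered.retained, dataset.metadata, n_perm=config.n_perm,
        seed=config.seed,
    )
    _write(assoc, outdir / "associations.tsv", index=False)
    trend = gingivitis_trend_tests(
        filtered.retained, dataset.metadata, n_perm=config.n_perm,
        seed=config.seed + 1,
    )
    _write(trend, outdir / "trend.tsv", index=False)

    # --- aggregates -------------------------------------------------------
    agg = aggregate_tests(
        filtered.retained, dataset.annotations, dataset.metadata,
        denominator=config.aggregate_denominator,
    )
    _write(agg, outdir / "aggregates.tsv", index=False)

    # --- diversity & ordination ------------------------------------------
    # Richness counts OTUs detected per sample before rare pooling.
    div = diversity_frame(dataset.counts.counts)
    div["health_status"] = dataset.metadata.loc[div.index, "health_status"]
    _write(div, outdir / "diversity.tsv", index_label="sample_id")
    labels = div["health_status"].to_numpy()
    shannon_model = trait_linear_model(div["shannon"].to_numpy(), labels)
    richness_model = trait_linear_model(
        div["richness"].to_numpy(), labels,
        covariate=div["total_reads"].to_numpy(),
    )

    adj = adjusted_proportions(filtered.retained)
    pca = pca_scores(np.log10(adj.values).T)
    _write(pca.coordinates, outdir / "pca_scores.tsv", index_label="sample_id")
    _write(
        pd.DataFrame(
            {
                "axis": [f"axis{i+1}" for i in range(len(pca.explained_fraction))],
                "explained_fraction": pca.explained_fraction,
                "eigenvalue": pca.eigenvalues,
            }
        ),
        outdir / "pca_explained.tsv", index=False,
    )
    rel = raw_proportions(filtered.retained).values.T
    dm = jsd_distance_matrix(rel)
    _write(dm, outdir / "jsd_distance.tsv", index_label="sample_id")
    ordn = pcoa(dm)
    _write(ordn.coordinates, outdir / "pcoa_coords.tsv", index_label="sample_id")

    # --- core microbiota --------------------------------------------------
    cores = classify_core(
        filtered.retained, dataset.metadata,
        abundance_threshold=config.core_abundance_threshold,
        prevalence_threshold=config.core_prevalence_threshold,
        tier_prevalence=config.core_tier_prevalence,
        tier_abundance=config.core_tier_abundance,
        skew_ratio=config.core_skew_ratio,
    )
    core_df = core_frame(cores)
    _write(core_df, outdir / "core.tsv", index=False)

    # --- report -----------------------------------------------------------
    summary = build_report(outdir, alpha=config.alpha)
    summary["config_hash"] = config.config_hash()
    summary["seed"] = config.seed
    summary["shannon_overall_p"] = round(shannon_model.overall_p, 6)
    summary["richness_overall_p"] = round(richness_model.overall_p, 6)
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", outdir / "report.json")
    return summary


def build_report(outdir: str | Path, alpha: float = 0.05) -> dict:
    """Re-tally headline numbers from the stage TSVs in ``outdir``."""
    outdir = Path(outdir)
    filtered = pd.read_csv(outdir / "filtered_counts.tsv", sep="\t", index_col="otu_id")
    metadata = pd.read_csv(outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    assoc = pd.read_csv(outdir / "associations.tsv", sep="\t")
    trend = pd.read_csv(outdir / "trend.tsv", sep="\t")
    agg = pd.read_csv(outdir / "aggregates.tsv", sep="\t")
    assignments = pd.read_csv(outdir / "assignments.tsv", sep="\t")
    core_df = pd.read_csv(outdir / "core.tsv", sep="\t")

    summary: dict = {
        "n_samples": int(filtered.shape[1]),
        "n_non_rare_otus": int((filtered.index != RARE_ID).sum()),
    }
    sig = assoc[assoc["q_value"] < alpha]
    summary["n_significant"] = {
        contrast: int((sig["contrast"] == contrast).sum())
        for contrast in ("overall", "H-vs-G", "G-vs-PD1", "H-vs-PD1")
    }
    summary["n_trend_significant"] = int((trend["q_value"] < alpha).sum())
    summary["n_core"] = {
        cat: int((core_df["category"] == cat).sum())
        for cat in ("shared_core", "health_core", "disease_core", "none")
    }

    # Phylum-level percent abundance per health group from the lineage of
    # each OTU's taxonomy assignment.
    phylum = assignments.set_index("otu_id")["lineage"].str.split(";").str[0]
    props = filtered.div(filtered.sum(axis=0), axis=1)
    props = props.loc[props.index != RARE_ID]
    by_phylum = props.groupby(phylum.reindex(props.index)).sum()
    phylum_pct = {}
    for state in HEALTH_STATES:
        samples = metadata.index[metadata["health_status"] == state]
        phylum_pct[state] = (
            (100.0 * by_phylum[samples].mean(axis=1)).round(2).to_dict()
        )
    summary["phylum_pct_by_group"] = phylum_pct

    means = agg[agg["contrast"] == "overall"]
    summary["aggregate_mean_pct"] = {
        f"{row.axis}:{row.label}": {
            s: round(getattr(row, f"mean_pct_{s}"), 2) for s in HEALTH_STATES
        }
        for row in means.itertuples()
    }
    return summary
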