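"""Seeded synthetic datasets emulating a subgingival-plaque 16S survey.

The generator reproduces the statistical structure that the downstream
analyses assume, so every stage of the pipeline can be exercised and
validated without any sequence downloads:

* 92 samples in three health-status groups (20 health / 50 gingivitis /
  22 mild periodontitis), uniform per-sample read depths in
  5,000-16,000;
* a shared Dirichlet-drawn base composition over the common OTUs plus a
  rare tail whose per-group mean proportions sit below the 0.05%
  rare-classification cutoff by construction;
* group-specific composition shifts expressed on the logit (log-odds)
  scale, matching the effect the downstream binomial GLM estimates;
* per-sample multinomial counts at the drawn depth;
* clinical metadata: average gingivitis score fixed at 0 for health and
  uniform on [1, 3] otherwise; age and sex carried but not modelled;
* Gram-stain and oxygen-requirement annotations per OTU;
* three synthetic 16S reference sets (FOMD / COMD / SILVA analogues)
  with taxonomy strings, plus query sequences mutated into controlled
  identity bands for testing the taxonomy-assignment cascade.

Every draw flows from a single integer seed; identical configurations
yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import HEALTH_STATES, OtuTable

# Identity bands requested for synthetic taxonomy queries (percent
# identity of query vs its source reference).  "<95" is floored at 90 so
# the local alignment stays full length.
IDENTITY_BANDS = {
    ">=99": (99.0, 100.0000001),
    "[98,99)": (98.0, 99.0),
    "[96,98)": (96.0, 98.0),
    "[95,96)": (95.0, 96.0),
    "<95": (90.0, 95.0),
}

_END_MARGIN = 12  # mutations are kept away from sequence ends

GRAM_LABELS = ("gram_positive", "gram_negative")
OXYGEN_LABELS = ("aerobe", "anaerobe", "facultative")


class SimulationConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated survey: group sizes 20/50/22, depths
    uniform on 5,000-16,000, 267 common OTUs plus a 40-OTU rare tail.
    ``effect_otus`` lists ``(otu_index, target_state, log_odds_shift)``
    triples; the shift is applied exactly on the log-odds of that OTU's
    proportion in the target group's composition.
    """

    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"health": 20, "gingivitis": 50, "pd1": 22}
    )
    depth_range: tuple[int, int] = (5000, 16000)
    n_otus: int = 267
    n_rare_otus: int = 40
    base_composition_concentration: float = 0.5
    effect_otus: Sequence[tuple[int, str, float]] = field(default_factory=list)
    gram_fraction: float = 0.35
    oxygen_fractions: tuple[float, float, float] = (0.2, 0.6, 0.2)
    seed: int = 0
    # Reference-database block
    n_refs_per_db: int = 5
    n_queries: int = 40
    ref_length: int = 500

    def validate(self) -> None:
        if set(self.n_samples_per_group) != set(HEALTH_STATES):
            raise SimulationConfigError(
                f"groups must be exactly {set(HEALTH_STATES)}"
            )
        for state, n in self.n_samples_per_group.items():
            if n <= 0:
                raise SimulationConfigError(f"group {state!r} has zero samples")
        lo, hi = self.depth_range
        if lo < 1 or lo > hi:
            raise SimulationConfigError("depth_range must satisfy 1 <= min <= max")
        if self.n_otus <= 0 or self.n_rare_otus < 0:
            raise SimulationConfigError("n_otus must be positive, n_rare_otus >= 0")
        if self.base_composition_concentration <= 0:
            raise SimulationConfigError("Dirichlet concentration must be positive")
        if not 0 <= self.gram_fraction <= 1:
            raise SimulationConfigError("gram_fraction must lie in [0,1]")
        if abs(sum(self.oxygen_fractions) - 1.0) > 1e-9:
            raise SimulationConfigError("oxygen_fractions must sum to 1")
        for idx, state, _shift in self.effect_otus:
            if not 0 <= idx < self.n_otus:
                raise SimulationConfigError(
                    f"effect OTU index {idx} out of range [0, {self.n_otus})"
                )
            if state not in HEALTH_STATES:
                raise SimulationConfigError(f"unknown effect target state {state!r}")


@dataclass
class SyntheticDataset:
    """Counts, metadata, annotations and ground truth of one simulation."""

    counts: OtuTable
    metadata: pd.DataFrame
    annotations: pd.DataFrame
    truth: list[dict]
    group_compositions: pd.DataFrame  # OTU x health-state proportions


def _shift_composition(
    base: np.ndarray, shifts: Sequence[tuple[int, float]]
) -> np.ndarray:
    """Apply exact log-odds shifts to selected components.

    Each shifted component's odds p/(1-p) are multiplied by exp(shift)
    exactly; the remaining components are rescaled proportionally within
    the leftover mass, so the vector stays a distribution and the
    realized log-odds difference for the shifted OTU equals the
    requested shift.
    """
    comp = base.copy()
    for idx, shift in shifts:
        p = comp[idx]
        odds = p / (1.0 - p) * np.exp(shift)
        q = odds / (1.0 + odds)
        others = np.ones(len(comp), dtype=bool)
        others[idx] = False
        comp[others] *= (1.0 - q) / (1.0 - p)
        comp[idx] = q
    return comp


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset per the configuration (seed-deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_common = config.n_otus
    n_rare = config.n_rare_otus
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_common + n_rare)]

    # Shared base composition.  Components are floored at 0.1% before
    # renormalisation so every common OTU clears the 0.05% rare cutoff
    # in all groups (the generator's common OTUs model the retained set).
    alpha = np.full(n_common, config.base_composition_concentration)
    base = rng.dirichlet(alpha)
    base = np.maximum(base, 1e-3)
    base = base / base.sum()

    # Rare tail: fixed tiny per-group proportions, mean < 0.05% each.
    rare_props = (
        rng.uniform(5e-6, 4e-4, size=n_rare) if n_rare else np.zeros(0)
    )
    rare_mass = rare_props.sum()
    base = base * (1.0 - rare_mass)

    group_comps = {}
    for state in HEALTH_STATES:
        shifts = [
            (idx, shift) for idx, tgt, shift in config.effect_otus if tgt == state
        ]
        common = _shift_composition(base / (1.0 - rare_mass), shifts)
        common = common * (1.0 - rare_mass)
        group_comps[state] = np.concatenate([common, rare_props])
    comp_df = pd.DataFrame(group_comps, index=otu_ids)

    sample_rows = []
    counts_cols = {}
    meta_rows = []
    i_sample = 0
    lo, hi = config.depth_range
    for state in HEALTH_STATES:
        probs = comp_df[state].to_numpy()
        for _ in range(int(config.n_samples_per_group[state])):
            i_sample += 1
            sid = f"S{i_sample:03d}"
            depth = int(rng.integers(lo, hi + 1))
            counts_cols[sid] = rng.multinomial(depth, probs)
            score = 0.0 if state == "health" else float(rng.uniform(1.0, 3.0))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "health_status": state,
                    "avg_gingivitis_score": round(score, 2),
                    "age": round(float(rng.uniform(1.0, 15.0)), 1),
                    "sex": "M" if rng.random() < 0.5 else "F",
                }
            )
            sample_rows.append(sid)

    counts = pd.DataFrame(counts_cols, index=otu_ids)
    counts.index.name = "otu_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    gram = np.where(
        rng.random(len(otu_ids)) < config.gram_fraction,
        GRAM_LABELS[0],
        GRAM_LABELS[1],
    )
    oxygen = rng.choice(
        OXYGEN_LABELS, size=len(otu_ids), p=list(config.oxygen_fractions)
    )
    annotations = pd.DataFrame(
        {"gram": gram, "oxygen": oxygen}, index=pd.Index(otu_ids, name="otu_id")
    )

    truth = [
        {
            "otu_id": otu_ids[idx],
            "otu_index": int(idx),
            "target_state": state,
            "log_odds_shift": float(shift),
        }
        for idx, state, shift in config.effect_otus
    ]
    return SyntheticDataset(
        counts=OtuTable(counts),
        metadata=metadata,
        annotations=annotations,
        truth=truth,
        group_compositions=comp_df,
    )


# ---------------------------------------------------------------------------
# Synthetic reference databases and taxonomy queries
# ---------------------------------------------------------------------------

_RANK_NAMES = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class ReferenceSet:
    """Synthetic FOMD/COMD/SILVA analogues plus queries and truth.

    ``fomd``/``comd``/``silva`` map reference id -> (sequence, taxonomy
    string with six semicolon-separated ranks).  ``truth`` maps query id
    to its source database, source reference, requested identity band
    and exact substitution count.
    """

    fomd: dict[str, tuple[str, str]]
    comd: dict[str, tuple[str, str]]
    silva: dict[str, tuple[str, str]]
    queries: dict[str, str]
    truth: dict[str, dict]


def _taxonomy_string(db: str, i: int) -> str:
    stem = f"{db}{i:02d}"
    parts = [
        f"Phylum_{stem}",
        f"Class_{stem}",
        f"Order_{stem}",
        f"Family_{stem}",
        f"Genus_{stem}",
        f"Genus_{stem} species {stem}",
    ]
    return ";".join(parts)


def _substitutions_for_band(length: int, band: str) -> list[int]:
    """Integer substitution counts whose exact identity lies in the band."""
    lo, hi = IDENTITY_BANDS[band]
    ns = [
        n
        for n in range(0, length + 1)
        if lo <= 100.0 * (length - n) / length < hi
    ]
    usable = length - 2 * _END_MARGIN
    ns = [n for n in ns if n <= usable]
    if not ns:
        raise SimulationConfigError(
            f"identity band {band} unachievable for length-{length} sequences"
        )
    return ns


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    bases = "ACGT"
    positions = rng.choice(
        np.arange(_END_MARGIN, len(seq) - _END_MARGIN),
        size=n_subs,
        replace=False,
    )
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in bases if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_reference_db(config: SimulationConfig) -> ReferenceSet:
    """Generate reference FASTA sets and identity-banded query sequences.

    Queries cycle over (database, band) combinations; each query is a
    copy of one reference with ``n`` interior substitutions chosen so
    its exact identity ``100 (L - n) / L`` falls in the requested band.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    length = config.ref_length
    bases = np.array(list("ACGT"))

    dbs: dict[str, dict[str, tuple[str, str]]] = {}
    prefixes = {"FOMD": "FOT", "COMD": "COT", "SILVA": "SLV"}
    for db, prefix in prefixes.items():
        refs = {}
        for i in range(config.n_refs_per_db):
            seq = "".join(rng.choice(bases, size=length))
            refs[f"{prefix}-{i + 1:03d}"] = (seq, _taxonomy_string(prefix, i + 1))
        dbs[db] = refs

    band_names = list(IDENTITY_BANDS)
    db_names = list(prefixes)
    queries: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for q in range(config.n_queries):
        db = db_names[q % len(db_names)]
        band = band_names[(q // len(db_names)) % len(band_names)]
        ref_ids = sorted(dbs[db])
        ref_id = ref_ids[int(rng.integers(0, len(ref_ids)))]
        seq, _tax = dbs[db][ref_id]
        candidates = _substitutions_for_band(length, band)
        n_subs = int(candidates[int(rng.integers(0, len(candidates)))])
        qid = f"Q{q + 1:04d}"
        queries[qid] = _mutate(seq, n_subs, rng)
        truth[qid] = {
            "db": db,
            "source": ref_id,
            "band": band,
            "n_substitutions": n_subs,
            "identity": 100.0 * (length - n_subs) / length,
        }
    return ReferenceSet(
        fomd=dbs["FOMD"],
        comd=dbs["COMD"],
        silva=dbs["SILVA"],
        queries=queries,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fasta(records: Mapping[str, str | tuple[str, str]], path: str | Path) -> None:
    """Write sequences (optionally with taxonomy descriptions) as FASTA."""
    with open(path, "w") as fh:
        for name, value in records.items():
            if isinstance(value, tuple):
                seq, desc = value
                fh.write(f">{name} {desc}\n")
            else:
                seq = value
                fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write counts/metadata/annotations TSVs and truth JSON; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    dataset.counts.counts.to_csv(paths["counts"], sep="\t", index_label="otu_id")
    dataset.metadata.to_csv(
        paths["metadata"], sep="\t", index_label="sample_id", float_format="%.6g"
    )
    dataset.annotations.to_csv(
        paths["annotations"], sep="\t", index_label="otu_id"
    )
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def write_reference_set(refset: ReferenceSet, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, records in (
        ("fomd", refset.fomd),
        ("comd", refset.comd),
        ("silva", refset.silva),
        ("queries", refset.queries),
    ):
        paths[name] = outdir / f"{name}.fasta"
        write_fasta(records, paths[name])
    paths["ref_truth"] = outdir / "ref_truth.json"
    with open(paths["ref_truth"], "w") as fh:
        json.dump(refset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
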