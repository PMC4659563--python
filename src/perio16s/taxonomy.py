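"""Taxonomy assignment of OTU representative sequences.

Assignment follows a reference-database cascade: a hit from the feline
oral reference set (FOMD) is accepted outright when it reaches >=99%
identity over >=99% query coverage; failing that, the same criteria are
applied to the canine set (COMD); failing both, the best-scoring hit
from any database (including SILVA) is used.  The chosen hit's identity
then caps the taxonomic rank of the annotation: >=98% keeps the species
name, [95, 98) is demoted to genus, and <95% to family.

Pairwise similarity is scored like the BLASTN parameterisation used to
produce the hits (match +4, mismatch -5, gap of length k costs 5 + 5k),
with identity computed over alignment columns (gaps included) and query
coverage as the aligned query span over the query length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

DATABASES = ("FOMD", "COMD", "SILVA")
SPECIES_MIN_IDENTITY = 98.0
GENUS_MIN_IDENTITY = 95.0
ACCEPT_IDENTITY = 99.0
ACCEPT_COVERAGE = 99.0

_RANK_INDEX = {"species": 5, "genus": 4, "family": 3}


class HitRecordError(ValueError):
    """A hit record is malformed."""


@dataclass(frozen=True)
class HitRecord:
    """One query-vs-reference alignment result (BLAST outfmt-6 flavoured)."""

    query_id: str
    subject_id: str
    database: str
    identity: float
    query_coverage: float
    score: float
    subject_taxonomy: str  # semicolon-separated phylum..species

    def __post_init__(self) -> None:
        if self.database not in DATABASES:
            raise HitRecordError(f"unknown database {self.database!r}")
        if not (0.0 <= self.identity <= 100.0):
            raise HitRecordError(f"identity out of range: {self.identity}")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise HitRecordError(f"coverage out of range: {self.query_coverage}")
        if self.score < 0:
            raise HitRecordError(f"negative score: {self.score}")


@dataclass(frozen=True)
class TaxonomyAssignment:
    otu_id: str
    assigned_name: str
    rank: str  # species | genus | family
    source: str  # FOMD_accept | COMD_accept | best_hit
    identity: float
    coverage: float
    lineage: tuple[str, ...] = ()  # ranks retained after demotion


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=4,
        mismatch_score=-5,
        open_gap_score=-10,  # first gap column: open (5) + extend (5)
        extend_gap_score=-5,
    )


_ALIGNER = _make_aligner()


def compute_identity(query: str, subject: str) -> tuple[float, float, float]:
    """Best local alignment statistics under the BLAST-like scoring.

    Returns ``(identity, query_coverage, score)`` where identity is
    matches over alignment columns (gaps included) x 100 and coverage is
    the aligned query span over the query length x 100.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    allowed = set("ACGTN")
    if not set(query) <= allowed or not set(subject) <= allowed:
        raise ValueError("sequences must be over the alphabet ACGTN")
    alignments = _ALIGNER.align(subject, query)
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qcoords = aln.coordinates[1]
    span = int(qcoords.max() - qcoords.min())
    coverage = 100.0 * span / len(query)
    return identity, coverage, float(aln.score)


def rank_for_identity(identity: float) -> str:
    """Demote the annotation rank according to the chosen hit's identity."""
    if identity >= SPECIES_MIN_IDENTITY:
        return "species"
    if identity >= GENUS_MIN_IDENTITY:
        return "genus"
    return "family"


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    # Highest score, ties broken by higher identity then subject id.
    return min(hits, key=lambda h: (-h.score, -h.identity, h.subject_id))


def assign_taxonomy(otu_id: str, hits: Iterable[HitRecord]) -> TaxonomyAssignment:
    """Run the FOMD -> COMD -> global-best-hit cascade for one OTU."""
    hits = list(hits)
    for h in hits:
        if not isinstance(h, HitRecord):
            raise HitRecordError(f"not a HitRecord: {h!r}")
    if not hits:
        return TaxonomyAssignment(
            otu_id=otu_id,
            assigned_name="Unclassified",
            rank="family",
            source="best_hit",
            identity=0.0,
            coverage=0.0,
            lineage=(),
        )
    chosen = None
    source = None
    for db in ("FOMD", "COMD"):
        qualifying = [
            h
            for h in hits
            if h.database == db
            and h.identity >= ACCEPT_IDENTITY
            and h.query_coverage >= ACCEPT_COVERAGE
        ]
        if qualifying:
            chosen = _best_hit(qualifying)
            source = f"{db}_accept"
            break
    if chosen is None:
        chosen = _best_hit(hits)
        source = "best_hit"
    rank = rank_for_identity(chosen.identity)
    parts = [p.strip() for p in chosen.subject_taxonomy.split(";") if p.strip()]
    keep = min(_RANK_INDEX[rank] + 1, len(parts))
    lineage = tuple(parts[:keep])
    name = lineage[-1] if lineage else "Unclassified"
    return TaxonomyAssignment(
        otu_id=otu_id,
        assigned_name=name,
        rank=rank,
        source=source,
        identity=chosen.identity,
        coverage=chosen.query_coverage,
        lineage=lineage,
    )


def flag_shallow_annotations(
    assignments: Sequence[TaxonomyAssignment], min_depth: int = 5
) -> list[str]:
    """OTUs whose retained lineage has fewer than ``min_depth`` ranks.

    The cascade never overrides a winning hit by hand; instead, winners
    with shallow annotation (e.g. demoted to family, or a poorly
    annotated reference) can be flagged here for manual review.
    """
    return [a.otu_id for a in assignments if len(a.lineage) < min_depth]


def hits_for_query(
    query_id: str,
    query_seq: str,
    databases: Mapping[str, Mapping[str, tuple[str, str]]],
) -> list[HitRecord]:
    """Align a query against every reference and build hit records.

    ``databases`` maps database name (FOMD/COMD/SILVA) to
    ``{reference_id: (sequence, taxonomy_string)}``.
    """
    records = []
    for db, refs in databases.items():
        for ref_id, (seq, tax) in refs.items():
            identity, coverage, score = compute_identity(query_seq, seq)
            records.append(
                HitRecord(
                    query_id=query_id,
                    subject_id=ref_id,
                    database=db,
                    identity=identity,
                    query_coverage=coverage,
                    score=score,
                    subject_taxonomy=tax,
                )
            )
    return records


def assign_all(
    queries: Mapping[str, str],
    databases: Mapping[str, Mapping[str, tuple[str, str]]],
) -> list[TaxonomyAssignment]:
    """Cascade assignment for a whole set of query sequences."""
    return [
        assign_taxonomy(qid, hits_for_query(qid, seq, databases))
        for qid, seq in queries.items()
    ]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

# BLAST outfmt-6 columns plus `database`; coverage is reconstructed from
# qstart/qend and the supplied query lengths, taxonomy from a subject map.
OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "database",
]


def read_hits_table(
    path: str | Path,
    query_lengths: Mapping[str, int],
    subject_taxonomy: Mapping[str, str],
) -> dict[str, list[HitRecord]]:
    """Read a 13-column hits TSV into per-query hit-record lists."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    out: dict[str, list[HitRecord]] = {}
    for row in df.itertuples(index=False):
        qlen = query_lengths.get(row.qseqid)
        if qlen is None:
            raise HitRecordError(f"no length known for query {row.qseqid!r}")
        span = abs(int(row.qend) - int(row.qstart)) + 1
        coverage = 100.0 * span / qlen
        record = HitRecord(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            database=str(row.database),
            identity=float(row.pident),
            query_coverage=min(coverage, 100.0),
            score=float(row.bitscore),
            subject_taxonomy=subject_taxonomy.get(str(row.sseqid), ""),
        )
        out.setdefault(record.query_id, []).append(record)
    return out


def write_assignments(
    assignments: Sequence[TaxonomyAssignment], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "otu_id": [a.otu_id for a in assignments],
            "name": [a.assigned_name for a in assignments],
            "rank": [a.rank for a in assignments],
            "source": [a.source for a in assignments],
            "identity": [a.identity for a in assignments],
            "coverage": [a.coverage for a in assignments],
            "lineage": [";".join(a.lineage) for a in assignments],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
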