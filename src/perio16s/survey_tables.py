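"""Published summary tables from the 92-cat subgingival plaque survey.

These are the printed whole-study summaries that the pipeline's report
arithmetic reproduces: the cohort sizes, the total denoised read count,
the 34 most abundant OTUs (read counts and the printed per-OTU and
cumulative percentages), and the taxonomy-annotation tallies of the 267
non-rare OTUs.  The per-row printed proportions are not always exactly
``100 * reads / total`` (the first row is; later rows reflect per-sample
averaging in the source), so both schemes are exposed and report code
labels which is used.
"""

from __future__ import annotations

import io

import pandas as pd

from .abundance import pooled_proportion

#: Samples per health-status group in the surveyed cohort.
COHORT_GROUP_SIZES = {"health": 20, "gingivitis": 50, "pd1": 22}

#: Denoised sequence reads across all 92 samples.
TOTAL_SEQUENCE_READS = 1_112_543

#: Per-sample read-depth range and medians per group.
DEPTH_RANGE = (4_989, 15_941)

#: Taxonomy-annotation tallies for the 267 non-rare OTUs:
#: species-level (>=98% identity), genus-level ([96, 98)), below 96%.
ANNOTATION_TALLIES = {"species": 227, "genus": 25, "below_genus": 15}
N_NON_RARE_OTUS = 267

# The 34 most abundant OTUs: reads plus the percentages as printed
# (per-OTU proportion and running cumulative).
_TOP_OTUS_TSV = """\
otu_id\tspecies\tidentity\treads\tprinted_pct\tprinted_cumulative_pct
OTU8255\tPeptostreptococcaceae XIII [G-1] bacterium FOT-028\t100\t32599\t2.93\t2.93
OTU7092\tPorphyromonas sp. FOT-110\t99.71\t29691\t2.64\t5.57
OTU8837\tPorphyromonas canoris\t99.14\t27727\t2.41\t7.98
OTU1062\tFusobacterium sp. FOT-120\t99.43\t24851\t2.20\t10.18
OTU3989\tTreponema sp. FOT-201\t100\t22825\t2.07\t12.25
OTU1079\tPeptostreptococcaceae XI [G-1] bacterium FOT-036\t99.71\t22462\t2.10\t14.35
OTU1473\tMoraxella sp. FOT-087\t100\t22331\t1.88\t16.23
OTU7082\tBergeyella zoohelcum strain 357 FOT-329\t99.71\t21744\t2.04\t18.27
OTU2094\tChlorobi bacterium COT-312\t98.86\t19715\t1.69\t19.96
OTU906\tClostridiales [F-1][G-2] bacterium FOT-072\t100\t18494\t1.78\t21.73
OTU7952\tPorphyromonas circumdentaria FOT-102\t100\t18292\t1.57\t23.30
OTU6282\tPorphyromonas gulae FOT-105\t99.71\t17759\t1.68\t24.98
OTU7692\tMoraxella sp. FOT-089\t100\t16027\t1.40\t26.38
OTU574\tFilifactor villosus FOT-044\t100\t15704\t1.45\t27.83
OTU1976\tAquaspirillum sp. FOT-080\t100\t15400\t1.32\t29.15
OTU1500\tChlorobi [G] bacterium FOT-101\t99.14\t15304\t1.39\t30.54
OTU2476\tLautropia sp. COT-175\t99.43\t14565\t1.29\t31.83
OTU7091\tChloroflexi bacterium FOT-333\t100\t14227\t1.33\t33.16
OTU473\tHelcococcus sp. COT-140\t100\t13695\t1.24\t34.40
OTU8729\tPeptostreptococcaceae XI [G-4] bacterium FOT-065\t100\t13519\t1.25\t35.65
OTU4533\tActinomyces sp. FOT-320\t100\t13321\t1.30\t36.95
OTU7613\tLachnospiraceae XIVa [G-5] bacterium FOT-021\t100\t13107\t1.21\t38.16
OTU5191\tFretibacterium sp. FOT-215\t100\t12683\t1.16\t39.32
OTU6461\tCapnocytophaga sp. FOT-330\t100\t11841\t0.97\t40.29
OTU8764\tTreponema sp. COT-249\t99.71\t11443\t1.07\t41.36
OTU4910\tTreponema sp. COT-207\t99.71\t11238\t1.02\t42.38
OTU7305\tLachnospiraceae XIVa [G-3] bacterium FOT-156\t99.71\t11197\t1.07\t43.45
OTU2615\tActinomyces sp. COT-404\t100\t11073\t0.99\t44.44
OTU6787\tPorphyromonas sp. COT-290\t99.14\t10977\t0.97\t45.41
OTU9414\tLachnospiraceae XIVa [G-2] bacterium FOT-007\t99.14\t10697\t0.96\t46.37
OTU2425\tFilifactor sp. FOT-129\t99.43\t10598\t0.93\t47.30
OTU298\tPeptostreptococcaceae XI [G-1] bacterium FOT-035\t100\t10518\t0.97\t48.27
OTU2679\tProteocatella sp. FOT-127\t100\t10459\t0.95\t49.22
OTU883\tPeptostreptococcaceae XI [G-1] bacterium FOT-040\t100\t9958\t0.90\t50.12
"""


def top_otus() -> pd.DataFrame:
    """The 34 most abundant OTUs of the survey as a DataFrame."""
    return pd.read_csv(io.StringIO(_TOP_OTUS_TSV), sep="\t")


def cohort_total() -> int:
    """Total cats across the three health-status groups."""
    return sum(COHORT_GROUP_SIZES.values())


def top_otu_pooled_pct() -> float:
    """Pooled percentage of the most abundant OTU's reads (2 dp)."""
    df = top_otus()
    return round(
        pooled_proportion(int(df.loc[0, "reads"]), TOTAL_SEQUENCE_READS), 2
    )


def cumulative_printed_pct(n_rows: int) -> float:
    """Running sum of the printed per-OTU percentages over the top rows."""
    df = top_otus()
    if not 1 <= n_rows <= len(df):
        raise ValueError(f"n_rows must be in [1, {len(df)}]")
    return round(float(df["printed_pct"].iloc[:n_rows].sum()), 2)


def cumulative_pooled_pct(n_rows: int) -> float:
    """Pooled count/total percentage over the top rows (2 dp)."""
    df = top_otus()
    if not 1 <= n_rows <= len(df):
        raise ValueError(f"n_rows must be in [1, {len(df)}]")
    reads = int(df["reads"].iloc[:n_rows].sum())
    return round(pooled_proportion(reads, TOTAL_SEQUENCE_READS), 2)


def annotation_rate_pct(level: str) -> float:
    """Percentage of the 267 non-rare OTUs annotated at a given level.

    Levels: ``species`` (>=98% identity), ``genus`` ([96, 98)),
    ``below_genus`` (<96%).  Rounded to the integer percent the survey
    reports.
    """
    if level not in ANNOTATION_TALLIES:
        raise KeyError(f"unknown level {level!r}")
    return round(100.0 * ANNOTATION_TALLIES[level] / N_NON_RARE_OTUS)
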