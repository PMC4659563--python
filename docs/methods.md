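# Methods

This note records the models implemented in `perio16s`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Data model

The unit of analysis is an OTU × sample integer count table with
per-sample clinical metadata: health status (`health`, `gingivitis`,
`pd1` = mild periodontitis, <25% attachment loss), the average
gingivitis score of the sampled teeth (0 for health, 1–3 otherwise),
age and sex. Age and sex are carried but never modelled.

**Rare rule.** An OTU is rare iff its mean raw proportion is below
`prop_threshold` (default 0.05%, a detection limit established for
454-era mock communities) within *every* health group, or it has a
positive count in fewer than `min_samples` (default 2) samples.
"Present" for the second clause means count > 0, independent of the
proportion clause. The rule uses raw proportions because filtering
precedes the pseudo-count adjustment. Rare counts are pooled per sample
into a reserved `RARE` row, so sample totals are conserved exactly. The
`RARE` row takes part in the gingivitis-trend analysis and all totals,
but is excluded from health-status testing, taxonomy and core
classification.

## Association tests

Counts are adjusted as (c+2)/(T+4) — two pseudo-successes and two
pseudo-failures — before fitting a binomial GLM with logit link by
IRLS (convergence: deviance change < 1e-8 or 100 iterations;
non-convergence is flagged, never silent). Because the proportions are
far from asymptotic comfort, inference is by permutation:

* **Overall health effect** — statistic: deviance reduction of adding
  the three-level health factor to the intercept-only model; null: all
  labels shuffled. The GLM literature offers both deviance and Wald
  statistics here; deviance was chosen as the default for its invariance
  to factor coding (a Wald option exists for the pairwise contrasts,
  which use squared Wald z).
* **Pairwise contrasts** (H-vs-G, G-vs-PD1, H-vs-PD1) — two-group
  refit on the two groups' samples only, labels permuted within them,
  conditioning on the third group. Estimates are reported as
  logit(p_first) − logit(p_second), antisymmetric under group swap.
* **Gingivitis trend** — score enters as a continuous fixed effect; the
  permutation shuffles the score vector; the slope is logit change per
  score unit. Trend curves are the inverse-logit of the linear
  predictor with a ±1.96 SE band computed on the logit scale.

p = (1 + #{permuted ≥ observed}) / (1 + B), which is positive and valid
by construction. Permuting the (count, total) pairs rather than the
design rows is an exact relabelling equivalence and lets one IRLS run
fit all B replicates as a batch; it also means the intercept-only
deviance is permutation-invariant and computed once. A relative
tolerance of 1e-9 is applied when comparing permuted statistics to the
observed one so that exchangeable inputs (identical counts) yield p = 1
rather than an arbitrary float-noise ranking.

Benjamini–Hochberg adjustment is applied across OTUs separately within
each family (overall, each contrast, trend), mirroring a correction
performed per analysis over the OTU panel. Note the q-value floor under
B permutations is m/(B+1) for a panel of m OTUs: with B = 1000 a
discovery at q < 0.05 is only possible for panels of fewer than ~50
OTUs unless several OTUs carry signal. The power study below sizes its
panel accordingly.

## Gram-stain and oxygen aggregates

Per-OTU labels are summed to per-sample counts per label; unannotated
OTUs and the `RARE` row fall into `unknown`, so reads are conserved.
The tested proportion's denominator defaults to the *labelled* reads
(the curated label set of the emulated survey was complete, so its
denominators were effectively labelled totals); `denominator="total"`
includes unknown reads instead. The quasi-binomial fit estimates
dispersion φ = Pearson X²/(n−3), scales the contrast standard errors by
√φ (t-tests, n−3 df), and tests the overall effect with
F = (ΔD/2)/φ on (2, n−3) df. Pairwise p-values are reported unadjusted;
multiplicity over the three contrasts is left to the caller.

## Diversity and ordination

* Shannon H = −Σ p ln p (natural log; H ≤ ln richness). Richness counts
  OTUs with positive counts per sample *before* rare pooling.
* Both traits are compared across health states by OLS; richness
  adjusts for the sample's total sequence count. A constant trait
  yields F = 0, p = 1 by definition rather than 0/0.
* PCA operates on log₁₀ adjusted proportions over retained OTUs + RARE,
  column-centered, covariance scaling (the log transform is already the
  variance stabiliser; no correlation scaling), via SVD. Sign
  convention: the largest-magnitude loading of each axis is positive.
* JSD uses natural log (range [0, ln 2]; a base-2 option rescales to
  [0, 1]), with 0·ln 0 = 0 and no pseudo-counts — the mixture midpoint
  is positive wherever either input is. Distances for PCoA are √JSD,
  which is a metric. PCoA is classical scaling: Gower double-centering,
  eigendecomposition, axes with eigenvalue > 1e-10 retained, negative
  eigenvalues reported but their axes dropped, explained fractions over
  the positive eigenvalues.

## Taxonomy cascade

Pairwise similarity uses local alignment under the BLASTN-like scoring
match +4, mismatch −5, gap of length k costing 5 + 5k (Biopython's
`PairwiseAligner`; identity = matches over alignment columns including
gaps; coverage = aligned query span / query length). The cascade accepts
an FOMD hit at ≥99% identity and ≥99% coverage, then a COMD hit by the
same rule, then the best hit by score from any database. Within a stage
the qualifying hit with the highest score wins; ties break by higher
identity, then lexicographic subject id (the accept rule is read as
"best qualifying hit", the documented resolution of an ambiguity in the
verbal rule). The chosen hit's identity sets the rank: ≥98% species,
[95, 98) genus, <95% family, with the taxonomy string truncated to that
rank. Manual re-assignment of poorly annotated best hits is deliberately
not automated. Empty hit lists yield `Unclassified` at family rank.

## Core microbiota

Computed on health and PD1 samples only. Core-eligible in a group:
relative abundance ≥0.5% in ≥50% of the group's samples (the prevalence
denominator is within-group). Eligible in one group → that group's core;
in both → shared, unless one group's qualifying prevalence *and* mean
abundance are both ≥1.5-fold the other's (the `skew_ratio`), in which
case the OTU moves to the dominant group's core. The dual-condition
1.5-fold rule is this package's deterministic, symmetric
operationalisation of "more prevalent and abundant" — it is a tunable
interpretation, not a community standard. Tiers: 1 = prevalence ≥2/3 and
mean abundance ≥2%; 2 = prevalence ≥2/3, abundance <2%; 3 = prevalence
in [1/2, 2/3). Shared OTUs tier on their higher-prevalence group
(ties: higher mean abundance, then health).

## Synthetic-data generator

The generator mirrors the emulated survey's design: groups 20/50/22,
uniform integer depths on [5000, 16000] (only min/max/median were
reported, so uniform is the least-informative choice), gingivitis score
0 in health and uniform on [1, 3] otherwise, age uniform 1–15 y, sex
Bernoulli(1/2), Gram-positive fraction 0.35 and oxygen fractions
(0.2, 0.6, 0.2) aerobe/anaerobe/facultative — round figures consistent
with a plaque community dominated by Gram-negative anaerobes.

The shared base composition is Dirichlet(0.5) over the common OTUs,
floored at 0.1% and renormalised so every common OTU clears the rare
cutoff in all groups; a configurable rare tail draws per-OTU proportions
uniformly on [5·10⁻⁶, 4·10⁻⁴], below the 0.05% rule by construction.
Group effects are applied on the log-odds scale: the effect OTU's odds
are multiplied by exp(shift) exactly and the remaining OTUs rescaled
proportionally within the leftover mass. This exact-odds construction
(rather than shifting every logit and renormalising everything) keeps
the realized log odds ratio equal to the seeded shift, which is what
makes parameter-recovery tests sharp. Counts are multinomial at the
drawn depth; OTUs are conditionally independent given the group
composition (no within-group covariance was available to emulate).

Reference databases are random 500-nt sequences with synthetic
six-rank taxonomy strings and disjoint FOT-/COT-/SLV- identifiers.
Queries are copies of a reference carrying n interior substitutions
(kept ≥12 nt from the ends) with n chosen so the identity
100(L−n)/L lands exactly in the requested band among
{≥99, [98,99), [96,98), [95,96), <95 (floored at 90)}; a band no integer
n can reach for the configured length raises an error. Substitutions
only (no indels) are used because interior substitutions leave the
optimal local alignment full-length and unique, making the band truth
exact; indel-containing queries would make realized identity depend on
co-optimal alignment choices.

**What the generator does not emulate:** sequencing noise and chimeras,
within-group OTU covariance, phylogenetic structure in the reference
sets, and real taxonomies. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the assumed
design, not robustness to artefacts the upstream denoising pipeline is
supposed to remove.

## Validation problem sizes

The simulation-based checks use these sizes, chosen to estimate each
rate with useful precision while keeping the default test run quick:
type-I error from 300 null OTUs at the full 92-sample design with
B = 200 permutations; power from 50 replicates of a 40-OTU panel
(depths 10,000–14,000, one OTU at +1.5 log-odds toward PD1, B = 1000 —
the panel is kept at 40 because the BH floor m/(B+1) must sit below
0.05 for a single-signal discovery to be possible); taxonomy agreement
from 1000 queries against 5-reference databases. Oracle-equivalence
tests run 100 random instances per operation against independent
brute-force implementations (including a quadratic Gotoh aligner).

## Known limitations

* Permutation tests treat samples as exchangeable under the null; any
  unmodelled structure (e.g. clinic of origin) would not be respected.
* The quasi-binomial F/t inference is approximate under strong
  overdispersion with unequal totals.
* The skew-ratio rule for shared-vs-specific core membership is an
  interpretation; published analyses made this call qualitatively.
* The pooled `RARE` row's proportion is a mixture and its trend slope
  has no single-taxon interpretation.
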