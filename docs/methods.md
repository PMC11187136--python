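# Methods

This note documents the models and procedures `matneo` implements, the
defaults and why, what the synthetic cohort does and does not emulate,
and the numerical choices that matter for reproducing results.

## Synthetic mother–neonate cohort

The generator exists because the clinical datasets this style of
analysis targets are controlled-access. It emulates structure, not
marginals.

**Maternal factors.** Variables are organized in blocks. Each block has
one latent standard-normal factor per dyad; variable *j* in a block with
within-block correlation ρ is √ρ·f + √(1−ρ)·ε, so every within-block
pair has latent correlation ρ and blocks are mutually independent (a
one-factor Gaussian copula). Marginals are then produced per variable:
binary by a median cut, ordinal by uniform quantile cuts into 3–5
levels (the level count drawn per variable), interval kept Gaussian.
Missing cells are injected completely at random (MCAR) at a configurable
rate (default 5%); nothing in the generator models informative
missingness. The latent block factor is kept as the ground-truth "block
score" that planted effects act on.

**Microbiota.** Each body site gets a base composition with geometric
log-abundance decay and one strongly dominant taxon (emulating
*Streptococcus*-dominant buccal and *E. coli*-dominant stool profiles).
Per sample, a composition is drawn from a Dirichlet with concentration
40 around the (possibly perturbed) base, and counts from a multinomial
at a depth uniform in the configured range (default 5,000–20,000).
Neonatal samples exist for days 0–2 (no day-0 stool, matching real
neonatal sampling schedules); maternal samples come from one pregnancy
visit. Planted effects act on dyads in the high half of a source block
score: composition effects add a log-fold shift to designated taxa;
alpha-diversity effects temper the base composition (p → p^(1/eᵉ)),
flattening it for positive effects and hence raising Shannon diversity.

**Outcomes.** Preterm birth and NICU admission are Bernoulli draws from
logistic models whose intercepts are logit of the configured baseline
prevalences (defaults 0.17 and 0.10, matching the cohort frequencies the
package's summary tables reproduce) and whose slopes are the configured
per-block coefficients on standardized block scores. The NICU linear
predictor additionally carries a coefficient (default 2.5) on the
mean-centered preterm indicator, because prematurity is the dominant
clinical driver of NICU admission. Effect targets are declared as
`outcome_preterm` / `outcome_nicu` (plain `outcome` means NICU).

Everything is bit-reproducible: each generator stage derives its RNG
from the spec seed XOR a CRC32 of the stage name, so the factor table,
counts and outcomes can be regenerated independently.

**What passing tests do not show.** The synthetic cohort has
equicorrelated blocks, MCAR missingness, Dirichlet-multinomial counts
and site-independent taxa; real cohorts have heavier-tailed abundance
distributions, structured missingness, shared taxa across sites and
confounded factor blocks. Effect sizes for module→microbiota influences
are not reported in the literature this emulates; the defaults are set
for detectability, not realism. Finite cohorts also produce chance
correlations between block latent factors (SD ≈ 1/√n), which is why
planted-block recovery is evaluated as an average over seeds rather
than per seed.

## Feature tables

- Sample filter: total reads ≥ 5,000, inclusive at the boundary.
- Taxon filter: keep iff relative abundance > 0.001 in **strictly** more
  than 5% of samples, or ≥ 1 read in strictly more than 15% of samples.
  The filter is idempotent.
- Rarefaction: one multivariate-hypergeometric draw per sample (without
  replacement), seeded; a sample below depth raises an error naming it.
- Dyad matching: maternal sample = last pregnancy visit; neonatal
  day-0 = first day-0 visit; "day 1 or 2" = first day-1 sample, else
  first day-2. Collection-time ties break by sample id.
- Cohort summary percentages are rounded half-up to one decimal, the
  convention used in hand-tabulated clinical tables.

## Diversity and permutation tests

Shannon entropy uses natural logs (nats); evenness is H/ln S and is
undefined below two observed taxa. Bray–Curtis is computed on counts
(rarefied tables make depths comparable).

**PERMANOVA.** The distance matrix is converted to the Gower-centered
inner-product matrix G; for a design hat matrix H, the explained sum of
squares is tr(HG) and pseudo-F follows. `by="margin"` tests each term by
the increase in residual SS when the term is dropped from the full
design. Permutations shuffle rows/columns of G; p = (1 + #{F* ≥ F}) /
(1 + n_perm), never zero. For single binary terms, `n_perm="exact"`
enumerates all distinct label assignments and reports the fraction
(observed included) with F at least as large. Marginal testing permutes
the raw distance matrix rather than residualized permutation — simpler,
and adequate for balanced two-level terms; with strongly unbalanced or
correlated terms the residualized scheme would be preferable.

**PERMDISP.** Samples are embedded by principal coordinates, keeping
only positive-eigenvalue axes (no Lingoes/Cailliez correction: the
dbRDA consumer needs a real coordinate space, and Bray–Curtis negative
eigenvalues are typically tiny). Each sample's distance to its group's
spatial median (Weiszfeld iteration; `center="centroid"` available)
feeds a one-way ANOVA F; the null distribution comes from permuting
group labels and recomputing medians. When all dispersion sums of
squares are at floating-point noise level (identical groups), F is
defined as 0.

**MRPP.** δ = Σ_g (n_g/N) · mean within-group distance; significance
from small δ under permutation; A = 1 − δ/mean(δ*).

**t-SNE** uses the precomputed-distance mode with random initialization
under a fixed seed; perplexity defaults to 30 and is reduced to
⌊(n−2)/3⌋ when infeasible. Embeddings are internally reproducible but
not comparable across library versions, so downstream mean-split
grouping (high = strictly above the mean) is the stable interface.

## Differential abundance

Per sample and Monte-Carlo instance, proportions are drawn from
Dirichlet(counts + 0.5) — the uninformative Jeffreys-style prior that is
the convention for this family of tools — and CLR-transformed. Each of
the (default) 128 instances gets a two-sided Mann–Whitney test per taxon
and BH correction across taxa; the reported p and adjusted p are means
over instances (expected-value reporting), and the effect is the median
over instances of the between-condition difference in median CLR. The
plain median CLR difference is reported, without the within-condition
dispersion scaling some tools fold into their effect size. Condition
order is the sorted label order, so exchanging labels negates every
effect exactly.

## Maternal factor network

Association dispatch by declared type: Spearman (interval/ordinal
pairs), point-biserial = Pearson on the 0/1 coding (binary vs numeric),
chi-squared on the 2×2 table (binary pairs, no Yates correction by
default, with a flag). When any expected cell is below 5 the chi-squared
test falls back to Fisher's exact test and records the switch; the
result stays in the chi-squared BH family. Observations are
pairwise-complete; pairs with fewer than 10 complete observations or a
zero-variance member are skipped with a reason. Spearman p-values use
the t approximation with tie-corrected ρ; below 10 complete
observations, p comes from permutation — full enumeration up to n = 7,
a 50,000-draw seeded Monte Carlo for n = 8–9 (the branch is unreachable
at the default minimum pair size and exists for explicit overrides).

BH adjustment runs within each of the three method families separately.
Edges are pairs with adjusted p ≤ 0.05 (boundary inclusive). Modules
come from Louvain modularity at resolution 0.7, keeping the best of 10
seeded restarts to damp the algorithm's instability; module ids are
ordered by each community's smallest member, making the partition
invariant to node input order. Isolated nodes are pooled into a single
catch-all module with the highest id, mirroring the "everything else"
module such analyses report separately from the numbered partition.
Betweenness is unweighted shortest-path centrality, unnormalized.

## Dyad classification

All-interval modules use Euclidean (Minkowski exponent 2, the distance
function's default) distance on z-scored variables; mixed modules use
Gower's distance (binary: 0/1 mismatch; ordinal: rank-coded,
range-normalized absolute difference; interval: range-normalized
absolute difference; mean over co-observed variables). A dyad pair with
no co-observed variable gets the mean of the defined distances, with a
warning — a declared artifact policy for an edge case the source
procedure leaves unstated. Clustering is ward.D: the Ward
Lance–Williams update applied directly to the raw dissimilarities (not
squared first, which would be ward.D2), cut at k = 2. Label A is the
larger cluster (ties: the cluster holding the lexicographically
smallest dyad id); every downstream test is label-symmetric, so the
orientation is cosmetic. For heatmap export, ordinal variables are
rank-coded and all module variables z-scaled.

## Outcome associations

Mann–Whitney batteries are BH-adjusted across modules within each
dependent summary. Marginal PERMANOVA fits one multi-term model with
all usable module terms and reports each module's drop-one p. dbRDA
follows the capscale recipe: PCoA (positive axes) → least-squares
projection of site coordinates onto the centered one-hot constraint
design → SVD of the fitted matrix gives constrained axes and
eigenvalues; the residual gives unconstrained axes. Total inertia
splits exactly (to machine precision) into constrained + unconstrained,
which the test suite verifies to 1e-8. dbRDA for a displayed constraint
set is unconditioned on the other modules.

Odds ratios are cross-products of the (A/B) × (yes/no) table with Wald
95% CIs, exp(ln OR ± 1.96·√Σ1/nᵢⱼ); zero cells get the
Haldane–Anscombe 0.5 correction and are flagged. The two-sided p is
Fisher's exact test. Dyads with unknown outcome are excluded listwise.
BH runs across modules within each stratum; stratified runs (term-only,
preterm-only) reuse the same machinery.

## NICU risk model

Ordinal variables are dichotomized at the level boundary minimizing
|n_high − n_low| (ties place the median level in "low"); binary and
dichotomized variables become single 0/1 indicators; interval variables
pass through. Screening keeps features whose unadjusted Spearman p
against the outcome is ≤ 0.05. Missing values are imputed by iterative
random-forest proximity averaging (≤ 5 rounds or change < 1e-6):
initialize with median/mode, fit a forest, replace missing entries with
proximity-weighted averages (weighted votes, for binary columns) of the
observed entries.

The forest uses 500 trees and √p features per split (the tool-family
defaults), stratified 5-fold cross-validation with 10 repeats, pooling
out-of-fold predicted probabilities for the auROC within each repeat
and averaging across repeats. By default screening and imputation are
refit inside each training fold so the cross-validated auROC is
leak-free — stricter than the screen-once ordering such analyses
usually describe; `screen_scope="all_data"` reproduces that simpler
ordering. Because the provenance of a published auROC (out-of-fold vs
resubstitution) is often unstated, both are reported. Importances are
mean decrease in Gini from a final all-data forest.

## Pipeline

`run_pipeline` derives each stage's seed from the global seed XOR a
CRC32 of the stage name, writes only tidy TSV/JSON artifacts plus a
manifest with output hashes, and is byte-reproducible under a fixed
config. Sample sets smaller than 8 are skipped in the per-site/per-slot
diversity stage.

## Problem sizes in the shipped checks

The acceptance script and test suite run reduced-but-representative
problem sizes chosen to keep a full desk run in minutes: 164-dyad
cohorts with 200 variables; 10–20 seeds for averaged properties;
199–999 permutations; 64–128 Monte-Carlo instances; 200-tree forests in
sanity checks (the pipeline default stays at 500). The acceptance
pipeline run uses 199 permutations and 3 cross-validation repeats.

## Known limitations

- Marginal PERMANOVA uses raw (not residualized) permutation.
- PCoA discards negative-eigenvalue axes rather than correcting them.
- t-SNE coordinates are reproducible only within a library version.
- The Louvain partition and the catch-all module are reported
  separately; no attempt is made to force a particular module count.
- The spatial-median PERMDISP statistic differs slightly from
  centroid-based dispersion; both are available.
- The synthetic cohort is a structural emulation; none of its marginal
  distributions should be read as clinical estimates.
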