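# Methods

`hccmet` re-implements, as a tested library plus numbered analysis drivers,
four computational procedures used in liver-cancer metabolism studies:
cross-cohort consensus calling of tumor-altered metabolic genes, atom-mapped
¹³C isotopologue route prediction, expression-stratified overall-survival
analysis, and extracellular-flux ATP-rate partitioning. Every stage runs on
synthetic inputs with planted ground truth, so the whole pipeline is
verifiable without any external download.

## Differential expression and the DE gate

Each cohort is a genes × samples matrix of log2 intensities with tumor and
normal sample labels (pre-normalized inputs are assumed; normalization is
out of scope). Per gene, log2FC = mean(tumor) − mean(normal) and the
two-sided p-value comes from the unequal-variance (Welch) t test with
Welch–Satterthwaite degrees of freedom. We deliberately use the plain Welch
test rather than a moderated (shrinkage) t: the downstream consensus is
threshold-based, not rank-based, and a self-contained test keeps the
procedure reproducible from first principles. No multiple-testing correction
is applied; the gate is on raw P.

The primary gate keeps genes with **P < 0.001 and |log2FC| > 1.5** (strict
inequalities). The absolute-value reading is the default because both up-
and down-regulated genes are classified downstream; `absolute=False`
preserves the literal one-sided reading. Degenerate genes follow a fixed
convention: zero variance in both groups with equal means → p = 1; zero
variance with unequal means → p = 0.

## Adaptive cutoff and cross-cohort consensus

After gating, tables are restricted to a metabolism-annotated gene list
(the analysis drivers use a 2752-gene synthetic stand-in list of that size).
Each cohort then gets an adaptive fold-change threshold: the mean |log2FC|
used as a reference for calling direction. By default this mean is taken
over **all genes of the cohort's DE output** (`adaptive_cutoff(...,
over="all")`), which yields a small threshold whose role is to exclude
probes with very small expression changes. The alternative base,
`over="gated"`, averages over gate-passing genes only; because every gated
gene already has |log2FC| > 1.5, that variant produces a threshold at the
typical DE effect size and discards roughly half of the gated genes — it is
provided for completeness but is not the default, since a small-change
filter that removes half of the strong changes contradicts its purpose.
Both cutoff bases can also be computed after metabolic restriction
(`cutoff_over_metabolic_only=True`); the default computes them before.

Direction calls are inclusive at the boundary: up ⇔ log2FC ≥ +cutoff,
down ⇔ log2FC ≤ −cutoff, else ns. A gene absent from a cohort's gated
table counts as ns (not as a missing cohort), keeping the number of
datasets fixed at the design value. The consensus vote marks a gene
consistently altered when it is in the same **exclusive** direction in at
least `min_datasets` of `n_datasets` cohorts (default 8 of 10): a single
opposite-direction call anywhere vetoes consistency. The vote is
equivariant under a global direction flip and monotone in `min_datasets`.

Under full penetrance and effect ≫ noise (the planted-recovery conditions:
10 cohorts, 200 planted genes at 3.0 log2 units, noise SD 0.5, 20/20
samples), the expected sensitivity is ~1 and the expected number of false
consistent calls among n null genes is bounded by
2·n·P[Binom(10, q) ≥ 8] with q ≤ p_max/2 per direction — numerically
negligible at the default gate. With penetrance π the expected recovered
fraction is the binomial tail P[Binom(10, π) ≥ 8] (0.6778 at π = 0.8),
which the simulation reproduces.

## ¹³C label propagation

The tracer engine tracks the full positional labeling state of one molecule
(a distribution over per-carbon ¹²C/¹³C patterns). Reactions are
carbon-level bijections from substrate slots to product slots, shipped as a
reviewable JSON library (`src/hccmet/data/network.json`) and validated for
carbon conservation (CO₂ included) at load and on every application.
Condensations combine independent substrate distributions; on the
mass-shift level this is exactly the convolution
f(m+k) = Σ_j f₁(m+j)·f₂(m+(k−j)).

Key atom-map conventions, all standard biochemistry:

* PDH releases pyruvate C1 as CO₂; PC adds a (by default unlabeled) CO₂ as
  the C4 carboxyl of oxaloacetate.
* Citrate carries the oxaloacetate carbons as C1–C4 and the acetyl carbons
  as C5/C6; oxidative IDH (lumped with aconitase) releases citrate C1 and
  places the acetyl carbons at α-ketoglutarate C4/C5, so **both**
  first-turn decarboxylations (IDH, OGDH) release oxaloacetate-derived
  carbons. This single convention simultaneously yields m+2 first-turn TCA
  intermediates from ¹³C₆-glucose via PDH, m+4 species from ¹³C₅-glutamine
  oxidation, and — because reductive carboxylation is the exact inverse
  map — m+5 citrate and m+3 aspartate from the reductive route.
* 6-phosphogluconate dehydrogenase releases glucose C1, so the oxidative
  PPP yields m+5 ribose 5-phosphate from m+6 glucose; the non-oxidative
  route rearranges glycolytic triose carbons (m+3 ribose 5-phosphate from
  m+3 glyceraldehyde 3-phosphate with other inputs unlabeled), with
  transketolase moving C1–C2 units and transaldolase C1–C3 units.
* Succinate and fumarate are 2-fold symmetric; orientation is scrambled
  50/50 at production. Scrambling changes positional patterns only — the
  mass-shift distribution is permutation-invariant, which the tests assert
  by toggling it.

Semantics are single-pass ("first turn"): each route applies its reactions
once, with co-substrates drawn from explicitly declared unlabeled pools
(CO₂ for PC and reverse IDH, oxaloacetate for citrate synthase, F6P in the
non-oxidative PPP) or from saved intermediates (the PDH+PC citrate route
condenses two products of the same labeled pyruvate). The routes are
shipped as JSON (`src/hccmet/data/routes.json`) so every pool assumption is
inspectable rather than hard-coded. Steady-state flux fitting, multi-turn
TCA enrichment and natural-abundance correction are out of scope; tracer
purity is 100%.

The engine's independent oracle in the tests is a seeded single-molecule
simulator that shares no code with the exact enumeration: it pushes one
molecule at a time through a route, choosing symmetric orientations at
random, and tallies terminal label counts; exact and simulated MIDs agree
within the Monte-Carlo band on every shipped route. Mixtures of route MIDs
(e.g. oxidative vs reductive citrate) invert by least squares to the
generating weight within 1e-9.

## Survival analysis

Patients are ranked by expression and stratified either at the median
(bottom vs top 50%) or into tertiles (low / intermediate / high, with the
middle third dropped when comparing extremes). Ties are broken by stable
rank order; with odd n the median split assigns the extra subject to the
high stratum, and tertile remainders go to the later strata.

The Kaplan–Meier estimator and the log-rank test are implemented from the
formulas (the product-limit over distinct event times; the Mantel–Cox
statistic (Σ(O−E))²/ΣV with hypergeometric moments, referred to χ²₁), with
lifelines used in the tests only as an independent cross-check. Events
precede censoring at tied times; zero total variance returns statistic 0
and p = 1. The synthetic generator draws exponential event times with rate
λ₀·exp(β·x) (λ₀ = 0.02/month by default, median ≈ 35 months — a realistic
five-year horizon for this disease setting), optional uniform censoring,
and administrative censoring at 60 months. At β = 0 the implemented test's
type-I error over 2000 replicates of n = 100 sits inside (0.04, 0.06) at
α = 0.05, and power is monotone in both n and β.

## Bioenergetics

Stress-test traces carry three measurement points per phase (the plate
convention); the per-phase summary is the mean. Metric definitions, with
negatives clipped to 0 and a warning:

* mito (OCR): basal = baseline − post_rot/AA; ATP-linked = baseline −
  post_oligomycin; proton leak = post_oligomycin − post_rot/AA; maximal =
  post_uncoupler − post_rot/AA; spare = maximal − basal. The identity
  basal = ATP-linked + leak holds exactly.
* glyco (ECAR): glycolysis = post_glucose − baseline; capacity =
  post_oligomycin − baseline; reserve = capacity − glycolysis.

ATP partitioning follows the extracellular-flux accounting of Mookerjee &
Brand: J_glyc = max(0, ECAR·BF − c·OCR_ATP)·(ATP per lactate) and
J_ox = 2·(P/O)·OCR_ATP, where BF converts mpH/min to proton flux and c
corrects for respiratory CO₂ acidification. The constants are configuration
values (defaults: ATP/lactate = 1, P/O = 2.486, BF = 1, c = 0); they are
instrument- and medium-dependent, so every check on this module is
algebraic or oracle-based (limit cases 0 and 1, monotonicity in ECAR and
OCR, conservation J_total = J_glyc + J_ox) rather than tied to particular
constants. Well-level DNA normalization is accepted as a pre-scaled input
only.

## What the synthetic data does and does not show

The generators emulate the features the methods rely on — shared planted
effects with cohort-specific noise and penetrance, a hazard actually linked
to expression, plateaued injection phases — with i.i.d. Gaussian log2 noise,
no batch or platform effects beyond per-cohort baselines, no probe-level
structure, exponential (constant-hazard) survival, and Gaussian plate noise.
Passing tests therefore demonstrate correctness of the procedures under
their own assumptions, not robustness to the correlation structure,
heavy tails or missingness of real cohort data.

## Problem sizes

The analysis drivers use 10 cohorts × 5200 genes × 40 samples, a 2752-gene
metabolic list, 200 planted genes, a 200-patient survival cohort and
8-well plates; the recovery and calibration tests use the same design (2000
replicates for the type-I error check). These sizes give stable estimates —
binomial/CLT errors well below the tested margins — while keeping a full
run in seconds.
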