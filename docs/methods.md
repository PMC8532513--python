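# Methods

This note documents the models and procedures implemented in `evogem`, the
assumptions behind them, the synthetic data they are tested on, and the
numerical and design choices a maintainer should know about.

## Pan-model and species-model derivation

The pan-model is the union metabolic network over a species panel:
metabolites, reactions with stoichiometry and flux bounds
(mmol gDW⁻¹ h⁻¹), and a boolean gene–reaction (GPR) tree per reaction keyed
by ortholog-group identifiers. A species model is derived from one row of a
binary species × ortholog existence matrix by re-evaluating every GPR:

* An AND node models an enzyme complex. It is active iff **strictly more
  than 50%** of its distinct gene leaves are present (2 of 4 subunits is
  inactive; 2 of 3 is active). The count is over distinct gene leaves of
  the (flattened) AND subtree, not stoichiometry-weighted — subunit copy
  numbers are not part of the data model. When active, missing subunits are
  pruned from the retained rule.
* An OR node models isozymes: active iff any child is active; inactive
  children are pruned.
* Reactions without a GPR (exchange, spontaneous) and the biomass
  pseudo-reaction are always retained.

Homolog integration OR-s a duplicate of every *maximal* AND-term containing
the reference gene, with the reference substituted by the homolog
(`A and B -> (A and B) or (C and B)`); a bare reference leaf gains the
homolog as an OR sibling. The operation never deactivates a rule that was
active (property-tested). GPR trees are kept normalized (same-kind nodes
flattened, duplicates merged, children sorted), which also defines the
behaviour for rules nested deeper than complex-of-isozymes: they are
flattened before the majority rule applies.

## Flux balance analysis

FBA maximizes an objective flux subject to steady state (S·v = 0) and
bounds; parsimonious FBA then fixes the objective at its optimum and
minimizes total absolute flux via forward/reverse splitting (or total
protein-pool usage for enzyme-constrained models). Only the objective value
is contract-bound; flux vectors can be degenerate. Media are maps from
exchange-reaction id to bounds; exchanges not listed are closed for uptake
but open for secretion, so a medium fully determines the environment.
The minimal medium convention is free uptake of the ammonia, oxygen,
phosphate and sulfate analogues and a constrained carbon uptake.

Substrate-utilization tests *replace* the default carbon (or nitrogen)
source with the test substrate at an uptake of 10 mmol gDW⁻¹ h⁻¹ and apply
a growth threshold of 10⁻⁶ h⁻¹. Growth exactly at the threshold counts as
growth (the no-growth classification is "below 10⁻⁶"). A species lacking
the substrate's exchange reaction altogether is a non-utilizer. Oxygen
uptake is left unconstrained in these tests. Gene essentiality re-evaluates
every GPR of the species model with the gene removed, disables inactive
reactions, and classifies the gene essential when maximal growth falls
below the threshold. Because pruned complexes can be more permissive than a
full re-derivation from the pan-model when a complex was already partially
present, the rebuild-from-scratch oracle equivalence is asserted on the
synthetic worlds, where complexes are complete or absent.

All LPs run on HiGHS through `scipy.optimize.linprog` (feasibility ~1e-9).
Reported fluxes are rounded at 1e-10 to suppress solver noise.

## Gap-filling

Gap-filling finds a **minimum-cardinality** subset of pan-model reactions
whose addition lets a non-growing species model reach the growth threshold.
It is one MILP: a binary indicator per candidate reaction couples the
reaction's bounds (lb·y ≤ v ≤ ub·y), plus the growth floor; the objective
is the indicator sum. Two numerical points matter:

* the growth-floor row is rescaled so its right-hand side is O(1) —
  thresholds of 10⁻⁶ would otherwise disappear inside the MIP feasibility
  tolerance;
* coupling rows are scaled up (×10⁴) and the HiGHS
  `mip_feasibility_tolerance` is tightened to 10⁻⁹, because a flux leak of
  tolerance size through a switched-off candidate can otherwise fake
  threshold-level growth.

Among equal-cardinality optima, the lexicographically smallest reaction-id
set is returned (greedy prefix fixing with one feasibility MILP per
candidate), making results reproducible; the choice of tie-break is ours.
An optional preferred-candidate pool is tried before the full
pan-minus-model pool, standing in for evidence-guided filling; auxotrophies
are handled by media augmentation, not gap-filling. Optimality is verified
against exhaustive subset enumeration on pools of up to ~8 candidates.

## Enzyme-constrained models and flux control

An enzyme-constrained model adds a usage variable e_i ≥ 0 per enzyme with
per-reaction coupling v_j ≤ Σ_i kcat_ij·e_i (isozymes additive; reversible
reactions are split into irreversible pairs first, each direction coupled)
and a shared pool Σ_i MW_i·e_i ≤ P. Without kcats the model reduces exactly
to its base. Enzyme complexes are represented as single enzymes whose MW
the caller supplies (e.g. the subunit-MW sum at equal stoichiometry — the
simplest consistent choice when subunit stoichiometries are unknown).

The flux control coefficient of enzyme i over flux v_j multiplies all of
the enzyme's kcats by 1.001 and returns the scaled finite difference
((v_j* − v_j)/v_j)/0.001. The unperturbed flux normalizes the difference;
the alternative (perturbed-flux denominator, differing by O(0.1%)) is
available via a flag. On a single-enzyme chain the FCC is analytically 1
(flux = kcat·P/MW), and over a pooled linear pathway the FCCs sum to 1
(the summation theorem), both asserted in tests; a finite difference of
0.0005 vs 0.001 changes FCCs by < 10⁻³ on these smooth fixtures.

kcat fold-scans re-run ec-pFBA per fold (biomass maximization, then
pool-usage minimization) and report fluxes, optionally normalized per gram
of consumed carbon substrate (default molar mass 0.18 g mmol⁻¹, a hexose).
Iterative kcat curation against measured growth rates is replaced by a
single optional global rescaling: the curation loop requires
species-specific measurements, which are inputs rather than computation.

## Trait evolution

A reaction's presence across species is treated as a predictor of a binary
trait; NA observations are excluded per reaction. Reactions with accuracy
**> 0.83** and sensitivity **> 0.92** (both strict) are "highly
correlated" with the trait; the thresholds are those calibrated on the
galactose-utilization gene set in the literature this workflow follows.
Trait changes are classified against a per-trait ancestral posterior:
ancestrally present at p ≥ 0.85, absent at p < 0.15 (boundaries chosen at
the stated one-sided readings), intermediate posteriors or NA observations
are undetermined.

Loss attribution applies three rules in order: (a) a correlated reaction is
missing; (b) a direct-pathway reaction is missing (but no correlated one);
(c) the direct pathway is complete and gap-filling to restore utilization
adds only reactions *outside* it — the downstream-pathway gap, the
signature of a loss caused by a distantly related dependency such as a
gluconeogenic step. Anything else is unexplained. Gain tallies are pure
aggregation over supplied HGT, family-expansion and promiscuity gene sets
(computing family expansion itself is out of scope); categories overlap and
are reported separately.

## HGT screening

The Alien Index uses the best (minimum) E-values of group-lineage and
outside-group hits with a 10⁻²⁰⁰ pseudo-count; a lineage with no hit enters
as E-value 1.0 (the conventional no-significant-hit ceiling; configurable).
Distant candidates satisfy AI ≥ 45 and out_pct ≥ 90%, both inclusive.
out_pct counts unique hit species (deduplicated when a species column is
present) among non-recipient hits; the denominator is configurable since
only the numerator is standardized. The close screen applies three
sequential filters: best non-recipient hit in the group lineage with
bitscore ≥ 100; ≥ 90% group-lineage share among non-recipient hits; HGT
index (best group bitscore / best recipient bitscore) ≥ 0.5, read as a
ratio. Screens report candidates only; phylogenetic confirmation is a
manual, out-of-scope step.

## Site-level analyses

Conservation is the Jensen–Shannon divergence (base 2, λ = 0.5) between a
column's residue distribution (gaps excluded) and a background (uniform by
default), multiplied by (1 − gap fraction). Columns with gap fraction
above 0.3 are flagged low-confidence but still scored, and an all-gap
column scores 0 — flagging rather than dropping keeps the position indexing
stable. Unique mutations for a tolerant/non-tolerant split report residues
with frequency > 0.80 among tolerant species that are absent from the
reference set (> 0.20 among non-tolerant); frequencies are over species
with a non-gap character at the column (a flag switches to gap-inclusive
denominators), and only columns mappable to the ungapped reference are
reported.

The clustering test scores a site set by Σ over pairs of
exp(−d²/(2t²)) with t = 6 Å (the published Gaussian pair potential;
configurable) on Cα distances, against a null of equally many residues
re-placed uniformly without replacement; p = (1 + #{null ≥ obs})/(1 + N)
stays in (0, 1]. Functional-site distances use a 10 Å adjacency radius.
PDB I/O is restricted to Cα traces (ATOM records); structure quality
filtering is upstream.

## Essential-gene features and evaluation

Dinucleotide composition divides overlapping pair counts by N−1. The 3-mer
frequency divides overlapping triple counts by **N**, the sequence length,
so the 64 entries sum to (N−2)/N — the printed normalization is kept
literally, and the (N−2) alternative plus a codon-frame mode are flags.
Ambiguous bases are rejected, not skipped; a pre-filter reports their
positions. Evolution features are the ortholog-group mean conservation,
gene-level dN/dS, occurrence count, and average paralog number
(sequences / unique species). Class balance is restored by oversampling the
minority class with replacement (seeded). ROC/AUC uses the rank
(Mann–Whitney) formulation with midrank ties; feature ranking uses the
chi-square statistic on class-aggregated feature mass (dN/dS clipped at a
configurable maximum). Classifiers (random forest, RBF SVM) are consumed
through scikit-learn and are deliberately not part of the contribution.

## Synthetic worlds and what they do (not) show

The generators define the study conditions for all tests.

The pan-network (default: 4 substrates, 16 species, ≈30 reactions) has one
catabolic branch per substrate feeding one of two hub metabolites; biomass
(a single pseudo-reaction over 5 precursors) needs both hubs, the upper→
lower conversion runs through a 3-subunit respiratory complex or a
fermentative bypass, and the lower→upper direction requires one
gluconeogenesis-like "downstream" reaction — so substrates entering at the
lower hub silently depend on it. Planted events are placed on branches of a
random bifurcating species tree so losses are clade-structured: per loss
trait one clade (≈⌈0.17·n⌉–⌊0.3·n⌋ species) loses the catabolic ortholog
and one terminal branch the transporter; one terminal branch loses the
downstream ortholog; a gain trait's transporter (the planted HGT gene)
exists only in one clade. Event clades are kept mutually disjoint — nested
or identical loss clades for two traits would make each trait's causal
reaction correlate with the other trait too. The clade sizes are chosen so
the published 0.83/0.92 thresholds separate planted causal reactions
exactly: the transporter-loss and downstream singletons keep the catabolic
reaction's accuracy above 0.83 while the catabolic-loss clade pushes the
transporter's accuracy to or below it; the arithmetic requires n ≥ 12, so
transporter losses are only planted at that size. Ancestral posteriors are
emitted as 0.95 for loss traits and 0.05 for the gain trait; a single trait
cannot be both ancestrally present and absent, so "gains and losses" are
planted across the trait set rather than within one trait.

Hit tables give ordinary genes strong recipient hits and weak group/outside
hits; distant-HGT genes outside-group best hits at least e⁴⁵ stronger than
any group hit with ≥ 90% outside rows; close-HGT genes group-lineage best
hits ≥ 100 bits at 0.6–0.9× the recipient bitscore with ≥ 90% group rows.
"No hit" is an absent row, never a sentinel. Sequences come from an
order-2 Markov chain whose conditional profile is displaced in log-space by
0.6·shift (calibrated so shift = 0.2 gives a sequence-only AUC ≈ 0.75–0.85
at a few hundred genes per class); evolution-feature separations also scale
with shift, so shift = 0 carries no signal anywhere. Structures are ideal
helices (1.5 Å rise, 100° turn, 2.3 Å radius); on such a helix, Cα pairs
below 6 Å only occur at sequence offsets ≤ 4, so the planted cluster uses
offsets of 1, 3 and 4 — consecutive cluster sites are spatially adjacent
while the cluster spans several turns — and invariant functional columns
are placed ≥ 10 Å away.

These worlds establish *correctness of the logic* — oracle agreement,
planted-signal recovery at the published thresholds, permutation-test
calibration — not realism: no sequence evolution is simulated, networks are
orders of magnitude smaller than genome scale (defaults ≤ 200 reactions),
trait noise is independent Bernoulli, and structures are idealized.
Passing tests therefore show the machinery is implemented correctly, not
that the thresholds are optimal for real panels.

## Problem sizes and determinism

Default test sizes (16–100 species, ≤ 8-candidate gap-fill pools, 10,000
permutations for the planted-cluster test, 150–300 genes per class,
200-replicate null calibration at 1,000 permutations) were chosen so the
full suite and the acceptance script each finish in minutes on one CPU
while keeping every statistical check well-powered. All randomness flows
through `numpy.random.default_rng` seeds; the end-to-end pipeline writes
sorted-key JSON and fixed-format TSVs and is byte-identical across runs
with the same seed.

## Known limitations

* SBML import/export is not supported; the pan-model schema is JSON.
* Thermodynamic constraints, flux variability analysis and biomass
  re-scaling by phenotype group are out of scope.
* dN/dS values, ancestral-state posteriors, taxonomy classes and
  family-expansion calls are consumed as inputs, never computed.
* The >50%-of-subunits rule is applied to flattened complexes; behaviour on
  GPRs nested deeper than complex-of-isozymes is a documented convention,
  not a validated biological claim.
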