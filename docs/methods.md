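# Methods

## The additive model and epistasis magnitude

All analyses operate on a genotype × trait table for the 2^n deconvolution
genotypes between a parent and an n-fold variant.  The reference state is the
experiment's parent (for the BM3 series, the F87A background written `---`),
not wild type: F87A is background shared by every genotype, so effects
*w(A) = f(A) − f(parent)* are defined relative to it.

For a split of genotype *U* into k ≥ 2 disjoint mutation sets, additivity
predicts `expected = f(parent) + Σ w(Aᵢ)`, and the epistasis magnitude is
`ε = f(U) − expected`.  ε is computed **on each trait's own scale** (%,
kJ/mol, min⁻¹) with no log transform: the quantities being compared are plain
differences of assay values, and reported ε values are directly
interpretable in trait units.  Users who prefer multiplicative fitness can
derive a log-scale trait before analysis (`augment_dataset` accepts any
derived-trait formula); the analysis itself is transform-agnostic.

ε is symmetric under permutation of parts, and nested splits obey the exact
decomposition `ε(A,B,C) = ε(A, B∪C) + ε(B, C)` — both are algebraic
identities of the definition and are verified as property tests rather than
assumed.

## Error propagation

Replicate measurements (n = 2 in the reference data) carry SEM =
sd/√n with the sample (n−1) standard deviation.  Propagation treats genotype
means as independent:

* `SEM(expected)² = Σᵢ sem(Aᵢ)² + (k−1)²·sem(parent)²` — the parent mean
  enters the expectation k−1 times, so its error is scaled, not counted
  per part;
* `sem(ε)² = sem(U)² + SEM(expected)²`.

Derived traits (ΔΔG‡, PFR, CE, TTF, leak-corrected NCR) are recomputed per
replicate when replicates are available, which captures input correlations
exactly; the first-order delta method is the fallback for summary-only data.
Both routes are checked against 10⁵-draw Monte-Carlo resampling oracles in
the test suite (agreement within 10% for SEM/mean < 0.2; the delta method
degrades, as expected, for relative errors much larger than that).

## The selectivity → ΔΔG‡ transform

Regioselectivity is converted to a transition-state free-energy difference
`ΔΔG‡ = RT·ln(p/(1−p))` (R = 8.314 J·mol⁻¹·K⁻¹, default T = 298.15 K since
assays run at 25 °C), positive when the target regioisomer dominates.  *p*
defaults to the **total** basis — the fraction of all quantified products
going to the target — because published selectivity percentages include
minor regioisomers; a pairwise basis (target vs one competitor) is available
via `SelectivityValue(basis="pairwise")`.  The transform is undefined at
p ∈ {0, 1}; callers may clamp upstream, the library refuses silently
infinite energies.

## Interaction taxonomy and the significance rule

Classification uses the signs of the *oriented* part effects (each trait
declares higher- or lower-is-better), of ε, and of the combined effect
w(U):

* **ADD** when |ε| ≤ max(k_sig·sem(ε), abs_tol) — defaults k_sig = 1,
  abs_tol = 0.  With duplicate assays, one propagated standard error is a
  defensible resolution limit; no published rule exists for this call, so
  both knobs are exposed and ε is reported regardless of label.
* **ME** (±, by the sign of ε) when all parts share one effect sign and the
  combination keeps it; the k-way case generalizes the pairwise definitions
  by reading "both" as "all parts".
* **RSE** when all parts share one sign but w(U) is significantly opposite
  (+RSE: deleterious parts, beneficial combination; −RSE the reverse).
* **SE** (±, by the sign of ε) when part signs are mixed.

Part effects within threshold of zero are sign *ties*.  Ties are grouped
with the majority sign of the significant parts (falling back to the sign of
the combined effect, then of ε, when every part is tied), which prefers ME
over SE calls; tied parts are flagged `marginal` in every output so the
ambiguity is never hidden.  This rule is a design choice: near-zero effects
under n = 2 noise would otherwise flip SE/ME calls from replicate to
replicate.  Consequently label counts for traits whose single-mutant effects
hover near zero (conversion, NCR, CE in the reference data) depend on this
rule and on the assumed SEMs, whereas ε magnitudes do not; the selectivity
column, whose single-mutant effects are all clearly resolved, reproduces the
published 6 +SE / 1 +ME pattern exactly, with the lone magnitude-epistasis
case at the (R47I, T49I) pair.

The truth table is total — every reachable combination of signs maps to
exactly one of the seven labels — and is tested exhaustively.

## Split enumeration

Three modes, all in deterministic canonical order (union size, union
indices, parts):

* `paper` (default): every unordered binary split of every sub-genotype with
  ≥ 2 mutations, plus the all-singles split of the full genotype — 7 rows
  for n = 3 (6 binary + 1 tertiary), 26 for n = 4;
* `binary_only`: the binary splits alone;
* `all_kway`: every set partition with ≥ 2 blocks of every sub-genotype.

Splits whose required genotypes are unmeasured are skipped and listed with a
reason, so partial deconvolutions analyze cleanly.

## Pathway accessibility

Each of the n! orderings is scanned step by step; a step is permitted for a
trait when its oriented change is ≥ −tol with
tol = max(k_sig·√(sem_from² + sem_to²), abs_tol), k_sig = 1 by default.
A pathway is favoured iff every step is permitted for every considered
trait, so the multi-trait accessible set is exactly the intersection of the
single-trait sets.  Ties (changes within tolerance) are permitted: a
favoured pathway is one that never *significantly* worsens, which is robust
to duplicate-assay noise; whether published analyses treated exact ties as
permitted is unknowable from summary data, and with the reference values the
verdicts do not depend on the choice.  Verdicts are invariant under
increasing affine rescaling of a trait (SEM-based tolerances rescale with
the data; an absolute tolerance must be rescaled by the caller).

Pathways are numbered 1..n! in lexicographic order of the site ordering.
For (R47I, T49I, Y51I) this places the two Y51I-first orderings at numbers
5 (`--- → --I → I-I → III`) and 6 (`--- → --I → -II → III`), matching the
published numbering where pathway 6 carries the activity series
21 → 72 → 158.

## The synthetic generator

`generate_dataset` realizes `f(g) = parent + Σ_{i∈g} aᵢ + Σ_{S⊆g,|S|≥2} ε_S`
with i.i.d. normal replicate noise (default n = 2 replicates, matching the
duplicate-assay design of the reference data; a heteroscedastic
sd-proportional-to-mean variant can be expressed by giving each trait its
own landscape).  It emulates the *statistical* shape of a deconvolution —
additive structure, injected interactions, replicate scatter — and none of
the biochemistry: no NADPH trace kinetics, no enzyme inactivation, no
correlated errors between traits measured from the same HPLC run.  Passing
tests on synthetic data therefore demonstrate correct inversion of the
additive-plus-interaction model and calibrated error propagation, not that
real assay errors are normal or independent.

Zero-noise landscapes invert exactly: pairwise ε equals the injected
coefficient and the all-singles ε equals the sum of all injected interaction
terms — tested, not assumed.  With noise, recovered ε is unbiased and its
seed-to-seed spread matches the propagated SEM within 15% over 300 seeds.

## The frozen reference fixture

`bm3_fixture()` ships 8 genotypes × 7 traits (conv, ddg, ncr, pfr, ce, ttn,
ttf; mean/SEM/n = 2) as frozen constants with per-value provenance tags
(`reported` / `solved` / `derived` / `assumed`); the sidecar YAML documents
every constraint honoured.  Key facts the suite asserts: the activity series
11 → 21 → 72 → 158 and the four single/double TTFs recovered from the
published ε identities; CE = 37% for `-II` and `III` against 15–30%
elsewhere; selectivity energies with singles summing to −3.45 ± 0.25 kJ/mol
against the measured 5.6 ± 0.0 for `III` (ε = 9.05, tertiary +SE); TTN ε
terms within ±1 of the published table; PFR = NCR × CE exactly.  Values
tagged `assumed` are synthetic stand-ins — the true per-mutant numbers live
in supplementary material not reproduced here — chosen once and never
regenerated, so downstream expectations are stable.  Solving the published
ε grid from rounded printed values leaves ±1 discrepancies in the last digit
of some binary-to-triple terms (e.g. 134 vs the printed 133, 141 vs 140);
these are printed-rounding artifacts, not model error.

## Numerical and degenerate-input choices

* Genotype labels: `-` = absent; any other single character = present
  (strict mode additionally requires the site's introduced-residue letter).
  Labels are case-sensitive; parse∘format is the identity.
* Missing genotypes never abort an analysis: affected splits/pathways are
  skipped/unevaluable with reasons.
* Leak-corrected NCR may be negative (leak exceeds consumption, common for
  poorly coupled mutants); it is flagged, never clamped.
* SEM of a single replicate is 0 by convention (no spread information), and
  a sem of 0 simply makes every nonzero effect significant.
* Report tables round ε to each trait's declared display precision; CSV and
  JSON outputs always carry full precision, so rounding is presentation
  only.  (With ε exactly 9.05, one-decimal display shows 9.1.)

## Problem sizes

Property suites run at n = 3–4 sites (8–16 genotypes), 1000 random
landscapes for the decomposition identity, 10⁵ Monte-Carlo draws for SEM
oracles and 300 seeds for calibration — sizes at which the combinatorial
enumerations are exhaustive and the statistical tolerances (10–15%) are
comfortably resolved.  All quantities scale factorially/exponentially in n;
the implementation enumerates rather than samples, which is the right
trade-off for the n ≤ 6 deconvolutions the tool targets.

## Known limitations

* No multiple-testing correction across traits or splits: with 7 traits × 7
  splits, a 1-SEM ADD threshold will miscall some interactions by chance;
  treat label counts as descriptive.
* The additive model is not a Walsh/Fourier decomposition over incomplete
  landscapes; it requires the specific genotypes of each split.
* Classification near sign boundaries is threshold-dependent by nature; the
  `marginal` flag is the honest signal, not a fix.
* ΔΔG‡ assumes two-state transition-state competition; multi-product systems
  folded into a "total" basis lose mechanistic interpretability at extreme
  p.
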