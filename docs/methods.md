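# Methods

This note documents the models and procedures implemented in `mfbo`, the
parameters that matter, the synthetic benchmark they are validated on, and
the limits of what those validations show.

## The discovery problem

A discrete library of N molecules can be interrogated at three tiers of
experiment ("fidelities") of increasing cost and quality:

| level | experiment | relative cost | value stored |
|---|---|---|---|
| 0 (low) | docking-like score | 0.01 | dimensionless, lower = better binding |
| 1 (medium) | single-point % inhibition at a screen concentration | 0.2 | percent in [0, 100] |
| 2 (high) | dose–response IC50 | 1.0 | pIC50 = −log10(IC50 / M) |

The costs (0.01, 0.2, 1.0) reflect a throughput of roughly 1,000 dockings,
100 single-point syntheses+assays, and 10 dose–response measurements per
iteration of an autonomous platform. The goal is to *confirm* — i.e. to
measure at the highest fidelity — as many of the library's top-N% most
potent molecules as possible under a fixed per-iteration budget
(`budget_frac × N × cost_high`, default the cost of dose–response testing
2% of the library).

Before modeling, all values are oriented so that higher = better: docking
scores are negated, percent inhibition and pIC50 pass through.

## Surrogate model

A single exact Gaussian process is placed over (molecule, fidelity) pairs
with an intrinsic-coregionalization kernel

    k((x, f), (x', f')) = a · B[f, f'] · T(x, x'),

where `T` is the Tanimoto similarity of binary circular substructure
fingerprints (radius 2, 1024 bits, no chirality, no counts) — a valid PSD
kernel on bit vectors — `a > 0` an amplitude, and `B` an F×F PSD
coregionalization matrix parameterized as a rank-2 factor plus a positive
diagonal. Each fidelity has its own Gaussian noise variance with a floor of
1e−6 (standardized units). Training values are z-scored per fidelity inside
the model.

Cross-fidelity information flows through `B`: with strongly coupled
fidelities a cheap measurement at `x` sharply reduces the dose–response
posterior variance at `x`. Although `B` is a global matrix, the *effective*
correlation between assays varies over chemical space through posterior
conditioning on whichever fidelities have been measured near `x`.

Hyperparameters (a, B-factor, noises — 13 parameters for 3 fidelities)
maximize the log marginal likelihood by multi-start L-BFGS-B with analytic
gradients (default 5 seeded restarts, bounded log-space search). When the
training set exceeds `max_fit_points` (default 256) the likelihood is
maximized on a seeded subsample and the returned state conditions on the
full set; the GP itself is exact (no sparse approximations), which caps
comfortable training sizes at a few thousand pairs. Campaigns refit once
per iteration with a lighter setting (3 restarts, 60 iterations, 224-point
subsample) so a full benchmark stays at desk scale.

## Acquisition

The acquisition follows targeted variance reduction: per fidelity, posterior
means over the candidate pool are min–max scaled to [0, 1], and posterior
variances are divided by the squared pool range *and by the fidelity's
relative cost*, so cheap assays carry inflated variance. The pool always
contains every (molecule, fidelity) pair of the library; already-measured
pairs are excluded from selection but retained in the scaling statistics so
that the incumbent — the best measured highest-fidelity value, on the same
scaled axis — is commensurable with the candidate means. (Scaling over the
un-measured remainder alone lets the incumbent scale past 1.0 and clip,
flattening the whole EI landscape.)

The score of a candidate pair (x, f) is the closed-form expected
improvement whose **mean is the molecule's scaled highest-fidelity
posterior mean** and whose spread is the candidate pair's own cost-inflated
scaled standard deviation: every experiment, cheap or dear, is valued by
how much it could improve our estimate of the molecule's dose–response
performance. This produces the expected funnel-like cascade — a promising
molecule is docked, then screened, then confirmed — because a cheaper
unmeasured tier of the same molecule always carries more cost-inflated
spread than the dose–response tier itself.

Batches are assembled by a beam-style fantasy search: select the argmax
pair (ties to lower cost, then lexicographic id), draw `n_fantasies`
outcomes from its posterior, condition each into a child branch (an exact
rank-1 update of the joint pool posterior; hyperparameters are not refit —
a full refit per fantasy exists behind `MCConfig.refit_per_fantasy`), keep
the `keep_branches` branches with the highest cumulative EI, and repeat
until no branch can afford another experiment. Defaults: 3 fantasies, beam
width 5. Scaling statistics and the incumbent are frozen at batch start.
With one fantasy and one branch the procedure reduces exactly to the
sequential "believer" greedy loop, which the test suite verifies against an
independent implementation.

## Assay simulation

Retrospective campaigns measure against an oracle built from stored ground
truth. Single-point inhibition follows the noncooperative Hill equation,

    inhibition% = 100 / (1 + (IC50 / [L])^h),  h = 1,

so inhibition is exactly 50% at [L] = IC50. Noise is additive Gaussian:
defaults 5 percentage points (medium, clipped to [0, 100]), 0.1 pIC50 units
(high), and 10% of the low-value range (low). Each (molecule, fidelity)
query draws from its own hashed substream and is memoized, so oracle
answers are independent of query order. Decoy injection dilutes a library
with presumed inactives that still receive plausible docking scores
(resampled from the actives' distribution) but a fixed pIC50 sentinel of
3.0 (≈1 mM), keeping them out of every top-N% label set.

## Synthetic benchmark libraries

`generate_synthetic_library(n, target_D, target_rho, seed)` replaces
downloaded screening data. Molecules are unique valid SMILES assembled from
a packaged fragment vocabulary (20 cores × 8 linkers × 20 tails); the
breadth of the vocabulary slice is bisected until the set diversity
D = 1 − mean pairwise Tanimoto similarity is within 0.1 of the target
(achievable range with the packaged vocabulary: roughly 0.69–0.87).

Latent potency is a noise-free draw from a Tanimoto-kernel GP over the
fingerprints, rank-transformed onto a right-skewed Beta(2, 5) marginal over
pIC50 ∈ [4, 9]: most molecules are weakly active and only a thin tail is
potent, as in real screening decks. The docking-like channel blends the
standardized potency with an independent GP draw, with the mixing weight
bisected until the docking↔potency correlation |ρ| (absolute Pearson, the
single-predictor multiple correlation) is within 0.05 of the target.

Two deliberate design choices deserve emphasis:

* **Correlation is calibrated on the docking channel only.** The
  single-point channel is by construction a (noisy) monotone Hill transform
  of potency, so the two-predictor multiple correlation has a floor around
  0.55–0.85 regardless of the blend; the docking channel is the actual free
  lever. The `multiple_correlation` metric itself supports both one and two
  predictors (default two), and the generator manifest reports both values.
* **The screen concentration is matched to the deck.** The generator
  realizes its single-point column at 0.2 µM, near the top decile of its
  potency marginal, where the Hill curve discriminates the potent tail
  (pIC50 7 → 67%, 8 → 95%, 9 → 99.5%). A screen far above the leaders'
  IC50s (e.g. 20 µM against nanomolar leads) reads ≈100% for everything
  potent and carries no ranking information — no selection strategy can
  then decide which leader deserves confirmation. The concentration is
  recorded in the dataset metadata and honored by the oracle; for user
  data the assay-simulation default remains 20 µM.

What the generator does **not** emulate: activity cliffs, assay artifacts
and frequent hitters, systematic docking bias against particular
chemotypes, heteroscedastic dose–response noise, and the size and
clustered redundancy of real vendor libraries. Benchmarks on these decks
demonstrate the *mechanisms* of the algorithms (cost-aware exploration,
cross-fidelity transfer, funnel staging) at desk scale; they do not predict
absolute recovery rates on any real target.

## Structured subsets

`build_structured_subset` mirrors the protocol of probing diversity and
correlation regimes from a fixed pool: k-medoids (PAM with a deterministic
greedy build plus seeded restarts, Tanimoto distance) partitions the pool
into 25 clusters; a *narrow* subset draws from the minimal prefix of
clusters (by size) that can supply n molecules, a *diverse* subset draws
proportionally from all clusters. The commanded |ρ| is approached by
drawing molecules with softmax weights on their absolute residuals from
the high-on-low regression — upweighting high-residual molecules weakens
the relationship, downweighting strengthens it — with the inverse
temperature bisected (25 steps, tolerance 0.05) over deterministic
re-draws. An unreachable target returns the best-achieved subset with a
warning flag in its metadata.

## Campaign protocol and baselines

Campaigns are initialized by measuring `round(0.05·N)` molecules, sampled
uniformly from outside the top-N% label set, at **every** fidelity
(uncharged), so the surrogate can learn the interfidelity relationship.
Recovery counts a top molecule as found only once it has a highest-fidelity
measurement; a flag (`count_medium_as_found`) exposes the more lenient
rule. Baselines:

* `bo_high` — a single-fidelity GP on dose–response data with the same
  EI/batch machinery, all spend at cost 1.0;
* `random` — uniform unmeasured dose–response picks;
* `funnel` — fixed allocation (20/40/40% of budget at low/medium/high),
  survivors of each stage ranked into the next; the low stage is randomly
  ranked (no model);
* `transfer` — the funnel flow, but the high stage ranks by a random-forest
  regression of observed pIC50 on fingerprint ⊕ observed lower-fidelity
  values — a deliberately simple feature-augmentation transfer baseline.

`fold_improvement(a, b, at_iteration=5)` is the recovery ratio after five
iterations (10% of the space by cost); a zero denominator returns NaN
rather than infinity.

At the benchmark's scale (n = 400, D ≈ 0.85, |ρ| ≈ 0.4, 2% budget, 6
replicate seeds) MF-BO's spend drifts across iterations from docking to
single-point screens to dose–response confirmation, and its mean recovery
after 5 iterations exceeds both `random` and `bo_high`. Replicate seeds
vary initialization and assay noise on a fixed deck; deck-to-deck
realization variance at n = 400 (8 top molecules) is substantial, so
cross-deck comparisons hold the deck fixed.

**Known limitation.** A common expectation for multifidelity selection is
that its advantage peaks at *moderate* interfidelity correlation and falls
off at both extremes — at zero correlation cheap data carry no signal, and
at perfect correlation a plain funnel suffices. In this implementation the
falloff at the high end does not occur: with near-perfect docking↔potency correlation
MF-BO identifies and confirms leaders even faster (fold over `bo_high`
≈ 2.8 at |ρ| ≈ 0.95 vs ≈ 1.7 at |ρ| ≈ 0.4), because `bo_high` never reads
the cheap channel and is therefore regime-invariant while cost-aware EI
benefits monotonically from better cheap information. A per-fidelity-mean
EI variant (scoring each pair by its own fidelity's scaled mean) does
reproduce a stall at strong correlation, but it stalls everywhere else
too — under it the sampler never purchases dose–response experiments at
this scale — so the highest-fidelity-mean formulation was kept.

## Genetic molecular generator

The generator evolves candidates with synthesizable routes: every candidate
is a building block plus an ordered list of (reaction template, partner)
steps, replayable through RDKit reaction SMARTS. The packaged template set
contains ten robot-amenable transformations (amide coupling, sulfonamide
formation, reductive amination, N-alkylation, ester formation, urea
formation, SNAr amination, imine condensation, Boc removal, biaryl
coupling); users supply their own as `name<TAB>reaction-SMARTS`.

Selection is NSGA-style: non-dominated sorting ranks candidates across the
configured objectives, every rank-1 candidate survives unchanged (elitism),
and the remainder is drawn by stochastic universal sampling with fitness
1/rank, then mutated. Mutation chooses apply/remove/crossover with
molecular-weight-proportional weights (apply fades to zero at 500 Da,
remove fades in above 100 Da, fixed crossover share 0.2), keeping products
drug-sized. Crossover swaps route suffixes from a shared template step
onward, exchanging that step's partner; children that fail route replay are
discarded. All survivors must pass the substructure filter catalog — the
standard PAINS frequent-hitter set, a hydroxamate pattern
(`[CX3](=O)[NX3][OX2]`, excluded so an HDAC-inhibitor search cannot
converge on the known hydroxamate optimum), and reactive-group patterns
(acyl/sulfonyl halides, isocyanates, azides) that automated liquid handling
cannot test safely. A mutation that fails validation falls back to its
parent, so population size is invariant.

Expensive objectives are amortized: candidates are clustered by fingerprint
k-medoids, only medoids are scored, and each member inherits its medoid's
score. Multi-run mode (`run_generations`) pools the final nondominated
fronts of several short independent runs, which uncover distinct local
optima more reliably than one long run. Packaged mock objectives (QED,
cohort diversity, MW-target, seeded random) make the machinery testable
without trained property models; real scorers plug in through the same
`Objective` interface. On multiple template match sites the toolkit's first
product in canonical atom order is taken — documented and stable. Score
uncertainties can be carried by scorers but are not used in ranking.

## Numerical conventions

* Tanimoto similarity of two all-zero fingerprints is 1.0 (logged once).
* Degenerate scaling pools (max = min) map every mean to 0.5 (logged).
* Before any highest-fidelity observation exists the incumbent is 0 on the
  scaled axis — the most optimistic feasible value (logged).
* Top-N% labels break pIC50 ties by id order.
* Set diversity over more than 50,000 pairs is estimated on a seeded
  uniform sample of 50,000 unordered pairs.
* Repeat measurement of an already-observed pair is disallowed within and
  across batches: under this noise model a re-measurement adds no EI.
* All randomness flows from a single seed through hashed substreams
  (`seeding.derive_seed`), so adding a component never perturbs another's
  draws; derived seeds stay below 2^31.

## Reproducing the benchmark

`scripts/acceptance.py --seed 1 --out results/acceptance.json` recomputes
every headline quantity from scratch: the budget-percentage worked
examples, EI vs a 10^6-draw Monte-Carlo oracle, GP posterior vs a
dense-solve oracle, Hill identities, batch-selection contracts over 300
seeded runs, synthetic-dataset structuring fidelity, and the six-seed
retrospective benchmark on fixed n = 400 decks at |ρ| ≈ 0.4 and 0.95. It
finishes in a few minutes on one CPU; problem sizes were chosen so the
whole suite stays at desk scale.
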