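# mfbo — multifidelity Bayesian optimization for molecular libraries

Drug-discovery campaigns can interrogate the same molecule at very
different price points: a docking calculation costs almost nothing, a
single-point percent-inhibition screen is cheap, a dose–response IC50
measurement is expensive. Classic experimental funnels fix the allocation
between these tiers in advance; classic Bayesian optimization spends
everything at the top tier. `mfbo` implements the batched, cost-aware
alternative: one surrogate model over *(molecule, fidelity)* pairs decides,
each iteration, which molecules to dock, which to screen, and which to
confirm — under a single experiment budget.

The package is aimed at computational chemists benchmarking experiment-
selection strategies on discrete libraries, and at autonomous-platform
builders who need a one-shot batch proposer between robot iterations.

## The model and the selection rule

Assay outcomes are modeled by an exact Gaussian process over
(molecule, fidelity) pairs with an intrinsic-coregionalization Tanimoto
kernel on binary circular fingerprints (radius 2, 1024 bits):

    k((x, f), (x', f')) = a · B[f, f'] · T(x, x')

with `B` a learned PSD matrix coupling the fidelities and per-fidelity
noise. Experiments are scored by cost-aware expected improvement
(targeted variance reduction): per fidelity, posterior means over the
candidate pool are min–max scaled to [0, 1] and posterior variances are
divided by the squared pool range and by the fidelity's relative cost
(defaults 0.01 / 0.2 / 1.0 for docking / single-point / dose–response).
The EI of a pair (x, f) targets the improvement of x's outcome *at the
highest fidelity*, with the pair's own cost-inflated spread:

    EI(x, f) = E[ max(Y − y*, 0) ],   Y ~ N(μ̂_high(x), σ̂²(x, f) / cost_f)

so cheap assays are drawn often while their information lasts, and spend
migrates to dose–response confirmation as leaders emerge. Batches are
assembled by a Monte-Carlo fantasy beam search under the budget.

Around that core the package provides the retrospective benchmark protocol
(experimental-funnel, transfer-learning, single-fidelity-BO and random
baselines; top-N% recovery curves; fold improvement), a Hill-equation assay
simulator with a seeded measurement oracle and decoy injection, a
synthetic-library generator with controllable set diversity D and
docking↔potency correlation |ρ|, structured-subset construction, and a
reaction-template genetic molecule generator with non-dominated sorting.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a 400-molecule synthetic deck with high diversity and weak
docking↔potency correlation — the regime where multifidelity selection
should pay off — then race three strategies over five 2%-budget iterations:

```bash
mfbo simulate-data --n 400 --diversity 0.85 --rho 0.4 --seed 101 --out library.csv
# -> wrote library.csv (D=0.863, |rho|=0.425)

for s in mfbo bo_high random; do
  mfbo benchmark --dataset library.csv --strategy $s --seeds 3 --iters 5 \
       --seed 1 --out curves_$s.csv
done
python -c "import pandas as pd; pd.concat(map(pd.read_csv,
  ['curves_mfbo.csv','curves_bo_high.csv','curves_random.csv'])).to_csv('curves.csv', index=False)"
mfbo report --curves curves.csv --at-iteration 5
```

which prints:

```
recovery after 5 iterations:
              mean       std  count
strategy
bo_high   0.416667  0.072169      3
mfbo      0.458333  0.072169      3
random    0.208333  0.190941      3
fold improvement mfbo vs bo_high: 1.10
fold improvement random vs bo_high: 0.50
```

Reading: after spending the equivalent of dose–response-testing 10% of the
library, multifidelity selection has *confirmed* (measured at dose–response)
46% of the deck's top-2% molecules, versus 42% for BO that spends only at
the top tier and 21% for random selection — and it did so while also
building docking and single-point coverage of the space. Per-iteration
spend logs show the characteristic drift from docking-heavy early
iterations toward dose–response confirmation.

The genetic generator and one-shot selection are exposed the same way:

```bash
mfbo generate --generations 5 --runs 4 --population 30 --seed 1 --out candidates.csv
mfbo select --dataset library.csv --observations obs.csv --budget 10.0 --out plan.json
```

Library files are plain delimited text (`id, smiles, low, medium, high`);
every artifact-producing command writes a JSON run manifest beside its
output.

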