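"""The iterative discovery loop and retrospective benchmark strategies.

A campaign searches a discrete library for its most potent molecules under a
per-iteration experiment budget, using one of five selection strategies:

* ``mfbo`` — multifidelity Bayesian optimization: a coregionalized Tanimoto
  GP over all (molecule, fidelity) pairs plus cost-aware fantasy batch EI.
* ``bo_high`` — classic single-fidelity BO: a GP on dose-response data only,
  all spend at the highest fidelity.
* ``funnel`` — a fixed experimental funnel: a share of the budget is spent at
  each fidelity, survivors of each cheap stage advancing to the next.
* ``transfer`` — the funnel flow, but the final stage ranks candidates with
  a model trained on high-fidelity outcomes using the molecule's observed
  lower-fidelity measurements appended to its fingerprint.
* ``random`` — uniform unmeasured picks at the highest fidelity.

Bookkeeping follows the retrospective benchmark protocol: campaigns are
initialized by measuring a small random fraction of molecules (drawn from
outside the top-N% label set) at every fidelity; each iteration's budget is
a fixed fraction of the library priced at the highest-fidelity cost; and
performance is the cumulative fraction of top-N% molecules that have
received a highest-fidelity measurement ("found" requires confirmed
potency — a cheap measurement of a top molecule does not count, though a
flag exposes the alternative counting rule).

Value orientation: the oracle returns raw assay values; this module
canonicalizes them so that higher = better (docking-like low scores are
negated; percent inhibition and pIC50 pass through).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .acquisition import BatchPlan, MCConfig, PairPool, select_batch
from .assaysim import AssayOracle, make_oracle
from .benchdata import LibraryDataset, top_fraction_labels
from .seeding import derive_seed, substream
from .surrogate import (
    FidelitySchedule,
    Observation,
    SurrogateConfig,
    fit_surrogate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "RecoveryCurve",
    "ReplicateSummary",
    "initialize_campaign",
    "run_campaign",
    "benchmark_strategies",
    "fold_improvement",
    "summarize_replicates",
    "strategy_mfbo",
    "strategy_bo_high",
    "strategy_random",
    "strategy_funnel",
    "strategy_transfer",
]

STRATEGIES = ("mfbo", "bo_high", "funnel", "transfer", "random")

#: docking / single-point / dose-response relative costs
DEFAULT_COSTS = (0.01, 0.2, 1.0)


@dataclass(frozen=True)
class CampaignConfig:
    """Benchmark campaign settings.

    The per-iteration budget is ``budget_frac * pool size * highest-fidelity
    cost`` — by default the equivalent of testing 2% of the library at the
    highest fidelity each iteration. Initialization measures
    ``round(init_frac * N)`` molecules (sampled outside the top-N% labels)
    at every fidelity and is not charged to the iteration budget.
    """

    strategy: str = "mfbo"
    n_iterations: int = 5
    init_frac: float = 0.05
    top_percent: float = 2.0
    budget_frac: float = 0.02
    seed: int = 0
    costs: tuple[float, ...] = DEFAULT_COSTS
    count_medium_as_found: bool = False
    funnel_allocation: tuple[float, float, float] = (0.2, 0.4, 0.4)
    mc_config: MCConfig = MCConfig()
    # desk-scale surrogate refit settings; the loop refits once per iteration
    surrogate_config: SurrogateConfig = SurrogateConfig(
        n_restarts=3, max_iter=60, max_fit_points=224
    )

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if not 0 < self.init_frac <= 1 or not 0 < self.budget_frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class RecoveryCurve:
    """Per-iteration cumulative top-N% rediscovery for one strategy/seed."""

    strategy: str
    seed: int
    values: list[float]  # nondecreasing, in [0, 1]
    spend: list[dict[int, float]]  # per-iteration cost charged per fidelity

    def __post_init__(self):
        vals = np.asarray(self.values)
        if len(vals) and (np.any(vals < 0) or np.any(vals > 1)):
            raise ValueError("recovery values must lie in [0, 1]")
        if np.any(np.diff(vals) < -1e-12):
            raise ValueError("recovery curve must be nondecreasing")


@dataclass
class ReplicateSummary:
    """Mean and sample SD of recovery per iteration over replicate seeds."""

    mean: np.ndarray
    sd: np.ndarray
    seeds: list[int]


@dataclass
class CampaignState:
    dataset: LibraryDataset
    oracle: AssayOracle
    config: CampaignConfig
    schedule: FidelitySchedule
    top_ids: set[str]
    observations: list[Observation] = field(default_factory=list)
    observed: set[tuple[str, int]] = field(default_factory=set)
    iteration: int = 0

    def canonical(self, fidelity: int, raw_value: float) -> float:
        return -raw_value if fidelity == 0 else raw_value

    def measure(self, molecule_id: str, fidelity: int) -> None:
        raw = self.oracle.query(molecule_id, fidelity)
        self.observations.append(
            Observation(molecule_id, fidelity, self.canonical(fidelity, raw))
        )
        self.observed.add((molecule_id, fidelity))

    def recovery(self) -> float:
        fids = (1, 2) if self.config.count_medium_as_found else (2,)
        found = {
            mid for mid in self.top_ids if any((mid, f) in self.observed for f in fids)
        }
        return len(found) / len(self.top_ids)


# ---------------------------------------------------------------------------
# initialization and loop
# ---------------------------------------------------------------------------


def initialize_campaign(
    dataset: LibraryDataset, config: CampaignConfig, oracle: AssayOracle
) -> CampaignState:
    """Measure a random non-top fraction of the library at every fidelity."""
    n = len(dataset.molecules)
    budget = config.budget_frac * n * config.costs[-1]
    schedule = FidelitySchedule(
        levels=tuple(zip(("low", "medium", "high"), config.costs)), budget=budget
    )
    top_ids = top_fraction_labels(dataset, config.top_percent)
    n_init = int(round(config.init_frac * n))
    non_top = [mid for mid in dataset.ids if mid not in top_ids]
    if n_init > len(non_top):
        raise ValueError("initialization sample larger than the non-top pool")
    if n_init == 0:
        logger.warning("init_frac rounds to zero molecules; starting cold")
    rng = substream(config.seed, "init")
    picked = rng.choice(len(non_top), size=n_init, replace=False)
    state = CampaignState(
        dataset=dataset, oracle=oracle, config=config, schedule=schedule, top_ids=top_ids
    )
    for i in sorted(picked):
        for fid in range(len(config.costs)):
            state.measure(non_top[i], fid)
    return state


def run_campaign(
    dataset: LibraryDataset, config: CampaignConfig, oracle: AssayOracle
) -> RecoveryCurve:
    """Run the full iterative loop and return the recovery curve."""
    state = initialize_campaign(dataset, config, oracle)
    values: list[float] = []
    spend: list[dict[int, float]] = []
    for it in range(1, config.n_iterations + 1):
        state.iteration = it
        plan = _propose(state)
        if plan.total_cost > state.schedule.budget + 1e-9:
            raise RuntimeError("strategy exceeded the iteration budget")
        for mid, fid in plan.pairs:
            if (mid, fid) in state.observed:
                raise RuntimeError("strategy repeated an observed pair")
            state.measure(mid, fid)
        it_spend: dict[int, float] = {}
        for _, fid in plan.pairs:
            it_spend[fid] = it_spend.get(fid, 0.0) + config.costs[fid]
        spend.append(it_spend)
        values.append(state.recovery())
    return RecoveryCurve(strategy=config.strategy, seed=config.seed, values=values, spend=spend)


def _propose(state: CampaignState) -> BatchPlan:
    strategy = state.config.strategy
    if strategy == "mfbo":
        return strategy_mfbo(state)
    if strategy == "bo_high":
        return strategy_bo_high(state)
    if strategy == "random":
        return strategy_random(state)
    if strategy == "funnel":
        return strategy_funnel(state)
    return strategy_transfer(state)


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------


def strategy_mfbo(state: CampaignState) -> BatchPlan:
    cfg = state.config
    fps = state.dataset.fingerprint_map()
    surrogate = fit_surrogate(
        state.observations,
        fps,
        n_levels=len(cfg.costs),
        config=cfg.surrogate_config,
        seed=derive_seed(cfg.seed, "fit", state.iteration),
    )
    pool = PairPool.build(state.dataset.ids, fps, len(cfg.costs), observed=state.observed)
    return select_batch(
        surrogate,
        pool,
        state.schedule,
        mc_config=cfg.mc_config,
        seed=derive_seed(cfg.seed, "batch", state.iteration),
    )


def strategy_bo_high(state: CampaignState) -> BatchPlan:
    """Single-fidelity BO: GP on highest-fidelity data, EI, spend at cost 1.0."""
    cfg = state.config
    highest = len(cfg.costs) - 1
    fps = state.dataset.fingerprint_map()
    high_obs = [
        Observation(o.molecule_id, 0, o.value)
        for o in state.observations
        if o.fidelity == highest
    ]
    if not high_obs:
        raise ValueError("bo_high requires at least one highest-fidelity observation")
    surrogate = fit_surrogate(
        high_obs, fps, n_levels=1,
        config=cfg.surrogate_config,
        seed=derive_seed(cfg.seed, "fit", state.iteration),
    )
    single = FidelitySchedule(levels=(("high", 1.0),), budget=state.schedule.budget)
    observed_single = {
        (mid, 0) for mid in state.dataset.ids if (mid, highest) in state.observed
    }
    pool = PairPool.build(state.dataset.ids, fps, 1, observed=observed_single)
    plan = select_batch(
        surrogate, pool, single,
        mc_config=cfg.mc_config,
        seed=derive_seed(cfg.seed, "batch", state.iteration),
    )
    pairs = [(mid, highest) for mid, _ in plan.pairs]
    return BatchPlan(
        pairs=pairs, total_cost=plan.total_cost,
        per_fidelity_counts={highest: len(pairs)}, trace=plan.trace, seed=plan.seed,
    )


def strategy_random(state: CampaignState) -> BatchPlan:
    """Uniform unmeasured highest-fidelity picks until the budget is spent."""
    cfg = state.config
    highest = len(cfg.costs) - 1
    cost = cfg.costs[highest]
    n_picks = int(math.floor(state.schedule.budget / cost + 1e-9))
    unobserved = [m for m in state.dataset.ids if (m, highest) not in state.observed]
    rng = substream(cfg.seed, "random", state.iteration)
    take = min(n_picks, len(unobserved))
    picked = rng.choice(len(unobserved), size=take, replace=False)
    pairs = [(unobserved[i], highest) for i in sorted(picked)]
    return BatchPlan(
        pairs=pairs, total_cost=take * cost,
        per_fidelity_counts={highest: take}, trace=[0.0] * take, seed=cfg.seed,
    )


def _observed_value(state: CampaignState, mid: str, fid: int) -> float | None:
    for o in reversed(state.observations):
        if o.molecule_id == mid and o.fidelity == fid:
            return o.value
    return None


def _funnel_stages(state: CampaignState) -> tuple[list[str], list[str], list[str]]:
    """Stage candidate lists for funnel-style strategies (low, medium, high)."""
    cfg = state.config
    budget = state.schedule.budget
    alloc = cfg.funnel_allocation
    n_stage = [
        int(math.floor(alloc[f] * budget / cfg.costs[f] + 1e-9)) for f in range(3)
    ]
    # low stage: unmeasured molecules, randomly ranked each iteration
    unmeasured_low = [m for m in state.dataset.ids if (m, 0) not in state.observed]
    rng = substream(cfg.seed, "funnel", state.iteration)
    order = rng.permutation(len(unmeasured_low))
    low_picks = [unmeasured_low[i] for i in order[: n_stage[0]]]
    # medium stage: best observed low scorers not yet screened at medium
    cand_med = [
        (mid, _observed_value(state, mid, 0))
        for mid in state.dataset.ids
        if (mid, 0) in state.observed and (mid, 1) not in state.observed
    ]
    cand_med.sort(key=lambda t: (-t[1], t[0]))
    med_picks = [mid for mid, _ in cand_med[: n_stage[1]]]
    # high stage candidates: screened at medium, not yet at high
    cand_high = [
        mid
        for mid in state.dataset.ids
        if (mid, 1) in state.observed and (mid, 2) not in state.observed
    ]
    return low_picks, med_picks, cand_high


def _finish_funnel_plan(
    state: CampaignState, low: list[str], med: list[str], high: list[str]
) -> BatchPlan:
    cfg = state.config
    pairs = [(m, 0) for m in low] + [(m, 1) for m in med] + [(m, 2) for m in high]
    counts = {0: len(low), 1: len(med), 2: len(high)}
    total = sum(counts[f] * cfg.costs[f] for f in counts)
    return BatchPlan(
        pairs=pairs, total_cost=total, per_fidelity_counts=counts,
        trace=[0.0] * len(pairs), seed=cfg.seed,
    )


def strategy_funnel(state: CampaignState) -> BatchPlan:
    """Fixed-allocation experimental funnel (default 20/40/40% of budget)."""
    cfg = state.config
    low, med, cand_high = _funnel_stages(state)
    n_high = int(math.floor(cfg.funnel_allocation[2] * state.schedule.budget / cfg.costs[2] + 1e-9))
    ranked = [
        (mid, _observed_value(state, mid, 1)) for mid in cand_high
    ]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    high = [mid for mid, _ in ranked[:n_high]]
    return _finish_funnel_plan(state, low, med, high)


def strategy_transfer(state: CampaignState) -> BatchPlan:
    """Funnel flow whose high-fidelity stage ranks by a transfer model.

    The model regresses observed highest-fidelity values on the molecule's
    fingerprint with its observed lower-fidelity measurements appended as
    extra features (a deliberately simple feature-augmentation baseline).
    """
    cfg = state.config
    low, med, cand_high = _funnel_stages(state)
    n_high = int(math.floor(cfg.funnel_allocation[2] * state.schedule.budget / cfg.costs[2] + 1e-9))
    fps = state.dataset.fingerprint_map()

    def features(mid: str, low_mean: float) -> np.ndarray:
        lv = _observed_value(state, mid, 0)
        mv = _observed_value(state, mid, 1)
        return np.concatenate(
            [fps[mid].astype(float), [lv if lv is not None else low_mean, mv if mv is not None else 0.0]]
        )

    train_ids = [
        mid for mid in state.dataset.ids if (mid, 2) in state.observed
    ]
    high = []
    if cand_high:
        if train_ids:
            lows = [v for m in train_ids if (v := _observed_value(state, m, 0)) is not None]
            low_mean = float(np.mean(lows)) if lows else 0.0
            X = np.vstack([features(m, low_mean) for m in train_ids])
            y = np.array([_observed_value(state, m, 2) for m in train_ids])
            model = RandomForestRegressor(
                n_estimators=100, random_state=derive_seed(cfg.seed, "transfer", state.iteration)
            )
            model.fit(X, y)
            Xc = np.vstack([features(m, low_mean) for m in cand_high])
            preds = model.predict(Xc)
            ranked = sorted(zip(cand_high, preds), key=lambda t: (-t[1], t[0]))
        else:
            ranked = [(m, _observed_value(state, m, 1)) for m in cand_high]
            ranked.sort(key=lambda t: (-t[1], t[0]))
        high = [m for m, _ in ranked[:n_high]]
    return _finish_funnel_plan(state, low, med, high)


# ---------------------------------------------------------------------------
# metrics over curves
# ---------------------------------------------------------------------------


def fold_improvement(
    curve_a: RecoveryCurve, curve_b: RecoveryCurve, at_iteration: int = 5
) -> float:
    """Recovery ratio a/b after ``at_iteration`` iterations (1-based).

    Returns ``nan`` (the undefined flag) when the denominator is zero.
    """
    if len(curve_a.values) < at_iteration or len(curve_b.values) < at_iteration:
        raise ValueError("curves shorter than the requested iteration")
    a = curve_a.values[at_iteration - 1]
    b = curve_b.values[at_iteration - 1]
    if b == 0:
        return float("nan")
    return a / b


def benchmark_strategies(
    dataset: LibraryDataset,
    strategies: tuple[str, ...] = ("mfbo", "bo_high", "random"),
    n_seeds: int = 6,
    base_seed: int = 1,
    n_iterations: int = 5,
    top_percent: float = 2.0,
) -> dict[str, list[RecoveryCurve]]:
    """Replicate retrospective campaigns for several strategies on one dataset.

    Each replicate gets its own derived campaign seed; the oracle noise
    stream is shared across strategies so they face identical measurements.
    """
    out: dict[str, list[RecoveryCurve]] = {}
    for strat in strategies:
        curves = []
        for rep in range(n_seeds):
            cfg = CampaignConfig(
                strategy=strat,
                n_iterations=n_iterations,
                top_percent=top_percent,
                seed=derive_seed(base_seed, "replicate", strat, rep),
            )
            oracle = make_oracle(dataset, seed=derive_seed(base_seed, "oracle"))
            curves.append(run_campaign(dataset, cfg, oracle))
        out[strat] = curves
    return out


def summarize_replicates(curves: list[RecoveryCurve]) -> ReplicateSummary:
    """Per-iteration sample mean and SD (ddof=1) over replicate curves."""
    if len(curves) < 2:
        raise ValueError("need at least 2 replicate curves")
    lengths = {len(c.values) for c in curves}
    if len(lengths) != 1:
        raise ValueError("replicate curves have ragged lengths")
    arr = np.array([c.values for c in curves])
    return ReplicateSummary(
        mean=arr.mean(axis=0), sd=arr.std(axis=0, ddof=1), seeds=[c.seed for c in curves]
    )
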