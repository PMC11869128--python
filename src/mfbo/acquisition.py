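"""Cost-aware expected improvement and Monte-Carlo fantasy batch selection.

A batch of (molecule, fidelity) experiments is assembled sequentially under a
dimensionless budget. At each step the pair maximizing expected improvement
(EI) on the TVR-scaled axis is chosen. The EI of a candidate pair targets
the improvement of that molecule's outcome at the HIGHEST fidelity: its
mean is the molecule's scaled highest-fidelity posterior mean, while its
spread is the candidate pair's own predictive variance divided by the
pair's relative cost. Cheap assays therefore carry inflated variance and
are drawn more often until their information is exhausted, after which
spend migrates toward dose-response confirmation of the leaders.

After each selection, fantasy outcomes are drawn from the surrogate
posterior at the chosen pair and conditioned into child surrogates (exact
rank-1 updates of the joint pool posterior; hyperparameters are not refit
unless requested), giving a beam of candidate batch continuations. Branches
with poor cumulative EI are pruned to ``keep_branches``. The plan of the
best surviving branch is returned once no branch can afford another
experiment.

Scaling statistics (per-fidelity pool min/max of posterior means) and the
incumbent are frozen at the start of batch selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .surrogate import (
    FidelitySchedule,
    Observation,
    SurrogateState,
    pool_posterior,
    predict_batch,
    scale_prediction_arrays,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BatchPlan",
    "MCConfig",
    "PairPool",
    "expected_improvement",
    "pool_scaling_stats",
    "incumbent_best",
    "score_pair",
    "select_batch",
    "budget_breakdown",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCConfig:
    """Fantasy-search settings: samples per selection and beam width."""

    n_fantasies: int = 3
    keep_branches: int = 5
    refit_per_fantasy: bool = False  # refit hyperparameters inside each fantasy branch


@dataclass
class BatchPlan:
    """Selected (molecule id, fidelity) pairs for one iteration, with accounting."""

    pairs: list[tuple[str, int]]
    total_cost: float
    per_fidelity_counts: dict[int, int]
    trace: list[float]  # EI score of each pair at its selection time
    seed: int

    def to_json(self, schedule: FidelitySchedule) -> str:
        costs = schedule.costs
        return json.dumps(
            {
                "seed": self.seed,
                "pairs": [
                    {"id": mid, "fidelity": fid, "score": s, "cost": float(costs[fid])}
                    for (mid, fid), s in zip(self.pairs, self.trace)
                ],
                "total_cost": self.total_cost,
                "breakdown": budget_breakdown(self, schedule),
            },
            indent=2,
        )

    def save(self, path: str | Path, schedule: FidelitySchedule) -> None:
        Path(path).write_text(self.to_json(schedule))


@dataclass
class PairPool:
    """The candidate pool: every (molecule, fidelity) pair of the library.

    Already-observed pairs stay in the pool — the per-fidelity scaling
    statistics and the joint posterior are computed over the whole library,
    so the incumbent lands on the same [0, 1] axis — but are marked
    unselectable. ``highest_of_pair`` maps each pair to the index of the
    same molecule's highest-fidelity pair (the mean the acquisition aims to
    improve).
    """

    mol_ids: list[str]
    mol_fps: np.ndarray  # (n_mol, n_bits)
    pair_mol: np.ndarray  # (P,) index into mol_ids
    pair_fid: np.ndarray  # (P,)
    selectable: np.ndarray  # (P,) bool
    highest_of_pair: np.ndarray  # (P,) pair index of the molecule's top fidelity

    @classmethod
    def build(
        cls,
        mol_ids: Sequence[str],
        fingerprints: Mapping[str, np.ndarray],
        n_levels: int,
        observed: set[tuple[str, int]] = frozenset(),
        fidelities: Sequence[int] | None = None,
    ) -> "PairPool":
        mol_ids = list(mol_ids)
        if mol_ids:
            fps = np.vstack([fingerprints[i] for i in mol_ids])
        else:
            fps = np.zeros((0, 0), dtype=np.uint8)
        levels = list(fidelities) if fidelities is not None else list(range(n_levels))
        pm, pf, sel = [], [], []
        index: dict[tuple[int, int], int] = {}
        for fid in levels:
            for j, mid in enumerate(mol_ids):
                index[(j, fid)] = len(pm)
                pm.append(j)
                pf.append(fid)
                sel.append((mid, fid) not in observed)
        top = max(levels)
        hi = np.array([index.get((j, top), i) for i, (j, _) in enumerate(zip(pm, pf))])
        return cls(
            mol_ids=mol_ids, mol_fps=fps,
            pair_mol=np.array(pm, dtype=int), pair_fid=np.array(pf, dtype=int),
            selectable=np.array(sel, dtype=bool), highest_of_pair=hi,
        )

    def __len__(self) -> int:
        return len(self.pair_mol)

    def pair_id(self, i: int) -> tuple[str, int]:
        return self.mol_ids[self.pair_mol[i]], int(self.pair_fid[i])


# ---------------------------------------------------------------------------
# expected improvement
# ---------------------------------------------------------------------------


def expected_improvement(
    mean: np.ndarray | float, sd: np.ndarray | float, incumbent: float
) -> np.ndarray | float:
    """Closed-form EI: (mu - y*) Phi(z) + sigma phi(z), z = (mu - y*) / sigma.

    For sigma = 0 this degenerates to max(mu - y*, 0). Vectorized; negative
    sd raises.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be nonnegative")
    delta = mean - incumbent
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, delta / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(sd > 0, delta * norm.cdf(z) + sd * norm.pdf(z), np.maximum(delta, 0.0))
    ei = np.maximum(ei, 0.0)
    return float(ei) if ei.ndim == 0 else ei


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def pool_scaling_stats(
    state: SurrogateState, pool: PairPool, n_levels: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-fidelity min/max of pool posterior means, plus the pool mean/cov.

    Returns ``(pool_min, pool_max, mean, cov)``; fidelities absent from the
    pool get a degenerate (0, 0) range.
    """
    mean, cov = pool_posterior(state, pool.mol_fps, pool.pair_mol, pool.pair_fid)
    pool_min = np.zeros(n_levels)
    pool_max = np.zeros(n_levels)
    for lv in range(n_levels):
        sel = pool.pair_fid == lv
        if sel.any():
            pool_min[lv] = mean[sel].min()
            pool_max[lv] = mean[sel].max()
    return pool_min, pool_max, mean, cov


def incumbent_best(
    state: SurrogateState, pool_min: np.ndarray, pool_max: np.ndarray, highest: int
) -> float:
    """Best observed highest-fidelity value on the scaled [0, 1] axis.

    Before any highest-fidelity observation exists the incumbent defaults
    to 0 (the most optimistic feasible value), logged.
    """
    vals = [o.value for o in state.observations if o.fidelity == highest]
    if not vals:
        logger.info("no highest-fidelity observation yet; incumbent defaults to 0")
        return 0.0
    rng_h = pool_max[highest] - pool_min[highest]
    if rng_h <= 0:
        return 0.5
    return float(np.clip((max(vals) - pool_min[highest]) / rng_h, 0.0, 1.0))


def score_pair(
    state: SurrogateState,
    pool: PairPool,
    molecule_id: str,
    fidelity: int,
    schedule: FidelitySchedule,
) -> float:
    """Cost-aware EI score of one (molecule, fidelity) pair against the pool.

    The EI mean is the molecule's scaled posterior mean at the HIGHEST
    fidelity (the quantity a measurement is meant to improve); the EI spread
    is the candidate pair's own cost-inflated scaled standard deviation.
    """
    n_levels = schedule.n_levels
    pool_min, pool_max, mean, cov = pool_scaling_stats(state, pool, n_levels)
    y_star = incumbent_best(state, pool_min, pool_max, schedule.highest)
    j = pool.mol_ids.index(molecule_id)
    fp = pool.mol_fps[j][None, :]
    m_hi, _ = predict_batch(state, fp, np.array([schedule.highest]))
    _, v = predict_batch(state, fp, np.array([fidelity]))
    sm, _ = scale_prediction_arrays(
        m_hi, np.zeros(1), np.array([schedule.highest]), pool_min, pool_max, schedule.costs
    )
    _, sv = scale_prediction_arrays(
        np.zeros(1), v, np.array([fidelity]), pool_min, pool_max, schedule.costs
    )
    return float(expected_improvement(sm[0], np.sqrt(sv[0]), y_star))


# ---------------------------------------------------------------------------
# batch selection
# ---------------------------------------------------------------------------


@dataclass
class _Branch:
    mean: np.ndarray
    cov: np.ndarray  # shared between siblings; copy-on-write at update time
    chosen: list[int] = field(default_factory=list)
    chosen_mask: np.ndarray = None
    spent: float = 0.0
    cum_ei: float = 0.0
    trace: list[float] = field(default_factory=list)
    finished: bool = False
    obs: list[Observation] = field(default_factory=list)  # fantasy obs (refit mode)


def _argmax_with_tiebreak(
    ei: np.ndarray, affordable: np.ndarray, pool: PairPool, costs: np.ndarray
) -> int | None:
    """Argmax EI among affordable pairs; ties go to lower cost, then id, then fidelity."""
    if not affordable.any():
        return None
    masked = np.where(affordable, ei, -np.inf)
    best = masked.max()
    cand = np.flatnonzero(masked == best)
    if len(cand) == 1:
        return int(cand[0])
    return int(min(
        cand,
        key=lambda i: (costs[pool.pair_fid[i]], pool.mol_ids[pool.pair_mol[i]], pool.pair_fid[i]),
    ))


def select_batch(
    state: SurrogateState,
    pool: PairPool,
    schedule: FidelitySchedule,
    mc_config: MCConfig = MCConfig(),
    seed: int = 0,
) -> BatchPlan:
    """Assemble a batch of experiments by beam-style fantasy search.

    Deterministic given ``seed``. Returns an empty (valid) plan when the
    budget cannot afford even the cheapest experiment; raises on an empty
    pool.
    """
    if len(pool) == 0:
        raise ValueError("select_batch requires a nonempty pool")
    n_levels = schedule.n_levels
    costs = schedule.costs
    budget = schedule.budget
    pool_min, pool_max, mean0, cov0 = pool_scaling_stats(state, pool, n_levels)
    y_star = incumbent_best(state, pool_min, pool_max, schedule.highest)
    noise_assay = state.noises * state.y_sd**2  # per-fidelity noise in assay units
    rng = np.random.default_rng(seed)

    root = _Branch(mean=mean0, cov=cov0, chosen_mask=~pool.selectable.copy())
    branches = [root]
    while any(not b.finished for b in branches):
        children: list[_Branch] = []
        for branch in branches:
            if branch.finished:
                children.append(branch)
                continue
            affordable = (costs[pool.pair_fid] <= budget - branch.spent + 1e-12) & (
                ~branch.chosen_mask
            )
            var = branch.cov[np.arange(len(pool)), np.arange(len(pool))]
            sm, sv = scale_prediction_arrays(
                branch.mean, np.maximum(var, 0.0), pool.pair_fid, pool_min, pool_max, costs
            )
            # EI of improving the molecule's highest-fidelity outcome, with the
            # candidate pair's cost-inflated spread
            ei = expected_improvement(sm[pool.highest_of_pair], np.sqrt(sv), y_star)
            i_sel = _argmax_with_tiebreak(ei, affordable, pool, costs)
            if i_sel is None:
                branch.finished = True
                children.append(branch)
                continue
            fid_i = int(pool.pair_fid[i_sel])
            mu_i = branch.mean[i_sel]
            var_i = max(float(var[i_sel]), 0.0)
            draws = rng.normal(mu_i, np.sqrt(var_i), mc_config.n_fantasies)
            chosen = branch.chosen + [i_sel]
            mask = branch.chosen_mask.copy()
            mask[i_sel] = True
            spent = branch.spent + costs[fid_i]
            cum_ei = branch.cum_ei + float(ei[i_sel])
            trace = branch.trace + [float(ei[i_sel])]
            if mc_config.refit_per_fantasy:
                from .surrogate import fit_surrogate  # local import to avoid cycle at module load

                for y_f in draws:
                    obs = branch.obs + [
                        Observation(pool.mol_ids[pool.pair_mol[i_sel]], fid_i, float(y_f))
                    ]
                    fps_map = {mid: pool.mol_fps[j] for j, mid in enumerate(pool.mol_ids)}
                    fps_map.update({o.molecule_id: fp for o, fp in zip(
                        state.observations, state.X)})
                    child_state = fit_surrogate(
                        list(state.observations) + obs, fps_map, n_levels, seed=seed
                    )
                    c_mean, c_cov = pool_posterior(
                        child_state, pool.mol_fps, pool.pair_mol, pool.pair_fid
                    )
                    children.append(_Branch(
                        mean=c_mean, cov=c_cov, chosen=chosen, chosen_mask=mask,
                        spent=spent, cum_ei=cum_ei, trace=trace, obs=obs,
                    ))
            else:
                denom = var_i + noise_assay[fid_i]
                c = branch.cov[:, i_sel].copy()
                new_cov = branch.cov - np.outer(c, c) / denom
                for y_f in draws:
                    new_mean = branch.mean + c * (y_f - mu_i) / denom
                    children.append(_Branch(
                        mean=new_mean, cov=new_cov, chosen=chosen, chosen_mask=mask,
                        spent=spent, cum_ei=cum_ei, trace=trace,
                    ))
        # prune to the beam width; stable sort keeps insertion order on ties
        children.sort(key=lambda b: (-b.cum_ei, b.spent))
        branches = children[: mc_config.keep_branches]

    best = min(
        branches,
        key=lambda b: (-b.cum_ei, b.spent, [pool.pair_id(i) for i in b.chosen]),
    )
    pairs = [pool.pair_id(i) for i in best.chosen]
    counts: dict[int, int] = {}
    for _, fid in pairs:
        counts[fid] = counts.get(fid, 0) + 1
    return BatchPlan(
        pairs=pairs,
        total_cost=float(best.spent),
        per_fidelity_counts=counts,
        trace=best.trace,
        seed=seed,
    )


def budget_breakdown(plan: BatchPlan, schedule: FidelitySchedule) -> dict:
    """Per-fidelity (count, cost, percent of budget) plus unspent budget.

    Percentages are rounded to the nearest integer, as in printed campaign
    summaries (e.g. 336 single-point assays at cost 0.2 against a budget of
    100.0 -> 67%).
    """
    costs = schedule.costs
    out: dict = {"per_fidelity": {}, "total_cost": plan.total_cost}
    for fid, name in enumerate(schedule.names):
        count = plan.per_fidelity_counts.get(fid, 0)
        cost = count * float(costs[fid])
        out["per_fidelity"][name] = {
            "count": count,
            "cost": cost,
            "percent_of_budget": int(round(100.0 * cost / schedule.budget)),
        }
    out["unspent"] = float(schedule.budget - plan.total_cost)
    return out
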