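"""Reaction-template genetic algorithm with non-dominated sorting.

Generates synthesizable candidate molecules by iteratively applying
reaction templates (reaction-SMARTS) to building blocks, in the spirit of
template-based evolutionary generators. Each candidate carries its route —
the ordered list of (template, partner building block) steps from a root
building block — so every structure is backed by a synthesis plan and can
be replayed, undone (route truncation), or crossed over with another
candidate at a shared template step.

Selection is multi-objective: candidates are scored by a configurable
suite of objectives, ranked by non-dominated sorting (NDS), and the next
generation keeps every rank-1 candidate (elitism) while the remainder is
drawn by stochastic universal sampling with fitness 1/rank and then
mutated. The choice between applying a template, removing one, or crossing
over is guided by molecular weight so products stay in a drug-like 100-500
Da band. Candidates matching the substructure filter catalog (PAINS,
hydroxamates, reactive groups) are rejected.

Expensive scorers (docking-like) are amortized: candidates are clustered
by fingerprint k-medoids, only the medoid of each cluster is scored, and
the medoid's score is assigned to every cluster member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .chemio import (
    MoleculeRecord,
    SubstructureFilterReport,
    candidate_diversity,
    cluster_kmedoids,
    default_filter_patterns,
    filter_substructures,
    fingerprint,
)
from .seeding import derive_seed, substream

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionTemplate",
    "Candidate",
    "Objective",
    "GenerationConfig",
    "load_templates",
    "default_templates",
    "default_building_blocks",
    "non_dominated_sort",
    "stochastic_universal_sampling",
    "apply_template",
    "undo_last_step",
    "choose_operation",
    "crossover",
    "amortize_expensive_score",
    "evolve",
    "run_generations",
    "NoMatchError",
    "NoCommonTemplateError",
    "mock_scorers",
]


class NoMatchError(ValueError):
    """The molecule does not match the template's reactant pattern."""


class NoCommonTemplateError(ValueError):
    """Two candidates share no template step to cross over at."""


# ---------------------------------------------------------------------------
# templates and candidates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionTemplate:
    """A named reaction-SMARTS transformation (reactants >> product)."""

    name: str
    smarts: str
    arity: int  # 1 or 2
    reversible: bool = True

    def __post_init__(self):
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise ValueError(f"invalid reaction SMARTS for {self.name!r}")
        if rxn.GetNumReactantTemplates() != self.arity:
            raise ValueError(
                f"template {self.name!r}: arity {self.arity} but pattern has "
                f"{rxn.GetNumReactantTemplates()} reactants"
            )
        object.__setattr__(self, "_rxn", rxn)

    def matches(self, mol: Chem.Mol) -> bool:
        return mol.HasSubstructMatch(self._rxn.GetReactantTemplate(0))


@dataclass(frozen=True)
class Candidate:
    """A generated molecule plus the synthesis route that produced it."""

    smiles: str
    root_block: str  # SMILES of the starting building block
    route: tuple[tuple[str, str | None], ...] = ()  # (template name, partner SMILES)
    scores: tuple[float, ...] = ()
    nds_rank: int = 0

    @property
    def mw(self) -> float:
        return Descriptors.MolWt(Chem.MolFromSmiles(self.smiles))

    def record(self, cid: str) -> MoleculeRecord:
        return MoleculeRecord.from_smiles(cid, self.smiles)


@dataclass(frozen=True)
class Objective:
    """One optimization objective: scorer maps a SMILES list to values."""

    name: str
    direction: str  # "maximize" | "minimize"
    scorer: Callable[[list[str]], np.ndarray]

    def __post_init__(self):
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")


@dataclass(frozen=True)
class GenerationConfig:
    population_size: int = 50
    n_generations: int = 5
    n_independent_runs: int = 1
    mw_band: tuple[float, float] = (100.0, 500.0)
    p_crossover: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.mw_band[0] >= self.mw_band[1]:
            raise ValueError("mw_band must be (low, high) with low < high")


# Robot-amenable transformations: couplings and condensations that tolerate
# air and automated liquid handling.
_DEFAULT_TEMPLATES: tuple[tuple[str, str, int], ...] = (
    ("amide_coupling", "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]", 2),
    ("sulfonamide_formation", "[S:1](=[O:2])(=[O:3])[Cl].[NX3;H2,H1:4]>>[S:1](=[O:2])(=[O:3])[N:4]", 2),
    ("reductive_amination", "[CX3;H1:1]=[O:2].[NX3;H2,H1:3]>>[C:1][N:3]", 2),
    ("n_alkylation", "[CX4:1][Br,I].[NX3;H2,H1:2]>>[C:1][N:2]", 2),
    ("ester_formation", "[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]", 2),
    ("urea_formation", "[NX2:1]=[CX2:2]=[OX1:3].[NX3;H2,H1:4]>>[N:1][C:2](=[O:3])[N:4]", 2),
    ("snar_amination", "[c:1][F].[NX3;H2,H1:2]>>[c:1][N:2]", 2),
    ("imine_condensation", "[CX3;H1:1]=[O:2].[NX3;H2:3]>>[C:1]=[N:3]", 2),
    ("boc_removal", "[NX3:1]C(=O)OC(C)(C)C>>[N:1]", 1),
    ("suzuki_biaryl", "[c:1][Br].[c:2]B(O)O>>[c:1]-[c:2]", 2),
)

_DEFAULT_BLOCKS = (
    "CC(=O)O", "CCC(=O)O", "c1ccccc1C(=O)O", "c1ccncc1C(=O)O", "OC(=O)C1CCNC1",
    "CN", "CCN", "NCCO", "c1ccccc1N", "c1ccc(CN)cc1", "C1CCNCC1", "NCCc1ccccc1",
    "CC(C)N", "c1ccc(N)nc1", "CS(=O)(=O)Cl", "c1ccccc1S(=O)(=O)Cl",
    "CC=O", "c1ccccc1C=O", "CCBr", "c1ccc(CBr)cc1", "CCO", "OCC(C)C",
    "O=C=Nc1ccccc1", "CCN=C=O", "Fc1ccc(C=O)cc1", "Fc1ccccn1",
    "Brc1ccccc1", "OB(O)c1ccccc1", "OB(O)c1ccncc1", "CC(C)(C)OC(=O)NC1CCNCC1",
)


def default_templates() -> list[ReactionTemplate]:
    return [ReactionTemplate(n, s, a) for n, s, a in _DEFAULT_TEMPLATES]


def default_building_blocks() -> list[str]:
    return list(_DEFAULT_BLOCKS)


def load_templates(path: str | Path) -> list[ReactionTemplate]:
    """Read ``name<TAB>reaction-SMARTS`` lines; arity inferred from the pattern."""
    templates = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        arity = smarts.split(">>")[0].count(".") + 1
        templates.append(ReactionTemplate(name, smarts, arity))
    return templates


# ---------------------------------------------------------------------------
# NDS and SUS
# ---------------------------------------------------------------------------


def non_dominated_sort(scores: np.ndarray, directions: Sequence[str]) -> np.ndarray:
    """Pareto ranks (1 = nondominated) by repeated front peeling.

    ``scores`` is (n, k); ``directions`` gives per-objective orientation.
    Dominance: no worse in every objective and strictly better in at least
    one, after orienting all objectives to maximize.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    if scores.ndim != 2 or scores.shape[1] != len(directions):
        raise ValueError("scores must be (n, k) matching directions")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    sign = np.array([1.0 if d == "maximize" else -1.0 for d in directions])
    S = scores * sign
    n = len(S)
    ranks = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    rank = 0
    while len(remaining):
        rank += 1
        sub = S[remaining]
        # i dominated iff some j: all >= and any >
        ge = (sub[:, None, :] >= sub[None, :, :]).all(axis=2)
        gt = (sub[:, None, :] > sub[None, :, :]).any(axis=2)
        dominated = (ge & gt).any(axis=0)
        front = remaining[~dominated]
        ranks[front] = rank
        remaining = remaining[dominated]
    return ranks


def stochastic_universal_sampling(
    fitness: Sequence[float], n_draws: int, seed: int = 0
) -> list[int]:
    """Low-variance fitness-proportional selection with one random comb offset.

    Guarantees each index is drawn between floor and ceil of its expected
    count ``n_draws * f_i / sum(f)``.
    """
    f = np.asarray(fitness, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitness must be nonnegative")
    total = f.sum()
    if total <= 0:
        raise ValueError("total fitness must be positive")
    rng = np.random.default_rng(seed)
    step = total / n_draws
    start = rng.uniform(0, step)
    pointers = start + step * np.arange(n_draws)
    cum = np.cumsum(f)
    idx = np.searchsorted(cum, pointers, side="right")
    return [int(i) for i in idx]


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------


def _sanitized(mol: Chem.Mol) -> str | None:
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def apply_template(
    template: ReactionTemplate, molecule: str, partner: str | None = None
) -> str:
    """Apply a reaction template to ``molecule`` (with ``partner`` iff arity 2).

    Multiple match sites resolve to the first product in canonical atom
    order (the toolkit's deterministic enumeration). Raises
    :class:`NoMatchError` when the molecule lacks the required group.
    """
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"invalid SMILES {molecule!r}")
    if (partner is None) != (template.arity == 1):
        raise ValueError(f"template {template.name!r} has arity {template.arity}")
    if not template.matches(mol):
        raise NoMatchError(f"{molecule!r} does not match template {template.name!r}")
    reactants = (mol,) if template.arity == 1 else (mol, Chem.MolFromSmiles(partner))
    if template.arity == 2 and reactants[1] is None:
        raise ValueError(f"invalid partner SMILES {partner!r}")
    products = template._rxn.RunReactants(reactants)
    for prod_set in products:
        smi = _sanitized(prod_set[0])
        if smi is not None:
            return smi
    raise NoMatchError(
        f"template {template.name!r} produced no sanitizable product from {molecule!r}"
    )


def replay_route(candidate: Candidate, templates: dict[str, ReactionTemplate]) -> str:
    """Rebuild a candidate's SMILES from its route; the replay must succeed."""
    smiles = Chem.MolToSmiles(Chem.MolFromSmiles(candidate.root_block))
    for tname, partner in candidate.route:
        smiles = apply_template(templates[tname], smiles, partner)
    return smiles


def extend_candidate(
    candidate: Candidate, template: ReactionTemplate, partner: str | None
) -> Candidate:
    product = apply_template(template, candidate.smiles, partner)
    return replace(
        candidate, smiles=product, route=candidate.route + ((template.name, partner),)
    )


def undo_last_step(
    candidate: Candidate, templates: dict[str, ReactionTemplate]
) -> Candidate:
    """Remove the last reversible route step and replay the shortened route."""
    if not candidate.route:
        raise ValueError("candidate has no route steps to undo")
    tname, _ = candidate.route[-1]
    if not templates[tname].reversible:
        raise ValueError(f"last step {tname!r} is not reversible")
    trimmed = replace(candidate, route=candidate.route[:-1])
    smiles = replay_route(trimmed, templates)
    return replace(trimmed, smiles=smiles)


def choose_operation(mw: float, seed: int = 0, p_crossover: float = 0.2,
                     mw_band: tuple[float, float] = (100.0, 500.0)) -> str:
    """Pick apply / remove / crossover with MW-proportional weights.

    The apply weight falls linearly to zero at the top of the band, the
    remove weight rises from zero at the bottom, keeping products inside
    100-500 Da; a fixed crossover share is reserved.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    lo, hi = mw_band
    span = hi - lo
    w_apply = float(np.clip((hi - mw) / span, 0.0, 1.0))
    w_remove = float(np.clip((mw - lo) / span, 0.0, 1.0))
    if w_apply + w_remove == 0:
        w_apply = 1.0
    rng = np.random.default_rng(seed)
    if rng.random() < p_crossover:
        return "crossover"
    p = w_apply / (w_apply + w_remove)
    return "apply" if rng.random() < p else "remove"


def crossover(
    c1: Candidate,
    c2: Candidate,
    templates: dict[str, ReactionTemplate],
    seed: int = 0,
) -> tuple[Candidate | None, Candidate | None]:
    """Swap route suffixes at a shared template step and replay both children.

    Children whose replay fails are returned as ``None``. Raises
    :class:`NoCommonTemplateError` when the routes share no template name.
    """
    names1 = [t for t, _ in c1.route]
    names2 = [t for t, _ in c2.route]
    shared = sorted(set(names1) & set(names2))
    if not shared:
        raise NoCommonTemplateError("candidates share no template step")
    rng = np.random.default_rng(seed)
    tname = shared[int(rng.integers(len(shared)))]
    i1 = names1.index(tname)
    i2 = names2.index(tname)
    # swap from the shared step onward, so its partner is exchanged too
    child1 = replace(c1, route=c1.route[:i1] + c2.route[i2:])
    child2 = replace(c2, route=c2.route[:i2] + c1.route[i1:])
    out = []
    for child in (child1, child2):
        try:
            smiles = replay_route(child, templates)
            out.append(replace(child, smiles=smiles))
        except (NoMatchError, ValueError):
            out.append(None)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# amortized scoring
# ---------------------------------------------------------------------------


def amortize_expensive_score(
    candidates: Sequence[Candidate],
    scorer: Callable[[str], float],
    k: int,
    seed: int = 0,
) -> np.ndarray:
    """Score only cluster medoids and broadcast each score to its cluster.

    ``scorer`` is invoked exactly ``k`` times (once per medoid). A scorer
    failure marks the whole cluster with NaN, logged.
    """
    if k > len(candidates):
        raise ValueError("k exceeds the number of candidates")
    fps = np.vstack([fingerprint(c.smiles) for c in candidates])
    labels, medoids = cluster_kmedoids(fps, k, seed=seed)
    medoid_scores = np.empty(k)
    for ci, mi in enumerate(medoids):
        try:
            medoid_scores[ci] = float(scorer(candidates[int(mi)].smiles))
        except Exception as exc:  # scorer failure -> sentinel for the cluster
            logger.warning("scorer failed on medoid %s: %s", candidates[int(mi)].smiles, exc)
            medoid_scores[ci] = float("nan")
    return medoid_scores[labels]


# ---------------------------------------------------------------------------
# evolution loop
# ---------------------------------------------------------------------------


def _score_population(cands: list[Candidate], objectives: Sequence[Objective]) -> np.ndarray:
    smiles = [c.smiles for c in cands]
    cols = [np.asarray(obj.scorer(smiles), dtype=float) for obj in objectives]
    return np.column_stack(cols)


def _passes_filters(smiles: str, patterns) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return all(not p.matches(mol) for p in patterns)


def _mutate(
    cand: Candidate,
    population: list[Candidate],
    blocks: list[str],
    templates: dict[str, ReactionTemplate],
    config: GenerationConfig,
    rng: np.random.Generator,
) -> Candidate | None:
    op = choose_operation(
        cand.mw, seed=int(rng.integers(2**31)), p_crossover=config.p_crossover,
        mw_band=config.mw_band,
    )
    if op == "remove" and cand.route:
        try:
            return undo_last_step(cand, templates)
        except (ValueError, NoMatchError):
            return None
    if op == "crossover":
        partners = [c for c in population if set(n for n, _ in c.route) & set(n for n, _ in cand.route)]
        if partners:
            mate = partners[int(rng.integers(len(partners)))]
            try:
                ch1, ch2 = crossover(cand, mate, templates, seed=int(rng.integers(2**31)))
            except NoCommonTemplateError:
                ch1 = ch2 = None
            for ch in (ch1, ch2):
                if ch is not None:
                    return ch
        # fall through to apply when crossover is impossible
    mol = Chem.MolFromSmiles(cand.smiles)
    compatible = [t for t in templates.values() if t.matches(mol)]
    if not compatible:
        return None
    template = compatible[int(rng.integers(len(compatible)))]
    partner = None
    if template.arity == 2:
        partner = blocks[int(rng.integers(len(blocks)))]
        try:
            return extend_candidate(cand, template, partner)
        except (NoMatchError, ValueError):
            return None
    try:
        return extend_candidate(cand, template, None)
    except (NoMatchError, ValueError):
        return None


def evolve(
    generation: list[Candidate],
    blocks: list[str],
    templates: Sequence[ReactionTemplate],
    objectives: Sequence[Objective],
    config: GenerationConfig,
    generation_index: int = 0,
    filter_patterns=None,
) -> list[Candidate]:
    """One generation step: score, NDS-rank, elitism + SUS, mutate, filter.

    The next generation has exactly ``config.population_size`` members,
    contains every rank-1 candidate unchanged (elitism), and every member
    parses and passes the substructure filters (a mutation that fails
    validation falls back to its parent). Deterministic given the config
    seed and generation index.
    """
    if not generation:
        raise ValueError("empty generation")
    tdict = {t.name: t for t in templates}
    patterns = filter_patterns if filter_patterns is not None else default_filter_patterns()
    scores = _score_population(generation, objectives)
    directions = [o.direction for o in objectives]
    ranks = non_dominated_sort(scores, directions)
    ranked = [
        replace(c, scores=tuple(s), nds_rank=int(r))
        for c, s, r in zip(generation, scores, ranks)
    ]
    elites = [c for c in ranked if c.nds_rank == 1]
    if len(elites) >= config.population_size:
        return elites[: config.population_size]
    n_fill = config.population_size - len(elites)
    fitness = [1.0 / c.nds_rank for c in ranked]
    sus_seed = derive_seed(config.seed, "sus", generation_index)
    picks = stochastic_universal_sampling(fitness, n_fill, seed=sus_seed)
    rng = substream(config.seed, "mutate", generation_index)
    children: list[Candidate] = []
    for pick in picks:
        parent = ranked[pick]
        child = _mutate(parent, ranked, blocks, tdict, config, rng)
        if child is None or not _passes_filters(child.smiles, patterns):
            child = parent  # failed mutations fall back to the parent
        children.append(child)
    nxt = elites + children
    survivors = [c for c in nxt if _passes_filters(c.smiles, patterns)]
    if not survivors:
        raise RuntimeError(
            "population collapse: every candidate failed the substructure "
            "filters; review the template set and filter catalog"
        )
    return nxt


def seed_population(
    blocks: list[str],
    templates: Sequence[ReactionTemplate],
    config: GenerationConfig,
    run_index: int = 0,
    filter_patterns=None,
) -> list[Candidate]:
    """Build generation zero by applying random templates to random blocks."""
    tdict = {t.name: t for t in templates}
    patterns = filter_patterns if filter_patterns is not None else default_filter_patterns()
    rng = substream(config.seed, "seedpop", run_index)
    pop: list[Candidate] = []
    guard = 0
    while len(pop) < config.population_size and guard < 200 * config.population_size:
        guard += 1
        root = blocks[int(rng.integers(len(blocks)))]
        cand = Candidate(smiles=Chem.MolToSmiles(Chem.MolFromSmiles(root)), root_block=root)
        mol = Chem.MolFromSmiles(cand.smiles)
        compatible = [t for t in templates if t.matches(mol)]
        if not compatible:
            continue
        template = compatible[int(rng.integers(len(compatible)))]
        partner = blocks[int(rng.integers(len(blocks)))] if template.arity == 2 else None
        try:
            cand = extend_candidate(cand, tdict[template.name], partner)
        except (NoMatchError, ValueError):
            continue
        if _passes_filters(cand.smiles, patterns):
            pop.append(cand)
    if len(pop) < config.population_size:
        raise RuntimeError("could not seed a population from the given blocks/templates")
    return pop


def run_generations(
    blocks: list[str],
    templates: Sequence[ReactionTemplate],
    objectives: Sequence[Objective],
    config: GenerationConfig,
) -> list[Candidate]:
    """Multi-run GA: independent runs pool their final nondominated fronts.

    Short independent runs uncover distinct local optima and avoid the
    accumulation of odd functionality that single long runs exhibit.
    """
    front: list[Candidate] = []
    for run in range(max(1, config.n_independent_runs)):
        run_cfg = replace(config, seed=derive_seed(config.seed, "run", run))
        pop = seed_population(blocks, templates, run_cfg, run_index=run)
        for gen in range(config.n_generations):
            pop = evolve(pop, blocks, templates, objectives, run_cfg, generation_index=gen)
        scores = _score_population(pop, objectives)
        ranks = non_dominated_sort(scores, [o.direction for o in objectives])
        front.extend(
            replace(c, scores=tuple(s), nds_rank=int(r))
            for c, s, r in zip(pop, scores, ranks)
            if r == 1
        )
    # dedupe pooled front by canonical SMILES
    seen: dict[str, Candidate] = {}
    for c in front:
        seen.setdefault(c.smiles, c)
    return list(seen.values())


# ---------------------------------------------------------------------------
# packaged mock scorers
# ---------------------------------------------------------------------------


def mock_scorers(seed: int = 0, mw_target: float = 300.0) -> list[Objective]:
    """Cheap stand-in objectives for tests and demos.

    drug-likeness proxy (QED), cohort diversity, closeness to a target
    molecular weight, and a seeded random score standing in for an external
    model.
    """
    from rdkit.Chem import QED

    def qed_scorer(smiles: list[str]) -> np.ndarray:
        return np.array([QED.qed(Chem.MolFromSmiles(s)) for s in smiles])

    def diversity_scorer(smiles: list[str]) -> np.ndarray:
        fps = np.vstack([fingerprint(s) for s in smiles])
        out = np.zeros(len(smiles))
        for i in range(len(smiles)):
            others = np.delete(fps, i, axis=0)
            out[i] = candidate_diversity(fps[i], others) if len(others) else 1.0
        return out

    def mw_scorer(smiles: list[str]) -> np.ndarray:
        return np.array(
            [abs(Descriptors.MolWt(Chem.MolFromSmiles(s)) - mw_target) for s in smiles]
        )

    def random_scorer(smiles: list[str]) -> np.ndarray:
        return np.array(
            [substream(seed, "mock-random", s).random() for s in smiles]
        )

    return [
        Objective("qed", "maximize", qed_scorer),
        Objective("diversity", "maximize", diversity_scorer),
        Objective("mw_target", "minimize", mw_scorer),
        Objective("external", "maximize", random_scorer),
    ]
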