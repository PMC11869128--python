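"""Genetic generator: NDS, SUS, template algebra, amortized scoring, evolution."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfbo import molgen
from mfbo.chemio import HYDROXAMATE
from mfbo.molgen import (
    Candidate,
    GenerationConfig,
    NoCommonTemplateError,
    NoMatchError,
    Objective,
    amortize_expensive_score,
    apply_template,
    choose_operation,
    crossover,
    default_building_blocks,
    default_templates,
    evolve,
    load_templates,
    mock_scorers,
    non_dominated_sort,
    replay_route,
    run_generations,
    seed_population,
    stochastic_universal_sampling,
    undo_last_step,
)

TEMPLATES = default_templates()
TDICT = {t.name: t for t in TEMPLATES}
BLOCKS = default_building_blocks()


def brute_force_nds(scores: np.ndarray, directions) -> np.ndarray:
    """O(n^2 k) dominance-counting oracle, peeled front by front."""
    sign = np.array([1 if d == "maximize" else -1 for d in directions])
    S = scores * sign
    n = len(S)
    ranks = np.zeros(n, dtype=int)
    assigned = np.zeros(n, dtype=bool)
    rank = 0
    while not assigned.all():
        rank += 1
        front = []
        for i in range(n):
            if assigned[i]:
                continue
            dominated = False
            for j in range(n):
                if j == i or assigned[j]:
                    continue
                if (S[j] >= S[i]).all() and (S[j] > S[i]).any():
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        for i in front:
            ranks[i] = rank
            assigned[i] = True
    return ranks


class TestNDS:
    def test_single_candidate(self):
        assert list(non_dominated_sort(np.array([[1.0, 2.0]]), ["maximize"] * 2)) == [1]

    def test_strict_dominance(self):
        scores = np.array([[2.0, 2.0], [1.0, 1.0]])
        assert list(non_dominated_sort(scores, ["maximize"] * 2)) == [1, 2]

    def test_direction_awareness(self):
        scores = np.array([[1.0], [2.0]])
        assert list(non_dominated_sort(scores, ["minimize"])) == [1, 2]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=(20, 3)).astype(float)  # ties likely
        directions = ["maximize", "minimize", "maximize"]
        assert np.array_equal(
            non_dominated_sort(scores, directions),
            brute_force_nds(scores, directions),
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            non_dominated_sort(np.zeros((0, 2)), ["maximize"] * 2)


class TestSUS:
    def test_uniform_fitness_exact_coverage(self):
        picks = stochastic_universal_sampling([1.0] * 7, 7, seed=3)
        assert sorted(picks) == list(range(7))

    def test_exact_comb_counts(self):
        picks = stochastic_universal_sampling([3.0, 1.0], 4, seed=11)
        assert picks.count(0) == 3 and picks.count(1) == 1

    def test_single_positive_fitness(self):
        picks = stochastic_universal_sampling([0.0, 5.0, 0.0], 4, seed=0)
        assert picks == [1, 1, 1, 1]

    def test_zero_fitness_raises(self):
        with pytest.raises(ValueError):
            stochastic_universal_sampling([0.0, 0.0], 2)

    @settings(deadline=None, max_examples=40)
    @given(
        fitness=st.lists(st.floats(0.0, 10.0), min_size=2, max_size=8).filter(
            lambda f: sum(f) > 1e-6
        ),
        n_draws=st.integers(1, 20),
        seed=st.integers(0, 100),
    )
    def test_floor_ceil_bounds(self, fitness, n_draws, seed):
        picks = stochastic_universal_sampling(fitness, n_draws, seed=seed)
        total = sum(fitness)
        for i, f in enumerate(fitness):
            expect = n_draws * f / total
            assert np.floor(expect) <= picks.count(i) <= np.ceil(expect)


class TestTemplates:
    def test_amide_coupling_worked_example(self):
        # acetic acid + methylamine -> N-methylacetamide
        assert apply_template(TDICT["amide_coupling"], "CC(=O)O", "CN") == "CNC(C)=O"

    def test_no_match_is_typed_error(self):
        with pytest.raises(NoMatchError):
            apply_template(TDICT["amide_coupling"], "CCCC", "CN")

    def test_undo_restores_precursor(self):
        root = "CC(=O)O"
        cand = Candidate(smiles=root, root_block=root)
        grown = molgen.extend_candidate(cand, TDICT["amide_coupling"], "CN")
        restored = undo_last_step(grown, TDICT)
        assert restored.smiles == root and restored.route == ()

    def test_route_replay(self):
        cand = Candidate(smiles="CC(=O)O", root_block="CC(=O)O")
        cand = molgen.extend_candidate(cand, TDICT["amide_coupling"], "NCCO")
        assert replay_route(cand, TDICT) == cand.smiles

    def test_load_templates_file(self, tmp_path):
        p = tmp_path / "templates.tsv"
        p.write_text("amide\t[C:1](=[O:2])[OX2H1].[NX3;H2:3]>>[C:1](=[O:2])[N:3]\n")
        ts = load_templates(p)
        assert ts[0].arity == 2
        assert apply_template(ts[0], "CC(=O)O", "CN") == "CNC(C)=O"

    def test_bad_template_rejected(self):
        with pytest.raises(ValueError):
            molgen.ReactionTemplate("bad", "not a reaction", 1)


class TestChooseOperation:
    def test_light_molecule_never_removed(self):
        ops = {choose_operation(90.0, seed=s) for s in range(60)}
        assert "remove" not in ops

    def test_heavy_molecule_never_extended(self):
        ops = {choose_operation(550.0, seed=s) for s in range(60)}
        assert "apply" not in ops

    def test_midpoint_symmetric(self):
        ops = [choose_operation(300.0, seed=s, p_crossover=0.0) for s in range(400)]
        frac_apply = ops.count("apply") / len(ops)
        assert 0.4 < frac_apply < 0.6

    def test_crossover_share(self):
        ops = [choose_operation(300.0, seed=s, p_crossover=1.0) for s in range(10)]
        assert set(ops) == {"crossover"}

    def test_nonpositive_mw_raises(self):
        with pytest.raises(ValueError):
            choose_operation(0.0)


class TestCrossover:
    def make_pair(self):
        c1 = Candidate(smiles="CC(=O)O", root_block="CC(=O)O")
        c1 = molgen.extend_candidate(c1, TDICT["amide_coupling"], "CN")
        c2 = Candidate(smiles="CCC(=O)O", root_block="CCC(=O)O")
        c2 = molgen.extend_candidate(c2, TDICT["amide_coupling"], "NCCO")
        return c1, c2

    def test_identical_candidates_unchanged(self):
        c1, _ = self.make_pair()
        ch1, ch2 = crossover(c1, c1, TDICT, seed=0)
        assert ch1.smiles == c1.smiles and ch2.smiles == c1.smiles

    def test_partner_swap_at_shared_final_step(self):
        c1, c2 = self.make_pair()
        ch1, ch2 = crossover(c1, c2, TDICT, seed=0)
        # suffix swap exchanges the amide partners between the two acids
        assert ch1.smiles == apply_template(TDICT["amide_coupling"], "CC(=O)O", "NCCO")
        assert ch2.smiles == apply_template(TDICT["amide_coupling"], "CCC(=O)O", "CN")

    def test_disjoint_templates_typed_error(self):
        c1, _ = self.make_pair()
        c3 = Candidate(smiles="c1ccccc1N", root_block="c1ccccc1N")
        c3 = molgen.extend_candidate(c3, TDICT["sulfonamide_formation"], None) \
            if False else molgen.extend_candidate(
                Candidate(smiles="CS(=O)(=O)Cl", root_block="CS(=O)(=O)Cl"),
                TDICT["sulfonamide_formation"], "CN")
        with pytest.raises(NoCommonTemplateError):
            crossover(c1, c3, TDICT, seed=0)


class TestAmortizedScoring:
    def candidates(self):
        smiles = ["CCO", "CCO", "CCCO", "c1ccccc1", "c1ccccc1C", "c1ccccc1CC"]
        return [Candidate(smiles=s, root_block=s) for s in smiles]

    def test_k_equals_n_matches_direct(self):
        cands = self.candidates()
        scorer_calls = []

        def scorer(smi):
            scorer_calls.append(smi)
            return float(len(smi))

        scores = amortize_expensive_score(cands, scorer, k=len(cands), seed=0)
        assert len(scorer_calls) == len(cands)
        assert np.allclose(scores, [len(c.smiles) for c in cands])

    def test_scorer_called_exactly_k_times(self):
        calls = []
        amortize_expensive_score(self.candidates(), lambda s: calls.append(s) or 1.0, k=2, seed=0)
        assert len(calls) == 2

    def test_duplicate_groups_share_scores(self):
        cands = [Candidate(smiles=s, root_block=s)
                 for s in ["CCO", "CCO", "CCO", "c1ccccc1", "c1ccccc1", "c1ccccc1"]]
        scores = amortize_expensive_score(cands, lambda s: float(len(s)), k=2, seed=0)
        assert len(set(scores[:3])) == 1 and len(set(scores[3:])) == 1

    def test_failing_scorer_marks_cluster(self):
        def bad(smi):
            raise RuntimeError("docker down")

        scores = amortize_expensive_score(self.candidates(), bad, k=2, seed=0)
        assert np.isnan(scores).all()


@pytest.fixture(scope="module")
def evolved_run():
    cfg = GenerationConfig(population_size=24, n_generations=5, seed=13)
    objs = mock_scorers(seed=13)
    pop = seed_population(BLOCKS, TEMPLATES, cfg)
    history = [pop]
    for gen in range(cfg.n_generations):
        pop = evolve(pop, BLOCKS, TEMPLATES, objs, cfg, generation_index=gen)
        history.append(pop)
    return cfg, objs, history


class TestEvolution:
    def test_population_size_preserved(self, evolved_run):
        cfg, _, history = evolved_run
        assert all(len(pop) == cfg.population_size for pop in history)

    def test_elitism(self, evolved_run):
        """Every rank-1 candidate of generation t appears in generation t+1."""
        _, objs, history = evolved_run
        for prev, nxt in zip(history[:-1], history[1:]):
            scores = molgen._score_population(prev, objs)
            ranks = non_dominated_sort(scores, [o.direction for o in objs])
            elites = {c.smiles for c, r in zip(prev, ranks) if r == 1}
            survivors = {c.smiles for c in nxt}
            assert elites <= survivors

    def test_route_replay_every_generation(self, evolved_run):
        _, _, history = evolved_run
        for pop in history:
            for cand in pop:
                assert replay_route(cand, TDICT) == cand.smiles

    def test_no_hydroxamate_ever(self, evolved_run):
        from rdkit import Chem

        _, _, history = evolved_run
        for pop in history:
            for cand in pop:
                assert not HYDROXAMATE.matches(Chem.MolFromSmiles(cand.smiles))

    def test_deterministic(self):
        cfg = GenerationConfig(population_size=12, n_generations=2, seed=5)
        objs = mock_scorers(seed=5)

        def run():
            pop = seed_population(BLOCKS, TEMPLATES, cfg)
            for gen in range(cfg.n_generations):
                pop = evolve(pop, BLOCKS, TEMPLATES, objs, cfg, generation_index=gen)
            return [c.smiles for c in pop]

        assert run() == run()

    def test_mw_selection_pressure(self):
        """A MW-targeting objective pulls the population toward 300 Da."""
        mw_obj = [Objective(
            "mw_target", "minimize",
            lambda smiles: np.array([
                abs(molgen.Descriptors.MolWt(molgen.Chem.MolFromSmiles(s)) - 300.0)
                for s in smiles
            ]),
        )]
        deltas = []
        for seed in range(6):
            cfg = GenerationConfig(population_size=16, n_generations=5, seed=seed)
            pop = seed_population(BLOCKS, TEMPLATES, cfg)
            before = np.median([abs(c.mw - 300) for c in pop])
            for gen in range(cfg.n_generations):
                pop = evolve(pop, BLOCKS, TEMPLATES, mw_obj, cfg, generation_index=gen)
            after = np.median([abs(c.mw - 300) for c in pop])
            deltas.append(before - after)
        assert np.mean(deltas) > 0

    def test_multi_run_front_pooling(self):
        cfg = GenerationConfig(
            population_size=10, n_generations=2, n_independent_runs=3, seed=2
        )
        front = run_generations(BLOCKS, TEMPLATES, mock_scorers(seed=2), cfg)
        assert front and all(c.nds_rank == 1 for c in front)
        assert len({c.smiles for c in front}) == len(front)

    def test_empty_generation_raises(self):
        with pytest.raises(ValueError):
            evolve([], BLOCKS, TEMPLATES, mock_scorers(), GenerationConfig())
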