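import numpy as np
import pytest
from scipy.stats import norm

from crossplan import optimizer as op
from crossplan.diversity import grm
from crossplan.popdata import CrossScheme, TraitEffects


@pytest.fixture(scope="module")
def tiny_instance():
    rng = np.random.default_rng(5)
    n = 6
    preds = {
        (k, l): (float(rng.normal()), float(abs(rng.normal())))
        for k in range(n)
        for l in range(k + 1, n)
    }
    A = rng.standard_normal((n, 12))
    G = A @ A.T / 12
    cons = op.ConstraintSet(
        total_crosses=3, allow_repeats=True, propsd_cutoff=0.6,
        selected_per_family=5, progeny_per_cross=50,
    )
    return preds, cons, G


class TestSelectionIntensity:
    def test_no_selection(self):
        assert op.selection_intensity(1.0) == 0.0

    def test_half_selected(self):
        assert op.selection_intensity(0.5) == pytest.approx(norm.pdf(0) / 0.5)

    def test_ten_percent(self):
        assert op.selection_intensity(0.1) == pytest.approx(1.755, abs=1e-3)

    def test_invalid_proportion(self):
        with pytest.raises(ValueError):
            op.selection_intensity(0.0)


class TestMatingPlan:
    def test_canonical_form_and_counts(self):
        plan = op.MatingPlan.from_crosses([(3, 1), (1, 3), (0, 2)])
        assert plan.families == ((0, 2, 1), (1, 3, 2))
        assert plan.total_crosses == 3
        assert plan.selected_parents() == [0, 1, 1, 2, 3, 3]
        assert plan.selected_parents(unique=True) == [0, 1, 2, 3]

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            op.MatingPlan(families=((0, 1, 1), (0, 1, 2)))


class TestPlanFitness:
    def test_single_family_is_its_usefulness(self, tiny_instance):
        preds, cons, _ = tiny_instance
        plan = op.MatingPlan.from_crosses([(0, 1)])
        cons1 = op.ConstraintSet(total_crosses=1, selected_per_family=5, progeny_per_cross=50)
        rep = op.plan_fitness(plan, preds, cons1)
        mean, sd = preds[(0, 1)]
        i_f = op.selection_intensity(5 / 50)
        assert rep.fitness == pytest.approx(mean + i_f * sd)

    def test_replication_raises_usefulness(self, tiny_instance):
        preds, cons, _ = tiny_instance
        u1 = op.plan_fitness(op.MatingPlan.from_crosses([(0, 1)]), preds, cons).fitness
        u2 = op.plan_fitness(op.MatingPlan.from_crosses([(0, 1), (0, 1)]), preds, cons).fitness
        assert u2 > u1

    def test_three_family_average_by_hand(self, tiny_instance):
        preds, cons, _ = tiny_instance
        fams = [(0, 1), (2, 3), (4, 5)]
        plan = op.MatingPlan.from_crosses(fams)
        i_f = op.selection_intensity(cons.selected_per_family / cons.progeny_per_cross)
        expect = np.mean([preds[f][0] + i_f * preds[f][1] for f in fams])
        assert op.plan_fitness(plan, preds, cons).fitness == pytest.approx(expect)

    def test_missing_prediction_raises(self, tiny_instance):
        _, cons, _ = tiny_instance
        with pytest.raises(KeyError):
            op.plan_fitness(op.MatingPlan.from_crosses([(0, 9)]), {}, cons)


class TestFeasibility:
    def test_propsd_violation_flagged(self, tiny_instance):
        preds, cons, G = tiny_instance
        strict = op.ConstraintSet(total_crosses=3, propsd_cutoff=1e-6)
        plan = op.MatingPlan.from_crosses([(0, 1), (0, 1), (2, 3)])
        ok, violations, propsd = op.check_feasibility(plan, strict, G)
        assert not ok and "propsd" in violations and propsd > 1e-6

    def test_forbidden_pair_flagged(self, tiny_instance):
        preds, cons, G = tiny_instance
        mask = np.ones((6, 6), dtype=bool)
        mask[0, 1] = mask[1, 0] = False
        c = op.ConstraintSet(total_crosses=1, pair_mask=mask)
        ok, violations, _ = op.check_feasibility(op.MatingPlan.from_crosses([(0, 1)]), c, None)
        assert not ok and "pair_mask" in violations

    def test_parent_max_flagged(self):
        c = op.ConstraintSet(total_crosses=3, parent_max=2)
        plan = op.MatingPlan.from_crosses([(0, 1), (0, 2), (0, 3)])
        ok, violations, _ = op.check_feasibility(plan, c, None)
        assert not ok and "parent_max" in violations

    def test_repeats_disabled_flagged(self):
        c = op.ConstraintSet(total_crosses=2, allow_repeats=False)
        plan = op.MatingPlan.from_crosses([(0, 1), (0, 1)])
        ok, violations, _ = op.check_feasibility(plan, c, None)
        assert not ok and "repeats" in violations


class TestExhaustive:
    def test_single_feasible_plan(self, tiny_instance):
        preds, _, G = tiny_instance
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        cons = op.ConstraintSet(total_crosses=1, pair_mask=mask)
        plan, rep = op.exhaustive_search(preds, cons, G_pool=G)
        assert plan.families == ((0, 1, 1),)

    def test_forbidding_best_pair_drops_fitness(self, tiny_instance):
        preds, cons, G = tiny_instance
        plan, rep = op.exhaustive_search(preds, cons, G_pool=G)
        best_pair = max(plan.families, key=lambda f: f[2])[:2]
        mask = np.ones((6, 6), dtype=bool)
        mask[best_pair] = mask[best_pair[::-1]] = False
        cons2 = op.ConstraintSet(
            total_crosses=3, allow_repeats=True, propsd_cutoff=0.6,
            selected_per_family=5, progeny_per_cross=50, pair_mask=mask,
        )
        plan2, rep2 = op.exhaustive_search(preds, cons2, G_pool=G)
        assert rep2.fitness < rep.fitness

    def test_space_guard(self, tiny_instance):
        preds, _, _ = tiny_instance
        cons = op.ConstraintSet(total_crosses=40)
        with pytest.raises(ValueError, match="exceeds"):
            op.exhaustive_search(preds, cons, max_space=10)


class TestOptimize:
    def test_attains_exhaustive_optimum_on_seeded_runs(self, tiny_instance):
        """Default-config GA+SA hits the enumerated optimum in >= 95% of
        seeded runs on enumerable instances."""
        preds, cons, G = tiny_instance
        _, rep_ex = op.exhaustive_search(preds, cons, G_pool=G)
        wins = 0
        for seed in range(20):
            _, rep, trace = op.optimize(preds, cons, op.OptimizerConfig(seed=seed), G_pool=G)
            wins += abs(rep.fitness - rep_ex.fitness) < 1e-9
            assert all(trace[i] <= trace[i + 1] + 1e-12 for i in range(len(trace) - 1))
        assert wins >= 19

    def test_never_returns_infeasible_when_feasible_seen(self, tiny_instance):
        preds, cons, G = tiny_instance
        plan, rep, _ = op.optimize(preds, cons, op.OptimizerConfig(seed=1), G_pool=G)
        assert rep.feasible
        assert rep.propsd < cons.propsd_cutoff

    def test_repeated_family_bound(self, tiny_instance):
        """With an inactive diversity cutoff, the optimum is never below the
        best single-family fully-replicated plan."""
        preds, _, G = tiny_instance
        cons = op.ConstraintSet(
            total_crosses=3, allow_repeats=True, propsd_cutoff=1.0,
            selected_per_family=5, progeny_per_cross=50,
        )
        _, rep, _ = op.optimize(preds, cons, op.OptimizerConfig(seed=3), G_pool=None)
        best_single = max(
            op.plan_fitness(op.MatingPlan.from_crosses([p] * 3), preds, cons).fitness
            for p in preds
        )
        assert rep.fitness >= best_single - 1e-9

    def test_deterministic_under_seed(self, tiny_instance):
        preds, cons, G = tiny_instance
        r1 = op.optimize(preds, cons, op.OptimizerConfig(seed=7), G_pool=G)
        r2 = op.optimize(preds, cons, op.OptimizerConfig(seed=7), G_pool=G)
        assert r1[0] == r2[0] and r1[2] == r2[2]

    def test_raising_cutoff_never_decreases_optimum(self, tiny_instance):
        preds, _, G = tiny_instance
        fits = []
        for cutoff in (0.2, 0.4, 0.8):
            cons = op.ConstraintSet(
                total_crosses=2, allow_repeats=True, propsd_cutoff=cutoff,
                selected_per_family=5, progeny_per_cross=50,
            )
            try:
                _, rep = op.exhaustive_search(preds, cons, G_pool=G)
                fits.append(rep.fitness)
            except ValueError:
                fits.append(-np.inf)
        assert fits == sorted(fits)


class TestTestcrossObjective:
    def test_consistency_with_family_dists(self, het_panel, additive20):
        """Single tester, clonal base: equals the three-way prediction through
        the per-locus testcross distributions."""
        scheme = CrossScheme("F1", testers=(5,))
        df = op.testcross_objective(het_panel, scheme, additive20, ld_model="independent")
        from crossplan.crosspredict import CrossPredictor

        pred = CrossPredictor(het_panel, additive20, scheme, ld_model="independent")
        fp = pred.predict_pair(0, 1)
        row = df[(df.parent1 == "P0") & (df.parent2 == "P1")].iloc[0]
        assert row["mean"] == pytest.approx(fp.mean)

    def test_homozygous_tester_additive_mean(self, dh_panel, additive20):
        """Additive effects, fully homozygous tester: hybrid mean is half the
        family's additive dosage mean plus the constant tester contribution."""
        scheme = CrossScheme("DH", testers=(2,))
        from crossplan.crosspredict import CrossPredictor

        pred = CrossPredictor(dh_panel, additive20, scheme, ld_model="independent")
        fp = pred.predict_pair(0, 1)
        a = additive20.additive
        fam_mean = 0.5 * (dh_panel.dosages[0] + dh_panel.dosages[1])
        expect = (fam_mean / 2) @ a + (dh_panel.dosages[2] / 2) @ a
        assert fp.mean == pytest.approx(expect)

    def test_invalid_tester_rejected(self, het_panel, additive20):
        with pytest.raises(IndexError):
            op.testcross_objective(het_panel, CrossScheme("F1", testers=(99,)), additive20)
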