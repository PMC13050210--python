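import numpy as np
import pytest

from crossplan import crosspredict as cp
from crossplan import inheritance as inh
from crossplan.popdata import ClassValueMap, CrossScheme, PanelValidationError, TraitEffects


class TestLocusMean:
    def test_single_class(self, cvm2):
        assert cp.locus_mean([0, 1, 0], 1.0, 0.5, cvm2) == pytest.approx(1.5)

    def test_punnett_with_dominance(self, cvm2):
        # (1/4, 1/2, 1/4) over (0,1,2), a=1, d=1 -> 1/4*2 + 1/2*2 + 1/4*0 -- ordered (P0,P1,P2)
        assert cp.locus_mean([0.25, 0.5, 0.25], 1.0, 1.0, cvm2) == pytest.approx(1.5)

    def test_matches_monte_carlo_any_scheme(self, het_panel, effects20, cvm2):
        scheme = CrossScheme("SELF", t=1)
        mu = cp.family_mean(het_panel, (0, 1), scheme, effects20, cvm2)
        n = 30_000
        S = inh.simulate_progeny(het_panel, (0, 1), scheme, n, seed=8)
        g = S.astype(float) @ effects20.additive + cvm2.dominance_score[S] @ effects20.dominance
        assert mu == pytest.approx(g.mean(), abs=3 * g.std() / np.sqrt(n))


class TestFalconerComparator:
    def test_symmetric_additive(self):
        assert cp.falconer_f1_mean(0.5, 0.5, 0.0, 1.0, 0.0) == 0.0

    def test_additive_reduction(self):
        assert cp.falconer_f1_mean(0.3, 0.6, 0.1, 2.0, 0.0) == pytest.approx(2.0 * (0.3 - 0.6 - 0.1))

    def test_simulator_adjudicates_against_legacy_formula(self, cvm2):
        """Single-locus Aa x Aa with dominance: the class-frequency mean matches
        the Punnett expectation while the legacy formula deviates."""
        dist = inh.f1_locus_dist(inh.gamete_dist(1, 2), inh.gamete_dist(1, 2))
        ours = cp.locus_mean(dist, 1.0, 1.0, cvm2)
        exact = 0.25 * 2 + 0.5 * (1 + 1) + 0.25 * 0  # enumerate offspring classes
        assert ours == pytest.approx(exact)
        legacy = cp.falconer_f1_mean(0.5, 0.5, 0.0, 1.0, 1.0)
        assert legacy != pytest.approx(ours)


class TestLocusVariance:
    def test_single_class_zero(self, cvm2):
        assert cp.locus_variance([0, 1, 0], 1.0, 1.0, cvm2) == 0.0

    def test_additive_punnett(self, cvm2):
        assert cp.locus_variance([0.25, 0.5, 0.25], 1.0, 0.0, cvm2) == pytest.approx(0.5)

    def test_dominance_punnett(self, cvm2):
        assert cp.locus_variance([0.25, 0.5, 0.25], 0.0, 1.0, cvm2, "dominance_only") == pytest.approx(0.25)


class TestAdDecomposition:
    def test_zero_dominance_degenerate_rho(self, cvm2):
        s = cp.locus_ad_decomposition([0.25, 0.5, 0.25], 1.0, 0.0, cvm2)
        assert s.dominance_var == 0.0
        assert s.ad_correlation == 0.0

    def test_punnett_decomposition(self, cvm2):
        s = cp.locus_ad_decomposition([0.25, 0.5, 0.25], 1.0, 1.0, cvm2)
        assert s.total_var == pytest.approx(0.75)
        assert s.additive_var == pytest.approx(0.5)
        assert s.dominance_var == pytest.approx(0.25)
        assert s.ad_correlation == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rho_matches_enumeration(self, seed, cvm2):
        rng = np.random.default_rng(seed)
        dist = rng.dirichlet(np.ones(3))
        a, d = rng.normal(size=2)
        s = cp.locus_ad_decomposition(dist, a, d, cvm2)
        # brute-force correlation of (m(k)a, w(k)d) under dist
        va = np.array([0, 1, 2]) * a
        vd = np.array([0, 1, 0]) * d
        cov = dist @ (va * vd) - (dist @ va) * (dist @ vd)
        sa = np.sqrt(dist @ va**2 - (dist @ va) ** 2)
        sd = np.sqrt(dist @ vd**2 - (dist @ vd) ** 2)
        expect = cov / (sa * sd) if sa * sd > 0 else 0.0
        assert s.ad_correlation == pytest.approx(expect, abs=1e-9)
        # invariant: total = a + d + 2 rho sa sd
        assert s.total_var == pytest.approx(
            s.additive_var + s.dominance_var
            + 2 * s.ad_correlation * np.sqrt(s.additive_var * s.dominance_var),
            abs=1e-9,
        )


class TestCovCorr:
    def test_diagonal_to_identity(self):
        assert np.allclose(cp.cov_to_corr(np.diag([1.0, 4.0])), np.eye(2))

    def test_zero_variance_locus_no_nan(self):
        S = np.array([[1.0, 0.0], [0.0, 0.0]])
        C = cp.cov_to_corr(S)
        assert not np.any(np.isnan(C))
        assert C[0, 1] == 0.0 and C[1, 1] == 1.0

    def test_matches_brute_force_on_random_psd(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 10))
        S = A @ A.T
        C = cp.cov_to_corr(S)
        d = np.sqrt(np.diag(S))
        assert np.allclose(C, S / np.outer(d, d))


class TestSourcePopCov:
    def test_identical_individuals_zero(self, small_map, effects20, cvm2):
        from crossplan.popdata import ParentPanel

        dos = np.ones((3, 20), dtype=int)
        panel = ParentPanel(ploidy=2, dosages=dos, names=np.array(list("abc"), object), gmap=small_map)
        S = cp.source_pop_cov(panel, "pop0", effects20, cvm2)
        assert np.allclose(S, 0.0)

    def test_matches_brute_force(self, het_panel, effects20, cvm2):
        S = cp.source_pop_cov(het_panel, "a", effects20, cvm2)
        idx = np.nonzero(het_panel.subpop == "a")[0]
        M = het_panel.dosages[idx]
        X = (
            cvm2.additive_score[M] * effects20.additive
            + cvm2.dominance_score[M] * effects20.dominance
        )
        expect = np.cov(X.T, bias=True)
        assert np.allclose(S, expect)

    def test_small_subpop_rejected(self, small_map, effects20):
        from crossplan.popdata import ParentPanel

        panel = ParentPanel(
            ploidy=2, dosages=np.zeros((2, 20), dtype=int),
            names=np.array(["a", "b"], object), gmap=small_map,
            subpop=np.array(["x", "y"], object),
        )
        with pytest.raises(PanelValidationError):
            cp.source_pop_cov(panel, "x", effects20)


class TestPhasedAdditiveCov:
    def test_monomorphic_family_zero_row(self, effects20):
        Hk = np.ones((2, 20), dtype=np.int8)
        Hl = np.ones((2, 20), dtype=np.int8)
        Sk, Sl, p = cp.phased_additive_cov(Hk, Hl, effects20)
        assert np.all(p == 1.0)
        assert np.allclose(Sk, 0)

    def test_coupling_phase_positive_offdiagonal(self):
        eff = TraitEffects(additive=np.ones(2), dominance=np.zeros(2))
        Hk = np.array([[0, 0], [1, 1]], dtype=np.int8)  # coupling phase
        Hl = np.array([[0, 0], [0, 0]], dtype=np.int8)
        Sk, Sl, p = cp.phased_additive_cov(Hk, Hl, eff)
        assert Sk[0, 1] > 0
        # hand enumeration: p = (0.5 + 0)/2 = 0.25; centred rows +-(0.25/0.75)
        assert p == pytest.approx([0.25, 0.25])
        assert Sk[0, 1] == pytest.approx(np.mean([(0 - 0.25) * (0 - 0.25), (1 - 0.25) * (1 - 0.25)]))

    def test_matches_brute_force_random(self, effects20):
        rng = np.random.default_rng(3)
        Hk = rng.integers(0, 2, (4, 20)).astype(np.int8)
        Hl = rng.integers(0, 2, (4, 20)).astype(np.int8)
        Sk, Sl, p = cp.phased_additive_cov(Hk, Hl, effects20)
        Zk = (Hk - p) * effects20.additive
        assert np.allclose(Sk, Zk.T @ Zk / 4)


class TestPropagate:
    def test_f1_free_recombination_kills_offdiagonal(self):
        S = np.full((2, 2), 0.5)
        c = np.array([[0.0, 0.5], [0.5, 0.0]])
        out = cp.propagate_family_cov(S, S, c, CrossScheme("F1"))
        assert out[0, 1] == 0.0

    def test_f1_complete_linkage_averages_parents(self):
        Sk = np.array([[1.0, 0.5], [0.5, 1.0]])
        Sl = np.array([[2.0, -0.5], [-0.5, 2.0]])
        c = np.zeros((2, 2))
        out = cp.propagate_family_cov(Sk, Sl, c, CrossScheme("F1"))
        assert np.allclose(out, 0.5 * Sk + 0.5 * Sl)

    def test_f1_matches_simulated_progeny_covariance(self, het_panel, additive20):
        """Exact-path F1 covariance vs the covariance of per-locus additive
        effects in simulated progeny."""
        pred = cp.CrossPredictor(het_panel, additive20, CrossScheme("F1"), ld_model="full")
        Gamma, D, _ = pred._ld_inputs(0, 1, ())
        sigma = (pred.A * Gamma + pred.B * D) * pred.aa
        n = 60_000
        S = inh.simulate_progeny(het_panel, (0, 1), CrossScheme("F1"), n, seed=9)
        X = S.astype(float) * additive20.additive
        emp = np.cov(X.T, bias=True)
        scale = max(np.abs(emp).max(), 1e-9)
        assert np.abs(sigma - emp).max() / scale < 0.1

    def test_unknown_scheme_rejected(self):
        with pytest.raises(PanelValidationError):
            CrossScheme("BACKCROSS")


class TestVarianceModels:
    def test_independent_additivity(self):
        assert cp.variance_independent(np.array([0.5, 0.25])) == 0.75
        assert cp.variance_independent(np.zeros(4)) == 0.0

    def test_approx_identity_reduces_to_independent(self):
        v = np.array([0.5, 0.25, 1.0])
        assert cp.variance_approx(v, np.eye(3)) == pytest.approx(v.sum())

    def test_approx_perfect_correlation(self):
        C = np.ones((2, 2))
        assert cp.variance_approx(np.array([1.0, 1.0]), C) == pytest.approx(4.0)

    def test_full_single_locus_reduces_to_total_variance(self, cvm2):
        dist = np.array([0.2, 0.5, 0.3])
        a, d = 1.3, -0.7
        s = cp.locus_ad_decomposition(dist, a, d, cvm2)
        out = cp.variance_full(
            np.array([s.additive_var]), np.array([s.dominance_var]),
            np.array([s.ad_correlation]), np.eye(1),
        )
        assert out == pytest.approx(s.total_var, abs=1e-12)

    def test_full_identity_no_dominance(self):
        va = np.array([0.5, 0.25])
        out = cp.variance_full(va, np.zeros(2), np.zeros(2), np.eye(2))
        assert out == pytest.approx(va.sum())

    def test_negative_clip_counted(self):
        clip = cp.ClipCounter()
        C = np.array([[1.0, -2.0], [-2.0, 1.0]])  # indefinite 'correlation'
        out = cp.variance_approx(np.array([1.0, 1.0]), C, clip)
        assert out == 0.0 and clip.count == 1


class TestUsefulness:
    def test_no_selection_returns_mean(self):
        assert cp.usefulness(3.0, 4.0, 0.0, 1.0) == 3.0

    def test_sd_convention(self):
        assert cp.usefulness(3.0, 4.0, 1.0, 1.0) == 5.0
        assert cp.usefulness(3.0, 4.0, 1.0, 1.0, use_sd=False) == 7.0

    def test_monotone_in_variance(self):
        us = [cp.usefulness(0.0, v, 1.0, 0.8) for v in (0.5, 1.0, 2.0)]
        assert us[0] < us[1] < us[2]

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            cp.usefulness(0.0, -1.0, 1.0, 1.0)


class TestPredictor:
    def test_parameterization_consistency_without_dominance(self, dh_panel, additive20):
        """With d = 0, genotypic and breeding parameterizations coincide."""
        out = {}
        for par in ("genotypic", "breeding"):
            eff = TraitEffects(
                additive=additive20.additive, dominance=np.zeros(20), parameterization=par
            )
            p = cp.CrossPredictor(dh_panel, eff, CrossScheme("DH"), ld_model="full")
            out[par] = p.predict_pair(0, 1)
        assert out["genotypic"].mean == pytest.approx(out["breeding"].mean)
        assert out["genotypic"].variance == pytest.approx(out["breeding"].variance)

    def test_additive_f1_mean_is_midparent(self, het_panel, additive20):
        mu = cp.family_mean(het_panel, (0, 1), CrossScheme("F1"), additive20)
        mid = 0.5 * (het_panel.dosages[0] + het_panel.dosages[1]) @ additive20.additive
        assert mu == pytest.approx(mid)

    def test_selfing_homozygous_parent_returns_parent_value(self, dh_panel, effects20, cvm2):
        mu = cp.family_mean(dh_panel, (0, 0), CrossScheme("SELF", t=2), effects20, cvm2)
        M = dh_panel.dosages[0]
        expect = cvm2.additive_score[M] @ effects20.additive + cvm2.dominance_score[M] @ effects20.dominance
        assert mu == pytest.approx(expect)

    def test_full_model_requires_phased(self, small_map, additive20):
        from crossplan.popdata import ParentPanel

        panel = ParentPanel(
            ploidy=2, dosages=np.ones((4, 20), dtype=int) * 2,
            names=np.array(list("abcd"), object), gmap=small_map,
        )
        with pytest.raises(PanelValidationError, match="approx"):
            cp.CrossPredictor(panel, additive20, CrossScheme("DH"), ld_model="full")

    def test_predict_all_counting_symmetry_consistency(self, dh_panel, additive20):
        df = cp.predict_all_crosses(dh_panel, CrossScheme("DH"), additive20, ld_model="approx")
        n = dh_panel.n_parents
        assert len(df) == n * (n - 1) // 2
        pred = cp.CrossPredictor(dh_panel, additive20, CrossScheme("DH"), ld_model="approx")
        a = pred.predict_pair(0, 1)
        b = pred.predict_pair(1, 0)
        assert a.mean == pytest.approx(b.mean) and a.variance == pytest.approx(b.variance)
        row = df[(df.parent1 == "P0") & (df.parent2 == "P1")].iloc[0]
        assert row["mean"] == pytest.approx(a.mean)
        assert row["variance"] == pytest.approx(a.variance)


MC_CASES = [
    ("dh_panel", CrossScheme("DH"), False),
    ("dh_panel", CrossScheme("SELF", t=3), False),
    ("het_panel", CrossScheme("F1"), True),
    ("dh_panel", CrossScheme("DH", testers=(2,)), False),
    ("tetra_panel", CrossScheme("SELF", t=3), True),
    ("tetra_panel", CrossScheme("F1"), True),
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("panel_fx,scheme,dom", MC_CASES)
    def test_mean_and_full_variance_match_simulation(self, panel_fx, scheme, dom, request):
        """Predicted mean and full-model variance agree with Monte-Carlo
        progeny for every scheme family and both ploidies."""
        panel = request.getfixturevalue(panel_fx)
        rng = np.random.default_rng(42)
        a = rng.normal(size=panel.n_loci)
        d = rng.normal(size=panel.n_loci) * 0.5 if dom else np.zeros(panel.n_loci)
        eff = TraitEffects(additive=a, dominance=d)
        cvm = ClassValueMap.heterozygosity(panel.ploidy)
        pred = cp.CrossPredictor(panel, eff, scheme, ld_model="full", cvm=cvm)
        n = 30_000
        for pair in [(0, 1), (3, 4)]:
            fp = pred.predict_pair(*pair)
            sims = inh.simulate_progeny(panel, pair, scheme, n, seed=11)
            sims = sims if isinstance(sims, list) else [sims]
            mus, vars_ = [], []
            for S in sims:
                g = cvm.additive_score[S.astype(np.intp)] @ a + cvm.dominance_score[S.astype(np.intp)] @ d
                mus.append(g.mean())
                vars_.append(g.var(ddof=1))
            mu_t, var_t = np.mean(mus), np.mean(vars_)
            sd_g = np.sqrt(max(var_t, 1e-12))
            assert fp.mean == pytest.approx(mu_t, abs=4 * sd_g / np.sqrt(n) + 1e-9)
            if var_t > 1e-9:
                # variance within ~5% (Monte-Carlo SE of a variance ~ sqrt(2/n))
                assert fp.variance == pytest.approx(var_t, rel=0.06)

    def test_ordering_of_information(self, sim_diploid_small):
        """|predicted - true| SD error: full <= approx <= independent in
        aggregate with true effects on LD-rich data."""
        panel = sim_diploid_small
        rng = np.random.default_rng(13)
        eff = TraitEffects(additive=rng.normal(size=panel.n_loci), dominance=np.zeros(panel.n_loci))
        scheme = CrossScheme("DH")
        idx = np.nonzero(panel.subpop == panel.subpop[0])[0]
        pairs = [tuple(rng.choice(idx, 2, replace=False)) for _ in range(25)]
        truth = []
        for pair in pairs:
            S = inh.simulate_progeny(panel, (int(pair[0]), int(pair[1])), scheme, 3000, seed=17)
            truth.append((S.astype(float) @ eff.additive).std(ddof=1))
        truth = np.array(truth)
        med_err = {}
        for model in ("full", "approx", "independent"):
            pr = cp.CrossPredictor(panel, eff, scheme, ld_model=model)
            sds = np.array([pr.predict_pair(int(k), int(l)).sd for k, l in pairs])
            med_err[model] = np.median(np.abs(sds - truth))
        assert med_err["full"] <= med_err["approx"] + 1e-9
        assert med_err["approx"] <= med_err["independent"] + 1e-9
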