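import math

import numpy as np
import pandas as pd
import pytest

from oracles import anova_moments

from mutnet.ma_quantgen import (
    MATraitTable,
    anova_oneway,
    delta_M,
    mutational_params,
    mutational_variance,
    pairwise_rM,
    reml_multitrait,
    reml_oneway,
    restricted_loglik_oneway,
    rM_matrix,
    scalings,
    shared_mutation_inflation,
    subset_reml_sensitivity,
)


def simulate_groups(rng, q=20, n=4, v_l=2.0, v_e=1.0, balanced=True):
    groups = []
    for _ in range(q):
        n_i = n if balanced else int(rng.integers(2, 6))
        b = rng.normal(0, math.sqrt(v_l))
        groups.append(b + rng.normal(0, math.sqrt(v_e), size=n_i))
    return groups


def two_trait_table(rng, q=20, n=4, slope=2.0, noise=0.3, t=250):
    """Line-level signal in X copied (scaled) into Y plus replicate noise."""
    rows = []
    for li in range(q):
        bx = rng.normal(0, 1.0)
        for rep in range(n):
            x = 10 + bx + rng.normal(0, noise)
            y = 20 + slope * bx + rng.normal(0, noise)
            rows.append(("L%02d" % li, rep, "X", x, False))
            rows.append(("L%02d" % li, rep, "Y", max(y, 1e-3), False))
    for rep in range(5):
        rows.append(("G0", rep, "X", 10 + rng.normal(0, noise), True))
        rows.append(("G0", rep, "Y", 20 + rng.normal(0, noise), True))
    df = pd.DataFrame(rows, columns=["line", "replicate", "metabolite",
                                     "concentration", "is_ancestor"])
    return MATraitTable(data=df, t=t)


class TestDeltaM:
    def test_no_change(self):
        assert delta_M(3.0, 3.0, 250) == (0.0, 0.0)

    def test_hand_values(self):
        dm, dms = delta_M(1.5, 1.0, 250)
        assert dm == pytest.approx(0.002)
        assert dms == pytest.approx(math.log2(1.5))

    def test_doubling_is_unit_log_ratio(self):
        assert delta_M(4.2, 2.1, 100)[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("zma,z0,t", [(0.0, 1.0, 10), (1.0, -1.0, 10), (1.0, 1.0, 0)])
    def test_invalid_inputs(self, zma, z0, t):
        with pytest.raises(ValueError):
            delta_M(zma, z0, t)


class TestREMLOneway:
    def test_degenerate_no_within_variance(self):
        fit = reml_oneway([[1.0, 1.0], [3.0, 3.0]])
        assert fit.v_e == 0.0
        assert fit.v_l == pytest.approx(2.0)  # = (MSB - MSW)/n0 = (4-0)/2

    def test_all_identical(self):
        fit = reml_oneway([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert fit.v_l == 0.0 and fit.v_e == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_balanced_equals_anova(self, seed):
        """On balanced data REML coincides with the ANOVA moment estimator."""
        rng = np.random.default_rng(seed)
        groups = simulate_groups(rng)
        vl_o, ve_o = anova_moments(groups)
        fit = reml_oneway(groups)
        if vl_o >= 0:
            assert fit.v_l == pytest.approx(vl_o, abs=1e-6)
            assert fit.v_e == pytest.approx(ve_o, abs=1e-6)
        assert fit.v_l_anova == pytest.approx(vl_o, rel=1e-9)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_loglik_not_below_anova_fit(self, seed):
        rng = np.random.default_rng(seed)
        groups = simulate_groups(rng, balanced=False)
        fit = reml_oneway(groups)
        vl_o, ve_o = anova_moments(groups)
        if vl_o > 0 and ve_o > 0:
            assert fit.loglik >= restricted_loglik_oneway(groups, vl_o, ve_o) - 1e-9

    def test_negative_moment_estimate_pinned_at_zero(self):
        rng = np.random.default_rng(42)
        # no real line effects, few lines: moment estimate often negative
        for _ in range(20):
            groups = simulate_groups(rng, q=5, v_l=0.0)
            vl_o, _ = anova_moments(groups)
            fit = reml_oneway(groups)
            assert fit.v_l >= 0.0
            if vl_o < -0.05:
                assert fit.boundary and fit.v_l == pytest.approx(0.0, abs=1e-6)

    def test_relabelling_and_order_invariance(self):
        rng = np.random.default_rng(6)
        groups = simulate_groups(rng, balanced=False)
        fit = reml_oneway(groups)
        shuffled = [np.flip(g) for g in reversed(groups)]
        fit2 = reml_oneway(shuffled)
        assert fit2.v_l == pytest.approx(fit.v_l, rel=1e-6)
        assert fit2.v_e == pytest.approx(fit.v_e, rel=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        groups = simulate_groups(rng, balanced=False)
        fit = reml_oneway(groups)
        fit_scaled = reml_oneway([3.0 * g for g in groups])
        assert fit_scaled.v_l == pytest.approx(9.0 * fit.v_l, rel=1e-6)
        assert fit_scaled.v_e == pytest.approx(9.0 * fit.v_e, rel=1e-6)

    def test_all_singleton_lines_error(self):
        with pytest.raises(ValueError):
            reml_oneway([[1.0], [2.0], [3.0]])


class TestVMAndScalings:
    def test_hand_value(self):
        assert mutational_variance(0.05, 0.0, 250) == pytest.approx(1e-4)

    def test_equal_variances_give_zero(self):
        assert mutational_variance(0.3, 0.3, 100) == 0.0

    def test_h2_identity(self):
        i_m, i_e, h2 = scalings(2e-4, 0.05, 3.0)
        assert h2 == pytest.approx(i_m / i_e)

    def test_ve_zero_marks_h2_undefined(self):
        assert math.isnan(scalings(1e-4, 0.0, 1.0)[2])

    def test_mean_must_be_positive(self):
        with pytest.raises(ValueError):
            scalings(1e-4, 0.05, 0.0)


class TestMultitraitREML:
    def test_matches_univariate_on_single_trait(self):
        rng = np.random.default_rng(1)
        groups = simulate_groups(rng, balanced=False)
        uni = reml_oneway(groups)
        multi = reml_multitrait([g[:, None] for g in groups])
        assert multi.among[0, 0] == pytest.approx(uni.v_l, rel=1e-5, abs=1e-8)
        assert multi.within[0, 0] == pytest.approx(uni.v_e, rel=1e-5)

    def test_balanced_matches_manova_moments(self):
        rng = np.random.default_rng(2)
        q, n = 30, 4
        b_true = np.array([[1.0, 0.5], [0.5, 1.5]])
        lb = np.linalg.cholesky(b_true)
        groups = [lb @ rng.normal(size=2) + rng.normal(0, 0.5, size=(n, 2))
                  for _ in range(q)]
        fit = reml_multitrait(groups)
        ybar = np.stack([g.mean(0) for g in groups])
        grand = ybar.mean(0)
        msb = n * (ybar - grand).T @ (ybar - grand) / (q - 1)
        s_w = sum((g - g.mean(0)).T @ (g - g.mean(0)) for g in groups)
        msw = s_w / (q * n - q)
        b_moment = (msb - msw) / n
        assert np.allclose(fit.among, b_moment, atol=1e-6)
        assert np.allclose(fit.within, msw, atol=1e-6)


class TestPairwiseRM:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        table = two_trait_table(rng)
        dup = table.data[table.data["metabolite"] == "X"].copy()
        dup["metabolite"] = "X2"
        t2 = MATraitTable(data=pd.concat([table.data, dup]), t=table.t)
        est = pairwise_rM(t2, "X", "X2")
        assert est.r_m == pytest.approx(1.0)
        assert est.boundary  # perfect correlation sits on the boundary

    def test_strong_line_level_correlation_recovered(self):
        rng = np.random.default_rng(4)
        table = two_trait_table(rng, slope=2.0, noise=0.05)
        est = pairwise_rM(table, "X", "Y")
        assert est.defined and est.r_m > 0.98
        assert est.p_value < 1e-6

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(5)
        table = two_trait_table(rng, slope=1.0, noise=0.2)
        flipped = table.data.copy()
        mask = flipped["metabolite"] == "Y"
        flipped.loc[mask, "concentration"] = 50.0 - flipped.loc[mask, "concentration"]
        t2 = MATraitTable(data=flipped, t=table.t)
        a = pairwise_rM(table, "X", "Y")
        b = pairwise_rM(t2, "X", "Y")
        assert b.r_m == pytest.approx(-a.r_m, abs=1e-4)

    def test_no_line_variance_is_undefined(self):
        rng = np.random.default_rng(6)
        rows = []
        for li in range(10):
            for rep in range(3):
                rows.append((f"L{li}", rep, "X", 10 + rng.normal(0, 0.1), False))
                rows.append((f"L{li}", rep, "Y", 5 + rng.normal(0, 0.1), False))
        df = pd.DataFrame(rows, columns=["line", "replicate", "metabolite",
                                         "concentration", "is_ancestor"])
        est = pairwise_rM(MATraitTable(data=df, t=10), "X", "Y")
        assert not est.defined and math.isnan(est.r_m)


class TestRMMatrix:
    def test_two_traits(self):
        rng = np.random.default_rng(7)
        table = two_trait_table(rng)
        m = rM_matrix(table)
        assert m.r.shape == (2, 2)
        assert m.r.at["X", "X"] == 1.0 and m.r.at["Y", "Y"] == 1.0
        assert m.r.at["X", "Y"] == m.r.at["Y", "X"]
        assert m.n_pairs == 1

    def test_familywise_criterion_scales_with_pairs(self):
        rng = np.random.default_rng(8)
        table = two_trait_table(rng)
        assert rM_matrix(table, alpha=0.05).familywise_alpha == pytest.approx(0.05)
        # 25 traits give 300 pairs and the 0.000167 criterion
        assert 0.05 / math.comb(25, 2) == pytest.approx(0.000167, abs=5e-7)

    def test_symmetry_and_unit_diagonal(self, sim_experiment):
        _, _, table, _ = sim_experiment
        mets = table.metabolites[:5]
        m = rM_matrix(table, metabolites=mets)
        r = m.r.to_numpy()
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)
        assert m.n_pairs == 10
        defined = ~np.isnan(r)
        assert np.all(np.abs(r[defined]) <= 1.0)


class TestSubsetREMLSensitivity:
    def test_determinism_and_singleton(self, sim_experiment):
        _, _, table, _ = sim_experiment
        pair = ("M001", "M002")
        one = subset_reml_sensitivity(table, pair, n_fill=3, n_reps=1, seed=5)
        again = subset_reml_sensitivity(table, pair, n_fill=3, n_reps=1, seed=5)
        assert one.samples.size + one.n_dropped == 1
        assert np.array_equal(one.samples, again.samples)

    def test_median_near_pairwise_point_estimate(self, sim_experiment):
        _, _, table, _ = sim_experiment
        res = subset_reml_sensitivity(table, ("M001", "M003"), n_fill=4,
                                      n_reps=20, seed=9)
        assert res.samples.size >= 15
        assert abs(res.median - res.point_estimate) < 0.15

    def test_requires_enough_fill_traits(self, sim_experiment):
        _, _, table, _ = sim_experiment
        with pytest.raises(ValueError):
            subset_reml_sensitivity(table, ("M001", "M002"), n_fill=50, n_reps=1)


class TestSharedMutationInflation:
    @pytest.mark.parametrize("n,x,expected", [
        (43, 2, 43 / 42),
        (43, 1, 1.0),          # one line "sharing" means no sharing
        (10, 10, 10.0),        # all lines identical
        (5, 0, 5 / 6),         # documented < 1 edge case
    ])
    def test_bound_values(self, n, x, expected):
        assert shared_mutation_inflation(n, x) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shared_mutation_inflation(5, 6)
        with pytest.raises(ValueError):
            shared_mutation_inflation(0, 0)


class TestMutationalParams:
    def test_table_identities(self, sim_experiment):
        _, cfg, table, _ = sim_experiment
        params = mutational_params(table)
        assert set(params.index) == set(table.metabolites)
        ok = params["V_E"] > 0
        assert np.allclose(params.loc[ok, "h2_M"],
                           params.loc[ok, "I_M"] / params.loc[ok, "I_E"])
        assert np.allclose(params["V_M"], params["V_L"] / (2 * cfg.t))
        # ΔM* and ΔM agree in sign
        sgn = np.sign(params["delta_M"]) == np.sign(params["delta_M_star"])
        assert sgn.all()

    def test_scale_invariance_of_dimensionless_params(self, sim_experiment):
        _, _, table, _ = sim_experiment
        scaled = table.data.copy()
        scaled["concentration"] *= 7.0
        p1 = mutational_params(table)
        p2 = mutational_params(MATraitTable(data=scaled, t=table.t))
        for col in ("delta_M", "delta_M_star", "h2_M", "I_M", "I_E"):
            assert np.allclose(p1[col], p2[col], rtol=1e-8, equal_nan=True), col
        assert np.allclose(p2["V_L"], 49.0 * p1["V_L"], rtol=1e-6)


class TestTraitTableValidation:
    def test_rejects_single_replicate_lines(self):
        df = pd.DataFrame({
            "line": ["L1", "L1", "L2"], "replicate": [1, 2, 1],
            "metabolite": ["X"] * 3, "concentration": [1.0, 1.1, 0.9],
            "is_ancestor": [False] * 3,
        })
        with pytest.raises(ValueError, match="L2"):
            MATraitTable(data=df, t=100)

    def test_rejects_nonpositive_concentration(self):
        df = pd.DataFrame({
            "line": ["L1", "L1"], "replicate": [1, 2],
            "metabolite": ["X", "X"], "concentration": [1.0, -0.5],
            "is_ancestor": [False, False],
        })
        with pytest.raises(ValueError, match="positive"):
            MATraitTable(data=df, t=100)

    def test_tsv_round_trip(self, tmp_path, sim_experiment):
        _, _, table, _ = sim_experiment
        p = tmp_path / "traits.tsv"
        table.to_tsv(p, header_comment="round trip")
        back = MATraitTable.from_tsv(p, t=table.t)
        assert len(back.data) == len(table.data)
        assert back.metabolites == table.metabolites
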