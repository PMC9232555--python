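"""Gating-model unit and property tests: rate-matrix structure, binomial
equilibrium of the binding chain, the detailed-balance closed form for the
steady open probability, monotonicity in PIP2, and the stochastic oracle."""

from dataclasses import replace
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trpgate as tg
from trpgate.gating import OPEN, beta_of_dag, build_rate_matrix
from trpgate.signaling import LipidTimecourse


def closed_form_po(params, pip2, dag):
    """Independent oracle: detailed-balance weights of the binding chain
    (binomial in x = pip2/Kd) with the open state weighted theta relative
    to its gateway closed state."""
    x = pip2 / params.kd_pip2
    beta = beta_of_dag(params, dag)
    theta = beta / params.alpha if params.alpha > 0 else np.inf
    w = np.array([comb(4, i) * x ** i for i in range(5)], dtype=float)
    gate_w = w[4] if params.polarity == "supportive" else w[0]
    return gate_w * theta / (w.sum() + gate_w * theta)


class TestRateMatrix:
    def test_structure_and_row_sums(self):
        p = tg.GatingParams()
        Q = build_rate_matrix(p, pip2_uM=3.0, dag_uM=50.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        # binding chain stoichiometry
        for i in range(4):
            assert Q[i, i + 1] == pytest.approx((4 - i) * p.k_on * 3.0)
            assert Q[i + 1, i] == pytest.approx((i + 1) * p.k_off)
        assert Q[4, OPEN] == pytest.approx(beta_of_dag(p, 50.0))
        assert Q[OPEN, 4] == pytest.approx(p.alpha)
        assert Q[0, OPEN] == 0.0

    def test_inhibitory_mode_opens_from_empty_chain(self):
        p = tg.GatingParams(polarity="inhibitory")
        Q = build_rate_matrix(p, 3.0, 50.0)
        assert Q[0, OPEN] > 0 and Q[OPEN, 0] == p.alpha
        assert Q[4, OPEN] == 0.0

    def test_no_ligand_means_no_binding(self):
        p = tg.GatingParams()
        Q = build_rate_matrix(p, 0.0, 50.0)
        for i in range(4):
            assert Q[i, i + 1] == 0.0
            assert Q[i + 1, i] > 0.0

    @pytest.mark.parametrize("field,value", [("pip2_uM", -1.0), ("dag_uM", -0.5)])
    def test_negative_concentration_rejected(self, field, value):
        kw = {"pip2_uM": 1.0, "dag_uM": 1.0, field: value}
        with pytest.raises(ValueError, match=field):
            build_rate_matrix(tg.GatingParams(), **kw)

    def test_invalid_params_name_offending_field(self):
        with pytest.raises(ValueError, match="alpha"):
            tg.GatingParams(alpha=-1.0)
        with pytest.raises(ValueError, match="dag_hill"):
            tg.GatingParams(dag_hill=0.0)
        with pytest.raises(ValueError, match="polarity"):
            tg.GatingParams(polarity="both")


class TestSteadyState:
    @pytest.mark.parametrize("ratio", [0.1, 1.0, 3.0, 10.0])
    def test_binding_chain_is_binomial_without_opening(self, ratio):
        """With beta_max = 0 the subunits bind independently, so the chain
        occupancy is Binomial(4, L/(L+Kd))."""
        p = tg.GatingParams(beta_max=0.0)
        L = ratio * p.kd_pip2
        ss = tg.steady_state(p, L, 50.0)
        q = L / (L + p.kd_pip2)
        expected = [comb(4, i) * q ** i * (1 - q) ** (4 - i) for i in range(5)]
        assert np.allclose(ss.occupancy[:5], expected, atol=1e-8)
        assert ss.po == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_po_grid(self):
        """Steady Po matches the detailed-balance expression on a 5x5 grid
        of (x = pip2/Kd, theta = beta/alpha)."""
        for x in [0.2, 0.5, 1.0, 4.0, 12.5]:
            for theta in [0.1, 0.5, 1.0, 2.0, 10.0]:
                p = replace(tg.GatingParams(), beta_max=theta * 20.0,
                            alpha=20.0, dag_hill=1.0, dag_ec50=1e-9)
                # dag >> ec50 so beta == beta_max and theta is exact
                ss = tg.steady_state(p, x * p.kd_pip2, 1.0)
                assert ss.po == pytest.approx(closed_form_po(p, x * p.kd_pip2, 1.0),
                                              abs=1e-8)

    def test_po_monotone_in_pip2_both_polarities(self):
        ladder = [0.1, 0.5, 1.0, 2.0, 5.0, 20.0, 100.0]
        for polarity, sign in [("supportive", 1), ("inhibitory", -1)]:
            p = tg.GatingParams(polarity=polarity)
            po = [tg.steady_state(p, c, 50.0).po for c in ladder]
            diffs = sign * np.diff(po)
            assert np.all(diffs >= -1e-12), (polarity, po)

    def test_inhibitory_po_vanishes_at_saturating_pip2(self):
        p = tg.GatingParams(polarity="inhibitory")
        assert tg.steady_state(p, 1e6, 50.0).po < 1e-6

    def test_disconnected_chain_flagged_degenerate(self):
        """pip2 = 0 with beta = alpha = 0 leaves the open state
        disconnected: the stationary distribution is not unique and the
        result is flagged, not raised."""
        p = tg.GatingParams(beta_max=0.0, alpha=0.0)
        ss = tg.steady_state(p, 0.0, 0.0)
        assert ss.degenerate
        # still a valid distribution
        assert ss.occupancy.sum() == pytest.approx(1.0)

    def test_absorbing_c0_without_ligand(self):
        p = tg.GatingParams(beta_max=0.0)
        ss = tg.steady_state(p, 0.0, 0.0)
        assert not ss.degenerate
        assert ss.occupancy[0] == pytest.approx(1.0, abs=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(pip2=st.floats(0.0, 100.0), dag=st.floats(0.0, 200.0),
       k_on=st.floats(0.1, 20.0), k_off=st.floats(0.1, 200.0),
       theta_beta=st.floats(0.0, 100.0))
def test_generator_matrix_properties(pip2, dag, k_on, k_off, theta_beta):
    """Any valid parameter set yields a proper generator: nonnegative
    off-diagonal rates, zero row sums, and a normalized stationary vector."""
    p = tg.GatingParams(k_on=k_on, k_off=k_off, beta_max=theta_beta)
    Q = build_rate_matrix(p, pip2, dag)
    off = Q - np.diag(Q.diagonal())
    assert np.all(off >= 0)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-9 * max(1.0, np.abs(Q).max()))
    ss = tg.steady_state(p, pip2, dag)
    assert ss.occupancy.sum() == pytest.approx(1.0, abs=1e-9)


class TestSimulateGating:
    def test_constant_lipids_converge_to_steady_state(self):
        p = tg.GatingParams()
        ss = tg.steady_state(p, 6.0, 50.0)
        lip = LipidTimecourse.constant(6.0, 50.0, t_end_s=5.0, n=200)
        start = np.eye(6)[0]
        res = tg.simulate_gating(p, lip, p0=start)
        assert res.po[-1] == pytest.approx(ss.po, abs=1e-6)
        # occupancy conservation at every sample
        assert np.allclose(res.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_step_depletion_decreases_po_monotonically(self):
        p = tg.GatingParams()
        t = np.linspace(0, 2, 400)
        lip = LipidTimecourse(t, np.zeros_like(t), np.full_like(t, 50.0))
        p0 = tg.steady_state(p, 18.0, 50.0).occupancy
        res = tg.simulate_gating(p, lip, p0=p0)
        assert np.all(np.diff(res.po) <= 1e-10)
        assert res.po[-1] < 0.01 * res.po[0]

    def test_time_grid_must_increase(self):
        p = tg.GatingParams()
        with pytest.raises(ValueError, match="strictly increasing"):
            tg.simulate_gating(p, LipidTimecourse(np.array([0.0, 1.0]),
                                                  np.array([1.0, 1.0]),
                                                  np.array([0.0, 0.0])),
                               sample_times=np.array([0.0, 0.5, 0.5]))


class TestGillespieOracle:
    def test_matches_ode_within_three_se(self):
        """Mean occupancy of 10^4 stochastic channels agrees with the
        master-equation solution at every checkpoint."""
        p = tg.GatingParams(k_on=2.0, k_off=4.0, beta_max=10.0, alpha=5.0)
        lip = LipidTimecourse.constant(2.0, 50.0, t_end_s=1.0, n=21)
        n_ch = 10_000
        start = np.eye(6)[0]
        t, occ = tg.gillespie_oracle(p, lip, n_ch, seed=7, p0=start)
        res = tg.simulate_gating(p, lip, p0=start)
        po_ode = res.po
        se = np.sqrt(np.maximum(po_ode * (1 - po_ode), 1e-12) / n_ch)
        # skip t=0 where both are exactly the start state
        assert np.all(np.abs(occ[1:, 5] - po_ode[1:]) <= 3 * se[1:] + 1e-9)

    def test_single_channel_absorbed_without_ligand(self):
        p = tg.GatingParams(beta_max=0.0)
        lip = LipidTimecourse.constant(0.0, 0.0, t_end_s=1.0, n=11)
        t, occ = tg.gillespie_oracle(p, lip, 1, seed=1, p0=np.eye(6)[0])
        assert np.all(occ[:, 0] == 1.0)

    def test_same_seed_is_reproducible(self):
        p = tg.GatingParams()
        lip = LipidTimecourse.constant(2.0, 50.0, t_end_s=0.3, n=16)
        a = tg.gillespie_oracle(p, lip, 200, seed=42)[1]
        b = tg.gillespie_oracle(p, lip, 200, seed=42)[1]
        assert np.array_equal(a, b)
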