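"""Trafficking-model unit tests: vector field, integration, bookkeeping."""

import numpy as np
import pytest

from sirnatraffic import (
    HOUR,
    N_AVOGADRO,
    Protocol,
    SystemState,
    TraffickingParams,
    derivatives,
    initial_state,
    mass_balance_residual,
    set_free_fraction,
    silencing_readout,
    simulate,
    uptake_timecourse,
)
from sirnatraffic.model import SPECIES, _rhs


def vec(state):
    return state.to_vector()


class TestDerivatives:
    def test_unperturbed_cell_is_a_fixed_point(self, params):
        """No siRNA/carrier anywhere + reporter at steady state => zero derivative."""
        m0 = params.k_txn / params.k_deg_m
        p0 = params.k_tln * m0 / params.k_deg_p
        state = SystemState(
            s_x=0, c_x=0, x_x=0, r=params.R_tot, rc=0, rx=0,
            s_e=0, c_e=0, x_e=0, s_c=0, c_c=0, x_c=0,
            risc_a=0, mrna=m0, protein=p0, d_sink=0,
        )
        dy = vec(derivatives(state, params))
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_single_reaction_limit_pure_complex_dissociation(self):
        """With receptor binding and pinocytosis off, an extracellular
        complex pool only dissociates: dX/dt = -koff_s * X."""
        p = TraffickingParams(kon_r=0.0, k_pino=0.0)
        m0 = p.k_txn / p.k_deg_m
        p0 = p.k_tln * m0 / p.k_deg_p
        state = SystemState(
            s_x=0, c_x=0, x_x=2e-9, r=p.R_tot, rc=0, rx=0,
            s_e=0, c_e=0, x_e=0, s_c=0, c_c=0, x_c=0,
            risc_a=0, mrna=m0, protein=p0, d_sink=0,
        )
        dy = derivatives(state, p)
        assert dy.x_x == pytest.approx(-p.koff_s * 2e-9, rel=1e-12)
        assert dy.s_x == pytest.approx(p.koff_s * 2e-9, rel=1e-12)
        assert dy.c_x == pytest.approx(p.koff_s * 2e-9, rel=1e-12)
        others = [dy.rc, dy.rx, dy.s_e, dy.c_e, dy.x_e, dy.s_c, dy.c_c,
                  dy.x_c, dy.risc_a, dy.d_sink]
        assert np.allclose(others, 0.0, atol=1e-15)

    def test_matches_independent_flux_enumeration(self, params, rng):
        """The vector field equals the sum over a hand-enumerated reaction
        table (rate law + stoichiometry per reaction), evaluated at random
        valid states."""
        p = params.with_(k_pino=1e-14, k_dil=0.0)
        f = p.percell_to_molar
        kon_e = p.kon_s / (N_AVOGADRO * p.V_endo)
        kon_c = p.kon_s / (N_AVOGADRO * p.V_cyt)

        def flux_table(s):
            # (rate, {species: stoichiometry}); extracellular stoich in M,
            # per-cell stoich in molecules, conversions via f
            pino = p.k_pino * N_AVOGADRO
            return [
                (p.kon_s * s["s_x"] * s["c_x"],
                 {"s_x": -1, "c_x": -1, "x_x": +1}),
                (p.koff_s * s["x_x"], {"s_x": +1, "c_x": +1, "x_x": -1}),
                (p.kon_r * s["c_x"] * s["r"],
                 {"c_x": -f, "r": -1, "rc": +1}),
                (p.koff_r * s["rc"], {"c_x": +f, "r": +1, "rc": -1}),
                (p.kon_r * s["x_x"] * s["r"],
                 {"x_x": -f, "r": -1, "rx": +1}),
                (p.koff_r * s["rx"], {"x_x": +f, "r": +1, "rx": -1}),
                (p.kon_cmp * s["cmp_x"] * s["r"],
                 {"cmp_x": -f, "r": -1, "r_cmp": +1}),
                (p.koff_cmp * s["r_cmp"], {"cmp_x": +f, "r": +1, "r_cmp": -1}),
                (p.k_int * s["rc"], {"rc": -1, "r": +1, "c_e": +1}),
                (p.k_int * s["rx"], {"rx": -1, "r": +1, "x_e": +1}),
                (p.k_int * s["r_cmp"], {"r_cmp": -1, "r": +1}),
                (pino * s["s_x"], {"s_x": -f, "s_e": +1}),
                (pino * s["c_x"], {"c_x": -f, "c_e": +1}),
                (pino * s["x_x"], {"x_x": -f, "x_e": +1}),
                (kon_e * s["s_e"] * s["c_e"],
                 {"s_e": -1, "c_e": -1, "x_e": +1}),
                (p.koff_s * s["x_e"], {"s_e": +1, "c_e": +1, "x_e": -1}),
                (p.k_esc * s["s_e"], {"s_e": -1, "s_c": +1}),
                (p.k_esc * s["c_e"], {"c_e": -1, "c_c": +1}),
                (p.k_esc * s["x_e"], {"x_e": -1, "x_c": +1}),
                (p.k_deg_endo * s["s_e"], {"s_e": -1, "d_sink": +1}),
                (p.k_deg_endo * s["c_e"], {"c_e": -1}),
                (p.k_deg_endo * s["x_e"], {"x_e": -1, "d_sink": +1}),
                (kon_c * s["s_c"] * s["c_c"],
                 {"s_c": -1, "c_c": -1, "x_c": +1}),
                (p.koff_s * s["x_c"], {"s_c": +1, "c_c": +1, "x_c": -1}),
                (p.k_deg_s_cyt * s["s_c"], {"s_c": -1, "d_sink": +1}),
                (p.k_deg_c_cyt * s["c_c"], {"c_c": -1}),
                (p.k_deg_x_cyt * s["x_c"], {"x_c": -1, "d_sink": +1}),
                (p.k_load * s["s_c"] * (p.RISC_tot - s["risc_a"]),
                 {"s_c": -1, "risc_a": +1}),
                (p.k_risc_decay * s["risc_a"], {"risc_a": -1, "d_sink": +1}),
                (p.k_txn, {"mrna": +1}),
                (p.k_deg_m * s["mrna"], {"mrna": -1}),
                (p.k_slice * s["risc_a"] * s["mrna"], {"mrna": -1}),
                (p.k_tln * s["mrna"], {"protein": +1}),
                (p.k_deg_p * s["protein"], {"protein": -1}),
            ]

        for _ in range(20):
            raw = {}
            for name in SPECIES:
                if name in ("s_x", "c_x", "x_x", "cmp_x"):
                    raw[name] = rng.uniform(0, 2e-8)
                elif name in ("d_sink", "w_sink"):
                    raw[name] = 0.0
                else:
                    raw[name] = rng.uniform(0, 1e5)
            raw["risc_a"] = rng.uniform(0, p.RISC_tot)
            # enforce receptor conservation
            occ = rng.uniform(0, p.R_tot, size=3)
            occ *= rng.uniform(0, 1) * p.R_tot / max(occ.sum(), 1.0)
            raw["rc"], raw["rx"], raw["r_cmp"] = occ
            raw["r"] = p.R_tot - occ.sum()

            expected = dict.fromkeys(SPECIES, 0.0)
            for rate, stoich in flux_table(raw):
                for name, coef in stoich.items():
                    expected[name] += rate * coef
            got = _rhs(0.0, np.array([raw[n] for n in SPECIES]), p)
            want = np.array([expected[n] for n in SPECIES])
            scale = np.maximum(np.abs(want), 1e-30)
            assert np.all(np.abs(got - want) <= 1e-9 * scale + 1e-20)

    def test_rejects_negative_state(self, params):
        state = initial_state(Protocol(), params)
        bad = SystemState(**{**state.__dict__, "s_e": -1e3})
        with pytest.raises(ValueError, match="negative"):
            derivatives(bad, params)

    def test_rejects_nonfinite_parameter(self):
        with pytest.raises(ValueError, match="finite"):
            TraffickingParams(k_esc=float("nan"))


class TestSimulate:
    def test_zero_dose_is_inert(self, control_trajectory):
        traj = control_trajectory
        assert traj["protein"][-1] / traj["protein"][0] == pytest.approx(
            1.0, abs=1e-9)
        for name in ("s_x", "x_x", "s_e", "x_e", "s_c", "x_c", "risc_a"):
            assert np.all(traj[name] == 0.0)

    def test_no_escape_means_no_silencing(self, params, protocol):
        p = params.with_(k_esc=0.0)
        traj = simulate(protocol, p)
        control = simulate(protocol.with_(dose=0.0), p)
        assert np.all(traj["s_c"] == 0)
        assert np.all(traj["x_c"] == 0)
        assert np.all(traj["risc_a"] == 0)
        assert silencing_readout(traj, control) == pytest.approx(1.0, abs=1e-6)

    def test_media_swap_zeroes_extracellular_pools(self, params, protocol):
        """At the swap the medium is replaced: extracellular pools drop to
        zero (then only regrow marginally by dissociation of surface-bound
        material) and the removed siRNA is booked into the wash-out sink."""
        t_swap = protocol.t_transfect
        grid = np.array([0.0, t_swap, t_swap + 1.0, protocol.t_obs])
        traj = simulate(protocol, params)
        fine = simulate(protocol, params, grid)
        pre_x, post_x = fine["x_x"][1], fine["x_x"][2]
        assert post_x < 1e-3 * pre_x
        assert fine["s_x"][2] < 1e-3 * fine["s_x"][1]
        f = params.percell_to_molar
        washed = (fine["s_x"][1] + fine["x_x"][1]) / f
        assert fine["w_sink"][2] == pytest.approx(washed, rel=1e-9)
        assert np.all(traj["w_sink"][traj.times <= t_swap] == 0.0)

    def test_receptor_conservation_at_every_time(self, default_trajectory):
        traj = default_trajectory
        total = traj["r"] + traj["rc"] + traj["rx"] + traj["r_cmp"]
        assert np.max(np.abs(total - traj.params.R_tot)) <= 1e-6 * traj.params.R_tot

    def test_states_stay_nonnegative(self, default_trajectory):
        assert np.all(default_trajectory.states >= 0.0)

    def test_grid_validation(self, params, protocol):
        with pytest.raises(ValueError, match="within"):
            simulate(protocol, params, np.array([0.0, protocol.t_obs + 1.0]))
        with pytest.raises(ValueError, match="increasing"):
            simulate(protocol, params, np.array([0.0, 10.0, 10.0]))

    def test_preequilibrated_start_matches_quadratic_loading(self, params):
        proto = Protocol(dose=20e-9)
        s0 = initial_state(proto, params)
        free = set_free_fraction(20e-9, 20e-9, params.KD_s)
        assert s0.x_x == pytest.approx(20e-9 * (1 - free), rel=1e-12)
        assert s0.s_x == pytest.approx(20e-9 * free, rel=1e-12)

    def test_silencing_readout_matches_fixed_step_rk4(self, params):
        """The stiff-solver readout agrees with an independent fixed-step
        RK4 re-integration of the same vector field. The dose saturates
        the response; the step resolves the fastest cytoplasmic rate
        (RISC loading, ~1 s^-1)."""
        proto = Protocol(dose=2e-10)
        traj = simulate(proto, params)
        control = simulate(proto.with_(dose=0.0), params)
        readout = silencing_readout(traj, control)
        assert readout < 0.5  # saturating dose silences

        idx = {n: i for i, n in enumerate(SPECIES)}

        def rk4(p, protocol, dt=1.0):
            y = initial_state(protocol, p).to_vector()
            t = 0.0
            swapped = not protocol.media_swap
            while t < protocol.t_obs - 1e-9:
                if not swapped and t >= protocol.t_transfect - 1e-9:
                    f = p.percell_to_molar
                    y[idx["w_sink"]] += (y[idx["s_x"]] + y[idx["x_x"]]) / f
                    for nm in ("s_x", "c_x", "x_x", "cmp_x"):
                        y[idx[nm]] = 0.0
                    swapped = True
                h = min(dt, protocol.t_obs - t)
                if not swapped:
                    h = min(h, protocol.t_transfect - t)
                k1 = _rhs(t, y, p)
                k2 = _rhs(t, y + h / 2 * k1, p)
                k3 = _rhs(t, y + h / 2 * k2, p)
                k4 = _rhs(t, y + h * k3, p)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            return y[idx["protein"]]

        p_treated = rk4(params, proto)
        p_control = rk4(params, proto.with_(dose=0.0))
        assert readout == pytest.approx(p_treated / p_control, abs=1e-4)


class TestObservables:
    def test_uptake_counts_intact_intracellular_sirna(self, default_trajectory):
        traj = default_trajectory
        expected = (traj["s_e"] + traj["x_e"] + traj["s_c"] + traj["x_c"]
                    + traj["risc_a"])
        assert np.array_equal(uptake_timecourse(traj), expected)

    def test_uptake_zero_without_escape_route_to_cytoplasm(self, params, protocol):
        p = params.with_(k_esc=0.0)
        traj = simulate(protocol, p)
        series = uptake_timecourse(traj)
        assert np.array_equal(series, traj["s_e"] + traj["x_e"])

    def test_uptake_nondecreasing_during_exposure_without_degradation(self, params):
        p = params.with_(k_deg_endo=0.0, k_deg_s_cyt=0.0, k_deg_x_cyt=0.0,
                         k_deg_c_cyt=0.0, k_risc_decay=0.0)
        proto = Protocol(dose=50e-9, media_swap=False,
                         t_transfect=6 * HOUR, t_obs=6 * HOUR)
        traj = simulate(proto, p, np.linspace(0, 6 * HOUR, 49))
        series = uptake_timecourse(traj)
        assert np.all(np.diff(series) >= -1e-6 * series.max())

    def test_mass_balance_zero_dose_convention(self, control_trajectory):
        assert mass_balance_residual(control_trajectory) == 0.0

    def test_degenerate_control_raises(self, params, protocol, default_trajectory):
        p = params.with_(k_tln=0.0)
        control = simulate(protocol.with_(dose=0.0), p)
        with pytest.raises(ValueError, match="degenerate control"):
            silencing_readout(default_trajectory, control)


class TestProtocolValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(dose=-1e-9), dict(competitor_conc=-1.0),
         dict(t_transfect=0.0), dict(t_transfect=25 * HOUR)],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Protocol(**kwargs)
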