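"""Spiking network: connectivity, assemblies, OB drive, integration, binning."""

import numpy as np
import pandas as pd
import pytest

from pdpmanifold import (
    NeuronParams,
    SynapseParams,
    bin_to_activity,
    build_connectivity,
    default_panel,
    generate_mitral_patterns,
    generate_ob_spike_trains,
    rewire_assemblies,
    select_assembly,
    simulate,
)
from pdpmanifold.network import (
    Connectivity,
    PopulationParams,
    SpikeRecord,
    WEIGHT_PRESETS,
    bin_spikes,
)


def zero_p():
    return {k: 0.0 for k in SynapseParams().p}


# -------------------------------------------------------------- connectivity
class TestBuildConnectivity:
    def test_zero_probability_yields_no_edges(self):
        conn = build_connectivity({"exc": 5, "inh": 3, "ob": 4},
                                  SynapseParams(p=zero_p()), seed=0)
        assert all(c == 0 for c in conn.edge_counts().values())

    def test_full_probability_complete_graph_minus_self_edges(self):
        sp = SynapseParams(p={k: 1.0 for k in zero_p()})
        conn = build_connectivity({"exc": 3, "inh": 3, "ob": 3}, sp, seed=0)
        counts = conn.edge_counts()
        assert counts[("exc", "exc")] == 3 * 3 - 3    # no self-edges
        assert counts[("inh", "inh")] == 3 * 3 - 3
        assert counts[("ob", "exc")] == 3 * 3          # cross-population: all
        conn.validate()

    def test_edge_count_matches_binomial_oracle(self):
        """p = 0.1 on 300x300: counts within 4 SD of Binomial over 10 seeds."""
        p, n = 0.1, 300
        sp = SynapseParams(p={**zero_p(), ("ob", "exc"): p})
        mean = p * n * n
        sd = np.sqrt(n * n * p * (1 - p))
        for seed in range(10):
            conn = build_connectivity({"exc": n, "inh": 1, "ob": n}, sp, seed=seed)
            assert abs(conn.edge_count(("ob", "exc")) - mean) < 4 * sd

    def test_reproducible_given_seed(self):
        a = build_connectivity({"exc": 50, "inh": 20, "ob": 30}, seed=7)
        b = build_connectivity({"exc": 50, "inh": 20, "ob": 30}, seed=7)
        for pair in a.weights:
            assert np.array_equal(a.weights[pair], b.weights[pair])

    def test_weights_equal_configured_setting(self):
        conn = build_connectivity({"exc": 40, "inh": 10, "ob": 20}, seed=1)
        W = conn.weights[("ob", "exc")]
        vals = np.unique(W[W != 0])
        assert np.allclose(vals, WEIGHT_PRESETS["A"][("ob", "exc")])


class TestSelectAssembly:
    def test_hand_built_toy_graph_with_ties(self):
        """In-degrees (3,2,2,1,0,0); top-2 are the degree-3 neuron and the
        lower-indexed degree-2 neuron."""
        conn = build_connectivity({"exc": 6, "inh": 2, "ob": 4},
                                  SynapseParams(p=zero_p()), seed=0)
        W = np.zeros((4, 6), dtype=np.float32)
        W[:3, 0] = 1; W[:2, 1] = 1; W[:2, 2] = 1; W[:1, 3] = 1
        conn.weights[("ob", "exc")] = W * 128
        asm = select_assembly(conn, np.array([0, 1, 2, 3]), n_E=2, n_I=1)
        assert list(asm.e_members) == [0, 1]

    def test_all_excitatory_selected_when_requested(self):
        conn = build_connectivity({"exc": 10, "inh": 4, "ob": 8}, seed=0)
        asm = select_assembly(conn, np.arange(8), n_E=10, n_I=2)
        assert list(asm.e_members) == list(range(10))

    def test_matches_brute_force_indegree_sort(self):
        conn = build_connectivity({"exc": 200, "inh": 50, "ob": 100}, seed=3)
        up = np.arange(0, 100, 2)
        asm = select_assembly(conn, up, n_E=20, n_I=5)
        counts = np.count_nonzero(conn.weights[("ob", "exc")][up], axis=0)
        order = sorted(range(200), key=lambda i: (-counts[i], i))
        assert set(asm.e_members) == set(order[:20])

    def test_oversized_request_fails(self):
        conn = build_connectivity({"exc": 10, "inh": 4, "ob": 8}, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            select_assembly(conn, np.arange(8), n_E=11, n_I=2)


class TestRewireAssemblies:
    @pytest.fixture
    def conn_asm(self):
        conn = build_connectivity({"exc": 150, "inh": 40, "ob": 100}, seed=2)
        asm = select_assembly(conn, np.arange(50), n_E=30, n_I=10)
        return conn, asm

    def test_factor_one_is_identity(self, conn_asm):
        conn, asm = conn_asm
        out = rewire_assemblies(conn, [asm], enhancement_factor=1.0, seed=0)
        for pair in conn.weights:
            assert np.array_equal(out.weights[pair], conn.weights[pair])

    def test_within_assembly_count_multiplied_totals_conserved(self, conn_asm):
        conn, asm = conn_asm
        factor = 2.0
        before = conn.edge_counts()
        sub = conn.weights[("exc", "exc")][np.ix_(asm.e_members, asm.e_members)]
        within_before = int(np.count_nonzero(sub))
        out = rewire_assemblies(conn, [asm], factor, seed=1)
        sub_after = out.weights[("exc", "exc")][np.ix_(asm.e_members, asm.e_members)]
        assert int(np.count_nonzero(sub_after)) == round(within_before * factor)
        assert out.edge_counts() == before          # exact conservation
        out.validate()

    def test_degree_distribution_outside_assembly_unchanged(self, conn_asm):
        conn, asm = conn_asm
        out = rewire_assemblies(conn, [asm], 2.0, seed=3)
        outside = np.setdiff1d(np.arange(150), asm.e_members)
        W0 = conn.weights[("exc", "exc")]
        W1 = out.weights[("exc", "exc")]
        # edges among non-assembly neurons are never touched
        assert np.array_equal(W0[np.ix_(outside, outside)],
                              W1[np.ix_(outside, outside)])

    def test_infeasible_factor_reports_counts(self, conn_asm):
        conn, asm = conn_asm
        with pytest.raises(ValueError, match="edges"):
            rewire_assemblies(conn, [asm], 50.0, seed=0)


# ------------------------------------------------------------------ OB input
class TestOBSpikeTrains:
    @pytest.fixture(scope="class")
    def pattern(self):
        return generate_mitral_patterns(1500, default_panel(), seed=1)

    def test_baseline_rate_without_odor(self, pattern):
        """Population rest rate stays at the 6 Hz baseline."""
        rec = generate_ob_spike_trains(pattern, None, duration=10.0, seed=0)
        rate = rec.rate(1500)
        se = np.sqrt(6.0 / (1500 * 10.0))
        assert abs(rate - 6.0) < 3 * se

    def test_zero_rate_produces_no_spikes(self, pattern):
        silent = generate_mitral_patterns(
            100, default_panel(), n_up=10, n_down=5, baseline_rate=0.0,
            up_delta=0.0, down_delta=0.0, seed=0,
        )
        rec = generate_ob_spike_trains(silent, None, duration=5.0, seed=1)
        assert rec.n_spikes == 0

    def test_poisson_count_statistics(self):
        """One cell at 100 Hz for 1 s: count mean ~ 100, variance ~ 100."""
        panel = default_panel()
        pat = generate_mitral_patterns(
            20, panel, n_up=2, n_down=1, baseline_rate=100.0,
            up_delta=0.0, down_delta=0.0, seed=0,
        )
        counts = [
            np.sum(generate_ob_spike_trains(pat, None, 1.0, seed=s).neuron_ids == 0)
            for s in range(1000)
        ]
        assert np.mean(counts) == pytest.approx(100, abs=3 * np.sqrt(100 / 1000))
        assert np.var(counts, ddof=1) == pytest.approx(100, rel=0.2)

    def test_odor_window_modulates_up_and_down_cells(self, pattern):
        rec = generate_ob_spike_trains(pattern, "A1", 4.0, seed=2,
                                       odor_onset=1.0, odor_offset=3.0)
        up = pattern.up["A1"]
        down = pattern.down["A1"]
        in_odor = (rec.times >= 1.0) & (rec.times < 3.0)
        up_rate = np.isin(rec.neuron_ids[in_odor], up).sum() / len(up) / 2.0
        down_rate = np.isin(rec.neuron_ids[in_odor], down).sum() / len(down) / 2.0
        assert up_rate == pytest.approx(36.0, rel=0.1)
        assert down_rate == pytest.approx(0.0, abs=0.5)


# ---------------------------------------------------------------- integration
class TestSimulate:
    def test_unconnected_network_at_rest_stays_at_rest(self):
        conn = build_connectivity({"exc": 3, "inh": 2, "ob": 1},
                                  SynapseParams(p=zero_p()), seed=0)
        rec = simulate(conn, NeuronParams(), SynapseParams(p=zero_p()),
                       None, duration=0.2, record_traces=[0])
        assert rec.n_spikes == 0
        assert np.allclose(rec.traces[0]["V"], NeuronParams().exc.E_rest)

    def test_subthreshold_step_matches_rc_closed_form(self):
        """V relaxes with tau = C / g_rest; trace within 1% of closed form."""
        npar = NeuronParams(
            exc=PopulationParams(C=120.0, g_rest=2.5, E_rest=-66.0,
                                 V_th=-50.0, V_reset=-66.0, refractory=5.0),
            a=0.0, b=0.0,
        )
        sp = SynapseParams(p=zero_p())
        conn = build_connectivity({"exc": 1, "inh": 1, "ob": 1}, sp, seed=0)
        tau_m = npar.exc.tau_m                    # ms
        dt = 0.01 * tau_m / 1000.0                # s
        I = 20.0                                  # pA, subthreshold (8 mV)
        rec = simulate(conn, npar, sp, None, duration=0.4, dt=dt,
                       i_ext=np.array([I, 0.0]), record_traces=[0])
        V = rec.traces[0]["V"]
        t_ms = (np.arange(len(V)) + 1) * dt * 1000
        closed = npar.exc.E_rest + (I / npar.exc.g_rest) * (1 - np.exp(-t_ms / tau_m))
        assert np.max(np.abs(V - closed)) / (I / npar.exc.g_rest) < 0.01

    def test_single_epsc_conductance_matches_exponential(self):
        """After one presynaptic spike the conductance decays as w e^{-t/tau}."""
        sp = SynapseParams(p={**zero_p(), ("ob", "exc"): 1.0})
        conn = build_connectivity({"exc": 1, "inh": 1, "ob": 1}, sp, seed=0)
        npar = NeuronParams(a=0.0, b=0.0)
        w = sp.weights[("ob", "exc")] * 1e-3      # nS
        t_spk = 0.05
        ob = SpikeRecord(np.array([0]), np.array([t_spk]), duration=0.3,
                         n_neurons=1)
        dt = 1e-4
        rec = simulate(conn, npar, sp, ob, duration=0.3, dt=dt,
                       record_traces=[0])
        g = rec.traces[0]["g_ob"]
        t = (np.arange(len(g)) + 1) * dt
        tau = sp.tau_syn["ob"] / 1000.0
        jump_t = np.floor(t_spk / dt) * dt
        mask = t > t_spk + 1e-3
        closed = w * np.exp(-(t[mask] - jump_t) / tau)
        assert np.max(np.abs(g[mask] - closed)) / w < 0.01
        assert g.max() == pytest.approx(w, rel=0.01)

    def test_bit_identical_given_same_inputs(self):
        panel = default_panel()
        ident = pd.DataFrame(np.eye(6), index=panel.odor_ids,
                             columns=panel.odor_ids)
        pat = generate_mitral_patterns(300, panel, n_up=40, n_down=20,
                                       target_correlation=ident, seed=0)
        conn = build_connectivity({"exc": 50, "inh": 12, "ob": 300}, seed=4)
        ob = generate_ob_spike_trains(pat, "A1", 0.5, seed=9, odor_onset=0.1)
        r1 = simulate(conn, None, None, ob, duration=0.5)
        r2 = simulate(conn, None, None, ob, duration=0.5)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.neuron_ids, r2.neuron_ids)

    def test_refractory_period_respected(self):
        panel = default_panel()
        ident = pd.DataFrame(np.eye(6), index=panel.odor_ids,
                             columns=panel.odor_ids)
        pat = generate_mitral_patterns(300, panel, n_up=40, n_down=20,
                                       target_correlation=ident,
                                       baseline_rate=30.0, seed=0)
        conn = build_connectivity({"exc": 50, "inh": 12, "ob": 300},
                                  SynapseParams(
                                      p={**zero_p(), ("ob", "exc"): 0.3}),
                                  seed=4)
        ob = generate_ob_spike_trains(pat, None, 1.0, seed=2)
        rec = simulate(conn, None, SynapseParams(
            p={**zero_p(), ("ob", "exc"): 0.3}), ob, duration=1.0)
        rec.validate(refractory_s=NeuronParams().exc.refractory / 1000.0)

    def test_too_coarse_dt_rejected(self):
        conn = build_connectivity({"exc": 2, "inh": 2, "ob": 2},
                                  SynapseParams(p=zero_p()), seed=0)
        with pytest.raises(ValueError, match="dt"):
            simulate(conn, None, None, None, duration=0.01, dt=5e-3)


class TestBinning:
    def test_five_spikes_in_100ms_bin_is_50_hz(self):
        rec = SpikeRecord(np.zeros(5, dtype=int),
                          np.array([0.01, 0.03, 0.05, 0.07, 0.09]),
                          duration=0.2, n_neurons=2)
        out = bin_spikes(rec, 0.1, (0.0, 0.2), 2)
        assert out[0, 0] == pytest.approx(50.0)
        assert out[0, 1] == 0.0

    def test_no_spikes_all_zero(self):
        rec = SpikeRecord(np.empty(0, dtype=int), np.empty(0), 1.0, n_neurons=3)
        assert np.all(bin_spikes(rec, 0.1, (0.0, 1.0), 3) == 0)

    def test_tensor_totals_equal_event_counts(self, rng):
        """Random record: binned totals match the event table exactly."""
        n, dur = 30, 2.0
        ids = rng.integers(0, n, size=500)
        times = rng.random(500) * dur
        rec = SpikeRecord(ids, times, dur, n_neurons=n)
        out = bin_spikes(rec, 0.25, (0.5, 1.5), n)
        sel = (times >= 0.5) & (times < 1.5)
        assert out.sum() * 0.25 == pytest.approx(sel.sum())

    def test_assembled_tensor_shape_and_panel(self):
        panel = default_panel()
        recs = {
            o: [SpikeRecord(np.array([0, 1]), np.array([0.05, 0.15]), 0.4,
                            n_neurons=10) for _ in range(2)]
            for o in panel.odor_ids
        }
        ds = bin_to_activity(recs, 0.1, (0.0, 0.4), panel, n_exc=8)
        assert ds.rates.shape == (8, 4, 2, 6)
        assert ds.provenance == "simulated"

    def test_bin_width_must_divide_window(self):
        rec = SpikeRecord(np.empty(0, dtype=int), np.empty(0), 1.0, n_neurons=2)
        with pytest.raises(ValueError, match="divide"):
            bin_spikes(rec, 0.3, (0.0, 1.0), 2)
        with pytest.raises(ValueError, match="window"):
            bin_spikes(rec, 0.1, (0.5, 0.5), 2)


class TestIntegrationConvergence:
    def test_halving_dt_changes_rates_less_than_two_percent(self):
        """Population rate converged at the default 0.1 ms step."""
        panel = default_panel()
        pat = generate_mitral_patterns(1500, panel, seed=1)
        conn = build_connectivity(seed=0)
        ob = generate_ob_spike_trains(pat, "A1", 1.0, seed=5, odor_onset=0.2)
        r1 = simulate(conn, None, None, ob, duration=1.0, dt=1e-4)
        r2 = simulate(conn, None, None, ob, duration=1.0, dt=5e-5)
        rate1 = r1.n_spikes / 1.0
        rate2 = r2.n_spikes / 1.0
        assert rate1 > 50            # network actually active
        assert abs(rate1 - rate2) / rate2 < 0.02


class TestConnectivityIO:
    def test_edge_list_round_trip_with_assemblies(self, tmp_path):
        conn = build_connectivity({"exc": 60, "inh": 20, "ob": 40}, seed=5)
        asm = select_assembly(conn, np.arange(20), n_E=10, n_I=4, odor="A1")
        conn.assemblies.append(asm)
        conn.save(tmp_path / "net")
        back = Connectivity.load(tmp_path / "net")
        assert back.sizes == conn.sizes
        for pair in conn.weights:
            assert np.array_equal(back.weights[pair], conn.weights[pair])
        assert back.assemblies[0].odor == "A1"
        assert np.array_equal(back.assemblies[0].e_members, asm.e_members)
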