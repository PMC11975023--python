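"""Spiking network model of zebrafish pDp.

A conductance-based network of adaptive leaky integrate-and-fire neurons:
1000 excitatory (E) and 250 inhibitory (I) neurons receiving input from
1500 excitatory mitral cells of the olfactory bulb (OB), modeled as
rate-modulated Poisson sources.  Membrane dynamics per neuron x of
population X:

    C_X dV/dt = g_rest,X (E_rest,X - V) + g_OB (E_exc - V)
                + sum_P g_P (E_P - V) - z * 1{X = exc}

with spike-frequency adaptation z (excitatory neurons only) relaxing with
tau_ad, drifting with a (V - E_rest) and jumping by b after each spike.
Synaptic conductances decay exponentially with tau_syn,P and jump by the
synaptic weight w_yx on presynaptic spikes.  Connections are Bernoulli
with probability p_XY and uniform strength w_XY; the four published weight
settings ship as presets A-D.

Odor memories are stored structurally as E/I assemblies: the 100 E neurons
most strongly connected to the odor's activated mitral cells, and the 25 I
neurons most strongly connected to that E-assembly, are rewired to a
higher within/between connection count while conserving the total edge
count per projection.

Integration uses exponential Euler for the conductance and adaptation
decay and forward Euler for the membrane potential (default dt 0.1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import ActivityDataset
from .panel import OdorPanel
from .synthetic import MitralPatternSet

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "Connectivity",
    "SpikeRecord",
    "Assembly",
    "WEIGHT_PRESETS",
    "DEFAULT_SIZES",
    "build_connectivity",
    "select_assembly",
    "rewire_assemblies",
    "generate_ob_spike_trains",
    "simulate",
    "bin_spikes",
    "bin_to_activity",
    "PDpNetwork",
]


# Published weight-strength settings (pS) for the juvenile-scale network.
WEIGHT_PRESETS = {
    "A": {("exc", "exc"): 95, ("inh", "exc"): 410, ("ob", "exc"): 128,
          ("exc", "inh"): 58, ("ob", "inh"): 68, ("inh", "inh"): 180},
    "B": {("exc", "exc"): 94, ("inh", "exc"): 400, ("ob", "exc"): 128,
          ("exc", "inh"): 58, ("ob", "inh"): 66, ("inh", "inh"): 150},
    "C": {("exc", "exc"): 80, ("inh", "exc"): 450, ("ob", "exc"): 128,
          ("exc", "inh"): 68, ("ob", "inh"): 68, ("inh", "inh"): 220},
    "D": {("exc", "exc"): 95, ("inh", "exc"): 520, ("ob", "exc"): 95,
          ("exc", "inh"): 51, ("ob", "inh"): 42, ("inh", "inh"): 190},
}

PROJECTIONS = [
    ("exc", "exc"), ("inh", "exc"), ("ob", "exc"),
    ("exc", "inh"), ("ob", "inh"), ("inh", "inh"),
]

DEFAULT_SIZES = {"exc": 1000, "inh": 250, "ob": 1500}


@dataclass(frozen=True)
class PopulationParams:
    """Single-population membrane parameters (pF, nS, mV, ms)."""

    C: float              # membrane capacitance, pF
    g_rest: float         # leak conductance, nS
    E_rest: float         # resting potential, mV
    V_th: float           # spike threshold, mV
    V_reset: float        # reset potential, mV
    refractory: float     # ms

    def __post_init__(self):
        if self.C <= 0 or self.g_rest <= 0:
            raise ValueError("C and g_rest must be positive")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must lie below V_th")

    @property
    def tau_m(self) -> float:
        """Membrane time constant, ms."""
        return self.C / self.g_rest


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters for both populations plus excitatory adaptation.

    Defaults are package defaults calibrated for the juvenile-scale
    network (the source model's values are external); override via config.
    """

    exc: PopulationParams = PopulationParams(
        C=120.0, g_rest=2.5, E_rest=-66.0, V_th=-50.0, V_reset=-66.0,
        refractory=5.0,
    )
    inh: PopulationParams = PopulationParams(
        C=100.0, g_rest=4.0, E_rest=-66.0, V_th=-52.0, V_reset=-66.0,
        refractory=2.0,
    )
    # adaptation (excitatory only)
    a: float = 0.5        # nS, subthreshold adaptation
    b: float = 10.0       # pA, spike-triggered increment
    tau_ad: float = 200.0  # ms

    def __post_init__(self):
        if self.tau_ad <= 0:
            raise ValueError("tau_ad must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Reversal potentials, synaptic time constants, connectivity statistics.

    ``weights`` maps (pre, post) population pairs to strengths in pS;
    ``p`` maps the same pairs to Bernoulli connection probabilities.
    """

    E_exc: float = 0.0      # mV
    E_inh: float = -70.0    # mV
    tau_syn: dict = field(
        default_factory=lambda: {"exc": 20.0, "inh": 10.0, "ob": 10.0}   # ms
    )
    p: dict = field(
        default_factory=lambda: {
            ("exc", "exc"): 0.05, ("inh", "exc"): 0.08, ("ob", "exc"): 0.04,
            ("exc", "inh"): 0.06, ("ob", "inh"): 0.10, ("inh", "inh"): 0.10,
        }
    )
    weights: dict = field(default_factory=lambda: dict(WEIGHT_PRESETS["A"]))

    def __post_init__(self):
        for k, v in self.tau_syn.items():
            if v <= 0:
                raise ValueError(f"tau_syn[{k}] must be positive")
        for k, v in self.p.items():
            if not 0 <= v <= 1:
                raise ValueError(f"p[{k}] must be in [0, 1]")
        for k, v in self.weights.items():
            if v < 0:
                raise ValueError(f"weights[{k}] must be nonnegative")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SynapseParams":
        return cls(weights=dict(WEIGHT_PRESETS[name]), **overrides)


@dataclass
class Assembly:
    """E/I assembly membership for one stored odor."""

    odor: str
    e_members: np.ndarray
    i_members: np.ndarray


@dataclass
class Connectivity:
    """Directed weighted connectivity over the E/I/OB populations.

    Weights are stored as dense (n_pre, n_post) matrices per projection;
    every existing edge carries exactly the configured w_XY of its pair.
    """

    sizes: dict
    weights: dict                 # (pre, post) -> (n_pre, n_post) float32
    w_settings: dict              # (pre, post) -> pS
    assemblies: list = field(default_factory=list)

    def edge_count(self, pair) -> int:
        return int(np.count_nonzero(self.weights[pair]))

    def edge_counts(self) -> dict:
        return {pair: self.edge_count(pair) for pair in self.weights}

    def validate(self) -> None:
        for (pre, post), W in self.weights.items():
            if pre == post:
                if np.any(np.diag(W) != 0):
                    raise ValueError(f"self-edges present in {pre}->{post}")
            vals = np.unique(W[W != 0])
            w = self.w_settings[(pre, post)]
            if vals.size and not np.allclose(vals, w):
                raise ValueError(
                    f"{pre}->{post} edges deviate from configured {w} pS"
                )

    def copy(self) -> "Connectivity":
        return Connectivity(
            dict(self.sizes),
            {k: v.copy() for k, v in self.weights.items()},
            dict(self.w_settings),
            [replace(a, e_members=a.e_members.copy(),
                     i_members=a.i_members.copy()) for a in self.assemblies],
        )

    def to_frame(self) -> pd.DataFrame:
        """Edge-list export: pre_id, post_id, weight_pS, pair_type."""
        rows = []
        for (pre, post), W in self.weights.items():
            ii, jj = np.nonzero(W)
            rows.append(
                pd.DataFrame(
                    {
                        "pre_id": ii,
                        "post_id": jj,
                        "weight_pS": W[ii, jj],
                        "pair_type": f"{pre}->{post}",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        """Edge-list CSV plus a sizes/assembly sidecar (JSON)."""
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path / "edges.csv", index=False)
        meta = {
            "sizes": self.sizes,
            "w_settings": {f"{a}->{b}": w for (a, b), w in self.w_settings.items()},
            "assemblies": [
                {"odor": a.odor, "e_members": a.e_members.tolist(),
                 "i_members": a.i_members.tolist()}
                for a in self.assemblies
            ],
        }
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "Connectivity":
        import json
        from pathlib import Path

        path = Path(path)
        edges = pd.read_csv(path / "edges.csv")
        meta = json.loads((path / "meta.json").read_text())
        sizes = meta["sizes"]
        w_settings = {
            tuple(k.split("->")): w for k, w in meta["w_settings"].items()
        }
        weights = {
            pair: np.zeros((sizes[pair[0]], sizes[pair[1]]), dtype=np.float32)
            for pair in w_settings
        }
        for pair_name, sub in edges.groupby("pair_type"):
            pair = tuple(pair_name.split("->"))
            weights[pair][sub["pre_id"], sub["post_id"]] = sub["weight_pS"]
        assemblies = [
            Assembly(a["odor"], np.array(a["e_members"]), np.array(a["i_members"]))
            for a in meta["assemblies"]
        ]
        return cls(sizes, weights, w_settings, assemblies)


def build_connectivity(
    sizes: dict | None = None,
    synapse_params: SynapseParams | None = None,
    seed: int = 0,
) -> Connectivity:
    """Independent Bernoulli(p_XY) connections with strength w_XY, no self-edges."""
    sizes = dict(sizes or DEFAULT_SIZES)
    sp = synapse_params or SynapseParams()
    if any(n <= 0 for n in sizes.values()):
        raise ValueError("population sizes must be positive")
    rng = np.random.default_rng(seed)
    weights = {}
    for pre, post in PROJECTIONS:
        p = sp.p[(pre, post)]
        w = sp.weights[(pre, post)]
        mask = rng.random((sizes[pre], sizes[post])) < p
        if pre == post:
            np.fill_diagonal(mask, False)
        weights[(pre, post)] = mask.astype(np.float32) * np.float32(w)
    return Connectivity(sizes, weights, dict(sp.weights))


def _top_k_by_indegree(W_sub: np.ndarray, k: int) -> np.ndarray:
    """Top-k columns by incoming-edge count; ties broken by lowest index."""
    counts = np.count_nonzero(W_sub, axis=0)
    order = np.argsort(-counts, kind="stable")
    return np.sort(order[:k])


def select_assembly(
    conn: Connectivity,
    up_cells: np.ndarray,
    n_E: int = 100,
    n_I: int = 25,
    odor: str = "",
) -> Assembly:
    """E-assembly: top-n_E E neurons by input count from the odor's activated
    mitral cells; I-assembly: top-n_I I neurons by input count from the
    E-assembly.  Ties resolve to the lower neuron index.
    """
    if n_E > conn.sizes["exc"] or n_I > conn.sizes["inh"]:
        raise ValueError(
            f"requested assembly ({n_E} E, {n_I} I) exceeds population sizes"
        )
    e_members = _top_k_by_indegree(conn.weights[("ob", "exc")][up_cells, :], n_E)
    i_members = _top_k_by_indegree(conn.weights[("exc", "inh")][e_members, :], n_I)
    return Assembly(odor, e_members, i_members)


def rewire_assemblies(
    conn: Connectivity,
    assemblies: list,
    enhancement_factor: float = 4.0,
    seed: int = 0,
) -> Connectivity:
    """Multiply within-E-assembly and E<->I-assembly connection counts by
    ``enhancement_factor``; eliminate an equal number of edges between
    non-assembly and assembly neurons of the same projection, keeping the
    total edge count per projection exactly constant.
    """
    if enhancement_factor < 1:
        raise ValueError("enhancement_factor must be >= 1")
    out = conn.copy()
    rng = np.random.default_rng(seed)
    for asm in assemblies:
        blocks = [
            (("exc", "exc"), asm.e_members, asm.e_members),
            (("exc", "inh"), asm.e_members, asm.i_members),
            (("inh", "exc"), asm.i_members, asm.e_members),
        ]
        for pair, pre_set, post_set in blocks:
            W = out.weights[pair]
            w = np.float32(out.w_settings[pair])
            sub = W[np.ix_(pre_set, post_set)]
            same_pop = pair[0] == pair[1]
            if same_pop:
                self_mask = pre_set[:, None] == post_set[None, :]
            else:
                self_mask = np.zeros(sub.shape, dtype=bool)
            existing = (sub != 0) & ~self_mask
            c = int(existing.sum())
            target = int(round(c * enhancement_factor))
            n_add = target - c
            absent = (sub == 0) & ~self_mask
            free = np.argwhere(absent)
            if n_add > len(free):
                raise ValueError(
                    f"{pair}: need {n_add} new edges but only {len(free)} "
                    f"absent eligible pairs in the assembly block"
                )
            pick = free[rng.choice(len(free), size=n_add, replace=False)]
            W[pre_set[pick[:, 0]], post_set[pick[:, 1]]] = w
            # removal pool: edges from non-assembly neurons onto assembly
            # neurons, so assembly in-degree and the rest of the network
            # stay unchanged while the total count is conserved
            pre_in = np.zeros(conn.sizes[pair[0]], dtype=bool)
            pre_in[pre_set] = True
            post_in = np.zeros(conn.sizes[pair[1]], dtype=bool)
            post_in[post_set] = True
            boundary = (~pre_in[:, None]) & post_in[None, :]
            cand = np.argwhere((W != 0) & boundary)
            if n_add > len(cand):
                raise ValueError(
                    f"{pair}: need to remove {n_add} boundary edges but only "
                    f"{len(cand)} exist"
                )
            drop = cand[rng.choice(len(cand), size=n_add, replace=False)]
            W[drop[:, 0], drop[:, 1]] = 0.0
        out.assemblies.append(asm)
    return out


# --------------------------------------------------------------------------
# OB Poisson drive
# --------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """Spike events (neuron id, time in s) plus optional state traces."""

    neuron_ids: np.ndarray
    times: np.ndarray            # s, sorted
    duration: float              # s
    dt: float | None = None      # s, integration step if simulated
    n_neurons: int | None = None
    traces: dict = field(default_factory=dict)   # neuron id -> dict of arrays

    def __post_init__(self):
        order = np.argsort(self.times, kind="stable")
        self.times = np.asarray(self.times, dtype=float)[order]
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def rate(self, n_neurons: int | None = None) -> float:
        """Population mean firing rate, Hz."""
        n = n_neurons or self.n_neurons
        return self.n_spikes / (n * self.duration)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def validate(self, refractory_s: float = 0.0) -> None:
        if np.any(self.times < 0) or np.any(self.times > self.duration):
            raise ValueError("spike times outside [0, duration]")
        for n in np.unique(self.neuron_ids):
            t = self.spikes_of(n)
            if len(t) > 1 and np.min(np.diff(t)) < refractory_s - 1e-12:
                raise ValueError(f"neuron {n}: inter-spike gap below refractory")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids, "t_s": self.times})


def generate_ob_spike_trains(
    pattern: MitralPatternSet,
    odor: str | None,
    duration: float,
    seed: int = 0,
    odor_onset: float = 0.0,
    odor_offset: float | None = None,
    dt: float | None = None,
) -> SpikeRecord:
    """Inhomogeneous Poisson mitral spike trains.

    Rates sit at the baseline outside the odor interval and at the odor's
    up/down-modulated pattern (floored at 0) within it.  ``odor=None``
    keeps the baseline throughout.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = pattern.n_mitral
    base = np.full(n, max(pattern.baseline_rate, 0.0))
    if odor is None:
        segments = [(0.0, duration, base)]
    else:
        off = duration if odor_offset is None else min(odor_offset, duration)
        on = min(max(odor_onset, 0.0), off)
        segments = [
            (0.0, on, base),
            (on, off, pattern.rate_vector(odor)),
            (off, duration, base),
        ]
    ids, times = [], []
    for t0, t1, rates in segments:
        span = t1 - t0
        if span <= 0:
            continue
        counts = rng.poisson(rates * span)
        tot = int(counts.sum())
        if tot == 0:
            continue
        ids.append(np.repeat(np.arange(n), counts))
        times.append(t0 + rng.random(tot) * span)
    if ids:
        ids, times = np.concatenate(ids), np.concatenate(times)
    else:
        ids, times = np.empty(0, dtype=int), np.empty(0)
    return SpikeRecord(ids, times, duration, dt=dt, n_neurons=n)


# --------------------------------------------------------------------------
# Integration
# --------------------------------------------------------------------------

def _spikes_per_step(record: SpikeRecord, dt_ms: float, n_steps: int):
    """Sorted spike-step indices and ids for fast per-step lookup."""
    steps = np.floor(record.times * 1000.0 / dt_ms).astype(int)
    keep = steps < n_steps
    steps, ids = steps[keep], record.neuron_ids[keep]
    order = np.argsort(steps, kind="stable")
    return steps[order], ids[order]


def simulate(
    conn: Connectivity,
    neuron_params: NeuronParams | None = None,
    synapse_params: SynapseParams | None = None,
    ob_spikes: SpikeRecord | None = None,
    duration: float = 1.0,         # s
    dt: float = 1e-4,              # s (0.1 ms)
    i_ext: np.ndarray | None = None,   # pA per neuron (E then I), constant
    record_traces: list | None = None,  # global neuron ids (E: 0..nE-1, I: nE..)
    v_init: np.ndarray | None = None,
) -> SpikeRecord:
    """Integrate the network; deterministic given (connectivity, inputs, dt).

    Exponential Euler for conductance/adaptation decay, forward Euler for
    V.  Spikes reset V to V_reset, hold through the refractory period and
    increment the adaptation current (E cells).  Aborts with a diagnostic
    if any membrane potential leaves the physically possible range.
    """
    np_ = neuron_params or NeuronParams()
    sp = synapse_params or SynapseParams()
    dt_ms = dt * 1000.0
    min_tau = min(
        np_.exc.tau_m, np_.inh.tau_m, np_.tau_ad, *sp.tau_syn.values()
    )
    if dt_ms > min_tau / 10:
        raise ValueError(
            f"dt = {dt_ms} ms too coarse for smallest time constant {min_tau} ms"
        )
    nE, nI = conn.sizes["exc"], conn.sizes["inh"]
    n_steps = int(round(duration / dt))
    W_ee = conn.weights[("exc", "exc")] * 1e-3   # pS -> nS
    W_ie = conn.weights[("inh", "exc")] * 1e-3
    W_oe = conn.weights[("ob", "exc")] * 1e-3
    W_ei = conn.weights[("exc", "inh")] * 1e-3
    W_oi = conn.weights[("ob", "inh")] * 1e-3
    W_ii = conn.weights[("inh", "inh")] * 1e-3

    dec = {k: np.exp(-dt_ms / tau) for k, tau in sp.tau_syn.items()}
    V_e = np.full(nE, np_.exc.E_rest) if v_init is None else v_init[:nE].copy()
    V_i = np.full(nI, np_.inh.E_rest) if v_init is None else v_init[nE:].copy()
    z = np.zeros(nE)
    g_oe = np.zeros(nE); g_ee = np.zeros(nE); g_ie = np.zeros(nE)
    g_oi = np.zeros(nI); g_ei = np.zeros(nI); g_ii = np.zeros(nI)
    refr_e = np.zeros(nE, dtype=int)
    refr_i = np.zeros(nI, dtype=int)
    ref_steps_e = max(int(round(np_.exc.refractory / dt_ms)), 1)
    ref_steps_i = max(int(round(np_.inh.refractory / dt_ms)), 1)
    iext_e = np.zeros(nE) if i_ext is None else np.asarray(i_ext[:nE], float)
    iext_i = np.zeros(nI) if i_ext is None else np.asarray(i_ext[nE:], float)

    if ob_spikes is not None:
        ob_steps, ob_ids = _spikes_per_step(ob_spikes, dt_ms, n_steps)
    else:
        ob_steps = np.empty(0, dtype=int); ob_ids = ob_steps
    ob_ptr = 0

    v_floor = min(sp.E_inh, np_.exc.E_rest, np_.exc.V_reset,
                  np_.inh.E_rest, np_.inh.V_reset) - 30.0
    v_ceil = max(sp.E_exc, np_.exc.V_th, np_.inh.V_th) + 30.0

    spike_ids, spike_steps = [], []
    prev_e = np.empty(0, dtype=int)
    prev_i = np.empty(0, dtype=int)
    trace_ids = list(record_traces or [])
    traces = {
        gid: {"V": np.empty(n_steps), "g_exc": np.empty(n_steps),
              "g_inh": np.empty(n_steps), "g_ob": np.empty(n_steps),
              "z": np.empty(n_steps)}
        for gid in trace_ids
    }

    for k in range(n_steps):
        # conductance decay + synaptic input from last step's spikes
        g_oe *= dec["ob"]; g_oi *= dec["ob"]
        g_ee *= dec["exc"]; g_ei *= dec["exc"]
        g_ie *= dec["inh"]; g_ii *= dec["inh"]
        lo = ob_ptr
        while ob_ptr < len(ob_steps) and ob_steps[ob_ptr] == k:
            ob_ptr += 1
        if ob_ptr > lo:
            ids = ob_ids[lo:ob_ptr]
            g_oe += W_oe[ids].sum(axis=0)
            g_oi += W_oi[ids].sum(axis=0)
        if prev_e.size:
            g_ee += W_ee[prev_e].sum(axis=0)
            g_ei += W_ei[prev_e].sum(axis=0)
        if prev_i.size:
            g_ie += W_ie[prev_i].sum(axis=0)
            g_ii += W_ii[prev_i].sum(axis=0)

        # adaptation (E only): exponential decay + subthreshold drift
        z += dt_ms * (np_.a * (V_e - np_.exc.E_rest) - z) / np_.tau_ad

        # membrane update (forward Euler), frozen during refractoriness
        I_e = (np_.exc.g_rest * (np_.exc.E_rest - V_e)
               + (g_oe + g_ee) * (sp.E_exc - V_e)
               + g_ie * (sp.E_inh - V_e) - z + iext_e)
        I_i = (np_.inh.g_rest * (np_.inh.E_rest - V_i)
               + (g_oi + g_ei) * (sp.E_exc - V_i)
               + g_ii * (sp.E_inh - V_i) + iext_i)
        active_e = refr_e == 0
        active_i = refr_i == 0
        V_e[active_e] += dt_ms * I_e[active_e] / np_.exc.C
        V_i[active_i] += dt_ms * I_i[active_i] / np_.inh.C
        refr_e[~active_e] -= 1
        refr_i[~active_i] -= 1

        sp_e = np.flatnonzero(V_e >= np_.exc.V_th)
        sp_i = np.flatnonzero(V_i >= np_.inh.V_th)
        if sp_e.size:
            V_e[sp_e] = np_.exc.V_reset
            refr_e[sp_e] = ref_steps_e
            z[sp_e] += np_.b
            spike_ids.append(sp_e)
            spike_steps.append(np.full(sp_e.size, k))
        if sp_i.size:
            V_i[sp_i] = np_.inh.V_reset
            refr_i[sp_i] = ref_steps_i
            spike_ids.append(sp_i + nE)
            spike_steps.append(np.full(sp_i.size, k))
        prev_e, prev_i = sp_e, sp_i

        for gid in trace_ids:
            if gid < nE:
                tr = traces[gid]
                tr["V"][k] = V_e[gid]; tr["g_exc"][k] = g_ee[gid]
                tr["g_inh"][k] = g_ie[gid]; tr["g_ob"][k] = g_oe[gid]
                tr["z"][k] = z[gid]
            else:
                j = gid - nE
                tr = traces[gid]
                tr["V"][k] = V_i[j]; tr["g_exc"][k] = g_ei[j]
                tr["g_inh"][k] = g_ii[j]; tr["g_ob"][k] = g_oi[j]
                tr["z"][k] = 0.0

        if k % 200 == 0:
            if (V_e.min() < v_floor or V_i.min() < v_floor
                    or V_e.max() > v_ceil or V_i.max() > v_ceil):
                raise RuntimeError(
                    f"numerical blow-up at t = {k * dt_ms:.2f} ms: membrane "
                    f"potential outside [{v_floor}, {v_ceil}] mV; reduce dt"
                )

    if spike_ids:
        ids = np.concatenate(spike_ids)
        times = (np.concatenate(spike_steps) + 1) * dt
    else:
        ids, times = np.empty(0, dtype=int), np.empty(0)
    return SpikeRecord(
        ids, times, duration, dt=dt, n_neurons=nE + nI, traces=traces
    )


# --------------------------------------------------------------------------
# Binning to the activity tensor
# --------------------------------------------------------------------------

def bin_spikes(
    record: SpikeRecord,
    bin_width: float,
    window: tuple,
    n_neurons: int,
) -> np.ndarray:
    """Spike counts / bin_width (Hz) per neuron per bin within ``window`` (s)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty analysis window")
    n_bins = (t1 - t0) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    n_bins = int(round(n_bins))
    sel = (record.times >= t0) & (record.times < t1)
    bins = np.floor((record.times[sel] - t0) / bin_width).astype(int)
    bins = np.minimum(bins, n_bins - 1)
    out = np.zeros((n_neurons, n_bins))
    np.add.at(out, (record.neuron_ids[sel], bins), 1.0)
    return out / bin_width


def bin_to_activity(
    records_by_odor: dict,
    bin_width: float,
    window: tuple,
    panel: OdorPanel,
    n_exc: int,
) -> ActivityDataset:
    """Assemble trial-wise spike records into the standard activity tensor.

    Only excitatory neurons enter (assembly and non-assembly alike).
    ``records_by_odor`` maps every panel odor to its list of per-trial
    :class:`SpikeRecord` objects.
    """
    missing = [o for o in panel.odor_ids if o not in records_by_odor]
    if missing:
        raise ValueError(f"missing spike records for odors: {missing}")
    n_trials = len(records_by_odor[panel.odor_ids[0]])
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_width))
    rates = np.zeros((n_exc, n_bins, n_trials, panel.n_odors))
    for k, odor in enumerate(panel.odor_ids):
        recs = records_by_odor[odor]
        if len(recs) != n_trials:
            raise ValueError("inconsistent trial count across odors")
        for tr, rec in enumerate(recs):
            n_total = rec.n_neurons or n_exc
            binned = bin_spikes(rec, bin_width, window, n_total)[:n_exc]
            rates[:, :, tr, k] = binned
    return ActivityDataset(
        rates=rates,
        frame_rate=1.0 / bin_width,
        panel=panel,
        onset_time=0.0,
        provenance="simulated",
    )


# --------------------------------------------------------------------------
# Network facade
# --------------------------------------------------------------------------

class PDpNetwork:
    """The pDp model as a mechanistic model object.

    Build with a weight preset and seed, optionally store odor memories
    (E/I assemblies), then simulate odor responses into an
    :class:`ActivityDataset` ready for the manifold analytics.
    """

    def __init__(
        self,
        preset: str = "A",
        sizes: dict | None = None,
        neuron_params: NeuronParams | None = None,
        synapse_params: SynapseParams | None = None,
        seed: int = 0,
    ):
        self.neuron_params = neuron_params or NeuronParams()
        self.synapse_params = synapse_params or SynapseParams.preset(preset)
        self.sizes = dict(sizes or DEFAULT_SIZES)
        self.seed = seed
        self.connectivity = build_connectivity(
            self.sizes, self.synapse_params, seed
        )

    def store_memories(
        self,
        pattern: MitralPatternSet,
        odors: list,
        n_E: int = 100,
        n_I: int = 25,
        enhancement_factor: float = 4.0,
    ) -> "PDpNetwork":
        """Return a copy of the network with E/I assemblies for ``odors``."""
        assemblies = [
            select_assembly(self.connectivity, pattern.up[o], n_E, n_I, odor=o)
            for o in odors
        ]
        new = PDpNetwork.__new__(PDpNetwork)
        new.neuron_params = self.neuron_params
        new.synapse_params = self.synapse_params
        new.sizes = dict(self.sizes)
        new.seed = self.seed
        new.connectivity = rewire_assemblies(
            self.connectivity, assemblies, enhancement_factor, seed=self.seed
        )
        return new

    def simulate_odor(
        self,
        pattern: MitralPatternSet,
        odor: str | None,
        duration: float,
        odor_onset: float = 0.5,
        seed: int = 0,
        dt: float = 1e-4,
        **kwargs,
    ) -> SpikeRecord:
        ob = generate_ob_spike_trains(
            pattern, odor, duration, seed=seed, odor_onset=odor_onset
        )
        return simulate(
            self.connectivity, self.neuron_params, self.synapse_params,
            ob, duration, dt, **kwargs,
        )

    def simulate_panel(
        self,
        pattern: MitralPatternSet,
        panel: OdorPanel,
        n_trials: int = 4,
        response_window: float = 2.0,
        odor_onset: float = 0.5,
        bin_width: float = 0.1,
        seed: int = 0,
        dt: float = 1e-4,
    ) -> ActivityDataset:
        """Simulate the full odor panel and bin to the activity tensor.

        The analysis window covers ``response_window`` seconds starting at
        odor onset, binned at ``bin_width`` (default 100 ms), over
        ``n_trials`` trials per odor; only excitatory neurons are kept.
        """
        ss = np.random.SeedSequence([seed, self.seed])
        duration = odor_onset + response_window
        records = {}
        for odor in panel.odor_ids:
            trials = []
            for tr in range(n_trials):
                s = int(ss.generate_state(1)[0] % 2**31)
                trials.append(
                    self.simulate_odor(
                        pattern, odor, duration, odor_onset, seed=s, dt=dt
                    )
                )
            records[odor] = trials
        return bin_to_activity(
            records, bin_width, (odor_onset, duration), panel,
            self.sizes["exc"],
        )
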