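"""Synthetic stand-ins for the study's raw data.

Two generators live here:

* :func:`generate_mitral_patterns` builds olfactory-bulb input patterns for
  the spiking simulator — per-odor sets of up- and down-modulated mitral
  cells whose rate-vector Pearson correlations match a target odor-by-odor
  correlation matrix (modest correlation within a chemical class, none
  across classes).
* :func:`generate_imaging_dataset` emulates the structure of the imaging
  data that the analytics consume: sparse nonnegative population responses
  with a phasic-tonic time course, high trial-to-trial variability, and
  configurable manifold geometry (center separation and cosine, covariance
  shape and elongation), with a "trained" regime that applies a directional
  amplification to the conditioned odors.

Correlations between odors are realized structurally, by sharing a
controlled block of cells between correlated odors rather than by mixing
noise, which keeps rates nonnegative and the realized correlation exactly
computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import ActivityDataset
from .panel import OdorPanel, default_panel

__all__ = [
    "MitralPatternSet",
    "generate_mitral_patterns",
    "PhasicTonicParams",
    "phasic_tonic_profile",
    "GeometrySpec",
    "generate_imaging_dataset",
    "default_target_correlation",
    "naive_spec",
    "trained_spec",
]


# --------------------------------------------------------------------------
# Mitral-cell input patterns
# --------------------------------------------------------------------------

@dataclass
class MitralPatternSet:
    """Per-odor up/down modulated mitral cells and their rate vectors."""

    n_mitral: int
    baseline_rate: float      # Hz
    up_delta: float           # Hz added on up-cells during odor
    down_delta: float         # Hz subtracted on down-cells during odor
    up: dict                  # odor -> int index array
    down: dict                # odor -> int index array
    target_correlation: pd.DataFrame

    def rate_vector(self, odor) -> np.ndarray:
        """Odor-period firing rate of every mitral cell (Hz), floored at 0."""
        r = np.full(self.n_mitral, self.baseline_rate)
        r[self.up[odor]] += self.up_delta
        r[self.down[odor]] -= self.down_delta
        return np.maximum(r, 0.0)

    def rate_matrix(self) -> pd.DataFrame:
        odors = list(self.target_correlation.index)
        return pd.DataFrame(
            {o: self.rate_vector(o) for o in odors}, columns=odors
        )

    def realized_correlation(self) -> pd.DataFrame:
        return self.rate_matrix().corr()


def default_target_correlation(
    panel: OdorPanel, within: float = 0.3, across: float = 0.0
) -> pd.DataFrame:
    """Block correlation matrix: ``within`` inside a class, ``across`` between."""
    n = panel.n_odors
    mat = np.full((n, n), across)
    for cls in panel.classes:
        idx = [panel.index(o) for o in panel.odors_of_class(cls)]
        mat[np.ix_(idx, idx)] = within
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=panel.odor_ids, columns=panel.odor_ids)


def _check_target(target: pd.DataFrame) -> None:
    m = target.to_numpy(dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("target correlation matrix must have unit diagonal")
    if np.min(np.linalg.eigvalsh(m)) < -1e-8:
        raise ValueError("target correlation matrix is not positive semidefinite")
    odors = list(target.index)
    for i, oi in enumerate(odors):
        for j, oj in enumerate(odors):
            if i < j and m[i, j] < 0:
                raise ValueError(
                    f"negative target correlation for pair ({oi}, {oj}): "
                    "the shared-cell construction cannot realize it"
                )


def _overlap_blocks(odors, counts, per_odor_total, pool, rng):
    """Allocate disjoint shared blocks per odor pair plus private cells.

    ``counts[(i, j)]`` cells are shared between odors i and j (i < j);
    every odor ends with exactly ``per_odor_total`` cells.  Consumes indices
    from ``pool`` (a list, mutated).  Returns (sets, blocks) where blocks
    lists (odor tuple, cell index array) for every shared and private block.
    """
    sets = {o: [] for o in odors}
    blocks = []
    try:
        for (oi, oj), k in counts.items():
            if k <= 0:
                continue
            block = [pool.pop() for _ in range(k)]
            sets[oi].extend(block)
            sets[oj].extend(block)
            blocks.append(((oi, oj), np.array(block, dtype=int)))
        for o in odors:
            n_priv = per_odor_total - len(sets[o])
            if n_priv < 0:
                raise ValueError(
                    f"requested overlaps for odor {o} exceed the set size "
                    f"({len(sets[o])} > {per_odor_total})"
                )
            priv = [pool.pop() for _ in range(n_priv)]
            sets[o].extend(priv)
            if priv:
                blocks.append(((o,), np.array(priv, dtype=int)))
    except IndexError:
        raise ValueError(
            "cell pool exhausted: shrink the per-odor set size or enlarge "
            "the population"
        ) from None
    return {o: np.array(sorted(s), dtype=int) for o, s in sets.items()}, blocks


def generate_mitral_patterns(
    n_mitral: int,
    panel: OdorPanel,
    n_up: int = 150,
    n_down: int = 75,
    baseline_rate: float = 6.0,
    up_delta: float = 30.0,
    down_delta: float = 6.0,
    target_correlation: pd.DataFrame | None = None,
    tolerance: float = 0.05,
    seed: int = 0,
) -> MitralPatternSet:
    """Generate per-odor mitral up/down sets matching a target correlation matrix.

    The Pearson correlation between two odors' rate vectors is controlled by
    the number of shared up- and down-cells; shared blocks are disjoint
    across pairs, so realized correlations are exact up to integer rounding.
    Raises if the requested matrix is infeasible or the realized correlation
    misses the target by more than ``tolerance``.
    """
    if n_up + n_down > n_mitral:
        raise ValueError("n_up + n_down must not exceed n_mitral")
    if down_delta > baseline_rate:
        raise ValueError("down_delta may not exceed the baseline rate (rates >= 0)")
    if target_correlation is None:
        target_correlation = default_target_correlation(panel)
    _check_target(target_correlation)
    odors = list(target_correlation.index)

    # overlap counts correcting for the mean offset of the deviation vectors
    a, d = float(up_delta), float(down_delta)
    S = n_up * a**2 + n_down * d**2
    mu = (n_up * a - n_down * d) / n_mitral
    denom = S - n_mitral * mu**2
    counts_up, counts_down = {}, {}
    for i, oi in enumerate(odors):
        for j, oj in enumerate(odors):
            if i >= j:
                continue
            r = float(target_correlation.iloc[i, j])
            if r >= 1.0:
                counts_up[(oi, oj)] = n_up
                counts_down[(oi, oj)] = n_down
                continue
            if S == 0:                 # unmodulated patterns: nothing to share
                counts_up[(oi, oj)] = 0
                counts_down[(oi, oj)] = 0
                continue
            q = r * denom + n_mitral * mu**2    # target raw dot of deviations
            ku = int(round(q * n_up / S))
            kd = int(round(q * n_down / S))
            counts_up[(oi, oj)] = min(max(ku, 0), n_up)
            counts_down[(oi, oj)] = min(max(kd, 0), n_down)

    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(n_mitral))
    up, _ = _overlap_blocks(odors, counts_up, n_up, pool, rng)
    down, _ = _overlap_blocks(odors, counts_down, n_down, pool, rng)

    pat = MitralPatternSet(
        n_mitral, baseline_rate, up_delta, down_delta, up, down, target_correlation
    )
    if S == 0:        # constant rate vectors: correlation undefined, nothing to verify
        return pat
    realized = pat.realized_correlation().to_numpy()
    target = target_correlation.to_numpy(dtype=float)
    err = np.abs(realized - target)
    if np.max(err) > tolerance:
        i, j = np.unravel_index(np.argmax(err), err.shape)
        raise RuntimeError(
            f"realized correlation for pair ({odors[i]}, {odors[j]}) misses "
            f"target by {err[i, j]:.3f} (> {tolerance})"
        )
    return pat


# --------------------------------------------------------------------------
# Phasic-tonic response profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasicTonicParams:
    """Shape of the odor-evoked rate time course (dimensionless multiplier).

    The profile is a unit-peak alpha-function transient riding on a
    saturating plateau: ``rho*(1-exp(-s/rise_tau)) +
    (1-rho)*(s/peak_time)*exp(1-s/peak_time)`` for time-from-onset ``s``.
    The transient peaks at ``peak_time`` (which is also its decay constant)
    and the profile settles to the plateau fraction ``rho``.
    """

    rise_tau: float = 0.1         # s, plateau rise
    peak_time: float = 0.5        # s, phasic peak time = phasic decay constant
    plateau_fraction: float = 0.4

    def __post_init__(self):
        if self.rise_tau <= 0 or self.peak_time <= 0:
            raise ValueError("time constants must be positive")
        if not 0 <= self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must be in [0, 1]")


def phasic_tonic_profile(t, params: PhasicTonicParams | None, onset: float = 0.0):
    """Dimensionless rate multiplier at time(s) ``t`` (s).

    Zero before ``onset``; with ``params=None`` a unit step at onset.
    """
    t = np.asarray(t, dtype=float)
    s = t - onset
    if params is None:
        return (s >= 0).astype(float)
    rho = params.plateau_fraction
    with np.errstate(over="ignore"):
        phasic = (s / params.peak_time) * np.exp(1.0 - s / params.peak_time)
        tonic = 1.0 - np.exp(-s / params.rise_tau)
    out = rho * tonic + (1.0 - rho) * phasic
    return np.where(s >= 0, np.maximum(out, 0.0), 0.0)


# --------------------------------------------------------------------------
# Imaging-like dataset with controllable manifold geometry
# --------------------------------------------------------------------------

@dataclass
class GeometrySpec:
    """Parameters of the synthetic imaging-like dataset.

    Manifold geometry knobs: each odor's manifold is a cloud of points
    ``baseline + profile(t) * (center + trial_offset + bin_noise)`` clipped
    at zero.  Centers are sparse nonnegative vectors with configured norm
    and pairwise cosine (within/across class); noise is covariance-shaped
    with an optional elongation along a chosen direction; trial offsets and
    per-bin noise have separate scales.  In the "trained" regime the CS+
    and CS− centers and covariances are amplified along a direction by
    ``amplification_gain`` (partially, by ``generalization``, for AA3).
    """

    n_neurons: int = 800
    frame_rate: float = 7.5        # Hz
    n_trials: int = 3
    duration: float = 10.0         # s
    onset: float = 2.0             # stimulus onset, s
    profile: PhasicTonicParams | None = field(default_factory=PhasicTonicParams)
    baseline_rate: float = 0.0     # Hz, added to every bin (documented optional)
    # manifold centers
    n_responsive: int | None = None   # support size of each odor's center
                                      # (None -> 12% of the population)
    center_norm: float = 30.0      # Hz (L2 over neurons)
    within_class_cosine: float = 0.3
    across_class_cosine: float = 0.0
    amplitude_sigma: float = 0.5   # lognormal sigma of responsive amplitudes
    # covariance descriptor
    bin_noise_scale: float = 1.0   # Hz per neuron, per (trial, bin) draw
    trial_jitter_scale: float = 0.6   # Hz per neuron, per trial draw
    elongation_factor: float = 1.0    # >= 1
    elongation_direction: str = "center"   # "center" | "random"
    # regime
    regime: str = "naive"          # "naive" | "trained"
    amplification_gain: float = 1.5
    amplification_direction: str = "center"
    generalization: float = 0.5    # fraction of the CS effect applied to AA3

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.elongation_factor < 1:
            raise ValueError("elongation_factor must be >= 1")
        if self.regime not in ("naive", "trained"):
            raise ValueError("regime must be 'naive' or 'trained'")
        if not 0 <= self.generalization <= 1:
            raise ValueError("generalization must be in [0, 1]")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration * self.frame_rate))


def naive_spec(**overrides) -> GeometrySpec:
    return GeometrySpec(regime="naive", **overrides)


def trained_spec(**overrides) -> GeometrySpec:
    return GeometrySpec(regime="trained", **overrides)


def _make_centers(spec: GeometrySpec, panel: OdorPanel, rng) -> dict:
    """Sparse nonnegative centers with configured pairwise cosines.

    Correlated odors share a block of responsive neurons with identical
    amplitudes; the shared fraction equals the target cosine.
    """
    n_resp = spec.n_responsive or max(10, int(round(0.12 * spec.n_neurons)))
    counts = {}
    odors = list(panel.odor_ids)
    for i, oi in enumerate(odors):
        for j, oj in enumerate(odors):
            if i >= j:
                continue
            rho = (
                spec.within_class_cosine
                if panel.class_of[oi] == panel.class_of[oj]
                else spec.across_class_cosine
            )
            counts[(oi, oj)] = int(round(rho * n_resp))
    pool = list(rng.permutation(spec.n_neurons))
    support, blocks = _overlap_blocks(odors, counts, n_resp, pool, rng)
    amp = np.exp(spec.amplitude_sigma * rng.standard_normal(spec.n_neurons))
    # fix each block's squared amplitude mass to its cell count so that the
    # pairwise cosine equals the shared fraction exactly (not just on average)
    for _, cells in blocks:
        mass = np.sum(amp[cells] ** 2)
        amp[cells] *= np.sqrt(len(cells) / mass)
    centers = {}
    for o in odors:
        u = np.zeros(spec.n_neurons)
        u[support[o]] = amp[support[o]]     # shared cells share amplitudes
        centers[o] = u * (spec.center_norm / np.linalg.norm(u))
    return centers


def _shaped_noise(rng, n, scale, direction, elong):
    """Draw with covariance ``scale^2 (I + (elong^2 - 1) d d^T)``."""
    xi = rng.standard_normal(n)
    if elong > 1.0 and direction is not None:
        xi = xi + (elong - 1.0) * (xi @ direction) * direction
    return scale * xi


def generate_imaging_dataset(
    spec: GeometrySpec, panel: OdorPanel | None = None, seed: int = 0
) -> ActivityDataset:
    """Emit an :class:`ActivityDataset` realizing the configured geometry.

    Bit-identical for identical (spec, seed).  Refuses fewer than 2 trials
    (downstream covariance would be undefined).
    """
    if panel is None:
        panel = default_panel()
    if spec.n_trials < 2:
        raise ValueError("need at least 2 trials (covariance undefined otherwise)")
    rng = np.random.default_rng(seed)
    centers = _make_centers(spec, panel, rng)

    # per-odor covariance direction and elongation, plus trained amplification
    gains = {o: 1.0 for o in panel.odor_ids}
    if spec.regime == "trained":
        g = spec.amplification_gain
        for o in panel.odor_ids:
            role = panel.conditioning.get(o)
            if role in ("CS+", "CS-"):
                gains[o] = g
            elif role == "AA3":
                gains[o] = 1.0 + (g - 1.0) * spec.generalization

    directions, elongs = {}, {}
    for o in panel.odor_ids:
        if spec.elongation_direction == "random":
            v = rng.standard_normal(spec.n_neurons)
        else:
            v = centers[o].copy()
        nrm = np.linalg.norm(v)
        directions[o] = v / nrm if nrm > 0 else None
        elongs[o] = spec.elongation_factor * gains[o]
        # amplify the center along the amplification direction
        if gains[o] != 1.0:
            d = directions[o]
            if spec.amplification_direction == "center" and d is not None:
                centers[o] = centers[o] + (gains[o] - 1.0) * (centers[o] @ d) * d

    prof = phasic_tonic_profile(
        (np.arange(spec.n_bins) + 0.5) / spec.frame_rate, spec.profile, spec.onset
    )
    rates = np.empty((spec.n_neurons, spec.n_bins, spec.n_trials, panel.n_odors))
    for k, o in enumerate(panel.odor_ids):
        d, e = directions[o], elongs[o]
        for tr in range(spec.n_trials):
            offset = _shaped_noise(rng, spec.n_neurons, spec.trial_jitter_scale, d, e)
            for b in range(spec.n_bins):
                xi = _shaped_noise(rng, spec.n_neurons, spec.bin_noise_scale, d, e)
                evoked = prof[b] * (centers[o] + offset + xi)
                rates[:, b, tr, k] = np.maximum(spec.baseline_rate + evoked, 0.0)

    return ActivityDataset(
        rates=rates,
        frame_rate=spec.frame_rate,
        panel=panel,
        onset_time=spec.onset,
        provenance="synthetic",
        meta={"regime": spec.regime, "seed": seed},
    )
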