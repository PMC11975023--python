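"""Per-odor manifolds and distance analytics.

A neural manifold here is the point cloud of population activity vectors
evoked by one odor, pooled over time bins and trials within an analysis
window.  Two distances compare manifolds:

* ``dE`` — Euclidean distance between manifold centers (Hz units,
  symmetric).
* ``dM`` — Mahalanobis distance from the points of a *sample* manifold X
  to the distribution of a *reference* manifold Y: the mean over x in X of
  ``sqrt((x - mu_Y)^T S_Y^{-1} (x - mu_Y))`` with S_Y the sample covariance
  of Y.  Directional (rows = sample, columns = reference) and
  dimensionless; because it is normalized by the reference covariance it
  tracks linear discriminability.

Because covariance inversion needs more points than dimensions, matrices
are computed on random neuron subsets (default 70 neurons, 50 repeats,
the same subset for every odor pair within a repeat) and averaged.
A label-shuffle control pools the two point clouds and re-splits them at
random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ActivityDataset

__all__ = [
    "Manifold",
    "WindowSpec",
    "DistanceMatrix",
    "build_manifolds",
    "euclidean_distance",
    "mahalanobis_distance",
    "distance_matrix",
    "shuffle_pair",
    "cosine_distance_matrix",
    "timelag_correlation",
    "ManifoldDistances",
    "DistanceResults",
]

DEFAULT_RIDGE = 1e-6   # times the mean covariance diagonal


# --------------------------------------------------------------------------
# Manifold construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: ``n_frames`` bins starting at ``start_time`` seconds.

    The juvenile default starts 1 s after response onset and spans 24
    frames at 7.5 Hz, giving 72 points per manifold from 3 trials.
    """

    start_time: float | None = None   # s from recording start; None -> onset + 1 s
    n_frames: int = 24

    @classmethod
    def fitted(cls, activity: ActivityDataset, n_frames: int = 24) -> "WindowSpec":
        """The default window, clipped to what the recording can hold."""
        start = activity.onset_time + 1.0
        first = int(np.floor(start * activity.frame_rate))
        return cls(start, min(n_frames, activity.n_bins - first))

    def bin_slice(self, activity: ActivityDataset) -> slice:
        start = self.start_time
        if start is None:
            start = activity.onset_time + 1.0
        first = int(np.floor(start * activity.frame_rate))
        last = first + self.n_frames
        if last > activity.n_bins:
            raise ValueError(
                f"window [{first}, {last}) exceeds recording of "
                f"{activity.n_bins} bins"
            )
        return slice(first, last)


@dataclass
class Manifold:
    """A labeled point cloud: one population vector per (trial, time bin)."""

    odor: str
    points: np.ndarray        # (n_points, n_neurons), Hz
    window: WindowSpec | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ValueError("a manifold needs at least 2 points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.points.shape[1]

    @property
    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def subsample_neurons(self, idx: np.ndarray) -> "Manifold":
        return Manifold(self.odor, self.points[:, idx], self.window)


def build_manifolds(
    activity: ActivityDataset, window: WindowSpec | None = None
) -> list[Manifold]:
    """One manifold per odor; point count = n_frames x n_trials."""
    if window is None:
        window = WindowSpec()
    sl = window.bin_slice(activity)
    out = []
    for odor in activity.panel.odor_ids:
        slab = activity.odor_slab(odor)[:, sl, :]          # (neurons, frames, trials)
        pts = slab.reshape(activity.n_neurons, -1).T       # (frames*trials, neurons)
        out.append(Manifold(odor, pts, window))
    return out


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def euclidean_distance(X: Manifold | np.ndarray, Y: Manifold | np.ndarray) -> float:
    """L2 distance between manifold centers (Hz)."""
    x = X.center if isinstance(X, Manifold) else np.mean(np.atleast_2d(X), axis=0)
    y = Y.center if isinstance(Y, Manifold) else np.mean(np.atleast_2d(Y), axis=0)
    return float(np.linalg.norm(x - y))


def _reference_solve(Y: np.ndarray, ridge: float):
    """Cholesky factor of the (ridge-regularized) sample covariance of Y."""
    from scipy.linalg import cho_factor

    S = np.cov(Y, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    if ridge > 0:
        S = S + ridge * np.mean(np.diag(S)) * np.eye(S.shape[0])
    try:
        return cho_factor(S, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover - scipy raises its own
        raise err


def mahalanobis_distance(
    X: Manifold | np.ndarray,
    Y: Manifold | np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Mean Mahalanobis distance of the points of X to the distribution of Y.

    ``ridge`` scales an identity added to S_Y as a fraction of its mean
    diagonal (0 disables regularization; a singular S_Y then raises with
    advice).  Asymmetric in general: X is the sample, Y the reference.
    """
    from scipy.linalg import cho_solve

    Xp = X.points if isinstance(X, Manifold) else np.atleast_2d(np.asarray(X, float))
    Yp = Y.points if isinstance(Y, Manifold) else np.atleast_2d(np.asarray(Y, float))
    mu = Yp.mean(axis=0)
    try:
        cf = _reference_solve(Yp, ridge)
    except Exception as err:
        raise np.linalg.LinAlgError(
            "singular reference covariance; pass ridge > 0 or use more "
            "points than dimensions"
        ) from err
    diff = Xp - mu
    q = np.einsum("ij,ji->i", diff, cho_solve(cf, diff.T))
    # numerical guard: quadratic forms are >= 0 up to roundoff
    return float(np.mean(np.sqrt(np.maximum(q, 0.0))))


def shuffle_pair(X: np.ndarray, Y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Pool the points of X and Y and split them into two equal halves.

    An odd pooled count drops one point at random (documented behavior).
    """
    pool = np.vstack([X, Y])
    idx = rng.permutation(pool.shape[0])
    if len(idx) % 2 == 1:
        idx = idx[:-1]
    half = len(idx) // 2
    return pool[idx[:half]], pool[idx[half:]]


@dataclass
class DistanceMatrix:
    """Odor x odor distance matrix with its computation protocol.

    For ``dM`` rows are the sample manifolds and columns the reference
    manifolds.  ``values`` is a labeled DataFrame.
    """

    metric: str                      # "dE" | "dM" | "cosine"
    values: pd.DataFrame
    n_neurons: int | None = None
    n_repeats: int | None = None
    seed: int | None = None
    shuffled: bool = False
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metric: {self.metric}\n")
            fh.write(
                f"# n_neurons: {self.n_neurons}  n_repeats: {self.n_repeats}  "
                f"seed: {self.seed}  shuffled: {self.shuffled}\n"
            )
            if self.metric == "dM":
                fh.write("# rows = sample manifold, columns = reference manifold\n")
            self.values.to_csv(fh)


def _pairwise(points: dict, metric: str, ridge: float) -> pd.DataFrame:
    odors = list(points)
    n = len(odors)
    vals = np.zeros((n, n))
    for i, oi in enumerate(odors):
        for j, oj in enumerate(odors):
            if metric == "dE":
                if j > i:
                    vals[i, j] = euclidean_distance(points[oi], points[oj])
                    vals[j, i] = vals[i, j]
            else:
                vals[i, j] = mahalanobis_distance(points[oi], points[oj], ridge)
    return pd.DataFrame(vals, index=odors, columns=odors)


def distance_matrix(
    manifolds: list[Manifold],
    metric: str = "dM",
    n_neurons: int = 70,
    n_repeats: int = 50,
    ridge: float = DEFAULT_RIDGE,
    seed: int = 0,
    shuffle: bool = False,
    n_shuffles: int = 50,
) -> DistanceMatrix:
    """Subsampled-and-averaged pairwise distances between manifolds.

    Per repeat one neuron subset is drawn without replacement and shared
    by all odor pairs; distances are averaged over ``n_repeats``.  With
    ``shuffle=True`` each pair's points are pooled and randomly re-split
    (``n_shuffles`` times, averaged) before measuring — the label-shuffle
    null control.
    """
    if metric not in ("dE", "dM"):
        raise ValueError("metric must be 'dE' or 'dM'")
    total = manifolds[0].n_neurons
    if n_neurons > total:
        raise ValueError(f"n_neurons={n_neurons} exceeds available {total}")
    if metric == "dM" and ridge == 0:
        for m in manifolds:
            if m.n_points <= n_neurons:
                raise ValueError(
                    f"manifold {m.odor}: {m.n_points} points <= {n_neurons} "
                    "dimensions needs ridge > 0"
                )
    rng = np.random.default_rng(seed)
    odors = [m.odor for m in manifolds]
    # neurons silent in every manifold make the reference covariance singular
    # and carry no distance information; subsample among the others
    var = np.vstack([m.points for m in manifolds]).var(axis=0)
    pool = np.flatnonzero(var > 0)
    if pool.size < n_neurons:
        raise ValueError(
            f"only {pool.size} neurons with nonzero variance < "
            f"n_neurons={n_neurons}"
        )
    acc = np.zeros((len(odors), len(odors)))
    for _ in range(n_repeats):
        idx = rng.choice(pool, size=n_neurons, replace=False)
        pts = {m.odor: m.points[:, idx] for m in manifolds}
        if not shuffle:
            acc += _pairwise(pts, metric, ridge).to_numpy()
        else:
            block = np.zeros_like(acc)
            for i, oi in enumerate(odors):
                for j, oj in enumerate(odors):
                    if j <= i:
                        continue
                    sij = 0.0
                    sji = 0.0
                    for _ in range(n_shuffles):
                        Xs, Ys = shuffle_pair(pts[oi], pts[oj], rng)
                        if metric == "dE":
                            sij += euclidean_distance(Xs, Ys)
                        else:
                            sij += mahalanobis_distance(Xs, Ys, ridge)
                            sji += mahalanobis_distance(Ys, Xs, ridge)
                    block[i, j] = sij / n_shuffles
                    block[j, i] = (sji if metric == "dM" else sij) / n_shuffles
            acc += block
    vals = pd.DataFrame(acc / n_repeats, index=odors, columns=odors)
    return DistanceMatrix(metric, vals, n_neurons, n_repeats, seed, shuffle)


# --------------------------------------------------------------------------
# Cosine and time-lag analytics
# --------------------------------------------------------------------------

def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(1.0 - (u @ v) / (nu * nv))


def cosine_distance_matrix(
    activity: ActivityDataset,
    mode: str = "odor-odor",
    window: WindowSpec | None = None,
) -> DistanceMatrix:
    """Cosine distances (1 − cosine similarity) between time-averaged patterns.

    ``mode="trial-trial"``: per odor, the mean distance between the
    time-averaged vectors of different trials (trial-to-trial variability;
    returned on the matrix diagonal, off-diagonal NaN).
    ``mode="odor-odor"``: between trial-averaged vectors of different
    odors, with the trial-trial value on the diagonal.
    Zero vectors are excluded with a warning (their entries become NaN).
    """
    if mode not in ("odor-odor", "trial-trial"):
        raise ValueError("mode must be 'odor-odor' or 'trial-trial'")
    if window is None:
        start = activity.onset_time + 1.0
        first = int(np.floor(start * activity.frame_rate))
        window = WindowSpec(start, min(24, activity.n_bins - first))
    sl = window.bin_slice(activity)
    odors = list(activity.panel.odor_ids)
    # time-averaged vectors: (neurons, trials, odors)
    avg = activity.rates[:, sl, :, :].mean(axis=1)
    if np.any(np.linalg.norm(avg, axis=0) == 0):
        warnings.warn("zero time-averaged vector excluded from cosine distances")
    n = len(odors)
    vals = np.full((n, n), np.nan)
    n_trials = activity.n_trials
    for i in range(n):
        pair = [
            _cosine_distance(avg[:, a, i], avg[:, b, i])
            for a in range(n_trials)
            for b in range(a + 1, n_trials)
        ]
        vals[i, i] = np.nanmean(pair)
    if mode == "odor-odor":
        trial_mean = avg.mean(axis=1)       # (neurons, odors)
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = _cosine_distance(
                    trial_mean[:, i], trial_mean[:, j]
                )
    df = pd.DataFrame(vals, index=odors, columns=odors)
    return DistanceMatrix("cosine", df, meta={"mode": mode})


def timelag_correlation(
    activity: ActivityDataset, odor: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation across neurons between population vectors at
    every pair of time bins, averaged over trials.

    Returns the time x time matrix and the per-bin correlation against the
    mean vector of the odor-application window.  Constant vectors yield
    NaN entries (flagged with a warning).
    """
    slab = activity.odor_slab(odor)        # (neurons, bins, trials)
    n_bins, n_trials = slab.shape[1], slab.shape[2]
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    mats = []
    onset_bin = int(np.floor(activity.onset_time * activity.frame_rate))
    ref_rows = []
    for tr in range(n_trials):
        pats = slab[:, :, tr]              # neurons x bins
        sd = pats.std(axis=0)
        if np.any(sd == 0):
            warnings.warn(f"constant population vector in trial {tr}: NaN entries")
        with np.errstate(invalid="ignore", divide="ignore"):
            mats.append(np.corrcoef(pats.T))
            ref = pats[:, onset_bin:].mean(axis=1)
            c = np.array(
                [
                    np.corrcoef(pats[:, b], ref)[0, 1] if sd[b] > 0 else np.nan
                    for b in range(n_bins)
                ]
            )
        ref_rows.append(c)
    times = activity.times
    mat = pd.DataFrame(np.nanmean(mats, axis=0), index=times, columns=times)
    ref_series = pd.Series(np.nanmean(ref_rows, axis=0), index=times)
    return mat, ref_series


# --------------------------------------------------------------------------
# Model / Results facade
# --------------------------------------------------------------------------

class ManifoldDistances:
    """Distance analysis of an activity dataset, statsmodels-style.

    ``ManifoldDistances(activity, window).fit(metric="dM")`` returns a
    :class:`DistanceResults` carrying the matrix, the shuffle control and a
    summary table.
    """

    def __init__(self, activity: ActivityDataset, window: WindowSpec | None = None):
        self.activity = activity
        self.window = window
        self.manifolds = build_manifolds(activity, window)

    def fit(
        self,
        metric: str = "dM",
        n_neurons: int = 70,
        n_repeats: int = 50,
        ridge: float = DEFAULT_RIDGE,
        seed: int = 0,
        with_shuffle: bool = True,
        n_shuffles: int = 50,
    ) -> "DistanceResults":
        mat = distance_matrix(
            self.manifolds, metric, n_neurons, n_repeats, ridge, seed
        )
        shuf = None
        if with_shuffle:
            shuf = distance_matrix(
                self.manifolds,
                metric,
                n_neurons,
                n_repeats,
                ridge,
                seed,
                shuffle=True,
                n_shuffles=n_shuffles,
            )
        return DistanceResults(self, mat, shuf)


@dataclass
class DistanceResults:
    model: ManifoldDistances
    matrix: DistanceMatrix
    shuffled: DistanceMatrix | None = None

    def by_class(self) -> pd.DataFrame:
        """Mean distance per odor-class pair (AA-AA, AA-BA directional, BA-BA)."""
        panel = self.model.activity.panel
        vals = self.matrix.values
        rows = []
        for ci in panel.classes:
            for cj in panel.classes:
                sub = vals.loc[panel.odors_of_class(ci), panel.odors_of_class(cj)]
                arr = sub.to_numpy().astype(float).copy()
                if ci == cj:
                    np.fill_diagonal(arr, np.nan)
                rows.append(
                    {"sample_class": ci, "reference_class": cj,
                     "mean_distance": float(np.nanmean(arr))}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.matrix
        lines = [
            f"Manifold distance analysis  (metric: {m.metric})",
            f"  subsampling: {m.n_neurons} neurons x {m.n_repeats} repeats, "
            f"seed {m.seed}",
            "",
            m.values.round(3).to_string(),
        ]
        if m.metric == "dM":
            lines.insert(1, "  rows = sample manifold, columns = reference manifold")
        if self.shuffled is not None:
            lines += ["", "Label-shuffle control:",
                      self.shuffled.values.round(3).to_string()]
        return "\n".join(lines)
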