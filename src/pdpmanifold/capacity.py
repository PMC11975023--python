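"""Manifold capacity estimation and effective geometric measures.

Manifold capacity alpha is the maximum number of manifolds per ambient
dimension that remain linearly separable under random binary labeling.  It
is computed as the inverse of a Gaussian average of a projection quadratic
program: for a Gaussian vector T,

    F(T) = min_{V in A_y} ||V - T||^2 ,
    A_y  = { V : y_mu V.x >= 0 for every point x of every manifold mu },

and  alpha = ( E_{T,y}[ F(T) ] / P )^{-1}  for P manifolds.

The projection of T onto the polyhedral cone A_y is solved exactly through
Moreau decomposition: the polar cone is the nonnegative span of the signed
points, so the projection reduces to a nonnegative least-squares problem
(Lawson–Hanson, ``scipy.optimize.nnls``).  The dual weights identify each
manifold's *anchor point* — the convex combination of its points active in
the program — and the distribution of anchor points over T draws yields
five effective geometric measures: radius, dimension, center alignment,
axes alignment, and center-axes alignment.

Because F(T) depends on T only through its component in the span of the
data points, the Gaussian average is evaluated in that subspace; this is
exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .dataset import ActivityDataset
from .geometry import WindowSpec, build_manifolds

__all__ = [
    "EmbeddedManifoldSet",
    "CapacityProtocol",
    "CapacityResult",
    "preprocess_manifolds",
    "solve_projection_qp",
    "estimate_capacity",
    "effective_measures",
    "capacity_pipeline",
    "ManifoldCapacity",
    "CapacityResultsSet",
]


# --------------------------------------------------------------------------
# Preprocessing: centers, axes, coordinates
# --------------------------------------------------------------------------

@dataclass
class EmbeddedManifoldSet:
    """P manifolds embedded in an N-dimensional state space.

    ``points[mu]`` holds the preprocessed points (global centering applied,
    bias coordinate appended when configured); each point reconstructs as
    ``center + coords @ axes``.  ``raw_centers`` keeps the pre-centering
    centers (used by the alignment measures, which compare the original
    activity directions).
    """

    points: list                    # per manifold: (M_mu, N) arrays
    centers: list                   # per manifold: (N,) preprocessed center
    axes: list                      # per manifold: (K_mu, N) orthonormal rows
    coords: list                    # per manifold: (M_mu, K_mu)
    raw_centers: list               # per manifold: (N_raw,) before preprocessing
    global_centering: bool
    bias: bool

    @property
    def n_manifolds(self) -> int:
        return len(self.points)

    @property
    def ambient_dim(self) -> int:
        return self.points[0].shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All points stacked, with the manifold index of every row."""
        X = np.vstack(self.points)
        owner = np.concatenate(
            [np.full(p.shape[0], mu) for mu, p in enumerate(self.points)]
        )
        return X, owner


def preprocess_manifolds(
    point_sets: list,
    global_centering: bool = True,
    bias: bool = True,
) -> EmbeddedManifoldSet:
    """Center, append the bias coordinate, and decompose into center + axes.

    Global centering translates the mean of the manifold centers to the
    origin; the bias coordinate (a constant 1) lets the separating
    hyperplane carry an offset.  Axes come from the singular decomposition
    of each manifold's centered points; degenerate manifolds (one repeated
    point) get zero axes.
    """
    if len(point_sets) < 2:
        raise ValueError("need at least 2 manifolds")
    pts = [np.atleast_2d(np.asarray(p, dtype=float)) for p in point_sets]
    raw_centers = [p.mean(axis=0) for p in pts]
    if global_centering:
        grand = np.mean(raw_centers, axis=0)
        pts = [p - grand for p in pts]
    if bias:
        pts = [np.hstack([p, np.ones((p.shape[0], 1))]) for p in pts]
    centers, axes, coords = [], [], []
    for p in pts:
        c = p.mean(axis=0)
        dev = p - c
        u, s, vt = np.linalg.svd(dev, full_matrices=False)
        keep = s > 1e-10 * max(1.0, s[0] if s.size else 1.0)
        axes.append(vt[keep])
        coords.append(u[:, keep] * s[keep])
        centers.append(c)
    return EmbeddedManifoldSet(
        pts, centers, axes, coords, raw_centers, global_centering, bias
    )


# --------------------------------------------------------------------------
# The projection quadratic program
# --------------------------------------------------------------------------

class _ConeProjector:
    """Projects Gaussian draws onto the label cone of a fixed point set.

    Precomputes an orthonormal basis Q of the span of the points (the only
    subspace F(T) depends on) and the reduced, row-normalized point matrix.
    Labels may change per draw (sign flips are cheap).
    """

    def __init__(self, X: np.ndarray, owner: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.owner = np.asarray(owner)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            # a zero point constrains nothing; keep it with weight zero
            norms = np.where(norms == 0, 1.0, norms)
        self.X = X
        self.norms = norms
        Xn = X / norms[:, None]
        # basis of the row space via SVD (rank-revealing)
        u, s, vt = np.linalg.svd(Xn, full_matrices=False)
        keep = s > 1e-12 * (s[0] if s.size else 1.0)
        self.Q = vt[keep].T                       # (N, r)
        self.XQ = Xn @ self.Q                     # (m, r)
        self.r = self.Q.shape[1]
        self.m = X.shape[0]

    def solve(self, t: np.ndarray, y_point: np.ndarray, maxiter: int | None = None):
        """Project ``t`` (reduced coords) onto {c : (y*Xn) Q c >= 0}.

        Returns (objective F, dual weights lambda per point).
        """
        B = y_point[:, None] * self.XQ            # (m, r)
        try:
            lam, _ = nnls(B.T, -t, maxiter=maxiter)
        except RuntimeError:
            # retry with a generous iteration budget before giving up
            lam, _ = nnls(B.T, -t, maxiter=50 * self.m)
        resid = B.T @ lam                          # = c* - t
        return float(resid @ resid), lam

    def anchors(self, lam: np.ndarray, n_manifolds: int):
        """Anchor point per manifold: dual-weighted convex combination.

        Returns a list with one (N,) array per manifold, or None for
        manifolds with no active constraint at this draw.
        """
        w = lam / self.norms                      # weights on the raw points
        out = []
        for mu in range(n_manifolds):
            sel = self.owner == mu
            tot = w[sel].sum()
            if tot <= 0:
                out.append(None)
            else:
                out.append((w[sel] @ self.X[sel]) / tot)
        return out


def solve_projection_qp(
    T: np.ndarray,
    embedded_set: EmbeddedManifoldSet,
    labels: np.ndarray,
):
    """Solve min ||V - T||^2 subject to y_mu V.x >= 0 for all points.

    ``T`` is an ambient-dimension vector; ``labels`` one +/-1 per manifold.
    Returns ``(V_star, anchor_points, objective)``.
    """
    X, owner = embedded_set.stacked()
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != embedded_set.n_manifolds:
        raise ValueError("one label per manifold required")
    proj = _ConeProjector(X, owner)
    T = np.asarray(T, dtype=float)
    if T.shape[0] != embedded_set.ambient_dim:
        raise ValueError("T must have the ambient dimension")
    t = proj.Q.T @ T
    F, lam = proj.solve(t, labels[owner])
    # lift back: V* = T + sum_i lam_i * ghat_i
    Ghat = (labels[owner, None] * proj.X) / proj.norms[:, None]
    V_star = T + lam @ Ghat
    anchors = proj.anchors(lam, embedded_set.n_manifolds)
    return V_star, anchors, F


# --------------------------------------------------------------------------
# Capacity estimation
# --------------------------------------------------------------------------

@dataclass
class CapacityProtocol:
    """Subsampling and Monte-Carlo settings for the capacity pipeline.

    The number of patterns per manifold must stay below the number of
    neurons so that a valid linear separator exists (the tensor is
    subsampled to enforce this, as in the source protocol: 700 neurons and
    140 patterns per manifold for juvenile-like data; 1000 neurons for
    simulated data).
    """

    n_neurons_subsample: int = 700
    n_patterns_subsample: int = 140
    n_repeats: int = 50
    n_gaussian_samples: int = 200
    global_centering: bool = True
    bias: bool = True
    shuffle: bool = False

    def __post_init__(self):
        if self.n_patterns_subsample >= self.n_neurons_subsample:
            raise ValueError(
                f"linear-separability precondition violated: "
                f"{self.n_patterns_subsample} patterns >= "
                f"{self.n_neurons_subsample} neurons"
            )


@dataclass
class CapacityResult:
    """Capacity and the five effective geometric measures for one manifold set."""

    alpha: float
    alpha_se: float
    radius: float
    dimension: float
    center_align: float
    axes_align: float
    center_axes_align: float
    n_gaussian_samples: int
    n_manifolds: int
    seed: int | None = None
    protocol: CapacityProtocol | None = None

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_se": self.alpha_se,
            "radius": self.radius,
            "dimension": self.dimension,
            "center_align": self.center_align,
            "axes_align": self.axes_align,
            "center_axes_align": self.center_axes_align,
        }


def _cos(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(u @ v / (nu * nv))


def effective_measures(
    anchor_samples: list,
    embedded_set: EmbeddedManifoldSet,
) -> dict:
    """Five geometric measures from the accumulated anchor distribution.

    ``anchor_samples[mu]`` is the list of anchor points collected for
    manifold mu over Gaussian draws (bias coordinate included if present;
    it is stripped here).  Radius is the root-mean-square anchor spread
    about the manifold center normalized by the center length; dimension
    is the participation ratio of the anchor second-moment spectrum;
    alignments are cosine statistics of centers and anchor displacement
    directions.
    """
    P = embedded_set.n_manifolds
    nb = -1 if embedded_set.bias else None
    centers = [c[:nb] if nb else c for c in embedded_set.centers]
    raw_centers = embedded_set.raw_centers
    disp = []
    for mu in range(P):
        arr = [a[:nb] if nb else a for a in anchor_samples[mu] if a is not None]
        disp.append(
            np.asarray(arr) - centers[mu] if arr else np.empty((0, len(centers[mu])))
        )

    radii, dims = [], []
    for mu in range(P):
        d = disp[mu]
        cn = np.linalg.norm(centers[mu])
        if d.shape[0] == 0:
            radii.append(0.0)
            dims.append(0.0)
            continue
        spread2 = float(np.mean(np.sum(d**2, axis=1)))
        radii.append(np.sqrt(spread2) / cn if cn > 0 else np.nan)
        s = np.linalg.svd(d, compute_uv=False)
        s2 = s**2
        tot = s2.sum()
        dims.append(float(tot**2 / np.sum(s2**2)) if tot > 1e-20 else 0.0)

    c_al, a_al, ca_al = [], [], []
    for mu, nu in combinations(range(P), 2):
        c_al.append(_cos(raw_centers[mu], raw_centers[nu]))
        n = min(disp[mu].shape[0], disp[nu].shape[0])
        if n > 0:
            cosines = [
                abs(_cos(disp[mu][k], disp[nu][k]))
                for k in range(n)
                if np.linalg.norm(disp[mu][k]) > 0 and np.linalg.norm(disp[nu][k]) > 0
            ]
            a_al.append(np.mean(cosines) if cosines else np.nan)
            ca = []
            for k in range(n):
                for a, b in ((mu, nu), (nu, mu)):
                    if np.linalg.norm(disp[a][k]) > 0:
                        ca.append(abs(_cos(disp[a][k], raw_centers[b])))
            ca_al.append(np.mean(ca) if ca else np.nan)
        else:
            a_al.append(np.nan)
            ca_al.append(np.nan)

    return {
        "radius": float(np.nanmean(radii)),
        "dimension": float(np.nanmean(dims)),
        "center_align": float(np.nanmean(c_al)),
        "axes_align": float(np.nanmean(a_al)),
        "center_axes_align": float(np.nanmean(ca_al)),
    }


def _draw_labels(P: int, rng) -> np.ndarray:
    """A dichotomy for the label average.

    For P = 2 the two non-trivial label classes are related by the
    V -> -V symmetry of the Gaussian measure, so the fixed labeling
    (+1, -1) already equals their average.  For P > 2 a uniform random
    dichotomy is drawn per Gaussian sample (Monte-Carlo over labels).
    """
    if P == 2:
        return np.array([1.0, -1.0])
    return rng.choice([-1.0, 1.0], size=P)


def estimate_capacity(
    embedded_set: EmbeddedManifoldSet,
    n_gaussian_samples: int = 200,
    seed: int = 0,
    n_batches: int = 10,
    collect_anchors: bool = True,
) -> CapacityResult:
    """Monte-Carlo estimate of manifold capacity (Eq.-1 style average).

    Draws T from the standard Gaussian measure (evaluated exactly in the
    span of the data), averages F(T)/P over draws and label dichotomies,
    and inverts.  The standard error comes from batch means; the anchor
    distribution feeds the effective geometric measures.
    """
    rng = np.random.default_rng(seed)
    X, owner = embedded_set.stacked()
    P = embedded_set.n_manifolds
    proj = _ConeProjector(X, owner)
    Fs = np.empty(n_gaussian_samples)
    anchors_acc = [[] for _ in range(P)]
    for k in range(n_gaussian_samples):
        labels = _draw_labels(P, rng)
        t = rng.standard_normal(proj.r)
        F, lam = proj.solve(t, labels[owner])
        Fs[k] = F
        if collect_anchors:
            for mu, a in enumerate(proj.anchors(lam, P)):
                anchors_acc[mu].append(a)
    mean_inv = Fs.mean() / P
    alpha = 1.0 / mean_inv if mean_inv > 0 else np.inf
    nb = max(2, min(n_batches, n_gaussian_samples))
    batches = np.array_split(Fs, nb)
    bm = np.array([b.mean() for b in batches])
    se_meanF = bm.std(ddof=1) / np.sqrt(len(bm))
    alpha_se = alpha**2 * se_meanF / P if np.isfinite(alpha) else np.nan

    if collect_anchors:
        meas = effective_measures(anchors_acc, embedded_set)
    else:
        meas = dict.fromkeys(
            ["radius", "dimension", "center_align", "axes_align",
             "center_axes_align"], np.nan
        )
    return CapacityResult(
        alpha=float(alpha),
        alpha_se=float(alpha_se),
        n_gaussian_samples=n_gaussian_samples,
        n_manifolds=P,
        seed=seed,
        **meas,
    )


# --------------------------------------------------------------------------
# Pairwise pipeline with subsampling and shuffle control
# --------------------------------------------------------------------------

def _subsample_pair(
    A: np.ndarray, B: np.ndarray, protocol: CapacityProtocol, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the neuron and pattern subsets for one repeat; shuffle if asked."""
    n_neu = protocol.n_neurons_subsample
    n_pat = protocol.n_patterns_subsample
    if A.shape[1] < n_neu:
        raise ValueError(
            f"activity has {A.shape[1]} neurons < protocol's {n_neu}"
        )
    if min(A.shape[0], B.shape[0]) < n_pat:
        raise ValueError(
            f"manifold has {min(A.shape[0], B.shape[0])} points < "
            f"protocol's {n_pat} patterns"
        )
    neu = rng.choice(A.shape[1], size=n_neu, replace=False)
    a = A[rng.choice(A.shape[0], size=n_pat, replace=False)][:, neu]
    b = B[rng.choice(B.shape[0], size=n_pat, replace=False)][:, neu]
    if protocol.shuffle:
        pool = np.vstack([a, b])
        perm = rng.permutation(pool.shape[0])
        a, b = pool[perm[:n_pat]], pool[perm[n_pat:]]
    return a, b


def capacity_pair(
    A: np.ndarray,
    B: np.ndarray,
    protocol: CapacityProtocol,
    seed: int = 0,
) -> tuple[CapacityResult, pd.DataFrame]:
    """Capacity + measures for one manifold pair, averaged over subsampling repeats."""
    ss = np.random.default_rng(seed)
    rows = []
    for rep in range(protocol.n_repeats):
        rng = np.random.default_rng(ss.integers(2**31))
        a, b = _subsample_pair(A, B, protocol, rng)
        emb = preprocess_manifolds(
            [a, b], protocol.global_centering, protocol.bias
        )
        res = estimate_capacity(
            emb,
            n_gaussian_samples=protocol.n_gaussian_samples,
            seed=int(rng.integers(2**31)),
        )
        rows.append(res.as_dict())
    df = pd.DataFrame(rows)
    mean = df.mean()
    agg = CapacityResult(
        alpha=float(mean["alpha"]),
        alpha_se=float(df["alpha"].std(ddof=1) / np.sqrt(len(df)))
        if len(df) > 1 else float(df["alpha_se"].iloc[0]),
        radius=float(mean["radius"]),
        dimension=float(mean["dimension"]),
        center_align=float(mean["center_align"]),
        axes_align=float(mean["axes_align"]),
        center_axes_align=float(mean["center_axes_align"]),
        n_gaussian_samples=protocol.n_gaussian_samples,
        n_manifolds=2,
        seed=seed,
        protocol=protocol,
    )
    return agg, df


def capacity_pipeline(
    activity: ActivityDataset,
    protocol: CapacityProtocol | None = None,
    window: WindowSpec | None = None,
    seed: int = 0,
    subject_id: str = "0",
) -> pd.DataFrame:
    """Per-odor-pair capacity and effective measures (long format).

    For each odor pair: repeat {subsample neurons and patterns, estimate
    capacity and measures}, average over repeats.  With
    ``protocol.shuffle`` the two point clouds are pooled and labels
    reassigned at random before every estimate (the null control).
    """
    if protocol is None:
        protocol = CapacityProtocol()
    manifolds = build_manifolds(activity, window)
    pts = {m.odor: m.points for m in manifolds}
    master = np.random.SeedSequence(seed)
    rows = []
    pairs = list(combinations(activity.panel.odor_ids, 2))
    child_seeds = master.generate_state(len(pairs))
    for (oa, ob), s in zip(pairs, child_seeds):
        res, _ = capacity_pair(pts[oa], pts[ob], protocol, seed=int(s % 2**31))
        rows.append(
            {
                "subject": subject_id,
                "odor_a": oa,
                "odor_b": ob,
                "class_a": activity.panel.class_of[oa],
                "class_b": activity.panel.class_of[ob],
                "shuffled": protocol.shuffle,
                "n_repeats": protocol.n_repeats,
                **res.as_dict(),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model / Results facade
# --------------------------------------------------------------------------

class ManifoldCapacity:
    """Capacity analysis of an activity dataset, statsmodels-style.

    ``ManifoldCapacity(activity, window, protocol).fit(seed)`` returns a
    :class:`CapacityResultsSet` whose table holds one row per odor pair.
    """

    def __init__(
        self,
        activity: ActivityDataset,
        window: WindowSpec | None = None,
        protocol: CapacityProtocol | None = None,
    ):
        self.activity = activity
        self.window = window
        self.protocol = protocol or CapacityProtocol()

    def fit(self, seed: int = 0, subject_id: str = "0") -> "CapacityResultsSet":
        table = capacity_pipeline(
            self.activity, self.protocol, self.window, seed, subject_id
        )
        return CapacityResultsSet(self, table)


@dataclass
class CapacityResultsSet:
    model: ManifoldCapacity
    table: pd.DataFrame

    @property
    def mean_alpha(self) -> float:
        return float(self.table["alpha"].mean())

    def summary(self) -> str:
        p = self.model.protocol
        cols = [
            "odor_a", "odor_b", "alpha", "radius", "dimension",
            "center_align", "axes_align", "center_axes_align",
        ]
        lines = [
            "Manifold capacity analysis",
            f"  protocol: {p.n_neurons_subsample} neurons x "
            f"{p.n_patterns_subsample} patterns, {p.n_repeats} repeats, "
            f"{p.n_gaussian_samples} Gaussian samples"
            + ("  [label-shuffled]" if p.shuffle else ""),
            "",
            self.table[cols].round(4).to_string(index=False),
            "",
            f"mean capacity alpha: {self.mean_alpha:.4f}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
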