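"""Behavioral scoring and the group statistics used across the analysis.

Naive-vs-trained comparisons use a two-sided Mann–Whitney U test; multiple
trained subgroups are compared against the naive control with a
Kruskal–Wallis test followed by Dunn's post-hoc z tests, Bonferroni-
adjusted over the contrasts with the control.  Correlations are ordinary
least squares with the Pearson r reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BehaviorRecord",
    "GroupComparison",
    "discrimination_score",
    "generate_behavior_records",
    "compare_groups_mwu",
    "kruskal_dunn_bonferroni",
    "ols_correlation",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------

@dataclass
class BehaviorRecord:
    """Per-fish appetitive scores (zeta) for CS+ and CS− trials.

    zeta scores are normalized appetitive-behavior measures; the
    discrimination score is the CS+/CS− zeta difference summed over trials
    and divided by the number of individual training days.
    """

    fish_id: str
    zeta_plus: np.ndarray      # one value per CS+ trial
    zeta_minus: np.ndarray     # one value per CS− trial
    n_days: int

    def __post_init__(self):
        self.zeta_plus = np.asarray(self.zeta_plus, dtype=float)
        self.zeta_minus = np.asarray(self.zeta_minus, dtype=float)
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.zeta_plus.size == 0 or self.zeta_minus.size == 0:
            raise ValueError("need at least one trial per conditioned odor")
        if self.zeta_plus.size != self.zeta_minus.size:
            raise ValueError("trial counts for CS+ and CS- must match")


def discrimination_score(record: BehaviorRecord) -> float:
    """Sum over trials of (zeta+ - zeta-) divided by the number of training days."""
    return float(np.sum(record.zeta_plus - record.zeta_minus) / record.n_days)


def generate_behavior_records(
    n_fish: int,
    n_trials: int = 9,
    n_days: int = 3,
    cs_offset: float = 0.5,
    noise: float = 1.0,
    seed: int = 0,
) -> list:
    """Synthetic zeta tables: CS+ trials offset above CS− by ``cs_offset``.

    A stand-in for the video-based appetitive scores, which are outside
    this package's scope; used to exercise the behavior-correlation stage.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_fish):
        zp = cs_offset + noise * rng.standard_normal(n_trials)
        zm = noise * rng.standard_normal(n_trials)
        out.append(BehaviorRecord(f"fish{i}", zp, zm, n_days))
    return out


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Result of a group test with raw and Bonferroni-adjusted P values."""

    test: str                         # "MWU" | "KW+Dunn"
    group_labels: list
    statistic: float
    p_value: float                    # raw omnibus / two-sample P
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    # comparisons columns: group, z_or_u, p_raw, p_adj, stars

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def compare_groups_mwu(values_a, values_b, label_a="a", label_b="b") -> GroupComparison:
    """Two-sided Mann–Whitney U test with tie correction.

    Uses the exact small-sample null when both groups have n <= 8 and no
    ties; the normal approximation (tie-corrected) otherwise.  Identical
    pooled values give P = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; P = 1")
        u = a.size * b.size / 2.0
        res_p = 1.0
    else:
        has_ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u, res_p = float(res.statistic), float(res.pvalue)
    table = pd.DataFrame(
        [{
            "group": f"{label_a} vs {label_b}", "statistic": u,
            "p_raw": res_p, "p_adj": res_p, "stars": significance_stars(res_p),
        }]
    )
    return GroupComparison("MWU", [label_a, label_b], u, res_p, table)


def _dunn_z(ranks: np.ndarray, groups: np.ndarray, gi, gj, tie_term: float) -> float:
    ri = ranks[groups == gi]
    rj = ranks[groups == gj]
    N = ranks.size
    var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / ri.size + 1.0 / rj.size)
    return float((ri.mean() - rj.mean()) / np.sqrt(var))


def kruskal_dunn_bonferroni(groups: dict, control_label: str) -> GroupComparison:
    """Kruskal–Wallis omnibus test followed by Dunn's z against the control.

    Only the contrasts against ``control_label`` enter the Bonferroni
    family (multiplier = number of such contrasts).  Dunn's variance uses
    the tie correction sum(t^3 - t) / (12 (N - 1)).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    pooled = np.concatenate(list(arrays.values()))
    labels = np.concatenate([np.full(v.size, k) for k, v in arrays.items()])
    if np.all(pooled == pooled[0]):
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = sps.kruskal(*arrays.values())
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts) / (12.0 * (pooled.size - 1)))
    others = [k for k in arrays if k != control_label]
    k_comp = len(others)
    rows = []
    for g in others:
        if np.all(pooled == pooled[0]):
            z, p_raw = 0.0, 1.0
        else:
            z = _dunn_z(ranks, labels, g, control_label, tie_term)
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * k_comp)
        rows.append(
            {"group": f"{g} vs {control_label}", "statistic": z,
             "p_raw": p_raw, "p_adj": p_adj, "stars": significance_stars(p_adj)}
        )
    return GroupComparison(
        "KW+Dunn", list(arrays), float(H), float(p_kw), pd.DataFrame(rows)
    )


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

def ols_correlation(x, y) -> dict:
    """OLS regression of y on x: slope, R^2, slope P, plus Pearson r and P.

    The Pearson r equals sign(slope) * sqrt(R^2); both the OLS slope P and
    the Pearson test P are reported (they coincide for simple regression).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired values")
    if np.all(x == x[0]):
        raise ValueError("x is constant; correlation undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    r2 = float(model.rsquared)
    p_slope = float(model.pvalues[1])
    pr = sps.pearsonr(x, y)
    return {
        "slope": slope,
        "intercept": float(model.params[0]),
        "r_squared": r2,
        "p_slope": p_slope,
        "pearson_r": float(pr.statistic),
        "p_pearson": float(pr.pvalue),
        "n": int(x.size),
    }
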