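"""Group statistics for the diet-by-development design.

Three pieces mirror the study's analysis plan:

* :func:`rout_screen` — ROUT outlier screening (robust fit + FDR) of a
  one-sample dataset before any hypothesis test, default Q = 1%.
* :func:`two_way_anova` — diet x time fixed-effects ANOVA with type-III
  sums of squares (tolerant of mildly unbalanced cells), Tukey HSD on
  the diet-by-time cells only when the interaction is significant.
* :func:`one_way_gate` — single-factor contrasts routed by a per-group
  Shapiro-Wilk normality gate to either one-way ANOVA or
  Kruskal-Wallis; the route taken is recorded.

The ANOVA is computed from effect-coded (sum-to-zero) least squares so
it can be run thousands of times in simulation calibrations; it is
parity-tested against statsmodels' anova_lm(typ=3).  Significance is
assessed at alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "RoutResult",
    "rout_screen",
    "two_way_anova",
    "one_way_gate",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
DEFAULT_ROUT_Q = 0.01


# ---------------------------------------------------------------- ROUT

@dataclass(frozen=True)
class RoutResult:
    """Outcome of a ROUT screen: retained values, flagged outliers."""

    retained: np.ndarray
    outliers: np.ndarray
    outlier_indices: tuple
    q: float
    skipped: bool = False


def rout_screen(values: Sequence[float], q: float = DEFAULT_ROUT_Q) -> RoutResult:
    """Screen a one-sample dataset for outliers by the ROUT procedure.

    Robust fit of the constant model: location is the median and scale
    the robust SD from the 68.27th percentile of absolute residuals
    (small-sample corrected by N/(N-K), K = 1).  Residual t-scores are
    tested outermost-first against false-discovery-rate thresholds
    i*Q/N; testing stops at the first non-outlier.  Fewer than 3 values
    skips the screen with a log notice.
    """
    x = np.asarray(values, dtype=float)
    if not (0.0 < q <= 0.1):
        raise ValueError(f"q must lie in (0, 0.1], got {q}")
    n = x.size
    if n < 3:
        logger.info("ROUT screen skipped: n=%d < 3", n)
        return RoutResult(x.copy(), np.array([]), (), q, skipped=True)

    resid = x - np.median(x)
    abs_resid = np.abs(resid)
    scale = np.percentile(abs_resid, 68.27) * n / (n - 1)

    if scale == 0.0:
        # degenerate scale: any non-zero residual is infinitely extreme
        flagged = abs_resid > 0
        p = np.where(flagged, 0.0, 1.0)
        t = np.where(flagged, np.inf, 0.0)
    else:
        t = abs_resid / scale
        p = 2.0 * sps.t.sf(t, df=n - 1)

    order = np.argsort(-t, kind="stable")  # outermost first
    out_idx: list[int] = []
    for rank, idx in enumerate(order, start=1):
        if p[idx] < q * rank / n:
            out_idx.append(int(idx))
        else:
            break
    mask = np.ones(n, dtype=bool)
    mask[out_idx] = False
    if out_idx:
        logger.info("ROUT flagged %d outlier(s) at Q=%g: %s", len(out_idx), q, x[~mask])
    return RoutResult(x[mask], x[~mask], tuple(sorted(out_idx)), q)


# ------------------------------------------------------ two-way ANOVA

@dataclass(frozen=True)
class AnovaResult:
    """One tested effect: F statistic, p value, optional post hoc."""

    effect: str
    f: float
    p: float
    df: tuple
    posthoc: tuple = ()  # (pair_label, difference, adjusted p)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _effect_codes(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero contrast columns (k-1) for a categorical factor."""
    k = len(levels)
    cols = np.zeros((labels.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (labels == lev).astype(float)
    cols[labels == levels[-1], :] = -1.0
    return cols


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "diet",
    factor_b: str = "timepoint",
    alpha: float = ALPHA,
    tukey: bool = True,
) -> "list[AnovaResult]":
    """Fixed-effects two-factor ANOVA with type-III sums of squares.

    Each effect's SS is the increase in residual SS when its
    effect-coded columns are dropped from the full interaction model.
    Tukey HSD over the factor-a x factor-b cells is appended to the
    interaction result only when the interaction is significant at
    ``alpha``.  Empty cells raise with the missing cells listed.
    """
    a = data[factor_a].to_numpy()
    b = data[factor_b].to_numpy()
    y = data[response].to_numpy(dtype=float)
    lev_a = sorted(pd.unique(a).tolist())
    lev_b = sorted(pd.unique(b).tolist())
    if len(lev_a) < 2 or len(lev_b) < 2:
        raise ValueError("each factor needs at least 2 levels")

    missing = [
        (la, lb)
        for la, lb in itertools.product(lev_a, lev_b)
        if not np.any((a == la) & (b == lb))
    ]
    if missing:
        raise ValueError(f"unbalanced design: empty cells {missing}")

    Xa = _effect_codes(a, lev_a)
    Xb = _effect_codes(b, lev_b)
    Xab = np.einsum("ij,ik->ijk", Xa, Xb).reshape(len(y), -1)
    ones = np.ones((len(y), 1))
    X_full = np.hstack([ones, Xa, Xb, Xab])

    sse_full = _sse(y, X_full)
    df_resid = len(y) - X_full.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (need replication)")
    # a residual SS at float-noise level (constant response / perfect
    # fit) is treated as exactly zero
    if sse_full <= 1e-10 * (float(y @ y) / len(y) + 1.0):
        sse_full = 0.0
    mse = sse_full / df_resid

    blocks = {
        factor_a: (1, 1 + Xa.shape[1]),
        factor_b: (1 + Xa.shape[1], 1 + Xa.shape[1] + Xb.shape[1]),
        f"{factor_a}:{factor_b}": (1 + Xa.shape[1] + Xb.shape[1], X_full.shape[1]),
    }
    results = []
    interaction_p = 1.0
    for name, (lo, hi) in blocks.items():
        X_red = np.delete(X_full, np.s_[lo:hi], axis=1)
        ss = _sse(y, X_red) - sse_full
        df_eff = hi - lo
        if mse == 0.0:
            # constant response (or perfect fit): no evidence of effects
            f_stat, p = 0.0, 1.0
        else:
            f_stat = max(ss, 0.0) / df_eff / mse
            p = float(sps.f.sf(f_stat, df_eff, df_resid))
        if name.count(":"):
            interaction_p = p
        results.append(AnovaResult(effect=name, f=float(f_stat), p=p,
                                   df=(df_eff, df_resid)))

    if tukey and interaction_p < alpha:
        posthoc = _tukey_cells(y, a, b)
        inter = results[-1]
        results[-1] = AnovaResult(
            effect=inter.effect, f=inter.f, p=inter.p, df=inter.df, posthoc=posthoc
        )
    return results


def _tukey_cells(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple:
    """Tukey HSD over all factor-cell pairs, via statsmodels."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    cells = np.array([f"{x}/{z}" for x, z in zip(a, b)])
    res = pairwise_tukeyhsd(y, cells)
    out = []
    for row in res.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], row[2], row[3]
        out.append((f"{g1} vs {g2}", float(meandiff), float(p_adj)))
    return tuple(out)


# ---------------------------------------------------- one-way gating

@dataclass(frozen=True)
class GatedResult:
    """Single-factor test outcome with the route that was taken."""

    route: str  # "anova" or "kruskal"
    statistic: float
    p: float
    shapiro_p: tuple


def one_way_gate(
    groups: "Sequence[Sequence[float]] | dict[str, Sequence[float]]",
    alpha: float = ALPHA,
) -> GatedResult:
    """Shapiro-gated single-factor comparison.

    Each group is tested for normality by Shapiro-Wilk at ``alpha``;
    if every group passes, a one-way ANOVA is run, otherwise
    Kruskal-Wallis.  Groups too small for Shapiro (n < 3) route to the
    nonparametric test with a log notice.
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")

    shapiro_ps: list[float] = []
    parametric = True
    for g in arrays:
        if g.size < 3:
            logger.info("group n=%d < 3: routing to Kruskal-Wallis", g.size)
            parametric = False
            shapiro_ps.append(float("nan"))
            continue
        if np.ptp(g) == 0.0:
            shapiro_ps.append(1.0)  # identical values: vacuously normal
            continue
        p = float(sps.shapiro(g).pvalue)
        shapiro_ps.append(p)
        if p < alpha:
            parametric = False

    if all(np.ptp(g) == 0.0 for g in arrays) and len({g[0] for g in arrays}) == 1:
        # all groups identical: no difference under either route
        route = "anova" if parametric else "kruskal"
        return GatedResult(route=route, statistic=0.0, p=1.0,
                           shapiro_p=tuple(shapiro_ps))

    if parametric:
        stat, p = sps.f_oneway(*arrays)
        route = "anova"
    else:
        stat, p = sps.kruskal(*arrays)
        route = "kruskal"
    logger.info("one-way gate routed to %s (p=%.4g)", route, p)
    return GatedResult(route=route, statistic=float(stat), p=float(p),
                       shapiro_p=tuple(shapiro_ps))
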