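"""Voxelwise 2x2 mixed-design ANOVA and regional correlation analyses.

The design has one between-subject factor (group: patients vs controls) and one
within-subject factor with two levels (frequency band: slow-4 vs slow-5).  With
two within-subject levels every effect reduces exactly to a t statistic on
per-subject summaries — with m_i = (y4_i + y5_i)/2 and d_i = y4_i - y5_i:

* group effect:       pooled-variance two-sample t on {m_i}
* interaction:        pooled-variance two-sample t on {d_i}
* band main effect:   t for the unweighted mean of the two group means of d
                      against 0, SE = s_d * sqrt((1/n1 + 1/n2) / 4)

All three use df = n1 + n2 - 2 and satisfy t^2 = F of the classical split-plot
ANOVA.  Signs: group = group1 - group2, band = slow4 - slow5.  The unweighted
band mean matches Type-III conventions under imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .errors import CollinearityError, DegenerateInputError, DomainError, FormatError


@dataclass(frozen=True)
class EffectResult:
    effect_name: str  # "group" | "band" | "interaction"
    t: float
    df: int
    p_two_tailed: float


@dataclass
class StatMaps:
    """Voxelwise signed t maps for the three mixed-ANOVA effects."""

    t_group: np.ndarray
    t_band: np.ndarray
    t_interaction: np.ndarray
    df: int
    n1: int
    n2: int

    def effect(self, name: str) -> np.ndarray:
        return {"group": self.t_group, "band": self.t_band,
                "interaction": self.t_interaction}[name]

    def p_map(self, name: str) -> np.ndarray:
        t = self.effect(name)
        with np.errstate(invalid="ignore"):
            return 2.0 * scipy.stats.t.sf(np.abs(t), self.df)


def _two_sample_t(values: np.ndarray, g1: np.ndarray, g2: np.ndarray):
    """Pooled-variance two-sample t along axis 0; returns (t, pooled s^2, dmean)."""
    n1, n2 = int(g1.sum()), int(g2.sum())
    v1, v2 = values[g1], values[g2]
    m1, m2 = v1.mean(axis=0), v2.mean(axis=0)
    ss = ((v1 - m1) ** 2).sum(axis=0) + ((v2 - m2) ** 2).sum(axis=0)
    s2 = ss / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return t, s2, (m1, m2)


def _anova_core(y4: np.ndarray, y5: np.ndarray, group: np.ndarray):
    """Vectorized closed-form 2x2 split-plot t statistics.

    ``y4``/``y5`` have subjects on axis 0; returns (t_group, t_band, t_int, df).
    Voxels with zero pooled variance come out NaN.
    """
    group = np.asarray(group)
    g1, g2 = group == 1, group == 2
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise DomainError(f"each group needs n >= 2, got n1={n1}, n2={n2}")
    if not np.all(g1 | g2):
        raise DomainError("group labels must be 1 or 2")
    m = 0.5 * (y4 + y5)
    d = y4 - y5
    t_group, s2_m, _ = _two_sample_t(m, g1, g2)
    t_int, s2_d, (d1m, d2m) = _two_sample_t(d, g1, g2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_band = (0.5 * (d1m + d2m)) / np.sqrt(s2_d * (1.0 / n1 + 1.0 / n2) / 4.0)
    # zero-variance voxels are degenerate, not evidence
    eps = np.finfo(float).tiny
    t_group = np.where(s2_m > eps, t_group, np.nan)
    t_band = np.where(s2_d > eps, t_band, np.nan)
    t_int = np.where(s2_d > eps, t_int, np.nan)
    return t_group, t_band, t_int, n1 + n2 - 2, n1, n2


def mixed_anova_2x2(
    y_band4: Sequence[float], y_band5: Sequence[float], group: Sequence[int]
) -> dict[str, EffectResult]:
    """Group, band and interaction effects for one voxel/region.

    Raises :class:`DegenerateInputError` when a pooled variance is zero.
    """
    y4 = np.asarray(y_band4, dtype=float)
    y5 = np.asarray(y_band5, dtype=float)
    group = np.asarray(group)
    if not (y4.shape == y5.shape == group.shape) or y4.ndim != 1:
        raise DomainError("y_band4, y_band5 and group must be equal-length vectors")
    t_g, t_b, t_i, df, _, _ = _anova_core(y4, y5, group)
    out = {}
    for name, t in (("group", t_g), ("band", t_b), ("interaction", t_i)):
        t = float(t)
        if not np.isfinite(t):
            raise DegenerateInputError(f"zero pooled variance for {name} effect")
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
        out[name] = EffectResult(name, t, df, p)
    return out


def voxelwise_mixed_anova(
    maps_band4: np.ndarray,
    maps_band5: np.ndarray,
    group: Sequence[int],
    mask: Optional[np.ndarray] = None,
) -> StatMaps:
    """Apply the 2x2 mixed ANOVA independently at every in-mask voxel.

    ``maps_band4``/``maps_band5`` are (n_subjects, x, y, z) stacks on a common
    grid.  Out-of-mask and degenerate (zero-variance) voxels are NaN.
    """
    y4 = np.asarray(maps_band4, dtype=float)
    y5 = np.asarray(maps_band5, dtype=float)
    if y4.shape != y5.shape or y4.ndim != 4:
        raise FormatError("band map stacks must share one (n, x, y, z) shape")
    if mask is None:
        mask = np.ones(y4.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != y4.shape[1:]:
        raise FormatError("mask shape does not match map grid")
    t_g, t_b, t_i, df, n1, n2 = _anova_core(y4[:, mask], y5[:, mask], np.asarray(group))

    def fill(values: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = values
        return out

    return StatMaps(fill(t_g), fill(t_b), fill(t_i), df=df, n1=n1, n2=n2)


def critical_t(p_two_tailed: float, df: int) -> float:
    """Two-tailed critical value of Student's t (e.g. 1.9908 for p=0.05, df=78)."""
    if not 0 < p_two_tailed < 1:
        raise DomainError("p must lie in (0, 1)")
    if df < 1:
        raise DomainError("df must be >= 1")
    return float(scipy.stats.t.ppf(1.0 - p_two_tailed / 2.0, df))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-tailed p (t with df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DomainError("pearson_corr needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * scipy.stats.t.sf(abs(t), n - 2))


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_corr(
    x: Sequence[float], y: Sequence[float], covariates: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Correlation of x and y after removing covariates from both by OLS.

    With k covariates the p-value uses df = n - 2 - k; with none this equals
    :func:`pearson_corr` exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return pearson_corr(x, y)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.size:
        cov = cov.T
    if cov.shape[0] != x.size:
        raise DomainError("covariate matrix must have one row per subject")
    n, k = cov.shape
    if n <= k + 2:
        raise DomainError(f"need n > k + 2 subjects (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate matrix (with intercept) is rank deficient")
    rx, ry = _residualize(x, design), _residualize(y, design)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError("a variable is fully explained by the covariates")
    xc, yc = rx - rx.mean(), ry - ry.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * scipy.stats.t.sf(abs(t), df))


def voxelwise_regression(
    maps: np.ndarray, covariate: Sequence[float], mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-voxel OLS slope t map of map value on a covariate (with intercept).

    df = n - 2.  Voxels with zero residual variance but nonzero slope come out
    +/-inf (flagged perfect fit); constant voxels come out NaN.
    """
    maps = np.asarray(maps, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if maps.ndim != 4 or maps.shape[0] != cov.size:
        raise FormatError("maps must be (n_subjects, x, y, z) matching the covariate")
    if cov.size < 3:
        raise DomainError("regression needs at least 3 subjects")
    if np.ptp(cov) == 0:
        raise DegenerateInputError("constant covariate")
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    y = maps[:, mask]
    n = cov.size
    c = cov - cov.mean()
    sxx = np.dot(c, c)
    slope = (c @ y) / sxx
    resid = y - np.outer(cov, slope) - (y.mean(axis=0) - cov.mean() * slope)
    sse = (resid ** 2).sum(axis=0)
    sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    perfect = sse <= 1e-12 * np.maximum(sst, np.finfo(float).tiny)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = slope / se
        t = np.where(perfect & (np.abs(slope) > 0), np.sign(slope) * np.inf, t)
        t = np.where(sst == 0, np.nan, t)
    out = np.full(mask.shape, np.nan)
    out[mask] = t
    return out


def extract_cluster_means(maps: np.ndarray, cluster_mask: np.ndarray) -> np.ndarray:
    """Mean in-cluster value per subject, preserving subject order."""
    maps = np.asarray(maps, dtype=float)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if maps.ndim != 4 or maps.shape[1:] != cluster_mask.shape:
        raise FormatError("maps must be (n_subjects, x, y, z) on the cluster grid")
    if not cluster_mask.any():
        raise DomainError("empty cluster mask")
    return maps[:, cluster_mask].mean(axis=1)
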