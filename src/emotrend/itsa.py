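"""Two-group interrupted time series analysis.

Segmented OLS on stacked weekly series from two groups with design columns
``[1, t, D, P, g, g*t, g*D, g*P]`` where ``D = 1{t >= T0}`` and
``P = (t - T0) * D`` (so P is 0 at the interruption week itself and the
level-change coefficient applies at T0). Standard errors are Newey-West
(Bartlett kernel, lag L) computed within each group's own time-ordered
series — lagged residual products never cross the group boundary — with the
``n / (n - k)`` small-sample factor. Two-sided p-values use a Student-t
reference with ``n - 8`` degrees of freedom.

Coefficient semantics (group g=0 is the reference):
  b0 level and b1 slope of the reference group pre-interruption; b2 level
  change and b3 slope change at the interruption; b4..b7 the corresponding
  group contrasts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COEF_NAMES",
    "COLUMN_LABELS",
    "ITSAFit",
    "build_design",
    "fit_ols",
    "newey_west_cov",
    "select_lag",
    "fit_itsa",
]

COEF_NAMES = tuple(f"b{i}" for i in range(8))
COLUMN_LABELS = ("1", "t", "D", "P", "g", "g*t", "g*D", "g*P")


def _series_dict(series_by_group) -> Dict[int, np.ndarray]:
    """Accept {0: values, 1: values} or a tidy (group, week, value) frame."""
    if isinstance(series_by_group, pd.DataFrame):
        need = {"group", "week", "value"}
        if not need.issubset(series_by_group.columns):
            raise ValueError(f"tidy input needs columns {sorted(need)}")
        out = {}
        for g, sub in series_by_group.groupby("group"):
            sub = sub.sort_values("week")
            weeks = sub["week"].to_numpy()
            if not np.array_equal(weeks, np.arange(weeks[0], weeks[0] + len(weeks))):
                raise ValueError(f"group {g!r}: weeks are not consecutive")
            out[g] = sub["value"].to_numpy(dtype=float)
        return out
    return {g: np.asarray(v, dtype=float) for g, v in dict(series_by_group).items()}


def build_design(series_by_group, t0: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack both groups into (X, y, group) with columns
    ``[1, t, D, P, g, g*t, g*D, g*P]``; weeks are 1-based."""
    series = _series_dict(series_by_group)
    if len(series) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(series)}")
    lengths = {g: len(v) for g, v in series.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"unequal week coverage across groups: {lengths}")
    n_weeks = next(iter(lengths.values()))
    if not 1 <= t0 <= n_weeks:
        raise ValueError(f"t0={t0} outside the 1..{n_weeks} week range")
    keys = sorted(series)
    blocks, ys, groups = [], [], []
    t = np.arange(1, n_weeks + 1, dtype=float)
    d = (t >= t0).astype(float)
    p = (t - t0) * d
    for gval, key in zip((0.0, 1.0), keys):
        y = series[key]
        if np.isnan(y).any():
            raise ValueError(f"group {key!r}: series contains missing values; supply complete series")
        base = np.column_stack([np.ones(n_weeks), t, d, p])
        blocks.append(np.hstack([base, gval * base]))
        ys.append(y)
        groups.append(np.full(n_weeks, gval))
    return np.vstack(blocks), np.concatenate(ys), np.concatenate(groups)


def fit_ols(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least squares fit; returns (beta, residuals, r_square).

    R^2 is ``1 - SSR/SST`` with SST centered on the grand mean; a constant
    response (zero SST) gets R^2 = 0 by convention. Rank deficiency raises,
    naming the involved columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more rows ({n}) than columns ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        cols = sorted({int(j) for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]})
        labels = [COLUMN_LABELS[j] if j < len(COLUMN_LABELS) else str(j) for j in cols]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {labels}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(resid @ resid)
    r2 = 0.0 if sst == 0.0 else 1.0 - ssr / sst
    return beta, resid, r2


def newey_west_cov(
    X: np.ndarray,
    residuals: np.ndarray,
    lag: int,
    groups: Optional[np.ndarray] = None,
    small_sample: bool = True,
) -> np.ndarray:
    """HAC sandwich covariance with Bartlett weights ``w_l = 1 - l/(L+1)``.

    ``groups`` marks contiguous per-group time series; lagged cross-products
    are only taken within a group, never across the boundary. ``lag=0``
    reduces exactly to the heteroskedasticity-robust (White) covariance.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n, k = X.shape
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if groups is None:
        groups = np.zeros(n)
    groups = np.asarray(groups)
    # contiguous blocks in row order
    boundaries = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1], True])
    blocks = [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]
    min_len = min(b - a for a, b in blocks)
    if lag >= min_len:
        raise ValueError(f"lag {lag} must be smaller than the shortest group series ({min_len})")

    meat = (X * e[:, None] ** 2).T @ X
    for l in range(1, lag + 1):
        w = 1.0 - l / (lag + 1.0)
        for a, b in blocks:
            Xb, eb = X[a:b], e[a:b]
            gamma = (Xb[l:] * (eb[l:] * eb[:-l])[:, None]).T @ Xb[:-l]
            meat += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ meat @ bread
    if small_sample:
        cov *= n / (n - k)
    return (cov + cov.T) / 2.0


def select_lag(
    residuals: Union[np.ndarray, Sequence[float]],
    max_lag: int,
    alpha: float = 0.05,
    groups: Optional[np.ndarray] = None,
) -> Tuple[int, pd.DataFrame]:
    """Residual-autocorrelation lag diagnostic.

    Computes per-lag autocorrelations with large-sample significance bounds
    ``z_{1-alpha/2}/sqrt(n)`` (per group when ``groups`` is given) and
    returns ``(suggested_lag, table)`` where the suggestion is the largest
    lag <= max_lag with a significant autocorrelation in any group, else 0.
    Constant residuals have undefined autocorrelation -> 0 with a warning.
    """
    e = np.asarray(residuals, dtype=float)
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    if groups is None:
        groups = np.zeros(len(e))
    groups = np.asarray(groups)
    rows = []
    suggested = 0
    for g in pd.unique(groups):
        eg = e[groups == g]
        n = len(eg)
        if max_lag >= n:
            raise ValueError(f"max_lag {max_lag} >= series length {n}")
        centered = eg - eg.mean()
        denom = float(centered @ centered)
        bound = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n)
        if denom == 0.0:
            warnings.warn("constant residuals: autocorrelation undefined; suggesting lag 0", stacklevel=2)
            for l in range(1, max_lag + 1):
                rows.append({"group": g, "lag": l, "acf": np.nan, "bound": bound, "significant": False})
            continue
        for l in range(1, max_lag + 1):
            r = float(centered[l:] @ centered[:-l]) / denom
            sig = abs(r) > bound
            rows.append({"group": g, "lag": l, "acf": r, "bound": bound, "significant": sig})
            if sig:
                suggested = max(suggested, l)
    return suggested, pd.DataFrame(rows)


@dataclass
class ITSAFit:
    """Fitted two-group segmented regression with HAC inference."""

    beta: np.ndarray
    hac_se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    r_square: float
    n: int
    lag: int
    t0: int
    cov: np.ndarray
    residuals: np.ndarray = field(repr=False, default=None)
    names: Tuple[str, ...] = COEF_NAMES

    @property
    def dof(self) -> int:
        return self.n - len(self.beta)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.t.ppf(0.5 + level / 2.0, self.dof)
        return np.column_stack([self.beta - q * self.hac_se, self.beta + q * self.hac_se])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "b": self.beta,
                "approx_se": self.hac_se,
                "t_value": self.t_stat,
                "p_value": self.p_value,
            }
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {nm: float(b) for nm, b in zip(self.names, self.beta)},
            "hac_se": {nm: float(s) for nm, s in zip(self.names, self.hac_se)},
            "t_value": {nm: float(t) for nm, t in zip(self.names, self.t_stat)},
            "p_value": {nm: float(p) for nm, p in zip(self.names, self.p_value)},
            "r_square": float(self.r_square),
            "n": int(self.n),
            "lag": int(self.lag),
            "t0": int(self.t0),
            "dof": int(self.dof),
            "conventions": {
                "post_time_origin": "P = 0 at the interruption week",
                "p_values": "two-sided Student-t, dof = n - 8",
                "small_sample_hac_factor": "n / (n - k)",
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"Two-group interrupted time series fit (n={self.n}, T0={self.t0}, lag={self.lag})",
            f"{'Parameter':<10}{'b':>12}{'Approx. SE':>12}{'t Value':>10}{'Pr > |t|':>12}",
        ]
        for nm, b, se, t, p in zip(self.names, self.beta, self.hac_se, self.t_stat, self.p_value):
            pstr = "<0.0001" if p < 1e-4 else f"{p:.4f}"
            lines.append(f"{nm:<10}{b:>12.3f}{se:>12.3f}{t:>10.2f}{pstr:>12}")
        lines.append(f"{'R-square':<10}{self.r_square:>12.3f}")
        return "\n".join(lines)


def fit_itsa(series_by_group, t0: int, lag: int) -> ITSAFit:
    """Compose design construction, OLS, and Newey-West inference."""
    X, y, groups = build_design(series_by_group, t0)
    beta, resid, r2 = fit_ols(X, y)
    cov = newey_west_cov(X, resid, lag, groups=groups)
    se = np.sqrt(np.diag(cov))
    n = len(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - X.shape[1])
    return ITSAFit(
        beta=beta,
        hac_se=se,
        t_stat=t_stat,
        p_value=p,
        r_square=r2,
        n=n,
        lag=lag,
        t0=t0,
        cov=cov,
        residuals=resid,
    )
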