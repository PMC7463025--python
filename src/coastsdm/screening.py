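"""Pre-model collinearity screening of continuous predictors.

Two iterative exclusion procedures mirror the `usdm` conventions used in
ecological modelling:

* ``vifcor`` — while the largest pairwise |Pearson r| exceeds a threshold
  (default 0.7), drop the member of that pair with the higher VIF;
* ``vifstep`` — while the largest VIF exceeds a threshold (default 3),
  drop that variable.

VIF_j = 1 / (1 - R²_j), with R²_j from an intercept-including ordinary
least-squares regression of variable j on all other retained variables.
Categorical predictors are excluded from screening (Pearson correlation
is undefined for unordered classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityConfig",
    "ScreeningReport",
    "pearson_matrix",
    "vif",
    "vifcor",
    "vifstep",
]


@dataclass(frozen=True)
class CollinearityConfig:
    r_threshold: float = 0.7
    vif_threshold: float = 3.0

    def __post_init__(self):
        if not (0 < self.r_threshold < 1):
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")


@dataclass
class ScreeningReport:
    """Outcome of one screening procedure."""

    retained: list
    removed: list = field(default_factory=list)  # (name, reason, value)

    def to_dict(self):
        return {
            "retained": list(self.retained),
            "removed": [
                {"variable": n, "reason": r, "value": float(v)}
                for n, r, v in self.removed
            ],
        }


def _continuous(features: pd.DataFrame) -> pd.DataFrame:
    num = features.select_dtypes(include=[np.number])
    dropped = [c for c in features.columns if c not in num.columns]
    if dropped:
        logger.info("screening skips non-numeric columns: %s", dropped)
    return num


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of continuous columns."""
    num = _continuous(features)
    if len(num) < 2:
        raise ValueError("need at least 2 rows")
    sd = num.std(ddof=0)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance columns: {zero_var}")
    return num.corr(method="pearson")


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each continuous column.

    Exact linear dependence is reported as ``inf`` rather than raised, so
    the exclusion loops can handle it.
    """
    num = _continuous(features)
    if len(num) <= num.shape[1]:
        raise ValueError("need more rows than variables")
    out = {}
    for col in num.columns:
        y = num[col].to_numpy(dtype=float)
        X = sm.add_constant(num.drop(columns=col).to_numpy(dtype=float))
        r2 = sm.OLS(y, X).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _max_offdiag(corr: pd.DataFrame):
    a = corr.to_numpy(copy=True)
    np.fill_diagonal(a, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(a)), a.shape)
    return corr.index[i], corr.columns[j], abs(a[i, j])


def _pick_higher_vif(pair, vifs, order):
    """Member of the pair with the higher VIF; ties -> later in input order."""
    va, vb = vifs[pair[0]], vifs[pair[1]]
    if va == vb:
        loser = max(pair, key=order.index)
        logger.info("VIF tie between %s; dropping later variable %s", pair, loser)
        return loser
    return pair[0] if va > vb else pair[1]


def vifcor(features: pd.DataFrame, config: CollinearityConfig | None = None) -> ScreeningReport:
    """Iterative exclusion driven by the maximum pairwise correlation."""
    config = config or CollinearityConfig()
    num = _continuous(features)
    order = list(num.columns)
    current = num.copy()
    removed = []
    while current.shape[1] >= 2:
        a, b, r = _max_offdiag(pearson_matrix(current))
        if r <= config.r_threshold:
            break
        vifs = vif(current)
        loser = _pick_higher_vif((a, b), vifs, order)
        removed.append((loser, "max-r", r))
        current = current.drop(columns=loser)
    return ScreeningReport(retained=list(current.columns), removed=removed)


def vifstep(features: pd.DataFrame, config: CollinearityConfig | None = None) -> ScreeningReport:
    """Iterative exclusion of the single highest-VIF variable."""
    config = config or CollinearityConfig()
    num = _continuous(features)
    order = list(num.columns)
    current = num.copy()
    removed = []
    while current.shape[1] >= 2:
        vifs = vif(current)
        vmax = vifs.max()
        if vmax <= config.vif_threshold:
            break
        worst = [c for c in current.columns if vifs[c] == vmax]
        loser = max(worst, key=order.index) if len(worst) > 1 else worst[0]
        removed.append((loser, "max-VIF", vmax))
        current = current.drop(columns=loser)
    if current.shape[1] == 0:
        raise ValueError("degenerate screening: all variables removed")
    if current.shape[1] == 1 and len(order) > 1:
        logger.warning("screening removed all but one variable")
    return ScreeningReport(retained=list(current.columns), removed=removed)
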