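"""Linear age trends in cell-type composition.

For each cell type within each (strain, tissue) stratum, percent is regressed
on age in months by ordinary least squares; the slope (percent per month) is
tested with a two-sided t-test and p-values are BH-adjusted across cell types
within the stratum. Percentages are fit untransformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from agesig.errors import AnalysisError
from agesig.diffassoc import bh_adjust

TREND_COLUMNS = ["cell_type", "stratum", "slope", "se", "p", "fdr", "n", "degenerate"]


def _ols_slope(age: np.ndarray, pct: np.ndarray) -> tuple[float, float, float, bool]:
    """Closed-form OLS of pct on age: (slope, se, p, degenerate)."""
    n = len(age)
    xbar, ybar = age.mean(), pct.mean()
    sxx = np.sum((age - xbar) ** 2)
    sxy = np.sum((age - xbar) * (pct - ybar))
    slope = sxy / sxx
    resid = pct - (ybar + slope * (age - xbar))
    sse = float(resid @ resid)
    scale = max(float(np.sum(pct**2)), 1.0)
    if sse <= 1e-12 * scale or n <= 2:
        return float(slope), 0.0, np.nan, True
    s2 = sse / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return float(slope), se, p, False


def fit_composition_trends(table: pd.DataFrame) -> pd.DataFrame:
    """Fit per-cell-type age trends within each strain x tissue stratum.

    ``table`` needs columns animal_id, strain, tissue, age_months, cell_type,
    percent. Degenerate zero-residual fits return the exact slope with p and
    fdr unavailable (NaN) and ``degenerate=True``. Raises
    :class:`AnalysisError` when a stratum has a single age.
    """
    required = {"animal_id", "strain", "tissue", "age_months", "cell_type", "percent"}
    missing = required - set(table.columns)
    if missing:
        raise AnalysisError(f"composition table missing columns: {sorted(missing)}")
    rows = []
    for (strain, tissue), stratum_table in table.groupby(["strain", "tissue"], sort=True):
        label = f"{strain}:{tissue}"
        if stratum_table["age_months"].nunique() < 2:
            raise AnalysisError(f"stratum {label!r}: needs >= 2 distinct ages")
        stratum_rows = []
        for cell_type, sub in stratum_table.groupby("cell_type", sort=True):
            age = sub["age_months"].to_numpy(dtype=float)
            pct = sub["percent"].to_numpy(dtype=float)
            if len(sub) < 3 or len(np.unique(age)) < 2:
                raise AnalysisError(
                    f"stratum {label!r}, cell type {cell_type!r}: "
                    "need >= 3 animals spanning >= 2 ages"
                )
            slope, se, p, degenerate = _ols_slope(age, pct)
            stratum_rows.append([cell_type, label, slope, se, p, np.nan, len(sub), degenerate])
        # BH across cell types within the stratum (degenerate fits excluded)
        ps = np.array([r[4] for r in stratum_rows])
        ok = ~np.isnan(ps)
        if ok.any():
            adj = bh_adjust(ps[ok])
            j = 0
            for i, r in enumerate(stratum_rows):
                if ok[i]:
                    r[5] = adj[j]
                    j += 1
        rows.extend(stratum_rows)
    return pd.DataFrame(rows, columns=TREND_COLUMNS)
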