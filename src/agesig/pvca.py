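"""Principal variance component analysis (PVCA).

PVCA attributes overall data variance to experimental factors by combining
PCA with per-component variance-component models: features are standardized,
the sample-sample covariance is eigendecomposed, and for each retained
principal component a random-intercept model with one random effect per
factor is fit (REML; non-negative method-of-moments fallback). Absolute
variance components are summed across retained PCs — the REML fits undo the
(L-1)/L shrinkage that realized level contrasts impose on eigenvalues — with
unretained eigenvalue mass credited to the residual, and the totals are
normalized to proportions.

Factors are treated as categorical (age included — a random intercept needs
levels); single-level factors are dropped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from agesig.errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class PvcaResult:
    """Eigenvalue-weighted variance proportions per factor (plus residual)."""

    proportions: pd.Series
    pc_weights: np.ndarray
    n_pcs: int
    cumulative_variance: float
    per_pc: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.proportions.rename("proportion").rename_axis("factor").reset_index()


def _reml_components(score: np.ndarray, factors: pd.DataFrame) -> dict[str, float] | None:
    """REML variance components via a mixed model with one VC per factor."""
    df = factors.copy()
    df["_score"] = score
    df["_all"] = 1
    vc = {f: f"0 + C({f})" for f in factors.columns}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "_score ~ 1", groups="_all", vc_formula=vc, re_formula="0", data=df
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=500, disp=False)
        comps = dict(zip(model.exog_vc.names, np.maximum(fit.vcomp, 0.0)))
        comps["residual"] = max(float(fit.scale), 0.0)
        if not all(np.isfinite(v) for v in comps.values()):
            return None
        # sanity check: the fitted components must roughly reproduce the score
        # variance (REML silently collapses on degenerate, noise-free scores)
        observed = float(np.var(score, ddof=1))
        if observed > 0 and not (observed / 3.0 <= sum(comps.values()) <= observed * 3.0):
            return None
        return comps
    except Exception:  # fall back to moments on any fitting failure
        return None


def _moment_components(score: np.ndarray, factors: pd.DataFrame) -> dict[str, float]:
    """Non-negative method-of-moments fallback for balanced designs.

    Residual variance from the additive fixed-effects OLS fit; each factor's
    component from the variance of its level means minus the residual share
    (other factors cancel in level-mean differences under balance).
    """
    n = len(score)
    dummies = [np.ones((n, 1))]
    for f in factors.columns:
        d = pd.get_dummies(factors[f], drop_first=True).to_numpy(dtype=float)
        dummies.append(d)
    X = np.column_stack(dummies)
    beta, *_ = np.linalg.lstsq(X, score, rcond=None)
    resid = score - X @ beta
    df_resid = max(n - np.linalg.matrix_rank(X), 1)
    s2_res = float(resid @ resid) / df_resid

    comps = {}
    for f in factors.columns:
        groups = pd.Series(score).groupby(factors[f].to_numpy())
        level_means = groups.mean().to_numpy()
        m_per_level = n / len(level_means)
        s2_means = float(np.var(level_means, ddof=1)) if len(level_means) > 1 else 0.0
        comps[f] = max(s2_means - s2_res / m_per_level, 0.0)
    comps["residual"] = s2_res
    return comps


def pvca_decompose(
    features: pd.DataFrame,
    factors: pd.DataFrame,
    var_threshold: float = 0.6,
    min_pcs: int = 3,
) -> PvcaResult:
    """Attribute data variance to metadata factors.

    ``features``: features x samples; ``factors``: samples x factor columns
    (categorical). Retains the smallest number of PCs whose cumulative
    variance reaches ``var_threshold`` (at least ``min_pcs``), fits per-PC
    variance components, and returns eigenvalue-weighted proportions summing
    to 1.
    """
    factors = factors.loc[features.columns]
    usable = []
    for f in factors.columns:
        if factors[f].nunique() < 2:
            logger.warning("factor %r has a single level; dropped from PVCA", f)
        else:
            usable.append(f)
    if not usable:
        raise AnalysisError("no factor with >= 2 levels; PVCA impossible")
    factors = factors[usable].astype(str)

    x = features.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = (x[keep] - mu[keep]) / sd[keep]
    if z.shape[0] == 0:
        raise AnalysisError("all features are constant")

    n = z.shape[1]
    cov = (z.T @ z) / (z.shape[0] - 1 if z.shape[0] > 1 else 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]

    total = eigval.sum()
    cum = np.cumsum(eigval) / total
    n_pcs = int(np.searchsorted(cum, var_threshold) + 1)
    n_pcs = max(n_pcs, min_pcs)
    n_pcs = min(n_pcs, n - 1, int((eigval > 1e-12 * total).sum()))
    n_pcs = max(n_pcs, 1)

    labels = usable + ["residual"]
    per_pc_rows = []
    abs_components = {k: 0.0 for k in labels}
    for i in range(n_pcs):
        score = eigvec[:, i] * np.sqrt(max(eigval[i], 0.0))
        comps = _reml_components(score, factors)
        if comps is None:
            comps = _moment_components(score, factors)
        total_var = sum(comps.values())
        if total_var <= 0:
            props = {f: 0.0 for f in usable}
            props["residual"] = 1.0
        else:
            props = {k: comps[k] / total_var for k in labels}
        per_pc_rows.append(props)
        for k in labels:
            abs_components[k] += comps.get(k, 0.0)

    per_pc = pd.DataFrame(per_pc_rows, index=[f"PC{i + 1}" for i in range(n_pcs)])
    # Aggregate ABSOLUTE variance components across retained PCs: the per-PC
    # REML fit corrects the (L-1)/L shrinkage that realized level contrasts
    # impose on the eigenvalues, so summed components recover the generative
    # variances where eigenvalue-share-weighted proportions systematically
    # under-count factors with few levels. Variance not captured by the
    # retained PCs is noise and is credited to the residual (per-entry units:
    # eigenvalue mass / n).
    abs_components["residual"] += (total - eigval[:n_pcs].sum()) / n
    grand = sum(abs_components.values())
    if grand <= 0:
        final = pd.Series({k: (1.0 if k == "residual" else 0.0) for k in labels})
    else:
        final = pd.Series({k: abs_components[k] / grand for k in labels})

    return PvcaResult(
        proportions=final[labels],
        pc_weights=eigval[:n_pcs] / total,
        n_pcs=n_pcs,
        cumulative_variance=float(cum[n_pcs - 1]),
        per_pc=per_pc,
    )
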