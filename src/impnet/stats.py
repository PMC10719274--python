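"""Covariate-residualized rank association analysis.

The inferential contract is Spearman's rank correlation between a behavioral
score (e.g. log10 discount rate) and a topological measure, computed on the
residuals of both variables after ordinary-least-squares regression on the
covariates (age, sex, education years) plus an intercept.  Two significance
regimes apply: p < 0.05 for global measures, and a per-node false-positive
adjustment p < 1/n_nodes for nodal measures (0.011 for the 90-node atlas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "BatterySpec",
    "residualize",
    "spearman_partial",
    "nodal_threshold",
    "run_association_battery",
]

GLOBAL_ALPHA = 0.05


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    rho: float
    p_value: float
    n: int
    covariates: list[str] = field(default_factory=list)
    threshold: float = GLOBAL_ALPHA
    significant: bool = False


@dataclass
class BatterySpec:
    """Names the variables entering the association battery."""

    behavioral: list[str]
    global_metrics: list[str]
    nodal_metrics: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    n_nodes: int = 90
    global_alpha: float = GLOBAL_ALPHA


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = sm.add_constant(np.asarray(covariates, dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column by leave-one-out rank
        names = ["intercept"] + list(covariates.columns)
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"covariate design is rank-deficient: column {names[j]!r} is collinear")
        raise ValueError("covariate design is rank-deficient")
    return X


def residualize(values, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, covariates].

    With no covariates the values are simply centered.  Residuals are
    orthogonal to every covariate column.  Accepts a 1-D vector or a 2-D
    array of columns (residualized against the same design).
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("missing values are not allowed; drop incomplete rows first")
    if covariates is None or len(getattr(covariates, "columns", [])) == 0:
        return v - v.mean(axis=0)
    if len(covariates) != v.shape[0]:
        raise ValueError("values and covariates must have the same length")
    if v.shape[0] <= len(covariates.columns) + 1:
        raise ValueError("need more observations than covariates")
    X = _design(covariates)
    if v.ndim == 1:
        return np.asarray(sm.OLS(v, X).fit().resid)
    # multi-column case: one shared projection
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def spearman_partial(
    x,
    y,
    covariates: pd.DataFrame | None = None,
    names: tuple[str, str] = ("x", "y"),
    alpha: float = GLOBAL_ALPHA,
    method: str = "t",
    n_permutations: int = 10000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation between covariate residuals of x and y.

    Both variables are residualized on the covariates, then ranked (ties get
    average ranks).  The two-sided p-value uses the t approximation with
    n - 2 degrees of freedom (``method="t"``), or an exact permutation null
    (``method="permutation"``) for small samples.
    """
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    n = len(rx)
    for r, orig in ((rx, x), (ry, y)):
        scale = float(np.std(np.asarray(orig, dtype=float)))
        if np.std(r) <= 1e-10 * max(1.0, scale):
            raise ValueError("degenerate after residualization: zero-variance variable")
    rho, _ = sps.spearmanr(rx, ry)
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            null[b] = sps.spearmanr(rx, rng.permutation(ry))[0]
        p = float((np.sum(np.abs(null) >= abs(rho)) + 1) / (n_permutations + 1))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    cov_names = list(covariates.columns) if covariates is not None else []
    return CorrelationResult(
        variable_x=names[0],
        variable_y=names[1],
        rho=float(rho),
        p_value=float(p),
        n=n,
        covariates=cov_names,
        threshold=alpha,
        significant=bool(p < alpha),
    )


def nodal_threshold(n_nodes: int) -> float:
    """Per-node false-positive adjustment: alpha = 1/n_nodes."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    return 1.0 / n_nodes


def _rank_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    return np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))


def run_association_battery(cohort: pd.DataFrame, spec: BatterySpec) -> pd.DataFrame:
    """Correlate every behavioral score with every topological measure.

    Behavioral x global pairs are tested at ``spec.global_alpha``; behavioral
    x nodal pairs at the adjusted threshold 1/n_nodes.  All variables are
    residualized once against the shared covariate design, then rank
    correlations are computed pairwise.  Returns the full table sorted by
    p-value with the top-decile |rho| nodal pairs flagged.
    """
    for name in spec.behavioral + spec.global_metrics + spec.nodal_metrics + spec.covariates:
        if name not in cohort.columns:
            raise ValueError(f"unknown variable {name!r} in battery spec")
    cov = cohort[spec.covariates] if spec.covariates else None
    cols = spec.behavioral + spec.global_metrics + spec.nodal_metrics
    resid = residualize(cohort[cols].to_numpy(dtype=float), cov)
    ranks = pd.DataFrame(resid, columns=cols).rank().to_numpy()
    n = len(cohort)
    nodal_alpha = nodal_threshold(spec.n_nodes)

    rows = []
    for xname in spec.behavioral:
        xi = cols.index(xname)
        for yname, family in [(g, "global") for g in spec.global_metrics] + [
            (m, "nodal") for m in spec.nodal_metrics
        ]:
            yi = cols.index(yname)
            rho = float(np.corrcoef(ranks[:, xi], ranks[:, yi])[0, 1])
            p = float(_rank_p(np.array(rho), n))
            alpha = spec.global_alpha if family == "global" else nodal_alpha
            rows.append(
                {
                    "x": xname,
                    "y": yname,
                    "family": family,
                    "rho": rho,
                    "p": p,
                    "n": n,
                    "threshold": round(alpha, 3),
                    "significant": p < alpha,
                }
            )
    table = pd.DataFrame(rows)
    table["top_decile_nodal"] = False
    nodal_mask = table["family"] == "nodal"
    if nodal_mask.any():
        cutoff = table.loc[nodal_mask, "rho"].abs().quantile(0.9)
        table.loc[nodal_mask & (table["rho"].abs() >= cutoff), "top_decile_nodal"] = True
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)
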