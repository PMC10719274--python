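"""Delay-discounting estimation and BIS-11 questionnaire scoring.

Intertemporal-choice behavior is modeled with the hyperbolic value function
``SV = A / (1 + k*D)`` where ``A`` is the reward amount, ``D`` the delay in
days and ``k`` the subject's discount rate (per day).  The probability of
choosing the larger-delayed option is a logistic function of the subjective
value difference with a free choice-sensitivity slope ``beta``; ``(k, beta)``
are estimated per subject by maximum likelihood with a multi-start bounded
quasi-Newton search.  Subjects who chose the same option on every trial carry
no information about ``k`` and are excluded up front.

BIS-11 records (30 items, 1..4 Likert) are scored into attentional, motor and
non-planning subscale sums plus a total, after reversing the reverse-keyed
items; the item-to-subscale key ships as an editable YAML data file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ChoiceDataset",
    "DiscountingFit",
    "BISRecord",
    "FitConfig",
    "subjective_value",
    "choice_probability",
    "fit_discounting",
    "detect_degenerate",
    "load_bis_key",
    "score_bis",
    "fit_cohort",
]

#: Per-day discount rate search box; fits at a bound are flagged, not dropped.
K_BOUNDS = (1e-6, 10.0)
#: Choice-sensitivity (logistic slope on the SV difference) search box.
BETA_BOUNDS = (1e-6, 1e3)

_TRIAL_COLUMNS = ["immediate_amount", "delayed_amount", "delay_days", "choice"]


@dataclass
class ChoiceDataset:
    """One subject's intertemporal-choice trials.

    ``trials`` is a DataFrame with columns immediate_amount, delayed_amount,
    delay_days, choice (1 = larger-delayed option chosen).
    """

    subject_id: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.trials
        missing = [c for c in _TRIAL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"choice table missing columns: {missing}")
        if len(t) < 1:
            raise ValueError("choice dataset must contain at least one trial")
        if (t["immediate_amount"] <= 0).any():
            raise ValueError("immediate_amount must be positive")
        if (t["delayed_amount"] <= t["immediate_amount"]).any():
            raise ValueError("delayed_amount must exceed immediate_amount")
        if (t["delay_days"] <= 0).any():
            raise ValueError("delay_days must be positive")
        if not t["choice"].isin([0, 1]).all():
            raise ValueError("choice must be 0 or 1")

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class DiscountingFit:
    """Maximum-likelihood hyperbolic-discounting fit for one subject."""

    subject_id: str
    k: float | None
    log10_k: float | None
    beta: float | None
    log_likelihood: float | None
    converged: bool
    excluded: bool = False
    reason: str = ""
    at_bound: bool = False


@dataclass
class FitConfig:
    """Multi-start optimizer settings for :func:`fit_discounting`."""

    k_bounds: tuple[float, float] = K_BOUNDS
    beta_bounds: tuple[float, float] = BETA_BOUNDS
    n_k_starts: int = 8
    n_beta_starts: int = 4
    k_start_range: tuple[float, float] = (1e-4, 1.0)
    beta_start_range: tuple[float, float] = (1e-4, 1e-1)


@dataclass
class BISRecord:
    subject_id: str
    items: list[int]
    attentional: int
    motor: int
    non_planning: int
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.attentional + self.motor + self.non_planning


def subjective_value(amount, delay, k):
    """Hyperbolically discounted value ``A / (1 + k*D)``.

    Strictly decreasing in ``delay`` for ``k > 0`` and increasing in
    ``amount``.  Accepts scalars or arrays.
    """
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if np.any(amount <= 0):
        raise ValueError("amount must be positive")
    if np.any(delay < 0):
        raise ValueError("delay must be nonnegative")
    if np.any(np.asarray(k) < 0):
        raise ValueError("discount rate k must be nonnegative")
    return amount / (1.0 + k * delay)


def choice_probability(immediate_amount, delayed_amount, delay_days, k, beta):
    """P(choose the larger-delayed option) under the logistic choice rule.

    ``logistic(beta * (SV_delayed - SV_immediate))``; the immediate option is
    available now, so its subjective value is its face amount.
    """
    if np.any(np.asarray(beta) < 0):
        raise ValueError("choice sensitivity beta must be nonnegative")
    sv_del = subjective_value(delayed_amount, delay_days, k)
    sv_imm = subjective_value(immediate_amount, 0.0, k)
    return expit(beta * (sv_del - sv_imm))


def detect_degenerate(data: ChoiceDataset) -> tuple[bool, str]:
    """Flag subjects who chose the same option on every trial.

    Returns ``(excluded, reason)`` with reason ``"always-delayed"`` or
    ``"always-immediate"``; such data carry no information about ``k``.
    """
    choices = data.trials["choice"].to_numpy()
    if choices.size == 0:
        raise ValueError("empty choice dataset")
    if np.all(choices == 1):
        return True, "always-delayed"
    if np.all(choices == 0):
        return True, "always-immediate"
    return False, ""


def negative_log_likelihood(theta: np.ndarray, trials: pd.DataFrame) -> float:
    """Bernoulli NLL at ``theta = (log10 k, log10 beta)``."""
    return _nll_grad(np.asarray(theta, dtype=float), trials)[0]


def _nll_grad(theta: np.ndarray, trials: pd.DataFrame) -> tuple[float, np.ndarray]:
    """NLL and its gradient in ``(log10 k, log10 beta)`` coordinates."""
    k = 10.0 ** theta[0]
    beta = 10.0 ** theta[1]
    a_imm = trials["immediate_amount"].to_numpy(dtype=float)
    a_del = trials["delayed_amount"].to_numpy(dtype=float)
    d = trials["delay_days"].to_numpy(dtype=float)
    y = trials["choice"].to_numpy(dtype=float)
    denom = 1.0 + k * d
    dsv = a_del / denom - a_imm
    arg = beta * dsv
    p = expit(arg)
    # stable Bernoulli NLL: sum softplus(arg) - y*arg; gradient wrt arg is p - y
    nll = float(np.sum(np.logaddexp(0.0, arg) - y * arg))
    resid = p - y
    d_dsv_dk = -a_del * d / denom**2
    ln10 = np.log(10.0)
    g_k = float(np.sum(resid * beta * d_dsv_dk)) * k * ln10
    g_beta = float(np.sum(resid * dsv)) * beta * ln10
    return nll, np.array([g_k, g_beta])


def fit_discounting(data: ChoiceDataset, config: FitConfig | None = None) -> DiscountingFit:
    """Estimate ``(k, beta)`` by maximum likelihood.

    The likelihood surface can be multimodal for extreme preference patterns,
    so L-BFGS-B runs from a log-spaced grid of ``(k, beta)`` starts in
    ``(log10 k, log10 beta)`` coordinates and the best optimum is kept.
    Deterministic given the data.  Degenerate (all-same-choice) data are
    refused; callers should exclude them via :func:`detect_degenerate`.
    """
    config = config or FitConfig()
    excluded, reason = detect_degenerate(data)
    if excluded:
        raise ValueError(f"degenerate preference ({reason}): cannot fit discount rate")
    if len(data) < 10:
        raise ValueError("at least 10 trials are required for a stable fit")

    bounds = [
        tuple(np.log10(config.k_bounds)),
        tuple(np.log10(config.beta_bounds)),
    ]
    k_starts = np.linspace(
        np.log10(config.k_start_range[0]), np.log10(config.k_start_range[1]), config.n_k_starts
    )
    beta_starts = np.linspace(
        np.log10(config.beta_start_range[0]),
        np.log10(config.beta_start_range[1]),
        config.n_beta_starts,
    )

    # screen the full start grid by likelihood, then polish the best basins
    grid = [np.array([k0, b0]) for k0 in k_starts for b0 in beta_starts]
    grid_nll = [negative_log_likelihood(x0, data.trials) for x0 in grid]
    order = np.argsort(grid_nll)
    n_polish = min(4, len(grid))
    best = None
    any_converged = False
    for idx in order[:n_polish]:
        res = minimize(
            _nll_grad,
            x0=grid[idx],
            args=(data.trials,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.success:
            any_converged = True
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return DiscountingFit(data.subject_id, None, None, None, None, converged=False)

    log10_k, log10_beta = best.x
    k = 10.0**log10_k
    beta = 10.0**log10_beta
    tol = 1e-9
    at_bound = bool(
        min(abs(log10_k - bounds[0][0]), abs(log10_k - bounds[0][1])) < tol
        or min(abs(log10_beta - bounds[1][0]), abs(log10_beta - bounds[1][1])) < tol
    )
    return DiscountingFit(
        subject_id=data.subject_id,
        k=float(k),
        log10_k=float(log10_k),
        beta=float(beta),
        log_likelihood=-float(best.fun),
        converged=any_converged,
        at_bound=at_bound,
    )


def fit_cohort(
    choices: pd.DataFrame, config: FitConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every subject in a long-format choice table.

    ``choices`` has columns subject_id + trial columns.  Returns
    ``(fits, exclusions)``: one row per fitted subject with k, log10_k, beta,
    log_lik, converged flags; and the excluded subjects with reasons.
    """
    fit_rows, excl_rows = [], []
    for sid, grp in choices.groupby("subject_id", sort=True):
        ds = ChoiceDataset(str(sid), grp.reset_index(drop=True))
        excluded, reason = detect_degenerate(ds)
        if excluded:
            excl_rows.append({"subject_id": str(sid), "reason": reason})
            continue
        fit = fit_discounting(ds, config)
        fit_rows.append(
            {
                "subject_id": fit.subject_id,
                "k": fit.k,
                "log10_k": fit.log10_k,
                "beta": fit.beta,
                "log_lik": fit.log_likelihood,
                "converged": fit.converged,
                "at_bound": fit.at_bound,
            }
        )
    fits = pd.DataFrame(fit_rows, columns=["subject_id", "k", "log10_k", "beta", "log_lik", "converged", "at_bound"])
    exclusions = pd.DataFrame(excl_rows, columns=["subject_id", "reason"])
    return fits, exclusions


def load_bis_key(path: str | None = None) -> dict:
    """Load the BIS-11 scoring key (packaged default or a user YAML).

    The key maps each of the 30 items to exactly one of the attentional,
    motor and non-planning subscales and lists the reverse-keyed items.
    """
    if path is None:
        ref = importlib.resources.files("impnet.data").joinpath("bis11_key.yaml")
        key = yaml.safe_load(ref.read_text())
    else:
        with open(path) as f:
            key = yaml.safe_load(f)
    subscales: Mapping[str, Sequence[int]] = key["subscales"]
    covered = sorted(i for items in subscales.values() for i in items)
    if covered != list(range(1, 31)):
        raise ValueError("BIS key must cover items 1..30 exactly once")
    if not set(key.get("reverse", [])) <= set(covered):
        raise ValueError("reverse-keyed items must be valid item numbers")
    return key


def score_bis(items: Sequence[int], key: dict | None = None, subject_id: str = "") -> BISRecord:
    """Score a 30-item BIS-11 response vector into subscale and total sums.

    Reverse-keyed items are reversed (``5 - response``) before summation;
    higher scores mean greater impulsivity.  ``items`` is indexed so that
    ``items[0]`` is item 1.
    """
    key = key or load_bis_key()
    items = list(items)
    if len(items) != 30:
        raise ValueError(f"expected 30 BIS items, got {len(items)}")
    for idx, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"item {idx} is missing")
        if int(v) != v or not 1 <= int(v) <= 4:
            raise ValueError(f"item {idx} out of range 1..4: {v!r}")
    reverse = set(key.get("reverse", []))
    scored = {i: (5 - int(items[i - 1]) if i in reverse else int(items[i - 1])) for i in range(1, 31)}
    sums = {name: sum(scored[i] for i in idxs) for name, idxs in key["subscales"].items()}
    return BISRecord(
        subject_id=subject_id,
        items=[int(v) for v in items],
        attentional=sums["attentional"],
        motor=sums["motor"],
        non_planning=sums["non_planning"],
    )
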