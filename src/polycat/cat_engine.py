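"""Adaptive administration loop: MAP scoring, MFI selection, stopping rules.

The engine is fully deterministic: item selection is maximum Fisher
information at the current ability estimate with ties broken by bank order,
scoring is maximum a posteriori under a normal prior, and the session stops
when estimate reliability reaches the threshold or the maximum test length
is hit (reliability checked first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .gpcm import BankMatrix, ThetaEstimate, reliability_from_se
from .item_bank import MISSING, ItemBank


@dataclass(frozen=True)
class CatConfig:
    reliability_threshold: float = 0.9
    max_items: int = 14
    initial_theta: float = 0.0
    prior_mean: float = 0.0
    prior_sd: float = 1.0
    selection: str = "MFI"
    estimator: str = "MAP"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.reliability_threshold < 1.0:
            raise ValueError("reliability_threshold must be in (0, 1)")
        if self.max_items < 1:
            raise ValueError("max_items must be at least 1")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.selection != "MFI" or self.estimator != "MAP":
            raise ValueError("only MFI selection with MAP scoring is supported")


@dataclass
class CatSession:
    """State of one adaptive administration."""

    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    theta_trajectory: list[ThetaEstimate] = field(default_factory=list)
    status: str = "running"

    def check(self) -> None:
        if not (len(self.administered) == len(self.responses) == len(self.theta_trajectory)):
            raise ValueError("session trajectories out of sync")
        if len(set(self.administered)) != len(self.administered):
            raise ValueError("an item was administered twice")


@dataclass(frozen=True)
class CatReport:
    final: ThetaEstimate
    n_items: int
    stop_reason: str
    items_saved_fraction: float
    age_equivalent: "AgeEquivalent | None" = None


@dataclass(frozen=True)
class AgeEquivalent:
    value: float
    ci95: tuple[float, float]
    clamped: bool = False


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _map_newton(
    mat: BankMatrix, idx: np.ndarray, resp: np.ndarray,
    prior_mean: float, prior_var: float, theta0: float,
) -> float:
    """Newton (= Fisher scoring: the GPCM log-likelihood Hessian in theta is
    -a^2 Var(K), response-free) ascent of the log posterior."""
    slopes = mat.slopes[idx]
    theta = theta0
    for _ in range(100):
        p = mat.probs(theta)[idx]
        ex = (p * mat.kk).sum(axis=1)
        ex2 = (p * mat.kk**2).sum(axis=1)
        grad = float((slopes * (resp - ex)).sum()) - (theta - prior_mean) / prior_var
        hess = -float((slopes**2 * np.maximum(ex2 - ex**2, 0.0)).sum()) - 1.0 / prior_var
        step = -grad / hess
        step = float(np.clip(step, -1.0, 1.0))
        theta += step
        if abs(step) < 1e-12:
            break
    return theta


def map_estimate(
    bank: ItemBank,
    response_vector: Sequence[int],
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
    method: str = "MAP",
) -> ThetaEstimate:
    """Maximum a posteriori ability estimate with posterior-curvature SE.

    With no answered items the prior itself is returned (theta = prior mean,
    SE = prior SD, reliability 0). The log posterior is strictly concave
    (item Hessians are -a^2 Var(K) <= 0 plus the normal prior), so Newton
    from the prior mean converges to the global maximum.
    """
    resp = np.asarray(response_vector, dtype=np.int64)
    if resp.shape != (len(bank),):
        raise ValueError("response vector length must equal bank size")
    prior_var = prior_sd**2
    answered = resp != MISSING
    if not answered.any():
        return ThetaEstimate(
            theta=float(prior_mean), se=float(prior_sd), reliability=0.0,
            ci95=(prior_mean - 1.96 * prior_sd, prior_mean + 1.96 * prior_sd),
            method=method,
        )
    mat = BankMatrix.for_bank(bank)
    idx = np.nonzero(answered)[0]
    kvals = resp[idx]
    for j, k in zip(idx, kvals):
        if not 0 <= k <= mat.m[j]:
            raise ValueError(
                f"response {k} out of range for item {bank.items[j].item_id!r}"
            )
    theta = _map_newton(mat, idx, kvals, prior_mean, prior_var, prior_mean)
    if not np.isfinite(theta) or abs(theta - prior_mean) > 10:
        # fall back to a coarse posterior scan, then polish
        grid = np.linspace(prior_mean - 8, prior_mean + 8, 321)
        best = max(
            grid,
            key=lambda t: _log_posterior(mat, idx, kvals, t, prior_mean, prior_var),
        )
        theta = _map_newton(mat, idx, kvals, prior_mean, prior_var, best)
    info = float(mat.informations(theta)[idx].sum()) + 1.0 / prior_var
    se = 1.0 / np.sqrt(info)
    return ThetaEstimate.from_theta_se(theta, se, prior_var, method=method)


def _log_posterior(mat, idx, kvals, theta, prior_mean, prior_var) -> float:
    lp = mat.logprobs(theta)
    ll = float(lp[idx, kvals].sum())
    return ll - 0.5 * (theta - prior_mean) ** 2 / prior_var


# ---------------------------------------------------------------------------
# Selection and stopping
# ---------------------------------------------------------------------------


def select_next_item(bank: ItemBank, session: CatSession, theta: float) -> str:
    """Unadministered item with maximum Fisher information at theta.

    Ties break to the lowest bank index, so sessions are reproducible
    without any randomness.
    """
    mat = BankMatrix.for_bank(bank)
    info = mat.informations(theta)
    used = {bank.position(iid) for iid in session.administered}
    if len(used) >= len(bank):
        raise RuntimeError("item bank exhausted")
    if used:
        info = info.copy()
        info[list(used)] = -np.inf
    return bank.items[int(np.argmax(info))].item_id


def check_stop(session: CatSession, config: CatConfig) -> str:
    """'stop_reliability' | 'stop_max_items' | 'continue' (reliability first)."""
    if not session.theta_trajectory:
        raise ValueError("session has no administered items yet")
    if session.theta_trajectory[-1].reliability >= config.reliability_threshold:
        return "stop_reliability"
    if len(session.administered) >= config.max_items:
        return "stop_max_items"
    return "continue"


# ---------------------------------------------------------------------------
# Full loop
# ---------------------------------------------------------------------------


def run_cat(
    bank: ItemBank,
    responder: Callable[[str], int],
    config: CatConfig | None = None,
    age_table: Sequence[tuple[float, float]] | None = None,
) -> tuple[CatSession, CatReport]:
    """Select -> respond -> estimate -> check, until a stopping rule fires.

    ``responder`` maps an item id to the respondent's category; an
    out-of-range return aborts with context. ``age_table`` is an optional
    monotone (age, typical theta) lookup for the report's age-equivalent.
    """
    if config is None:
        config = CatConfig()
    mat = BankMatrix.for_bank(bank)
    session = CatSession()
    resp_vec = np.full(len(bank), MISSING, dtype=np.int64)
    theta_cur = config.initial_theta
    while True:
        iid = select_next_item(bank, session, theta_cur)
        k = int(responder(iid))
        pos = bank.position(iid)
        if not 0 <= k <= mat.m[pos]:
            raise ValueError(
                f"responder returned {k} for item {iid!r} "
                f"(valid categories 0..{mat.m[pos]}) after "
                f"{len(session.administered)} items"
            )
        session.administered.append(iid)
        session.responses.append(k)
        resp_vec[pos] = k
        est = map_estimate(bank, resp_vec, config.prior_mean, config.prior_sd)
        session.theta_trajectory.append(est)
        theta_cur = est.theta
        decision = check_stop(session, config)
        if decision == "continue" and len(session.administered) >= len(bank):
            decision = "stop_max_items"  # bank exhausted before either rule fired
        if decision != "continue":
            session.status = {
                "stop_reliability": "stopped_reliability",
                "stop_max_items": "stopped_max_items",
            }[decision]
            break
    session.check()
    final = session.theta_trajectory[-1]
    report = CatReport(
        final=final,
        n_items=len(session.administered),
        stop_reason="reliability" if decision == "stop_reliability" else "max_items",
        items_saved_fraction=1.0 - len(session.administered) / len(bank),
        age_equivalent=age_equivalent(final, age_table) if age_table else None,
    )
    return session, report


def age_equivalent(
    estimate: ThetaEstimate, table: Sequence[tuple[float, float]]
) -> AgeEquivalent:
    """Linear interpolation of age at theta through a monotone norm table.

    ``table`` holds (age, typical theta) pairs, strictly monotone in theta.
    CI endpoints are mapped through the same interpolation; values outside
    the table range clamp to the nearest node and set the ``clamped`` flag.
    """
    if not table:
        raise ValueError("age-equivalent table is empty")
    ages = np.array([a for a, _ in table], dtype=float)
    thetas = np.array([t for _, t in table], dtype=float)
    order = np.argsort(thetas)
    thetas, ages = thetas[order], ages[order]
    if np.any(np.diff(thetas) <= 0):
        raise ValueError("age table must be strictly monotone in theta")
    lo, hi = estimate.ci95
    val, clo, chi = np.interp([estimate.theta, lo, hi], thetas, ages)
    clamped = bool(
        estimate.theta < thetas[0] or estimate.theta > thetas[-1]
        or lo < thetas[0] or hi > thetas[-1]
    )
    return AgeEquivalent(value=float(val), ci95=(float(clo), float(chi)), clamped=clamped)
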