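"""Generalized partial credit model kernels.

Category probabilities follow the adjacent-category logit form

    P_k(theta) = exp(sum_{v<=k} a (theta - b_v)) / sum_c exp(sum_{v<=c} a (theta - b_v)),

with the empty sum for k = 0 equal to zero and the logistic scaling constant
D = 1 throughout (pure logistic metric; parameters imported from software
using D = 1.7 must be rescaled). Fisher information of a polytomous item is
a^2 * Var(K | theta); for a dichotomous item this reduces to the 2PL value
a^2 p q.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .item_bank import MISSING, ItemBank, ItemParameters


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature support for EM / EAP: ordered points with prior weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 1 or pts.shape != wts.shape:
            raise ValueError("points and weights must be matching 1-D arrays")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(wts < 0):
            raise ValueError("weights must be non-negative")
        total = wts.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts / total)

    @classmethod
    def normal(
        cls, n_points: int = 41, lo: float = -4.0, hi: float = 4.0,
        mean: float = 0.0, sd: float = 1.0,
    ) -> "ThetaGrid":
        """Equally spaced points with renormalized normal prior weights."""
        pts = np.linspace(lo, hi, n_points)
        return cls(pts, norm.pdf(pts, loc=mean, scale=sd))


@dataclass(frozen=True)
class ThetaEstimate:
    """Ability point estimate with SE, reliability and 95% CI."""

    theta: float
    se: float
    reliability: float
    ci95: tuple[float, float]
    method: str = "MAP"

    @classmethod
    def from_theta_se(
        cls, theta: float, se: float, prior_variance: float = 1.0, method: str = "MAP"
    ) -> "ThetaEstimate":
        rel = reliability_from_se(se, prior_variance)
        return cls(
            theta=float(theta),
            se=float(se),
            reliability=rel,
            ci95=(float(theta - 1.96 * se), float(theta + 1.96 * se)),
            method=method,
        )


def reliability_from_se(se: float, prior_variance: float = 1.0) -> float:
    """CAT-sense reliability 1 - SE^2 / prior variance, floored at 0."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return max(0.0, 1.0 - se * se / prior_variance)


# ---------------------------------------------------------------------------
# Vectorized bank arrays
# ---------------------------------------------------------------------------

_matrix_cache: "weakref.WeakKeyDictionary[ItemBank, BankMatrix]" = weakref.WeakKeyDictionary()


class BankMatrix:
    """Padded array view of a calibrated bank for vectorized kernels.

    ``cumb[i, k]`` holds ``sum_{v<=k} b_iv`` (0 for k = 0); categories beyond
    an item's range are masked with -inf logits so softmax assigns them zero
    probability.
    """

    def __init__(self, bank: ItemBank):
        for it in bank:
            if not it.calibrated:
                raise ValueError(f"item {it.item_id!r} is uncalibrated (no step difficulties)")
        self.bank = bank
        self.slopes = np.array([it.slope for it in bank])
        self.m = np.array([it.max_category for it in bank])
        self.max_m = int(self.m.max())
        k = self.max_m + 1
        self.cumb = np.zeros((len(bank), k))
        self.valid = np.zeros((len(bank), k), dtype=bool)
        for i, it in enumerate(bank):
            steps = np.asarray(it.step_difficulties)
            self.cumb[i, 1 : it.n_categories] = np.cumsum(steps)
            self.valid[i, : it.n_categories] = True
        self.kk = np.arange(k)

    @classmethod
    def for_bank(cls, bank: ItemBank) -> "BankMatrix":
        try:
            mat = _matrix_cache.get(bank)
        except TypeError:
            mat = None
        if mat is None:
            mat = cls(bank)
            try:
                _matrix_cache[bank] = mat
            except TypeError:
                pass
        return mat

    def logprobs(self, theta: float) -> np.ndarray:
        """(K items, max_m+1) log category probabilities at a scalar theta."""
        z = self.slopes[:, None] * (theta * self.kk[None, :] - self.cumb)
        z = np.where(self.valid, z, -np.inf)
        z -= z.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    def probs(self, theta: float) -> np.ndarray:
        z = self.slopes[:, None] * (theta * self.kk[None, :] - self.cumb)
        z = np.where(self.valid, z, -np.inf)
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def expected_scores(self, theta: float) -> np.ndarray:
        return (self.probs(theta) * self.kk).sum(axis=1)

    def informations(self, theta: float) -> np.ndarray:
        p = self.probs(theta)
        ex = (p * self.kk).sum(axis=1)
        ex2 = (p * self.kk**2).sum(axis=1)
        return self.slopes**2 * np.maximum(ex2 - ex**2, 0.0)

    def logprob_grid(self, thetas: np.ndarray) -> np.ndarray:
        """(Q, K, max_m+1) log probabilities over an array of thetas."""
        thetas = np.asarray(thetas, dtype=float)
        z = self.slopes[None, :, None] * (
            thetas[:, None, None] * self.kk[None, None, :] - self.cumb[None, :, :]
        )
        z = np.where(self.valid[None, :, :], z, -np.inf)
        z -= z.max(axis=2, keepdims=True)
        with np.errstate(divide="ignore"):
            return z - np.log(np.exp(z).sum(axis=2, keepdims=True))


# ---------------------------------------------------------------------------
# Single-item kernels
# ---------------------------------------------------------------------------


def _item_logits(item: ItemParameters, theta) -> np.ndarray:
    if not item.calibrated:
        raise ValueError(f"item {item.item_id!r} is uncalibrated")
    theta = np.asarray(theta, dtype=float)
    kk = np.arange(item.n_categories)
    cumb = np.concatenate(([0.0], np.cumsum(item.step_difficulties)))
    return item.slope * (theta[..., None] * kk - cumb)


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Category probability vector(s) at theta (scalar or array).

    Numerically stabilized by max-subtraction; components are positive and
    sum to one.
    """
    z = _item_logits(item, theta)
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def expected_score(item: ItemParameters, theta) -> np.ndarray | float:
    p = category_probabilities(item, theta)
    out = (p * np.arange(item.n_categories)).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def item_information(item: ItemParameters, theta) -> np.ndarray | float:
    """Fisher information a^2 * Var(K | theta); non-negative everywhere."""
    p = category_probabilities(item, theta)
    kk = np.arange(item.n_categories)
    ex = (p * kk).sum(axis=-1)
    ex2 = (p * kk**2).sum(axis=-1)
    out = item.slope**2 * np.maximum(ex2 - ex**2, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def test_information(bank: ItemBank, item_subset: Sequence[str], theta) -> float:
    """Sum of item informations over a subset of the bank (additive)."""
    total = 0.0
    for iid in item_subset:
        total += item_information(bank[iid], theta)
    return total


def log_likelihood(bank: ItemBank, response_vector: Sequence[int], theta: float) -> float:
    """Sum of log category probabilities over answered items.

    ``response_vector`` is aligned with bank item order; :data:`MISSING`
    entries contribute zero.
    """
    resp = np.asarray(response_vector, dtype=np.int64)
    if resp.shape != (len(bank),):
        raise ValueError("response vector length must equal bank size")
    total = 0.0
    for it, k in zip(bank, resp):
        if k == MISSING:
            continue
        if not 0 <= k <= it.max_category:
            raise ValueError(
                f"response {k} out of range 0..{it.max_category} for item {it.item_id!r}"
            )
        with np.errstate(divide="ignore"):
            total += float(np.log(category_probabilities(it, theta)[k]))
    return total


# ---------------------------------------------------------------------------
# Cohort-level likelihood / EAP
# ---------------------------------------------------------------------------


def pointwise_loglik(bank: ItemBank, values: np.ndarray, grid_points: np.ndarray) -> np.ndarray:
    """(n respondents, Q) log-likelihood matrix for aligned response values."""
    mat = BankMatrix.for_bank(bank)
    logp = mat.logprob_grid(grid_points)  # (Q, K, C)
    n = values.shape[0]
    out = np.zeros((n, len(grid_points)))
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = col != MISSING
        if obs.any():
            out[obs] += logp[:, j, :][:, col[obs]].T
    return out


def eap_estimates(
    bank: ItemBank, values: np.ndarray, grid: ThetaGrid | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean thetas and posterior SDs for aligned response values."""
    if grid is None:
        grid = ThetaGrid.normal()
    ll = pointwise_loglik(bank, values, grid.points)
    logpost = ll + np.log(grid.weights)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    means = post @ grid.points
    var = post @ grid.points**2 - means**2
    return means, np.sqrt(np.maximum(var, 1e-12))
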