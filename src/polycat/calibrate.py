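"""Item calibration and model checking.

Marginal maximum likelihood (MML) estimation of GPCM / PCM parameters by an
EM algorithm: the E-step places posterior weight on a fixed quadrature grid
under a standard-normal prior, the M-step maximizes the expected
complete-data log-likelihood per item (quasi-Newton with analytic
gradients). The marginal likelihood is checked to be monotone non-decreasing
across iterations on every fit.

Also here: the GPCM-vs-PCM likelihood ratio test, a grouped G2 item-fit
statistic, step-difficulty reversal detection, a polychoric/one-factor
unidimensionality screen, and the orchestrated calibration pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, ndtr, ndtri, owens_t
from scipy.stats import chi2

from .gpcm import ThetaGrid, eap_estimates, category_probabilities
from .item_bank import (
    MISSING,
    ItemBank,
    ItemParameters,
    RecodeMap,
    ResponseMatrix,
    apply_recode,
)


class CalibrationError(RuntimeError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibConfig:
    max_iter: int = 500
    tol: float = 1e-4            # max absolute parameter change
    slope_bounds: tuple[float, float] = (0.05, 10.0)
    step_bound: float = 8.0
    compute_se: bool = True


@dataclass
class FitResult:
    bank: ItemBank
    standard_errors: dict[str, float]
    deviance: float
    n_parameters: int
    converged: bool
    n_iterations: int
    model: str = "GPCM"
    loglik_path: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class LrtResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ItemFitResult:
    item_id: str
    g2: float
    df: int
    p_value: float
    n_groups_used: int


@dataclass
class UnidimScreenResult:
    item_ids: list[str]
    polychoric_matrix: np.ndarray
    loadings: dict[str, float]
    eigenvalue_ratio: float
    flagged_items: list[str]
    excluded_items: list[str]


# ---------------------------------------------------------------------------
# Expected complete-data log-likelihood per item (M-step objective)
# ---------------------------------------------------------------------------


def _item_eloglik(a: float, b: np.ndarray, thetas: np.ndarray, r: np.ndarray):
    """Value, d/da, d/db of sum_qk r[q,k] log P_k(theta_q; a, b)."""
    m = b.size
    kk = np.arange(m + 1)
    cumb = np.concatenate(([0.0], np.cumsum(b)))
    s = thetas[:, None] * kk[None, :] - cumb[None, :]      # (Q, m+1)
    z = a * s
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    denom = ez.sum(axis=1, keepdims=True)
    p = ez / denom
    logp = z - np.log(denom)
    f = float((r * logp).sum())
    nq = r.sum(axis=1)
    g_a = float((r * s).sum() - (nq * (p * s).sum(axis=1)).sum())
    # reverse cumulative sums: column j holds sum over k >= j
    rge = np.cumsum(r[:, ::-1], axis=1)[:, ::-1]
    pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1]
    g_b = -a * (rge[:, 1:] - nq[:, None] * pge[:, 1:]).sum(axis=0)
    return f, g_a, g_b


def _maximize_item_gpcm(a0, b0, thetas, r, cfg: CalibConfig):
    m = b0.size

    def neg(x):
        f, ga, gb = _item_eloglik(x[0], x[1:], thetas, r)
        return -f, -np.concatenate(([ga], gb))

    x0 = np.concatenate(([a0], b0))
    bounds = [cfg.slope_bounds] + [(-cfg.step_bound, cfg.step_bound)] * m
    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B", bounds=bounds)
    f_old, _, _ = _item_eloglik(a0, b0, thetas, r)
    if -res.fun < f_old:        # guard: never accept a worse point than the warm start
        return a0, b0
    return float(res.x[0]), res.x[1:].copy()


def _maximize_item_steps(a, b0, thetas, r, cfg: CalibConfig):
    def neg(x):
        f, _, gb = _item_eloglik(a, x, thetas, r)
        return -f, -gb

    res = optimize.minimize(
        neg, b0, jac=True, method="L-BFGS-B",
        bounds=[(-cfg.step_bound, cfg.step_bound)] * b0.size,
    )
    f_old, _, _ = _item_eloglik(a, b0, thetas, r)
    if -res.fun < f_old:
        return b0
    return res.x.copy()


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _prepare_items(rm: ResponseMatrix):
    """Per-item response columns and category counts; rejects degenerates."""
    cols, m_per_item = [], []
    for j, iid in enumerate(rm.item_ids):
        col = rm.values[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise CalibrationError(f"item {iid!r} has no observed responses")
        if np.unique(obs).size < 2:
            raise CalibrationError(
                f"item {iid!r} is degenerate: all respondents chose category {obs[0]}"
            )
        m = int(obs.max())
        if m + 1 > 4:
            raise CalibrationError(f"item {iid!r}: more than 4 observed categories")
        cols.append(col)
        m_per_item.append(m)
    return cols, m_per_item


def _start_values(col: np.ndarray, m: int):
    obs = col[col != MISSING]
    pbar = float(np.clip(obs.mean() / m, 0.05, 0.95))
    loc = float(np.log((1 - pbar) / pbar))
    if m == 1:
        return 1.0, np.array([loc])
    return 1.0, loc + np.linspace(-0.5, 0.5, m)


def _em_fit(rm: ResponseMatrix, grid: ThetaGrid, cfg: CalibConfig, common_slope: bool):
    cols, m_per = _prepare_items(rm)
    K = len(cols)
    Q = grid.points.size
    thetas, logw = grid.points, np.log(grid.weights)
    slopes = np.empty(K)
    steps: list[np.ndarray] = []
    for i, (col, m) in enumerate(zip(cols, m_per)):
        a0, b0 = _start_values(col, m)
        slopes[i] = a0
        steps.append(np.asarray(b0, dtype=float))
    obs_masks = [c != MISSING for c in cols]

    def _logp_item(i):
        a, b = slopes[i], steps[i]
        kk = np.arange(m_per[i] + 1)
        cumb = np.concatenate(([0.0], np.cumsum(b)))
        z = a * (thetas[:, None] * kk[None, :] - cumb[None, :])
        z = z - z.max(axis=1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # E-step
        L = np.zeros((rm.n_respondents, Q))
        logps = []
        for i in range(K):
            lp = _logp_item(i)
            logps.append(lp)
            obs = obs_masks[i]
            L[obs] += lp[:, cols[i][obs]].T
        A = L + logw[None, :]
        ll = float(logsumexp(A, axis=1).sum())
        if ll_path and ll < ll_path[-1] - 1e-6 * max(1.0, abs(ll_path[-1])):
            raise CalibrationError(
                f"EM marginal log-likelihood decreased at iteration {it} "
                f"({ll_path[-1]:.6f} -> {ll:.6f})"
            )
        ll_path.append(ll)
        post = np.exp(A - logsumexp(A, axis=1, keepdims=True))
        # expected counts r_i[q, k]
        rs = []
        for i in range(K):
            r = np.zeros((Q, m_per[i] + 1))
            col, obs = cols[i], obs_masks[i]
            for k in range(m_per[i] + 1):
                sel = obs & (col == k)
                if sel.any():
                    r[:, k] = post[sel].sum(axis=0)
            rs.append(r)
        # M-step
        old = np.concatenate([slopes] + steps)
        if common_slope:
            for i in range(K):
                steps[i] = _maximize_item_steps(slopes[0], steps[i], thetas, rs[i], cfg)

            def neg_common(a):
                tot = 0.0
                for i in range(K):
                    f, _, _ = _item_eloglik(a, steps[i], thetas, rs[i])
                    tot += f
                return -tot

            res = optimize.minimize_scalar(
                neg_common, bounds=cfg.slope_bounds, method="bounded",
                options={"xatol": 1e-6},
            )
            if neg_common(res.x) <= neg_common(slopes[0]):
                slopes[:] = float(res.x)
        else:
            for i in range(K):
                slopes[i], steps[i] = _maximize_item_gpcm(
                    slopes[i], steps[i], thetas, rs[i], cfg
                )
        change = float(np.abs(np.concatenate([slopes] + steps) - old).max())
        if change < cfg.tol:
            converged = True
            break

    # final marginal log-likelihood at the converged parameters
    L = np.zeros((rm.n_respondents, Q))
    for i in range(K):
        lp = _logp_item(i)
        obs = obs_masks[i]
        L[obs] += lp[:, cols[i][obs]].T
    A = L + logw[None, :]
    ll = float(logsumexp(A, axis=1).sum())
    ll_path.append(ll)
    post = np.exp(A - logsumexp(A, axis=1, keepdims=True))

    items = [
        ItemParameters(
            item_id=iid,
            slope=float(slopes[i]),
            step_difficulties=tuple(steps[i]),
            n_categories=m_per[i] + 1,
        )
        for i, iid in enumerate(rm.item_ids)
    ]
    bank = ItemBank(items, name="calibrated")
    n_params = int(sum(m_per)) + (1 if common_slope else K)
    ses = (
        _empirical_ses(rm, cols, obs_masks, m_per, slopes, steps, thetas, post, common_slope)
        if cfg.compute_se
        else {}
    )
    if not converged:
        warnings.warn(
            f"EM did not converge in {cfg.max_iter} iterations "
            f"(last max parameter change above {cfg.tol})",
            RuntimeWarning,
        )
    return FitResult(
        bank=bank,
        standard_errors=ses,
        deviance=-2.0 * ll,
        n_parameters=n_params,
        converged=converged,
        n_iterations=it,
        model="PCM" if common_slope else "GPCM",
        loglik_path=ll_path,
    )


def _empirical_ses(rm, cols, obs_masks, m_per, slopes, steps, thetas, post, common_slope):
    """SEs from the empirical cross-product of per-respondent score vectors.

    The score of the marginal log-likelihood equals the posterior expectation
    of the complete-data score (Louis/Fisher identity), which is available
    in closed form per item.
    """
    n = rm.n_respondents
    K = len(cols)
    blocks = []
    names: list[str] = []
    slope_block = np.zeros((n, K))
    for i in range(K):
        a, b, m = slopes[i], steps[i], m_per[i]
        kk = np.arange(m + 1)
        cumb = np.concatenate(([0.0], np.cumsum(b)))
        s = thetas[:, None] * kk[None, :] - cumb[None, :]
        z = a * s
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1]
        es = (p * s).sum(axis=1)
        # per (q, k) gradients
        ga_qk = s - es[:, None]                     # d/da
        gb_qkj = -a * ((kk[None, :, None] >= np.arange(1, m + 1)[None, None, :])
                       - pge[:, None, 1:])          # (Q, m+1, m) d/db_j
        col, obs = cols[i], obs_masks[i]
        sc_a = np.zeros(n)
        sc_b = np.zeros((n, m))
        if obs.any():
            kobs = col[obs]
            sc_a[obs] = (post[obs] * ga_qk[:, kobs].T).sum(axis=1)
            for j in range(m):
                sc_b[obs, j] = (post[obs] * gb_qkj[:, kobs, j].T).sum(axis=1)
        slope_block[:, i] = sc_a
        blocks.append(sc_b)
        names.extend(f"{rm.item_ids[i]}:b{j + 1}" for j in range(m))
    if common_slope:
        S = np.column_stack([slope_block.sum(axis=1)] + blocks)
        names = ["common:a"] + names
    else:
        S = np.column_stack([slope_block] + blocks)
        names = [f"{iid}:a" for iid in rm.item_ids] + names
    info = S.T @ S
    cov = np.linalg.pinv(info)
    ses = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    return dict(zip(names, ses.tolist()))


def fit_gpcm(
    rm: ResponseMatrix, grid: ThetaGrid | None = None, config: CalibConfig | None = None
) -> FitResult:
    """MML-EM fit of the GPCM (item-specific slopes)."""
    if rm.n_items < 2:
        raise CalibrationError("need at least 2 items to calibrate")
    return _em_fit(rm, grid or ThetaGrid.normal(), config or CalibConfig(), common_slope=False)


def fit_pcm(
    rm: ResponseMatrix, grid: ThetaGrid | None = None, config: CalibConfig | None = None
) -> FitResult:
    """MML-EM fit of the PCM (one common slope, estimated)."""
    if rm.n_items < 2:
        raise CalibrationError("need at least 2 items to calibrate")
    return _em_fit(rm, grid or ThetaGrid.normal(), config or CalibConfig(), common_slope=True)


def likelihood_ratio_test(gpcm: FitResult, pcm: FitResult) -> LrtResult:
    """Deviance difference of the nested PCM against the GPCM.

    df equals the parameter-count difference (K - 1 for a K-item bank:
    K slopes versus one common slope).
    """
    chi = pcm.deviance - gpcm.deviance
    if chi < -1e-6:
        raise CalibrationError(
            f"PCM deviance below GPCM deviance ({chi:.4f}); a fit failed to converge"
        )
    chi = max(chi, 0.0)
    df = gpcm.n_parameters - pcm.n_parameters
    if df <= 0:
        raise CalibrationError("non-positive degrees of freedom in model comparison")
    return LrtResult(chi_square=chi, df=df, p_value=float(chi2.sf(chi, df)))


# ---------------------------------------------------------------------------
# Item fit (grouped G2)
# ---------------------------------------------------------------------------


def item_fit_g2(
    fit: FitResult,
    rm: ResponseMatrix,
    n_groups: int = 10,
    alpha: float = 0.05,
    grid: ThetaGrid | None = None,
) -> list[ItemFitResult]:
    """Likelihood-ratio chi-square of observed vs model-expected category
    counts in ability-ordered respondent groups.

    For each item, respondents are grouped into ``n_groups`` slices of the
    leave-one-out EAP score (the trait estimated from the *other* items),
    and expected counts are the leave-one-out posterior-predictive category
    probabilities summed within each group. Leaving the item out of both
    the grouping variable and the expectation makes O - E exactly mean-zero
    under the fitted model (grouping on a statistic that contains the item's
    own response would select on it and bias the counts). Adjacent groups
    are merged while any expected cell count is below 5; df per item is
    G * m_i - (m_i + 1) for G groups used.
    """
    if not fit.converged:
        warnings.warn("item fit computed on a non-converged fit", RuntimeWarning)
    if grid is None:
        grid = ThetaGrid.normal()
    values = rm.aligned_to(fit.bank)
    from .gpcm import pointwise_loglik

    ll = pointwise_loglik(fit.bank, values, grid.points)
    if rm.n_respondents < 2 * n_groups:
        raise CalibrationError("fewer than 2 usable respondent groups")
    results = []
    for pos, item in enumerate(fit.bank):
        m = item.max_category
        pk = category_probabilities(item, grid.points)      # (Q, m+1)
        col = values[:, pos]
        # leave-one-out posterior: remove item i's likelihood contribution
        ll_loo = ll.copy()
        obs_all = col != MISSING
        with np.errstate(divide="ignore"):
            logpk = np.log(pk)
        ll_loo[obs_all] -= logpk[:, col[obs_all]].T
        lp = ll_loo + np.log(grid.weights)
        lp -= logsumexp(lp, axis=1, keepdims=True)
        post_loo = np.exp(lp)
        eap_loo = post_loo @ grid.points
        obs_idx = np.nonzero(obs_all)[0]
        order = obs_idx[np.argsort(eap_loo[obs_idx], kind="stable")]
        group_slices = [g for g in np.array_split(order, n_groups) if g.size]
        if len(group_slices) < 2:
            raise CalibrationError("fewer than 2 usable respondent groups")
        O_rows, W_rows = [], []
        for sel in group_slices:
            O_rows.append(np.bincount(col[sel], minlength=m + 1).astype(float))
            W_rows.append(post_loo[sel].sum(axis=0))
        O = np.array(O_rows)
        W = np.array(W_rows)                                # (G, Q)
        E = W @ pk
        # merge adjacent groups while any expected count < 5
        while len(O) > 2 and E.min() < 5.0:
            g = int(np.unravel_index(np.argmin(E), E.shape)[0])
            nb = g - 1 if g > 0 else g + 1
            lo, hi = min(g, nb), max(g, nb)
            O = np.vstack([O[:lo], O[lo] + O[hi], O[hi + 1 :]])
            W = np.vstack([W[:lo], W[lo] + W[hi], W[hi + 1 :]])
            E = W @ pk
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(O > 0, O * np.log(O / E), 0.0)
        g2 = float(2.0 * terms.sum())
        G = len(O)
        df = G * m - (m + 1)
        p = float(chi2.sf(g2, max(df, 1)))
        results.append(
            ItemFitResult(item_id=item.item_id, g2=g2, df=df, p_value=p, n_groups_used=G)
        )
    return results


def detect_reversals(bank: ItemBank) -> list[str]:
    """Items whose step difficulties are not strictly increasing.

    A reversal signals an under-used middle category; two-category items
    cannot reverse.
    """
    out = []
    for it in bank:
        if not it.calibrated or it.n_categories < 3:
            continue
        steps = np.asarray(it.step_difficulties)
        if np.any(np.diff(steps) <= 0):
            out.append(it.item_id)
    return out


# ---------------------------------------------------------------------------
# Unidimensionality screen
# ---------------------------------------------------------------------------


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal CDF P(X <= h, Y <= k) via Owen's T."""
    if np.isinf(h) or np.isinf(k):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf:
            return float(ndtr(k))
        return float(ndtr(h))
    rho = float(np.clip(rho, -0.999999, 0.999999))
    den = np.sqrt(1.0 - rho * rho)
    eps = 1e-13
    hh = h if abs(h) > eps else eps
    kk = k if abs(k) > eps else eps
    a1 = (kk / hh - rho) / den
    a2 = (hh / kk - rho) / den
    c = 0.0 if hh * kk > 0 else 0.5
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hh, a1) - owens_t(kk, a2) - c
    return float(min(max(val, 0.0), 1.0))


def _rect_prob(tlo_x, thi_x, tlo_y, thi_y, rho) -> float:
    return (
        _bvn_cdf(thi_x, thi_y, rho)
        - _bvn_cdf(tlo_x, thi_y, rho)
        - _bvn_cdf(thi_x, tlo_y, rho)
        + _bvn_cdf(tlo_x, tlo_y, rho)
    )


def _thresholds(counts: np.ndarray) -> np.ndarray:
    """Normal thresholds from cumulative category proportions (with +-inf ends)."""
    p = counts / counts.sum()
    cum = np.clip(np.cumsum(p)[:-1], 1e-10, 1 - 1e-10)
    return np.concatenate(([-np.inf], ndtri(cum), [np.inf]))


def polychoric_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal variables.

    Thresholds are fixed at the empirical margins; the latent correlation
    maximizes the bivariate-normal contingency likelihood.
    """
    obs = (x != MISSING) & (y != MISSING)
    x, y = x[obs], y[obs]
    cx = np.bincount(x)
    cy = np.bincount(y)
    tx = _thresholds(cx)
    ty = _thresholds(cy)
    table = np.zeros((cx.size, cy.size))
    for i, j in zip(x, y):
        table[i, j] += 1

    def negll(rho):
        total = 0.0
        for i in range(cx.size):
            for j in range(cy.size):
                if table[i, j] > 0:
                    pij = _rect_prob(tx[i], tx[i + 1], ty[j], ty[j + 1], rho)
                    total += table[i, j] * np.log(max(pij, 1e-300))
        return -total

    res = optimize.minimize_scalar(
        negll, bounds=(-0.999, 0.999), method="bounded", options={"xatol": 1e-5}
    )
    return float(res.x)


def _principal_factor(R: np.ndarray, max_iter: int = 200, tol: float = 1e-6):
    """One-factor loadings by iterated principal-factor extraction."""
    p = R.shape[0]
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        h2 = np.clip(h2, 0.05, 0.995)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    lam1 = lam2 = 0.0
    load = np.zeros(p)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        lam1, lam2 = vals[-1], vals[-2]
        v1 = vecs[:, -1]
        if v1.sum() < 0:
            v1 = -v1
        load = v1 * np.sqrt(max(lam1, 0.0))
        h2_new = np.clip(load**2, 0.0, 0.995)
        if np.abs(h2_new - h2).max() < tol:
            h2 = h2_new
            break
        h2 = h2_new
    return load, lam1, lam2


def unidimensionality_screen(
    rm: ResponseMatrix, loading_cutoff: float = 0.4
) -> UnidimScreenResult:
    """Polychoric-correlation one-factor screen.

    A simplified surrogate for a full one-factor CFA: items whose
    principal-factor loading falls below ``loading_cutoff`` are flagged;
    items with a single observed category are excluded with a warning. The
    first-to-second eigenvalue ratio of the reduced correlation matrix
    summarizes dominance of the first factor.
    """
    usable, excluded = [], []
    for j, iid in enumerate(rm.item_ids):
        col = rm.values[:, j]
        obs = col[col != MISSING]
        if obs.size == 0 or np.unique(obs).size < 2:
            excluded.append(iid)
            warnings.warn(
                f"item {iid!r} excluded from the unidimensionality screen: "
                "a single observed category",
                RuntimeWarning,
            )
        else:
            usable.append(j)
    if len(usable) < 3:
        raise CalibrationError("need at least 3 usable items for the screen")
    p = len(usable)
    R = np.eye(p)
    for ai in range(p):
        for bi in range(ai + 1, p):
            rho = polychoric_correlation(
                rm.values[:, usable[ai]], rm.values[:, usable[bi]]
            )
            R[ai, bi] = R[bi, ai] = rho
    # ensure positive semi-definiteness before factoring
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        R = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    load, lam1, lam2 = _principal_factor(R)
    ids = [rm.item_ids[j] for j in usable]
    loadings = dict(zip(ids, load.tolist()))
    flagged = [iid for iid, l in loadings.items() if l < loading_cutoff]
    ratio = float(lam1 / max(lam2, 1e-9))
    return UnidimScreenResult(
        item_ids=ids,
        polychoric_matrix=R,
        loadings=loadings,
        eigenvalue_ratio=ratio,
        flagged_items=flagged,
        excluded_items=excluded,
    )


# ---------------------------------------------------------------------------
# Orchestrated pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    calib: CalibConfig = CalibConfig()
    grid: ThetaGrid | None = None
    min_group_specific_responses: int = 20
    min_category_count: int = 10
    loading_cutoff: float = 0.4
    lrt_alpha: float = 0.05
    item_fit_alpha: float = 0.01     # stricter than the per-item nominal level
    dif_group: bool = True           # scan for DIF when group labels exist
    min_items: int = 5
    group_specific: dict = field(default_factory=dict)  # item_id -> group tag


def _sparse_category_recodes(rm: ResponseMatrix, min_count: int) -> list[RecodeMap]:
    """Merge categories observed fewer than ``min_count`` times into a neighbor."""
    maps = []
    for j, iid in enumerate(rm.item_ids):
        col = rm.values[:, j]
        obs = col[col != MISSING]
        m = int(obs.max())
        counts = np.bincount(obs, minlength=m + 1)
        merged = [[k] for k in range(m + 1)]   # ordered merge classes
        while len(merged) > 2 and min(_class_counts(merged, counts)) < min_count:
            cc = _class_counts(merged, counts)
            g = int(np.argmin(cc))
            nb = g - 1 if g > 0 else g + 1
            lo, hi = min(g, nb), max(g, nb)
            merged = merged[:lo] + [merged[lo] + merged[hi]] + merged[hi + 1 :]
        if len(merged) < m + 1:
            mapping = {}
            for new_idx, cls in enumerate(merged):
                for old in cls:
                    mapping[old] = new_idx
            maps.append(RecodeMap(item_id=iid, mapping=mapping))
    return maps


def _class_counts(merged, counts):
    return [sum(counts[k] for k in cls) for cls in merged]


def _fit_chosen(rm, cfg: PipelineConfig, model: str) -> FitResult:
    if model == "GPCM":
        return fit_gpcm(rm, cfg.grid, cfg.calib)
    return fit_pcm(rm, cfg.grid, cfg.calib)


def calibration_pipeline(
    rm: ResponseMatrix, config: PipelineConfig | None = None
) -> tuple[ItemBank, dict]:
    """Sequenced calibration: response screens, unidimensionality, model
    comparison, item fit, reversal recoding, DIF, final re-fit.

    Returns the final calibrated bank and a machine-readable report listing
    every stage and every item removal with its reason.
    """
    cfg = config or PipelineConfig()
    report: dict = {"stages": []}
    current = rm

    def log(stage, **kw):
        report["stages"].append({"stage": stage, **kw})

    # 1. minimum-response screens + sparse-category merging
    dropped = []
    keep = []
    for j, iid in enumerate(current.item_ids):
        col = current.values[:, j]
        obs = col[col != MISSING]
        tag = cfg.group_specific.get(iid)
        if tag is not None and obs.size < cfg.min_group_specific_responses:
            dropped.append({"item_id": iid, "reason": f"group-specific ({tag}) with "
                            f"{obs.size} responses < {cfg.min_group_specific_responses}"})
            continue
        if obs.size == 0 or np.unique(obs).size < 2:
            dropped.append({"item_id": iid, "reason": "degenerate: single observed category"})
            continue
        keep.append(iid)
    current = current.subset_items(keep)
    recodes = _sparse_category_recodes(current, cfg.min_category_count)
    if recodes:
        current = _recode_matrix_only(current, recodes)
    log("min_responses", items_dropped=dropped,
        recoded_items=[m.item_id for m in recodes])

    # 2. unidimensionality screen
    screen = unidimensionality_screen(current, cfg.loading_cutoff)
    drop2 = [{"item_id": iid, "reason": f"loading {screen.loadings[iid]:.3f} < "
              f"{cfg.loading_cutoff}"} for iid in screen.flagged_items]
    drop2 += [{"item_id": iid, "reason": "single observed category"} for iid in screen.excluded_items]
    current = current.subset_items([i for i in current.item_ids
                                    if i not in {d["item_id"] for d in drop2}])
    log("unidimensionality", items_dropped=drop2,
        eigenvalue_ratio=screen.eigenvalue_ratio)
    _require(current, cfg)

    # 3. model comparison
    g_fit = fit_gpcm(current, cfg.grid, cfg.calib)
    p_fit = fit_pcm(current, cfg.grid, cfg.calib)
    lrt = likelihood_ratio_test(g_fit, p_fit)
    model = "GPCM" if lrt.p_value < cfg.lrt_alpha else "PCM"
    fit = g_fit if model == "GPCM" else p_fit
    log("model_comparison", chi_square=lrt.chi_square, df=lrt.df,
        p_value=lrt.p_value, chosen=model)

    # 4. item fit
    fits = item_fit_g2(fit, current, grid=cfg.grid)
    misfits = [f.item_id for f in fits if f.p_value < cfg.item_fit_alpha]
    current = current.subset_items([i for i in current.item_ids if i not in misfits])
    log("item_fit", items_dropped=[{"item_id": i, "reason":
        f"G2 p < {cfg.item_fit_alpha}"} for i in misfits])
    _require(current, cfg)
    if misfits:
        fit = _fit_chosen(current, cfg, model)

    # 5. reversals -> merge reversed category downward, re-fit
    reversed_ids = detect_reversals(fit.bank)
    if reversed_ids:
        maps = [_reversal_recode(fit.bank[iid]) for iid in reversed_ids]
        current = _recode_matrix_only(current, maps)
        fit = _fit_chosen(current, cfg, model)
    log("reversals", recoded_items=reversed_ids)

    # 6. DIF
    dif_flagged: list[str] = []
    if cfg.dif_group and current.groups is not None and len(set(current.groups)) == 2:
        from .dif import DifConfig, dif_scan

        results = dif_scan(fit.bank, current, config=DifConfig())
        dif_flagged = [r.item_id for r in results if r.classification != "none"]
        current = current.subset_items([i for i in current.item_ids if i not in dif_flagged])
        log("dif", items_dropped=[{"item_id": i, "reason": "gender/group DIF"}
                                  for i in dif_flagged])
        _require(current, cfg)
    else:
        log("dif", skipped=True, items_dropped=[])

    # 7. final calibration
    fit = _fit_chosen(current, cfg, model)
    log("final_fit", model=model, deviance=fit.deviance,
        n_items=len(fit.bank), converged=fit.converged)
    report["final_item_ids"] = fit.bank.item_ids
    report["model"] = model
    return fit.bank, report


def _require(rm: ResponseMatrix, cfg: PipelineConfig) -> None:
    if rm.n_items < cfg.min_items:
        raise PipelineError(
            f"only {rm.n_items} items survive, below min_items={cfg.min_items}"
        )


def _reversal_recode(item: ItemParameters) -> RecodeMap:
    """Merge the under-used category at the first reversal into the one below.

    A reversal b_j >= b_{j+1} signals that category j is rarely modal; the
    recode maps j into j-1 (downward, toward "total assistance") and shifts
    higher categories accordingly.
    """
    steps = np.asarray(item.step_difficulties)
    j = int(np.nonzero(np.diff(steps) <= 0)[0][0]) + 1  # sparse category index
    mapping = {k: (k if k < j else k - 1) for k in range(item.n_categories)}
    return RecodeMap(item_id=item.item_id, mapping=mapping)


def _recode_matrix_only(rm: ResponseMatrix, maps: Sequence[RecodeMap]) -> ResponseMatrix:
    """Apply recodes to a response matrix without a calibrated bank."""
    dummy_items = []
    for j, iid in enumerate(rm.item_ids):
        col = rm.values[:, j]
        obs = col[col != MISSING]
        m = int(obs.max()) if obs.size else 1
        dummy_items.append(
            ItemParameters(item_id=iid, slope=1.0,
                           step_difficulties=tuple(np.zeros(max(m, 1))),
                           n_categories=max(m, 1) + 1)
        )
    dummy = ItemBank(dummy_items, name="recode")
    _, new_rm = apply_recode(dummy, rm, maps)
    return new_rm
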