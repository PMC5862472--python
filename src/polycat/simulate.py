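"""Post-hoc CAT simulation over a cohort.

Complete recorded (or synthetic) response matrices are replayed through the
adaptive engine item by item, exactly as a stopping-rule study on real data:
no responses are ever imputed, the matrix supplies the answer the respondent
would have given to whichever item the CAT selects. Alongside the adaptive
replay, every respondent is scored on the full bank, yielding the
efficiency (test length, items saved) and validity (CAT-vs-full-bank
Pearson r) summary and the fixed-length reliability curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cat_engine import CatConfig, map_estimate, run_cat
from .gpcm import BankMatrix, ThetaEstimate
from .item_bank import MISSING, ItemBank, ResponseMatrix


@dataclass
class SimulationSummary:
    n_respondents: int
    pct_reliability_met: float
    mean_length_reliability_met: float
    mean_reliability_unmet: float
    pearson_r_cat_vs_full: float
    mean_items_saved_pct: float
    per_respondent: pd.DataFrame
    n_skipped: int = 0


@dataclass
class ReliabilityCurve:
    test_length: np.ndarray
    mean_reliability: np.ndarray
    ci90_low: np.ndarray
    ci90_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_length": self.test_length,
                "mean_reliability": self.mean_reliability,
                "ci90_low": self.ci90_low,
                "ci90_high": self.ci90_high,
            }
        )


def simulate_responses(
    bank: ItemBank, thetas, seed: int | np.random.Generator = 0
) -> ResponseMatrix:
    """Draw one response per respondent-item cell under the GPCM.

    Inverse-CDF sampling with a seeded generator; the same seed reproduces
    the matrix bit for bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    n = thetas.size
    mat = BankMatrix.for_bank(bank)
    values = np.empty((n, len(bank)), dtype=np.int64)
    # vectorized over respondents, one item at a time
    for j, item in enumerate(bank):
        kk = np.arange(item.n_categories)
        cumb = np.concatenate(([0.0], np.cumsum(item.step_difficulties)))
        z = item.slope * (thetas[:, None] * kk - cumb)
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n)
        values[:, j] = (u[:, None] > cum[:, :-1]).sum(axis=1)
    width = len(str(n))
    return ResponseMatrix(
        respondent_ids=[f"R{i + 1:0{width}d}" for i in range(n)],
        item_ids=bank.item_ids,
        values=values,
    )


def full_bank_scores(
    bank: ItemBank, rm: ResponseMatrix, prior_mean: float = 0.0, prior_sd: float = 1.0
) -> list[ThetaEstimate]:
    """MAP estimate per respondent using every answered item."""
    values = rm.aligned_to(bank)
    return [map_estimate(bank, values[i], prior_mean, prior_sd) for i in range(values.shape[0])]


def post_hoc_cat(
    bank: ItemBank, rm: ResponseMatrix, config: CatConfig | None = None
) -> SimulationSummary:
    """Replay each respondent's recorded responses through the CAT.

    Respondents missing a response for an item the CAT selects are skipped
    (counted in ``n_skipped``).
    """
    cfg = config or CatConfig()
    values = rm.aligned_to(bank)
    full = full_bank_scores(bank, rm, cfg.prior_mean, cfg.prior_sd)
    rows = []
    n_skipped = 0

    class _MissingResponse(Exception):
        pass

    for i, rid in enumerate(rm.respondent_ids):
        row = values[i]

        def responder(iid: str) -> int:
            k = row[bank.position(iid)]
            if k == MISSING:
                raise _MissingResponse(iid)
            return int(k)

        try:
            session, report = run_cat(bank, responder, cfg)
        except _MissingResponse:
            n_skipped += 1
            continue
        rows.append(
            {
                "respondent_id": rid,
                "theta_full": full[i].theta,
                "theta_cat": report.final.theta,
                "se_cat": report.final.se,
                "reliability_cat": report.final.reliability,
                "n_items": report.n_items,
                "stop_reason": report.stop_reason,
            }
        )
    per = pd.DataFrame(rows)
    if per.empty:
        raise ValueError("no respondent could be replayed (all skipped)")
    met = per["stop_reason"] == "reliability"
    r = float(np.corrcoef(per["theta_cat"], per["theta_full"])[0, 1])
    return SimulationSummary(
        n_respondents=len(per),
        pct_reliability_met=100.0 * float(met.mean()),
        mean_length_reliability_met=float(per.loc[met, "n_items"].mean()) if met.any() else float("nan"),
        mean_reliability_unmet=float(per.loc[~met, "reliability_cat"].mean()) if (~met).any() else float("nan"),
        pearson_r_cat_vs_full=r,
        mean_items_saved_pct=100.0 * (1.0 - float(per["n_items"].mean()) / len(bank)),
        per_respondent=per,
        n_skipped=n_skipped,
    )


def stopping_rule_replications(
    master_seed: int,
    n_reps: int = 10,
    max_curve_length: int = 20,
    config: CatConfig | None = None,
) -> pd.DataFrame:
    """Replicate the default-study stopping-rule evaluation over seeds.

    Each replication generates a fresh default synthetic study (bank and
    cohort seeds derived from ``master_seed``), replays it through the CAT
    with the default stopping rules, and computes the fixed-length
    reliability curve. Returns one row per replication with the efficiency
    and validity summary.
    """
    from .synthetic import BankGenConfig, CohortGenConfig, generate_study

    cfg = config or CatConfig()
    rows = []
    for rep in range(n_reps):
        ss = np.random.SeedSequence([master_seed, rep])
        s_bank, s_cohort, s_resp = (int(x % 2**31) for x in ss.generate_state(3))
        study = generate_study(
            BankGenConfig(seed=s_bank),
            CohortGenConfig(seed=s_cohort),
            response_seed=s_resp,
        )
        summary = post_hoc_cat(study.bank, study.responses, cfg)
        curve = reliability_curve(study.bank, study.responses, max_curve_length, cfg)
        above = curve.mean_reliability >= cfg.reliability_threshold
        rows.append(
            {
                "rep": rep,
                "pct_reliability_met": summary.pct_reliability_met,
                "mean_length_reliability_met": summary.mean_length_reliability_met,
                "mean_reliability_unmet": summary.mean_reliability_unmet,
                "pearson_r_cat_vs_full": summary.pearson_r_cat_vs_full,
                "mean_items_saved_pct": summary.mean_items_saved_pct,
                "curve_length_to_threshold": int(np.argmax(above) + 1)
                if above.any()
                else max_curve_length + 1,
                "n_respondents": summary.n_respondents,
            }
        )
    return pd.DataFrame(rows)


def reliability_curve(
    bank: ItemBank,
    rm: ResponseMatrix,
    max_length: int = 20,
    config: CatConfig | None = None,
) -> ReliabilityCurve:
    """Per-length reliability of a length-only-stopping CAT.

    For each respondent one adaptive session runs out to ``max_length``
    items (MFI selection is unaffected by the stopping rule, so the length-L
    prefix of that session IS the length-L CAT); the per-respondent
    reliability after each item is aggregated as the cohort mean with an
    empirical 90% band (5th/95th percentiles across respondents).
    """
    cfg = config or CatConfig()
    if max_length > len(bank):
        raise ValueError("max_length exceeds bank size")
    values = rm.aligned_to(bank)
    rel = np.empty((rm.n_respondents, max_length))
    long_cfg = CatConfig(
        reliability_threshold=0.999999, max_items=max_length,
        initial_theta=cfg.initial_theta, prior_mean=cfg.prior_mean,
        prior_sd=cfg.prior_sd,
    )
    for i in range(rm.n_respondents):
        row = values[i]
        if np.any(row == MISSING):
            raise ValueError(
                f"respondent {rm.respondent_ids[i]!r} has missing responses; "
                "the reliability curve needs a complete matrix"
            )

        def responder(iid: str) -> int:
            return int(row[bank.position(iid)])

        session, _ = run_cat(bank, responder, long_cfg)
        traj = [est.reliability for est in session.theta_trajectory]
        rel[i, : len(traj)] = traj
        rel[i, len(traj):] = traj[-1] if traj else 0.0
    return ReliabilityCurve(
        test_length=np.arange(1, max_length + 1),
        mean_reliability=rel.mean(axis=0),
        ci90_low=np.percentile(rel, 5, axis=0),
        ci90_high=np.percentile(rel, 95, axis=0),
    )
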