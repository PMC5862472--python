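"""Synthetic item banks, cohorts, and complete studies.

The default configurations emulate the published summaries of a 56-item
pediatric self-care bank: 32 two-category plus 24 three-category items,
slopes with sample mean 1.666 and SD 0.57 confined to (0.839, 3.547), item
locations spanning (-1.313, 3.232), and a respondent ability distribution
with roughly 19% of the cohort below -1.5 logits (Normal(0, 1.7), since
Phi(-1.5/1.7) is approximately 0.19). Only marginal summaries are published,
so slopes and locations are drawn independently.

Slope moments are exact by construction: raw draws are affinely
standardized to the configured sample mean and SD (ddof=1) and the whole
sample is redrawn if any standardized slope leaves the configured range.
Raw draws are lognormal (sigma_log 0.5), the customary right-skewed shape of
discrimination estimates; a symmetric normal sample of size 56 almost always
violates the asymmetric printed range after standardization, a lognormal
sample rarely does.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .item_bank import (
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    read_bank,
    read_responses,
    write_bank,
    write_responses,
)
from .simulate import simulate_responses


@dataclass(frozen=True)
class BankGenConfig:
    n_dichotomous: int = 32
    n_trichotomous: int = 24
    slope_mean: float = 1.666
    slope_sd: float = 0.57
    slope_range: tuple[float, float] = (0.839, 3.547)
    difficulty_range: tuple[float, float] = (-1.313, 3.232)
    step_spread: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dichotomous < 0 or self.n_trichotomous < 0 or self.n_items < 2:
            raise ValueError("need at least 2 items")
        if self.slope_sd <= 0 or self.step_spread <= 0:
            raise ValueError("slope_sd and step_spread must be positive")

    @property
    def n_items(self) -> int:
        return self.n_dichotomous + self.n_trichotomous


@dataclass(frozen=True)
class CohortGenConfig:
    n_respondents: int = 215
    theta_mean: float = 0.0
    theta_sd: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")


_SIGMA_LOG = 0.5  # shape of the raw (pre-standardization) slope draws


def generate_bank(config: BankGenConfig | None = None) -> ItemBank:
    """Seeded bank with exact slope moments and range-confined parameters.

    Raw slopes are drawn, affinely standardized so the sample mean and SD
    (ddof=1) equal the configured values exactly, and the sample is redrawn
    if any slope leaves ``slope_range`` (at most 100 redraws). Item
    locations are equally spaced across ``difficulty_range`` with jitter at
    interior positions; a trichotomous item places its two steps at
    location +- step_spread/2, a dichotomous item at the location itself.
    """
    cfg = config or BankGenConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_items
    lo, hi = cfg.slope_range
    slopes = None
    for _ in range(100):
        raw = rng.lognormal(mean=0.0, sigma=_SIGMA_LOG, size=n)
        sd = raw.std(ddof=1)
        if sd <= 0:
            continue
        cand = (raw - raw.mean()) / sd * cfg.slope_sd + cfg.slope_mean
        if cand.min() >= lo and cand.max() <= hi:
            slopes = cand
            break
    if slopes is None:
        raise ValueError(
            "could not draw slopes matching the configured moments within the "
            "configured range after 100 redraws"
        )
    d_lo, d_hi = cfg.difficulty_range
    locs = np.linspace(d_lo, d_hi, n)
    if n > 2:
        h = (d_hi - d_lo) / (n - 1)
        locs[1:-1] += rng.uniform(-h / 3, h / 3, size=n - 2)
    cats = np.array([2] * cfg.n_dichotomous + [3] * cfg.n_trichotomous)
    rng.shuffle(cats)
    width = len(str(n))
    items = []
    for i in range(n):
        if cats[i] == 2:
            steps: tuple[float, ...] = (float(locs[i]),)
        else:
            steps = (float(locs[i] - cfg.step_spread / 2), float(locs[i] + cfg.step_spread / 2))
        items.append(
            ItemParameters(
                item_id=f"I{i + 1:0{width}d}",
                slope=float(slopes[i]),
                step_difficulties=steps,
                n_categories=int(cats[i]),
            )
        )
    return ItemBank(items, name=f"synthetic-seed{cfg.seed}")


def generate_cohort(config: CohortGenConfig | None = None) -> np.ndarray:
    """Seeded normal ability draws (logits)."""
    cfg = config or CohortGenConfig()
    rng = np.random.default_rng(cfg.seed)
    return rng.normal(cfg.theta_mean, cfg.theta_sd, size=cfg.n_respondents)


@dataclass
class Study:
    bank: ItemBank
    responses: ResponseMatrix
    thetas: np.ndarray
    provenance: dict


def _response_seed(bank_cfg: BankGenConfig, cohort_cfg: CohortGenConfig) -> int:
    ss = np.random.SeedSequence([bank_cfg.seed, cohort_cfg.seed, 911])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(
    bank_cfg: BankGenConfig | None = None,
    cohort_cfg: CohortGenConfig | None = None,
    response_seed: int | None = None,
) -> Study:
    """Complete seeded study: bank, true abilities, full response matrix."""
    bank_cfg = bank_cfg or BankGenConfig()
    cohort_cfg = cohort_cfg or CohortGenConfig()
    if response_seed is None:
        response_seed = _response_seed(bank_cfg, cohort_cfg)
    bank = generate_bank(bank_cfg)
    thetas = generate_cohort(cohort_cfg)
    rm = simulate_responses(bank, thetas, seed=response_seed)
    # JSON-canonical from the start (tuples as lists) so the provenance block
    # compares equal after a write/read round trip
    provenance = json.loads(
        json.dumps(
            {
                "bank_config": asdict(bank_cfg),
                "cohort_config": asdict(cohort_cfg),
                "response_seed": response_seed,
            }
        )
    )
    return Study(bank=bank, responses=rm, thetas=thetas, provenance=provenance)


def save_study(study: Study, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bank(study.bank, out / "bank.csv")
    write_responses(study.responses, out / "responses.csv")
    np.savetxt(out / "thetas.csv", study.thetas, header="theta", comments="", fmt="%.17g")
    (out / "provenance.json").write_text(json.dumps(study.provenance, indent=1))


def load_study(out_dir: str | Path) -> Study:
    out = Path(out_dir)
    provenance = json.loads((out / "provenance.json").read_text())
    return Study(
        bank=read_bank(out / "bank.csv"),
        responses=read_responses(out / "responses.csv"),
        thetas=np.loadtxt(out / "thetas.csv", skiprows=1),
        provenance=provenance,
    )


def regenerate_study(provenance: dict) -> Study:
    """Rebuild a study bit-identically from its provenance block."""
    bank_cfg = dict(provenance["bank_config"])
    cohort_cfg = dict(provenance["cohort_config"])
    for key in ("slope_range", "difficulty_range"):
        bank_cfg[key] = tuple(bank_cfg[key])
    return generate_study(
        BankGenConfig(**bank_cfg),
        CohortGenConfig(**cohort_cfg),
        response_seed=provenance["response_seed"],
    )
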