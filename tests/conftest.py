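import numpy as np
import pytest

from polycat.item_bank import ItemBank, ItemParameters, ResponseMatrix
from polycat.simulate import simulate_responses
from polycat.synthetic import BankGenConfig, generate_bank


@pytest.fixture(scope="session")
def recovery_bank() -> ItemBank:
    """Fixed 10-item bank with moderate parameters for recovery studies."""
    specs = [
        ("I01", 0.9, (-1.2,), 2),
        ("I02", 1.3, (-0.8,), 2),
        ("I03", 1.7, (-0.4,), 2),
        ("I04", 2.1, (0.0,), 2),
        ("I05", 1.5, (0.6,), 2),
        ("I06", 1.1, (1.2,), 2),
        ("I07", 1.4, (-0.9, -0.1), 3),
        ("I08", 1.8, (-0.3, 0.5), 3),
        ("I09", 1.6, (0.2, 1.0), 3),
        ("I10", 2.0, (0.7, 1.5), 3),
    ]
    return ItemBank(
        [ItemParameters(i, a, b, c) for i, a, b, c in specs], name="recovery"
    )


@pytest.fixture(scope="session")
def screen_bank() -> ItemBank:
    """12-item synthetic bank with difficulties matched to a N(0,1) cohort."""
    return generate_bank(
        BankGenConfig(n_dichotomous=8, n_trichotomous=4, difficulty_range=(-1.5, 1.5), seed=6)
    )


@pytest.fixture(scope="session")
def small_study(screen_bank):
    """(bank, thetas, responses) for a clean one-factor cohort of 600."""
    thetas = np.random.default_rng(77).normal(0, 1, 600)
    rm = simulate_responses(screen_bank, thetas, 101)
    return screen_bank, thetas, rm


def two_group_matrix(bank_a: ItemBank, bank_b: ItemBank, n_per_group: int, seed: int) -> ResponseMatrix:
    """Pooled response matrix: group 'a' answers bank_a, group 'b' bank_b."""
    rng = np.random.default_rng(seed)
    tha = rng.normal(0, 1, n_per_group)
    thb = rng.normal(0, 1, n_per_group)
    ra = simulate_responses(bank_a, tha, int(rng.integers(2**31)))
    rb = simulate_responses(bank_b, thb, int(rng.integers(2**31)))
    return ResponseMatrix(
        respondent_ids=[f"A{i}" for i in range(n_per_group)]
        + [f"B{i}" for i in range(n_per_group)],
        item_ids=bank_a.item_ids,
        values=np.vstack([ra.values, rb.values]),
        groups=["a"] * n_per_group + ["b"] * n_per_group,
    )
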