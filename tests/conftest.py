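import numpy as np
import pytest

from isoresolve import CcsRead, TruthSet, simulate_ccs_reads


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def reads_from_template(
    template: str, n: int, error_rate: float, seed: int, prefix: str = "r"
) -> list[CcsRead]:
    """CCS-like reads from one template, ids prefixed for traceability."""
    truth = TruthSet({"t": template}, {"t": 1})
    reads = simulate_ccs_reads(truth, n, error_rate, seed)
    for r in reads:
        r.read_id = prefix + r.read_id
    return reads


def perfect_reads(template: str, n: int, prefix: str = "r", q: int = 40) -> list[CcsRead]:
    return [
        CcsRead(f"{prefix}{i:03d}", template, [q] * len(template)) for i in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
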