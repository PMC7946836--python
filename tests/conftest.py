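import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrfocus import Clone, Repertoire

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def two_clone_rep() -> Repertoire:
    return Repertoire(
        sample_id="two",
        clones=(
            Clone(cdr3_aa="CASSLG", count=30, v_call="TRAV1", j_call="TRAJ4"),
            Clone(cdr3_aa="CAWSVG", count=70, v_call="TRAV2", j_call="TRAJ9"),
        ),
        patient_id="P1",
        chain="alpha",
        timepoint="BL",
    )


@pytest.fixture
def skewed_rep() -> Repertoire:
    """900 singleton clones plus one clone of 100 reads (total 1000 reads)."""
    rng = np.random.default_rng(42)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seen = set()
    while len(seen) < 901:
        seen.add("".join(letters[i] for i in rng.integers(0, 20, size=12)))
    cdr3s = sorted(seen)
    clones = [Clone(cdr3_aa=cdr3s[0], count=100)]
    clones += [Clone(cdr3_aa=s, count=1) for s in cdr3s[1:]]
    return Repertoire(sample_id="skewed", clones=tuple(clones), patient_id="P2")


def random_distribution(rng: np.random.Generator, max_size: int = 50) -> np.ndarray:
    """Random strictly positive frequency vector summing to 1."""
    size = int(rng.integers(2, max_size + 1))
    p = rng.dirichlet(np.full(size, 0.5))
    p = np.clip(p, 1e-12, None)
    return p / p.sum()


def random_cdr3(rng: np.random.Generator, lo: int = 10, hi: int = 18) -> str:
    letters = "ACDEFGHIKLMNPQRSTVWY"
    length = int(rng.integers(lo, hi + 1))
    return "".join(letters[i] for i in rng.integers(0, 20, size=length))
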