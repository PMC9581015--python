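import numpy as np
import pytest

from centerscan.pattern import MotifPattern, PatternElement
from centerscan.scanner import builtin_motifs

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def curated():
    """The five bundled functional-center motif records, keyed by id."""
    return {m.motif_id: m for m in builtin_motifs()}


def random_sequence(rng: np.random.Generator, max_len: int = 40) -> str:
    n = int(rng.integers(0, max_len + 1))
    return "".join(AA[int(i)] for i in rng.integers(0, 20, size=n))


def random_pattern(rng: np.random.Generator, max_elements: int = 6) -> MotifPattern:
    """Small random motif for oracle-equivalence and monotonicity checks."""
    n = int(rng.integers(1, max_elements + 1))
    elements = []
    for _ in range(n):
        kind = ["fixed", "class", "excluded_class", "wildcard"][
            int(rng.integers(4))
        ]
        if kind == "wildcard":
            lo = int(rng.integers(0, 4))
            hi = lo + int(rng.integers(0, 4))
            elements.append(PatternElement("wildcard", frozenset(), lo, hi))
        else:
            size = 1 if kind == "fixed" else int(rng.integers(1, 5))
            residues = frozenset(
                AA[int(i)] for i in rng.choice(20, size=size, replace=False)
            )
            if kind == "fixed":
                rep = int(rng.integers(1, 3))
                elements.append(PatternElement("fixed", residues, rep, rep))
            else:
                elements.append(PatternElement(kind, residues, 1, 1))
    return MotifPattern("rand", tuple(elements))
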