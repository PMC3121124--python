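import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from domcrf.alignments import DomainAlignment, pair_rows


def make_alignment(domain_id: str, rows: list[tuple[str, str]]) -> DomainAlignment:
    """Rows as (organism, sequence); sequence ids are autogenerated."""
    return DomainAlignment(
        domain_id, [(org, f"{domain_id}row{k}_{org}", seq) for k, (org, seq) in enumerate(rows)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_pairing():
    """Two 4-column alignments over 5 shared organisms."""
    a = make_alignment(
        "DA",
        [("X", "ACDE"), ("Y", "ACDF"), ("Z", "AGDE"), ("W", "MCDE"), ("V", "ACKE")],
    )
    b = make_alignment(
        "DB",
        [("X", "TTKK"), ("Y", "TSKR"), ("Z", "TTGK"), ("W", "PTKK"), ("V", "TTKW")],
    )
    return pair_rows(a, b)
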