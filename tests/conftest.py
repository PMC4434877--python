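import numpy as np
import pandas as pd
import pytest

from dcreg import CoexpressionNetworkPair, ExpressionMatrix, LinkCutoff


def make_expression(values: dict[str, list[float]], groups: dict[str, int]) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-gene value lists and group sizes."""
    samples, cond = [], {}
    for g, n in groups.items():
        for k in range(n):
            s = f"{g}{k+1}"
            samples.append(s)
            cond[s] = g
    frame = pd.DataFrame(values, index=samples).T
    frame.columns = samples
    return ExpressionMatrix(values=frame, conditions=pd.Series(cond))


def make_network(links, r1, r2, labels=("c1", "c2")) -> CoexpressionNetworkPair:
    return CoexpressionNetworkPair(
        links=[tuple(sorted(l)) for l in links],
        r1=np.asarray(r1, dtype=float),
        r2=np.asarray(r2, dtype=float),
        condition_labels=labels,
        cutoff=LinkCutoff(),
    )


@pytest.fixture
def star_network() -> CoexpressionNetworkPair:
    """Hub H linked to A, B, C with enumerated coefficients."""
    return make_network(
        links=[("A", "H"), ("B", "H"), ("C", "H")],
        r1=[0.9, -0.8, 0.7],
        r2=[0.1, 0.8, -0.7],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
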