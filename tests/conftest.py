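import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Structure consistent with the published worked input-vector example:
#: a hydroxy-coumarin bearing a para-hydroxyphenyl substituent.
GOLDEN_SMILES = "O=C1Oc2cc(O)ccc2C=C1c1ccc(O)cc1"

#: The printed counts of the worked example.
GOLDEN_COUNTS = {
    ">C=C<(1)": 1,
    "Ar-Ar": 1,
    "N2(beta)": 2,
    "N1(para-)": 1,
    ">C=O(Ring)": 1,
    "-O-(Ring)": 1,
    ">C=(Ring)": 4,
    "-CH=(Ring)": 8,
    "-OH(ph)": 2,
    "Other groups": 0,
}
GOLDEN_A = 8
GOLDEN_B = 8


def _substituted_corpus() -> list[str]:
    """Deterministic corpus of >=100 valid SMILES built combinatorially."""
    scaffolds = [
        "c1ccccc1{0}",
        "c1ccc(cc1){0}",
        "c1ccc2ccccc2c1",
        "c1ccc2cc({0})ccc2c1",
        "O=C(c1ccccc1){0}",
        "C=Cc1ccc({0})cc1",
        "c1ccncc1",
        "CC(C){0}",
        "O=C1Oc2ccccc2C=C1{0}",
        "c1ccc(-c2ccccc2)cc1",
    ]
    subs = [
        "O", "N", "C", "Cl", "Br", "F", "I", "C#N", "C(=O)O", "C(=O)OC", "C(C)=O",
        "OC", "[N+](=O)[O-]", "S", "SC", "CC", "N(C)C", "C(N)=O", "S(C)(=O)=O", "OCC",
    ]
    out = []
    for sc in scaffolds:
        if "{0}" not in sc:
            out.append(sc)
            continue
        for su in subs:
            out.append(sc.format(su))
    return out


@pytest.fixture(scope="session")
def smiles_corpus() -> list[str]:
    corpus = _substituted_corpus()
    assert len(corpus) >= 100
    return corpus


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
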