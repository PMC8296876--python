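import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from stripalloc import (
    Center,
    FixtureSpec,
    Macroarea,
    NationConfig,
    Region,
    italy_fixture,
)


@pytest.fixture(scope="session")
def italy():
    """Italy topology, uniform 26% acceptance, 2017 donor-count weights."""
    return italy_fixture()


@pytest.fixture(scope="session")
def italy_sardegna_donor():
    """Italy topology where every surplus organ originates in Sardegna,
    a North region without a transplant center."""
    return italy_fixture(FixtureSpec(production_weights={"Sardegna": 1}))


def make_two_center_config(p: float, q: float) -> NationConfig:
    """Minimal nation: centers X (macroarea A, rate p) and Y (B, rate q),
    with all production in a no-center region of A."""
    return NationConfig(
        macroareas=(
            Macroarea(
                id="A",
                strip=("X",),
                regions=(
                    Region(name="rx", macroarea="A", center="X", production=0),
                    Region(name="src", macroarea="A", center=None, production=5),
                ),
            ),
            Macroarea(
                id="B",
                strip=("Y",),
                regions=(Region(name="ry", macroarea="B", center="Y", production=0),),
            ),
        ),
        centers=(
            Center(id="X", member_regions=frozenset({"rx"}), acceptance_rate=p),
            Center(id="Y", member_regions=frozenset({"ry"}), acceptance_rate=q),
        ),
    )


def make_single_center_config(p: float) -> NationConfig:
    """One center in macroarea A with all production outside its region, and
    an empty macroarea B: acceptances are i.i.d. Bernoulli(p)."""
    return NationConfig(
        macroareas=(
            Macroarea(
                id="A",
                strip=("X",),
                regions=(
                    Region(name="rx", macroarea="A", center="X", production=0),
                    Region(name="src", macroarea="A", center=None, production=3),
                ),
            ),
            Macroarea(
                id="B",
                strip=(),
                regions=(Region(name="rb", macroarea="B", center=None, production=0),),
            ),
        ),
        centers=(
            Center(id="X", member_regions=frozenset({"rx"}), acceptance_rate=p),
        ),
    )


def make_alternation_config() -> NationConfig:
    """Two always-accepting centers in one macroarea, donor outside both:
    allocation strictly alternates between them."""
    return NationConfig(
        macroareas=(
            Macroarea(
                id="A",
                strip=("X", "Y"),
                regions=(
                    Region(name="rx", macroarea="A", center="X", production=0),
                    Region(name="ry", macroarea="A", center="Y", production=0),
                    Region(name="src", macroarea="A", center=None, production=1),
                ),
            ),
            Macroarea(
                id="B",
                strip=(),
                regions=(Region(name="rb", macroarea="B", center=None, production=0),),
            ),
        ),
        centers=(
            Center(id="X", member_regions=frozenset({"rx"}), acceptance_rate=1.0),
            Center(id="Y", member_regions=frozenset({"ry"}), acceptance_rate=1.0),
        ),
    )
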