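"""Canonical Italian configuration and random-config generation.

``italy_fixture`` builds the two-macroarea lung topology of the national
surplus protocol: macroarea North with strip Piemonte, Emilia Romagna,
Toscana, NITp (the NITp unit covering several regions under one CRT) and
macroarea South with strip Lazio, Sicilia.  The default uniform acceptance
rate is 26% — the observed mean acceptance rate of the period the protocol
was evaluated on — and the default production preset uses the published
2017 per-region donor counts as proxy weights for the donor distribution
(121 Piemonte, 142 Emilia Romagna, 167 Toscana, 130 Veneto, 226 Lombardia,
50 Sicilia, 117 Lazio; all other regions 0).

The assignment of no-center regions to macroareas is only partially fixed by
the protocol documents; this fixture places Sardegna and Valle d'Aosta in the
North and Calabria, Basilicata, Abruzzo-Molise, Umbria, Campania and Puglia
in the South.  Pass ``production_weights`` (or edit a written config file) to
change any of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    Center,
    ConfigValidationError,
    Macroarea,
    NationConfig,
    Region,
)

__all__ = ["FixtureSpec", "italy_fixture", "random_config", "DONOR_COUNTS_2017"]

#: published 2017 per-region donor counts, the default production preset
DONOR_COUNTS_2017: dict[str, int] = {
    "Piemonte": 121,
    "Emilia Romagna": 142,
    "Toscana": 167,
    "Veneto": 130,
    "Lombardia": 226,
    "Sicilia": 50,
    "Lazio": 117,
}

_NITP_MEMBERS = (
    "Lombardia",
    "Veneto",
    "Friuli Venezia Giulia",
    "Trentino-Alto Adige",
    "Liguria",
    "Marche",
)
_NORTH_NO_CENTER = ("Valle d'Aosta", "Sardegna")
_SOUTH_NO_CENTER = (
    "Calabria",
    "Basilicata",
    "Abruzzo-Molise",
    "Umbria",
    "Campania",
    "Puglia",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the Italian fixture: uniform acceptance rate, number of
    surplus organs, and per-region production weights."""

    acceptance_rate: float = 0.26
    n_organs: int = 10
    production_weights: dict[str, int] = field(
        default_factory=lambda: dict(DONOR_COUNTS_2017)
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise ConfigValidationError("acceptance_rate must lie in [0, 1]")
        if self.n_organs < 1:
            raise ConfigValidationError("n_organs must be >= 1")
        if any(w < 0 for w in self.production_weights.values()):
            raise ConfigValidationError("production weights must be nonnegative")
        if self.production_weights and not any(self.production_weights.values()):
            raise ConfigValidationError("production weights must not all be zero")


def italy_fixture(spec: FixtureSpec | None = None) -> NationConfig:
    """The two-macroarea Italian lung-surplus topology."""
    spec = spec or FixtureSpec()
    w = spec.production_weights

    def region(name: str, ma: str, center: str | None) -> Region:
        return Region(name=name, macroarea=ma, center=center, production=w.get(name, 0))

    north_regions = (
        region("Piemonte", "North", "Piemonte"),
        region("Emilia Romagna", "North", "Emilia Romagna"),
        region("Toscana", "North", "Toscana"),
        *(region(n, "North", "NITp") for n in _NITP_MEMBERS),
        *(region(n, "North", None) for n in _NORTH_NO_CENTER),
    )
    south_regions = (
        region("Lazio", "South", "Lazio"),
        region("Sicilia", "South", "Sicilia"),
        *(region(n, "South", None) for n in _SOUTH_NO_CENTER),
    )
    rate = spec.acceptance_rate
    centers = tuple(
        Center(id=cid, member_regions=frozenset(members), acceptance_rate=rate)
        for cid, members in (
            ("Piemonte", ("Piemonte",)),
            ("Emilia Romagna", ("Emilia Romagna",)),
            ("Toscana", ("Toscana",)),
            ("NITp", _NITP_MEMBERS),
            ("Lazio", ("Lazio",)),
            ("Sicilia", ("Sicilia",)),
        )
    )
    return NationConfig(
        macroareas=(
            Macroarea(
                id="North",
                strip=("Piemonte", "Emilia Romagna", "Toscana", "NITp"),
                regions=north_regions,
            ),
            Macroarea(id="South", strip=("Lazio", "Sicilia"), regions=south_regions),
        ),
        centers=centers,
    )


def random_config(
    seed,
    *,
    max_centers_per_area: int = 4,
    max_slots_per_strip: int | None = None,
    max_no_center_regions: int = 2,
    allow_multislot: bool = True,
) -> NationConfig:
    """A random valid two-macroarea nation for property tests.

    Each macroarea receives 1..``max_centers_per_area`` single-region centers
    (occasionally a multi-region one), optional duplicate strip slots, random
    acceptance rates and random productions; the result always passes
    configuration validation and has positive total production.
    """
    rng = np.random.default_rng(seed)
    macroareas = []
    centers: list[Center] = []
    serial = 0
    for ma_name in ("A", "B"):
        n_centers = int(rng.integers(1, max_centers_per_area + 1))
        if max_slots_per_strip is not None:
            n_centers = min(n_centers, max_slots_per_strip)
        regions: list[Region] = []
        strip: list[str] = []
        for _ in range(n_centers):
            cid = f"C{serial}"
            members = [f"R{serial}"]
            serial += 1
            if rng.random() < 0.2:  # occasionally a multi-region center
                members.append(f"R{serial}")
                serial += 1
            for m in members:
                regions.append(
                    Region(
                        name=m,
                        macroarea=ma_name,
                        center=cid,
                        production=int(rng.integers(0, 10)),
                    )
                )
            centers.append(
                Center(
                    id=cid,
                    member_regions=frozenset(members),
                    acceptance_rate=float(np.round(rng.random(), 3)),
                )
            )
            strip.append(cid)
        if allow_multislot and (
            max_slots_per_strip is None or len(strip) < max_slots_per_strip
        ):
            if rng.random() < 0.25:
                strip.append(strip[int(rng.integers(0, len(strip)))])
        rng.shuffle(strip)
        for _ in range(int(rng.integers(0, max_no_center_regions + 1))):
            regions.append(
                Region(
                    name=f"R{serial}",
                    macroarea=ma_name,
                    center=None,
                    production=int(rng.integers(0, 10)),
                )
            )
            serial += 1
        macroareas.append(
            Macroarea(id=ma_name, strip=tuple(strip), regions=tuple(regions))
        )
    # guarantee positive total production
    if sum(r.production for ma in macroareas for r in ma.regions) == 0:
        ma0 = macroareas[0]
        r0 = ma0.regions[0]
        patched = (
            Region(name=r0.name, macroarea=r0.macroarea, center=r0.center, production=1),
        ) + ma0.regions[1:]
        macroareas[0] = Macroarea(id=ma0.id, strip=ma0.strip, regions=patched)
    return NationConfig(macroareas=tuple(macroareas), centers=tuple(centers))
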