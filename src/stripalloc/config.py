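"""Domain types and the national configuration file.

A nation is partitioned into exactly two *macroareas*.  Each macroarea owns an
ordered *strip* of transplant-center slots (the rotating priority queue of the
surplus protocol) and a set of regions.  Regions either host a center (possibly
shared with other regions, as with the NITp macroregion) or have none; every
region reports a *production* count — the number of surplus organs it provided
in the period — from which the donor distribution is derived.

The file format is YAML (JSON is valid YAML and is accepted too)::

    macroareas:
      - id: North
        strip: [Piemonte, "Emilia Romagna", Toscana, NITp]
        regions:
          - {name: Piemonte, center: Piemonte, production: 121}
          - {name: Sardegna, center: null, production: 0}
          ...
    centers:
      - {id: NITp, acceptance_rate: 0.26,
         member_regions: [Lombardia, Veneto, ...]}
    fallback_mode: cascade   # optional; 'cascade' (default) or 'head_only'
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Region",
    "Center",
    "Macroarea",
    "NationConfig",
    "RunParameters",
    "ConfigValidationError",
    "load_config",
    "write_config",
    "donor_distribution",
]


class ConfigValidationError(ValueError):
    """A national configuration violates a structural invariant."""


@dataclass(frozen=True)
class Region:
    """One administrative region.

    ``center`` is the id of the transplant-center unit this region belongs to,
    or ``None`` for regions without any lung-transplant center.  ``production``
    is the (integer) number of surplus organs the region provided in the
    period considered.
    """

    name: str
    macroarea: str
    center: str | None
    production: int = 0

    def __post_init__(self) -> None:
        if self.production < 0 or self.production != int(self.production):
            raise ConfigValidationError(
                f"region {self.name!r}: production must be a nonnegative "
                f"integer, got {self.production!r}"
            )


@dataclass(frozen=True)
class Center:
    """A transplant-center unit occupying slot(s) in a macroarea strip.

    ``acceptance_rate`` is the Bernoulli parameter of the models: the ratio of
    accepted organs to organs offered to the center over the period.  A center
    with more than one member region models a macroregion such as NITp.
    """

    id: str
    member_regions: frozenset[str]
    acceptance_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise ConfigValidationError(
                f"center {self.id!r}: acceptance_rate must lie in [0, 1], "
                f"got {self.acceptance_rate}"
            )
        if not self.member_regions:
            raise ConfigValidationError(
                f"center {self.id!r}: member_regions must be nonempty"
            )


@dataclass(frozen=True)
class Macroarea:
    """One of the two national groupings structuring the offer cascade."""

    id: str
    strip: tuple[str, ...]
    regions: tuple[Region, ...]

    @property
    def region_names(self) -> frozenset[str]:
        return frozenset(r.name for r in self.regions)


@dataclass(frozen=True)
class NationConfig:
    """Validated national protocol topology.

    Exactly two macroareas are required: the offer cascade falls back to "the
    other" macroarea, which is only unambiguous with two.  (An ordered list of
    fallback macroareas is the documented extension point should the protocol
    ever grow beyond two.)
    """

    macroareas: tuple[Macroarea, ...]
    centers: tuple[Center, ...]
    fallback_mode: str = "cascade"  # or 'head_only'

    def __post_init__(self) -> None:
        _validate(self)

    # -- lookups -----------------------------------------------------------
    @property
    def regions(self) -> tuple[Region, ...]:
        return tuple(r for ma in self.macroareas for r in ma.regions)

    @property
    def total_production(self) -> int:
        return sum(r.production for r in self.regions)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"unknown region {name!r}")

    def center(self, center_id: str) -> Center:
        for c in self.centers:
            if c.id == center_id:
                return c
        raise KeyError(f"unknown center {center_id!r}")

    def macroarea(self, ma_id: str) -> Macroarea:
        for ma in self.macroareas:
            if ma.id == ma_id:
                return ma
        raise KeyError(f"unknown macroarea {ma_id!r}")

    def other_macroarea(self, ma_id: str) -> Macroarea:
        others = [ma for ma in self.macroareas if ma.id != ma_id]
        if len(others) != 1:
            raise KeyError(f"unknown macroarea {ma_id!r}")
        return others[0]

    def macroarea_of_center(self, center_id: str) -> Macroarea:
        c = self.center(center_id)
        some_region = next(iter(c.member_regions))
        return self.macroarea(self.region(some_region).macroarea)

    def acceptance_rate(self, center_id: str) -> float:
        return self.center(center_id).acceptance_rate

    def center_of_region(self, region_name: str) -> str | None:
        return self.region(region_name).center

    def with_uniform_rate(self, rate: float) -> "NationConfig":
        """A copy with every center's acceptance rate set to ``rate``."""
        return replace(
            self,
            centers=tuple(replace(c, acceptance_rate=rate) for c in self.centers),
        )


@dataclass(frozen=True)
class RunParameters:
    """Run-level knobs: number of surplus organs M, engine, replications."""

    n_organs: int
    engine: str = "exact"  # exact | bahadur | independent | montecarlo
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organs < 1:
            raise ConfigValidationError("n_organs must be >= 1")
        if self.n_reps < 1:
            raise ConfigValidationError("n_reps must be >= 1")
        if self.engine not in {"exact", "bahadur", "independent", "montecarlo"}:
            raise ConfigValidationError(f"unknown engine {self.engine!r}")


# ---------------------------------------------------------------------------
# validation

def _validate(config: NationConfig) -> None:
    if len(config.macroareas) != 2:
        raise ConfigValidationError(
            f"exactly two macroareas are required, got {len(config.macroareas)}"
        )
    if config.fallback_mode not in {"cascade", "head_only"}:
        raise ConfigValidationError(
            f"fallback_mode must be 'cascade' or 'head_only', "
            f"got {config.fallback_mode!r}"
        )
    ma_ids = [ma.id for ma in config.macroareas]
    if len(set(ma_ids)) != 2:
        raise ConfigValidationError(f"macroarea ids must be distinct: {ma_ids}")

    names = [r.name for ma in config.macroareas for r in ma.regions]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigValidationError(f"region names must be globally unique: {sorted(dupes)}")

    center_ids = [c.id for c in config.centers]
    if len(set(center_ids)) != len(center_ids):
        raise ConfigValidationError("center ids must be unique")
    by_id = {c.id: c for c in config.centers}

    region_by_name = {r.name: r for ma in config.macroareas for r in ma.regions}
    for c in config.centers:
        mas = set()
        for rn in c.member_regions:
            if rn not in region_by_name:
                raise ConfigValidationError(
                    f"center {c.id!r}: member region {rn!r} is not a region"
                )
            if region_by_name[rn].center != c.id:
                raise ConfigValidationError(
                    f"region {rn!r} must declare center {c.id!r} to be a member"
                )
            mas.add(region_by_name[rn].macroarea)
        if len(mas) != 1:
            raise ConfigValidationError(
                f"center {c.id!r}: member regions span macroareas {sorted(mas)}"
            )
    for r in region_by_name.values():
        if r.center is not None:
            if r.center not in by_id:
                raise ConfigValidationError(
                    f"region {r.name!r} names unknown center {r.center!r}"
                )
            if r.name not in by_id[r.center].member_regions:
                raise ConfigValidationError(
                    f"center {r.center!r} must list member region {r.name!r}"
                )

    for ma in config.macroareas:
        ma_centers = {
            c.id for c in config.centers
            if region_by_name[next(iter(c.member_regions))].macroarea == ma.id
        }
        for slot in ma.strip:
            if slot not in ma_centers:
                raise ConfigValidationError(
                    f"macroarea {ma.id!r}: strip slot {slot!r} is not a center "
                    f"of this macroarea"
                )
        if ma_centers and not ma.strip:
            raise ConfigValidationError(
                f"macroarea {ma.id!r} has centers but an empty strip"
            )
        missing = ma_centers - set(ma.strip)
        if missing:
            raise ConfigValidationError(
                f"macroarea {ma.id!r}: centers {sorted(missing)} absent from strip"
            )


# ---------------------------------------------------------------------------
# donor distribution

def donor_distribution(config: NationConfig) -> dict[str, float]:
    """Per-region probability of providing a surplus organ.

    P(x) = S_x / sum(S) where S_x is the region's production count.  Raises if
    total production is zero (the donor distribution is then undefined).
    """
    total = config.total_production
    if total <= 0:
        raise ConfigValidationError(
            "total production is zero: donor distribution undefined"
        )
    return {r.name: r.production / total for r in config.regions}


# ---------------------------------------------------------------------------
# (de)serialization

def _to_dict(config: NationConfig) -> dict:
    return {
        "macroareas": [
            {
                "id": ma.id,
                "strip": list(ma.strip),
                "regions": [
                    {"name": r.name, "center": r.center, "production": r.production}
                    for r in ma.regions
                ],
            }
            for ma in config.macroareas
        ],
        "centers": [
            {
                "id": c.id,
                "acceptance_rate": c.acceptance_rate,
                "member_regions": sorted(c.member_regions),
            }
            for c in config.centers
        ],
        "fallback_mode": config.fallback_mode,
    }


def _from_dict(data: Mapping) -> NationConfig:
    try:
        macroareas = []
        for ma in data["macroareas"]:
            regions = tuple(
                Region(
                    name=str(r["name"]),
                    macroarea=str(ma["id"]),
                    center=None if r.get("center") is None else str(r["center"]),
                    production=int(r.get("production", 0)),
                )
                for r in ma["regions"]
            )
            macroareas.append(
                Macroarea(
                    id=str(ma["id"]),
                    strip=tuple(str(s) for s in ma.get("strip", [])),
                    regions=regions,
                )
            )
        centers = tuple(
            Center(
                id=str(c["id"]),
                member_regions=frozenset(str(m) for m in c["member_regions"]),
                acceptance_rate=float(c["acceptance_rate"]),
            )
            for c in data["centers"]
        )
    except KeyError as exc:  # pragma: no cover - message content only
        raise ConfigValidationError(f"missing configuration key: {exc}") from exc
    return NationConfig(
        macroareas=tuple(macroareas),
        centers=centers,
        fallback_mode=str(data.get("fallback_mode", "cascade")),
    )


def load_config(path) -> NationConfig:
    """Read and validate a national configuration from a YAML/JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigValidationError(f"{path}: top level must be a mapping")
    return _from_dict(data)


def write_config(config: NationConfig, path) -> None:
    """Serialize a configuration so that ``load_config`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False, allow_unicode=True)
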