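"""Deterministic mechanics of one surplus-organ allocation.

The protocol: each surplus organ is offered to the centers of the donor's
macroarea in the order of that macroarea's *strip*, skipping the donor's own
center (a region that produced the surplus organ is not asked to use it).  If
every center of the donor's macroarea refuses, the cascade continues down the
other macroarea's strip.  After an acceptance, the accepting center's strip is
rotated: the acceptor's slot and the slots of every center of that strip that
refused this organ move to the end, keeping their relative order; every other
slot keeps its place.  If nobody accepts the organ is lost and neither strip
changes.

Two behaviours are configurable on :class:`~stripalloc.config.NationConfig`:

* ``fallback_mode='cascade'`` (default) walks the whole fallback strip;
  ``'head_only'`` offers only to the head of the fallback strip.
* A center occupying several strip slots is queried once, at its earliest
  slot, and only that triggering slot moves on rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import NationConfig

__all__ = [
    "StripState",
    "JointState",
    "OfferOutcome",
    "LOST",
    "initial_state",
    "offer_order",
    "rotate_strip",
    "allocate_one",
]

LOST = "LOST"


@dataclass(frozen=True)
class StripState:
    """One arrangement of a macroarea's strip slots (a multiset permutation)."""

    arrangement: tuple[str, ...]

    def first_index(self, center_id: str) -> int:
        """Earliest (0-based) slot of ``center_id``; the querying/moving slot."""
        return self.arrangement.index(center_id)

    def order(self) -> tuple[str, ...]:
        """Centers in query order: first occurrence of each slot entry."""
        seen: list[str] = []
        for c in self.arrangement:
            if c not in seen:
                seen.append(c)
        return tuple(seen)


@dataclass(frozen=True)
class JointState:
    """One :class:`StripState` per macroarea, keyed by macroarea id."""

    strips: tuple[tuple[str, StripState], ...]  # (macroarea id, strip state)

    def strip(self, ma_id: str) -> StripState:
        for key, st in self.strips:
            if key == ma_id:
                return st
        raise KeyError(f"unknown macroarea {ma_id!r}")

    def replace_strip(self, ma_id: str, new: StripState) -> "JointState":
        return JointState(
            strips=tuple((k, new if k == ma_id else s) for k, s in self.strips)
        )


@dataclass(frozen=True)
class OfferOutcome:
    """Result of one allocation: who (if anyone) accepted, and the new state."""

    accepted_by: str  # center id or LOST
    offer_sequence: tuple[tuple[str, str], ...]  # (center id, 'accept'|'refuse')
    updated_state: JointState


def initial_state(config: NationConfig) -> JointState:
    """Joint state with every strip in its configured starting arrangement."""
    return JointState(
        strips=tuple(
            (ma.id, StripState(tuple(ma.strip))) for ma in config.macroareas
        )
    )


def offer_order(
    state: JointState, config: NationConfig, donor_region: str
) -> tuple[str, ...]:
    """Centers queried for an organ produced in ``donor_region``, in order.

    The donor macroarea's strip comes first with the donor's own center
    removed, then the other macroarea's strip (all of it under the default
    cascade fallback, only its head under ``fallback_mode='head_only'``).
    """
    region = config.region(donor_region)  # KeyError for unknown donors
    donor_center = region.center
    home = config.macroarea(region.macroarea)
    away = config.other_macroarea(home.id)

    order = [
        c for c in state.strip(home.id).order() if c != donor_center
    ]
    away_order = state.strip(away.id).order()
    if config.fallback_mode == "head_only":
        away_order = away_order[:1]
    order.extend(away_order)
    return tuple(order)


def rotate_strip(
    state: StripState,
    queried_refusers: tuple[str, ...] | list[str],
    acceptor: str | None,
) -> StripState:
    """Rotate a strip after an allocation decided within it.

    The triggering (earliest) slot of each refuser and of the acceptor move to
    the end of the strip, in their original relative order; all other slots
    keep their relative order.  With no acceptor the strip is unchanged.
    """
    if acceptor is None:
        return state
    if acceptor not in state.arrangement:
        raise ValueError(f"acceptor {acceptor!r} not in strip {state.arrangement}")
    moving = set()
    acceptor_idx = state.first_index(acceptor)
    for refuser in queried_refusers:
        idx = state.first_index(refuser)  # ValueError if absent
        if idx >= acceptor_idx:
            raise ValueError(
                f"refuser {refuser!r} does not precede acceptor {acceptor!r}"
            )
        moving.add(idx)
    moving.add(acceptor_idx)
    kept = [c for i, c in enumerate(state.arrangement) if i not in moving]
    moved = [c for i, c in enumerate(state.arrangement) if i in moving]
    return StripState(tuple(kept + moved))


def allocate_one(
    state: JointState,
    config: NationConfig,
    donor_region: str,
    decisions,
) -> OfferOutcome:
    """Run one organ through the cascade given fixed accept/refuse decisions.

    ``decisions`` maps center id to ``True`` (accept) / ``False`` (refuse) or
    to the strings ``'accept'`` / ``'refuse'``; it must cover every center in
    the offer order.  Only the strip of the macroarea where the acceptance
    occurred is rotated; a fully refused organ is LOST and changes nothing.
    """
    order = offer_order(state, config, donor_region)
    sequence: list[tuple[str, str]] = []
    for center_id in order:
        if center_id not in decisions:
            raise KeyError(f"no decision provided for queried center {center_id!r}")
        d = decisions[center_id]
        accept = d if isinstance(d, bool) else d == "accept"
        sequence.append((center_id, "accept" if accept else "refuse"))
        if accept:
            ma = config.macroarea_of_center(center_id)
            same_strip_refusers = tuple(
                c for c, dec in sequence[:-1]
                if dec == "refuse" and config.macroarea_of_center(c).id == ma.id
            )
            new_strip = rotate_strip(
                state.strip(ma.id), same_strip_refusers, center_id
            )
            return OfferOutcome(
                accepted_by=center_id,
                offer_sequence=tuple(sequence),
                updated_state=state.replace_strip(ma.id, new_strip),
            )
    return OfferOutcome(
        accepted_by=LOST,
        offer_sequence=tuple(sequence),
        updated_state=state,
    )
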