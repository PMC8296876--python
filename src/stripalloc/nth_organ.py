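"""First probability model: who obtains the t-th surplus organ.

The joint strip arrangement of the two macroareas is a Markov chain: each
organ draws a donor region from the production-weighted donor distribution,
runs the offer cascade, and rotates the strip where the acceptance occurred.
Because strips are finite multisets the chain lives on finitely many joint
states (48 for the default Italian topology), so all quantities are computed
*exactly* by evolving the full distribution over joint states:

* ``P_c^t`` — probability that center ``c`` is offered and accepts organ
  ``t``, together with the per-organ loss probability
  (``sum_c P_c^t + P_lost^t = 1``);
* ``T_c^{t,j}`` — probability that ``c`` sits at strip position ``j`` when
  organ ``t`` arrives;
* ``P_{c,j}^t`` — probability that ``c`` obtains organ ``t`` given it sits at
  position ``j`` (so ``P_c^t = sum_j T_c^{t,j} P_{c,j}^t``).

Convergence of the chain to its stationary distribution is what produces the
plateau of the per-organ probability curves as ``t`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigValidationError, NationConfig, donor_distribution
from .protocol import (
    LOST,
    JointState,
    StripState,
    initial_state,
    offer_order,
    rotate_strip,
)

__all__ = [
    "ChainDistribution",
    "NthOrganResult",
    "StateSpaceOverflowError",
    "ChainEvolver",
    "evolve",
    "nth_probability",
    "position_conditional_probability",
    "overall_use_probability",
]

#: refuse to track more reachable joint states than this; beyond it the exact
#: chain is impractical and the Monte Carlo engine should be used instead.
DEFAULT_STATE_CAP = 100_000


class StateSpaceOverflowError(RuntimeError):
    """Raised when the reachable joint-state space exceeds the cap."""


@dataclass(frozen=True)
class ChainDistribution:
    """Distribution over joint strip states at a given organ index."""

    t: int  # 1-based organ index this distribution refers to
    probabilities: tuple[tuple[JointState, float], ...]

    def as_dict(self) -> dict[JointState, float]:
        return dict(self.probabilities)

    def total(self) -> float:
        return float(sum(p for _, p in self.probabilities))


@dataclass(frozen=True)
class NthOrganResult:
    """Exact per-center probabilities for one organ index ``t``.

    ``position_distribution[c]`` is the vector ``T_c^{t,j}`` over 1-based
    strip positions ``j`` (stored at array index ``j - 1``);
    ``position_conditional[c]`` holds ``P_{c,j}^t`` with the convention 0 at
    positions the center never occupies.
    """

    t: int
    probabilities: dict[str, float]
    loss_probability: float
    position_distribution: dict[str, np.ndarray]
    position_conditional: dict[str, np.ndarray]


class ChainEvolver:
    """Evolves the joint-state chain and reads off per-organ probabilities.

    Donor regions are grouped by their (macroarea, own-center) pair — the only
    donor features the cascade sees — and offer orders/transitions are
    memoized per (state, donor group), which keeps the exact computation fast
    even for long horizons.
    """

    def __init__(self, config: NationConfig, state_cap: int = DEFAULT_STATE_CAP):
        self.config = config
        self.state_cap = state_cap
        self.rates = {c.id: c.acceptance_rate for c in config.centers}
        self.center_ma = {
            c.id: config.macroarea_of_center(c.id).id for c in config.centers
        }
        dist = donor_distribution(config)
        # donor groups: (macroarea id, donor's center id or None) -> total prob
        self.donor_groups: dict[tuple[str, str | None], float] = {}
        for region in config.regions:
            if dist[region.name] == 0.0:
                continue
            key = (region.macroarea, region.center)
            self.donor_groups[key] = self.donor_groups.get(key, 0.0) + dist[region.name]
        self._transitions: dict = {}
        self._seen_states: set[JointState] = set()

    # -- cascade enumeration ----------------------------------------------
    def cascade(self, state: JointState, donor_key: tuple[str, str | None]):
        """All outcomes of one organ from ``state`` for a donor group.

        Returns ``(outcomes, loss_prob)`` where outcomes is a list of
        ``(center id, probability, successor state)``.
        """
        memo_key = (state, donor_key)
        cached = self._transitions.get(memo_key)
        if cached is not None:
            return cached
        ma_id, donor_center = donor_key
        home = self.config.macroarea(ma_id)
        away = self.config.other_macroarea(ma_id)
        order = [c for c in state.strip(home.id).order() if c != donor_center]
        away_order = list(state.strip(away.id).order())
        if self.config.fallback_mode == "head_only":
            away_order = away_order[:1]
        order.extend(away_order)

        outcomes = []
        prefix = 1.0
        for i, center_id in enumerate(order):
            rate = self.rates[center_id]
            if rate > 0.0:
                strip_ma = self.center_ma[center_id]
                refusers = tuple(
                    c for c in order[:i] if self.center_ma[c] == strip_ma
                )
                new_strip = rotate_strip(state.strip(strip_ma), refusers, center_id)
                successor = state.replace_strip(strip_ma, new_strip)
                outcomes.append((center_id, prefix * rate, successor))
                self._note_state(successor)
            prefix *= 1.0 - rate
        result = (outcomes, prefix)
        self._transitions[memo_key] = result
        return result

    def _note_state(self, state: JointState) -> None:
        self._seen_states.add(state)
        if len(self._seen_states) > self.state_cap:
            raise StateSpaceOverflowError(
                f"more than {self.state_cap} reachable joint strip states; "
                "use the montecarlo engine for this configuration"
            )

    # -- public steps ------------------------------------------------------
    def initial_chain(self) -> ChainDistribution:
        s0 = initial_state(self.config)
        self._note_state(s0)
        return ChainDistribution(t=1, probabilities=((s0, 1.0),))

    def evolve(self, chain: ChainDistribution) -> ChainDistribution:
        """One organ's worth of evolution of the joint-state distribution."""
        out: dict[JointState, float] = {}
        for state, w in chain.probabilities:
            if w == 0.0:
                continue
            for donor_key, pd in self.donor_groups.items():
                outcomes, loss = self.cascade(state, donor_key)
                stay = w * pd * loss
                if stay:
                    out[state] = out.get(state, 0.0) + stay
                for _, p, successor in outcomes:
                    out[successor] = out.get(successor, 0.0) + w * pd * p
        return ChainDistribution(t=chain.t + 1, probabilities=tuple(out.items()))

    def result_at(self, chain: ChainDistribution) -> NthOrganResult:
        """Per-center probabilities for the organ index the chain sits at."""
        cfg = self.config
        probs = {c.id: 0.0 for c in cfg.centers}
        loss = 0.0
        strip_len = {
            c.id: len(cfg.macroarea(self.center_ma[c.id]).strip) for c in cfg.centers
        }
        T = {c.id: np.zeros(strip_len[c.id]) for c in cfg.centers}
        joint = {c.id: np.zeros(strip_len[c.id]) for c in cfg.centers}
        for state, w in chain.probabilities:
            if w == 0.0:
                continue
            pos = {
                c.id: state.strip(self.center_ma[c.id]).first_index(c.id)
                for c in cfg.centers
            }
            for cid, j in pos.items():
                T[cid][j] += w
            for donor_key, pd in self.donor_groups.items():
                outcomes, l = self.cascade(state, donor_key)
                loss += w * pd * l
                for center_id, p, _ in outcomes:
                    probs[center_id] += w * pd * p
                    joint[center_id][pos[center_id]] += w * pd * p
        cond = {}
        for cid in probs:
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(T[cid] > 0, joint[cid] / np.where(T[cid] > 0, T[cid], 1.0), 0.0)
            cond[cid] = c
        return NthOrganResult(
            t=chain.t,
            probabilities=probs,
            loss_probability=loss,
            position_distribution=T,
            position_conditional=cond,
        )


def evolve(config: NationConfig, chain: ChainDistribution) -> ChainDistribution:
    """Functional wrapper around :meth:`ChainEvolver.evolve`."""
    return ChainEvolver(config).evolve(chain)


def nth_probability(config: NationConfig, M: int) -> list[NthOrganResult]:
    """Exact :class:`NthOrganResult` for every organ ``t = 1..M``."""
    if M < 1:
        raise ConfigValidationError("M must be >= 1")
    ev = ChainEvolver(config)
    chain = ev.initial_chain()
    results = []
    for _ in range(M):
        results.append(ev.result_at(chain))
        chain = ev.evolve(chain)
    return results


def position_conditional_probability(
    config: NationConfig,
    state: JointState,
    center: str,
    position: int,
    donor_region: str,
    variant: str = "conditional",
) -> float:
    """Probability the center accepts the organ from strip position ``position``.

    ``position`` is 1-based.  The default ``'conditional'`` variant conditions
    exactly on the donor region: own acceptance rate, zeroed if the donor
    belongs to the center, times the product of refusal probabilities of every
    center queried before it in the full cascade order.  The
    ``'strip_marginal'`` variant is the literal within-strip formula that
    multiplies instead by the probability that the organ is *not produced* in
    the center's own regions and walks only the center's own strip; it is kept
    for comparison and does not satisfy per-organ conservation.
    """
    ma = config.macroarea_of_center(center)
    strip = state.strip(ma.id)
    if center not in strip.arrangement:
        raise ValueError(f"center {center!r} absent from strip of {ma.id!r}")
    if strip.first_index(center) != position - 1:
        raise ValueError(
            f"center {center!r} is not at position {position} (1-based) "
            f"of arrangement {strip.arrangement}"
        )
    own = config.acceptance_rate(center)
    if variant == "strip_marginal":
        dist = donor_distribution(config)
        own_mass = sum(dist[r] for r in config.center(center).member_regions)
        prod = 1.0
        for other in strip.order():
            if other == center:
                break
            prod *= 1.0 - config.acceptance_rate(other)
        return own * (1.0 - own_mass) * prod
    if variant != "conditional":
        raise ValueError(f"unknown variant {variant!r}")
    if donor_region in config.center(center).member_regions:
        return 0.0
    prod = 1.0
    for other in offer_order(state, config, donor_region):
        if other == center:
            return own * prod
        prod *= 1.0 - config.acceptance_rate(other)
    raise ValueError(
        f"center {center!r} is never queried for donor {donor_region!r}"
    )


def overall_use_probability(
    config: NationConfig, state: JointState | None = None
) -> float:
    """Probability that a surplus organ is used (accepted by some center).

    Computed by direct decomposition over donor regions: the production weight
    of each region times one minus the product of refusal probabilities over
    the centers eligible for its organs (its macroarea's centers except its
    own, then the other macroarea's centers).  Under the default full-cascade
    fallback the eligible *set* does not depend on the strip arrangement, so
    the result is the same for every organ index; under ``head_only`` fallback
    it depends on the arrangement, taken from ``state`` (default: the
    configured starting arrangement).
    """
    if state is None:
        state = initial_state(config)
    dist = donor_distribution(config)
    total = 0.0
    for ma in config.macroareas:
        away = config.other_macroarea(ma.id)
        away_order = state.strip(away.id).order()
        if config.fallback_mode == "head_only":
            away_order = away_order[:1]
        for region in ma.regions:
            if dist[region.name] == 0.0:
                continue
            eligible = [
                c for c in state.strip(ma.id).order() if c != region.center
            ] + list(away_order)
            miss = 1.0
            for c in eligible:
                miss *= 1.0 - config.acceptance_rate(c)
            total += dist[region.name] * (1.0 - miss)
    return total
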