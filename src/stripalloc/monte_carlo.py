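"""Stochastic season simulator and empirical estimator.

A *season* is a run of ``M`` surplus organs: for each organ a donor region is
drawn from the production-weighted donor distribution, every queried center
accepts independently with its acceptance rate, and the strip state carries
over to the next organ.  Seasons are independent (strips reset to the
configured starting arrangement).

``estimate`` aggregates many seasons into per-organ acceptance frequencies,
at-least-k frequencies and strip-state occupancies with binomial standard
errors, and serves both as the estimation engine for configurations whose
exact chain is too large and as an independent stochastic oracle for the
analytic modules.

Reproducibility: replicate ``i`` of ``estimate(config, M, n_reps, seed)``
consumes exactly the random stream of
``simulate_season(config, M, numpy.random.SeedSequence(seed, spawn_key=(i,)))``,
so any single season of an estimation run can be replayed in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NationConfig, donor_distribution
from .protocol import (
    LOST,
    JointState,
    OfferOutcome,
    allocate_one,
    initial_state,
    offer_order,
)

__all__ = ["SeasonTrace", "EmpiricalEstimates", "simulate_season", "estimate"]


@dataclass(frozen=True)
class SeasonTrace:
    """Full record of one simulated season of ``M`` organs."""

    organs: tuple[tuple[str, OfferOutcome], ...]  # (donor region, outcome)
    final_state: JointState


@dataclass(frozen=True)
class EmpiricalEstimates:
    """Aggregated frequencies over ``n_reps`` independent seasons.

    Counts are integers so conservation holds exactly:
    ``loss_counts[t] + sum_c organ_counts[c][t] == n_reps`` for every organ
    index.  Standard errors use the binomial formula
    ``sqrt(f (1 - f) / n_reps)``.
    """

    n_reps: int
    organ_counts: dict[str, np.ndarray]  # center -> counts per organ index
    loss_counts: np.ndarray
    at_least_counts: dict[str, np.ndarray]  # center -> counts per k in 0..M
    occupancy_counts: dict[JointState, np.ndarray]  # state -> counts per organ

    def organ_frequency(self, center: str) -> np.ndarray:
        return self.organ_counts[center] / self.n_reps

    @property
    def loss_frequency(self) -> np.ndarray:
        return self.loss_counts / self.n_reps

    def at_least_frequency(self, center: str) -> np.ndarray:
        return self.at_least_counts[center] / self.n_reps

    def occupancy_frequency(self, state: JointState) -> np.ndarray:
        return self.occupancy_counts[state] / self.n_reps

    def standard_error(self, frequency: np.ndarray) -> np.ndarray:
        f = np.asarray(frequency, dtype=float)
        return np.sqrt(f * (1.0 - f) / self.n_reps)


def _donor_sampler(config: NationConfig):
    """Region names and cumulative donor probabilities for inverse sampling."""
    dist = donor_distribution(config)
    names = [r.name for r in config.regions]
    cum = np.cumsum([dist[n] for n in names])
    cum[-1] = 1.0  # guard against rounding
    return names, cum


def simulate_season(config: NationConfig, M: int, seed) -> SeasonTrace:
    """Simulate one season of ``M`` organs; reproducible from the seed.

    Random stream per organ: one uniform for the donor region, then one
    uniform per queried center (in cascade order, stopping at the first
    acceptance).
    """
    rng = np.random.default_rng(seed)
    names, cum = _donor_sampler(config)
    rates = {c.id: c.acceptance_rate for c in config.centers}
    state = initial_state(config)
    organs = []
    for _ in range(M):
        donor = names[int(np.searchsorted(cum, rng.random(), side="right"))]
        decisions: dict[str, bool] = {}
        for center_id in offer_order(state, config, donor):
            accept = rng.random() < rates[center_id]
            decisions[center_id] = accept
            if accept:
                break
        outcome = allocate_one(state, config, donor, decisions)
        organs.append((donor, outcome))
        state = outcome.updated_state
    return SeasonTrace(organs=tuple(organs), final_state=state)


def estimate(
    config: NationConfig, M: int, n_reps: int, seed
) -> EmpiricalEstimates:
    """Aggregate ``n_reps`` independent seasons (streaming; no trace kept).

    Uses an interned integer coding of joint strip states with memoized offer
    orders and rotation successors, so large replication counts stay cheap;
    the sampled decisions are the same independent Bernoulli draws as in
    :func:`simulate_season`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names, cum = _donor_sampler(config)
    center_ids = [c.id for c in config.centers]
    center_index = {cid: i for i, cid in enumerate(center_ids)}
    rate_of = np.array([c.acceptance_rate for c in config.centers])

    # donor region index -> (macroarea, own center) group index
    donor_keys: list[tuple[str, str | None]] = []
    donor_key_index: dict[tuple[str, str | None], int] = {}
    region_group = []
    for r in config.regions:
        key = (r.macroarea, r.center)
        if key not in donor_key_index:
            donor_key_index[key] = len(donor_keys)
            donor_keys.append(key)
        region_group.append(donor_key_index[key])
    n_groups = len(donor_keys)

    states: list[JointState] = [initial_state(config)]
    state_index: dict[JointState, int] = {states[0]: 0}
    # (state idx * n_groups + group idx) -> (center idx array, rates array,
    #                                        successor state idx list)
    memo: dict[int, tuple[list[int], list[float], list[int]]] = {}

    def transitions(s_idx: int, g_idx: int):
        key = s_idx * n_groups + g_idx
        hit = memo.get(key)
        if hit is not None:
            return hit
        state = states[s_idx]
        ma_id, donor_center = donor_keys[g_idx]
        # pick any region of this donor group for offer_order
        donor_region = next(
            r.name
            for r in config.regions
            if r.macroarea == ma_id and r.center == donor_center
        )
        order = offer_order(state, config, donor_region)
        succ = []
        for i, cid in enumerate(order):
            decisions = {c: False for c in order[:i]}
            decisions[cid] = True
            out = allocate_one(state, config, donor_region, decisions)
            ns = out.updated_state
            if ns not in state_index:
                state_index[ns] = len(states)
                states.append(ns)
            succ.append(state_index[ns])
        entry = (
            [center_index[c] for c in order],
            [float(rate_of[center_index[c]]) for c in order],
            succ,
        )
        memo[key] = entry
        return entry

    n_centers = len(center_ids)
    organ_counts = np.zeros((n_centers, M), dtype=np.int64)
    loss_counts = np.zeros(M, dtype=np.int64)
    exact_k_counts = np.zeros((n_centers, M + 1), dtype=np.int64)
    occupancy: dict[int, np.ndarray] = {}

    season_counts = np.zeros(n_centers, dtype=np.int64)
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        s_idx = 0
        season_counts[:] = 0
        for t in range(M):
            occ = occupancy.get(s_idx)
            if occ is None:
                occ = occupancy.setdefault(s_idx, np.zeros(M, dtype=np.int64))
            occ[t] += 1
            g_idx = region_group[int(np.searchsorted(cum, rng.random(), side="right"))]
            order_idx, order_rates, succ = transitions(s_idx, g_idx)
            accepted = -1
            for i in range(len(order_idx)):
                if rng.random() < order_rates[i]:
                    accepted = i
                    break
            if accepted < 0:
                loss_counts[t] += 1
            else:
                ci = order_idx[accepted]
                organ_counts[ci, t] += 1
                season_counts[ci] += 1
                s_idx = succ[accepted]
        for ci in range(n_centers):
            exact_k_counts[ci, season_counts[ci]] += 1

    at_least = {
        cid: np.cumsum(exact_k_counts[ci, ::-1])[::-1].copy()
        for cid, ci in center_index.items()
    }
    for arr in at_least.values():
        arr[0] = n_reps
    return EmpiricalEstimates(
        n_reps=n_reps,
        organ_counts={cid: organ_counts[ci].copy() for cid, ci in center_index.items()},
        loss_counts=loss_counts,
        at_least_counts=at_least,
        occupancy_counts={states[si]: cnt for si, cnt in occupancy.items()},
    )
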