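"""Second probability model: obtaining at least k of the M surplus organs.

Three engines compute ``P(center obtains >= k of M organs)``:

``exact``
    Dynamic programming over (joint strip state, organs obtained so far),
    evolved one organ at a time.  Exact up to floating point; the default.

``independent``
    Treats the per-organ acceptance indicators as independent with marginals
    ``p_t = P_c^t`` — the Poisson-binomial upper tail, computed by a
    convolution DP rather than summing over all 2^M sequences.

``bahadur``
    Second-order Bahadur expansion around the independence product: the joint
    density of the indicators is the independence product times
    ``1 + sum_{s<t} r_st z_s z_t`` where ``z_t`` is the standardized
    indicator and ``r_st`` its pairwise correlation.  The corrected mass is
    accumulated on the count statistic (via exact Poisson-binomial DPs of the
    remaining indicators); truncation can drive some count masses negative,
    which are clipped to zero and the distribution renormalized, with the
    clipped mass reported.

The acceptance indicators of a rotating strip are genuinely correlated (a
center that just obtained an organ moves to the back of its strip), which is
why the independence engine is only an approximation and the exact engine is
the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .config import ConfigValidationError, NationConfig
from .nth_organ import ChainEvolver, StateSpaceOverflowError
from .protocol import JointState

__all__ = [
    "AcceptanceSequenceLaw",
    "CumulativeResult",
    "at_least_exact",
    "at_least_independent",
    "at_least_bahadur",
    "law_from_chain",
    "law_from_simulation",
    "cumulative_result",
]


@dataclass(frozen=True)
class AcceptanceSequenceLaw:
    """Marginals and pairwise correlations of the per-organ acceptance
    indicators of one target center.

    ``marginals[t-1]`` is ``p_t = P_c^t``; ``correlations[s-1, t-1]`` the
    Pearson correlation of the acceptance indicators at organs ``s`` and
    ``t`` (unit diagonal, zero by convention when either indicator is
    degenerate).
    """

    marginals: np.ndarray
    correlations: np.ndarray
    #: binomial standard errors of the marginals when the law was estimated
    #: by simulation; None for exact chain computations
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.marginals, dtype=float)
        r = np.asarray(self.correlations, dtype=float)
        object.__setattr__(self, "marginals", p)
        object.__setattr__(self, "correlations", r)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("marginals must lie in [0, 1]")
        if r.shape != (p.size, p.size):
            raise ValueError("correlation matrix shape must match marginals")
        if not np.allclose(r, r.T, atol=0.0, rtol=0.0):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(r) > 1) or not np.all(np.diag(r) == 1.0):
            raise ValueError("correlations must lie in [-1, 1] with unit diagonal")

    @property
    def n_organs(self) -> int:
        return int(self.marginals.size)

    @classmethod
    def independent(cls, marginals) -> "AcceptanceSequenceLaw":
        p = np.asarray(marginals, dtype=float)
        return cls(marginals=p, correlations=np.eye(p.size))


@dataclass(frozen=True)
class CumulativeResult:
    """``P(at least k)`` for ``k = 0..M`` for one center, plus method tag."""

    center: str | None
    method: str  # exact | bahadur | independent | montecarlo
    at_least: np.ndarray  # index k in 0..M
    clipped_mass: float = 0.0

    def probability(self, k: int) -> float:
        """``P(at least k)``; 1 for k <= 0 and 0 beyond M by contract."""
        if k <= 0:
            return 1.0
        if k >= self.at_least.size:
            return 0.0
        return float(self.at_least[k])

    @property
    def n_organs(self) -> int:
        return int(self.at_least.size - 1)


# ---------------------------------------------------------------------------
# exact engine

def at_least_exact(config: NationConfig, center: str, M: int) -> CumulativeResult:
    """Exact at-least-k probabilities by DP on (joint state, count so far)."""
    if M < 1:
        raise ConfigValidationError("M must be >= 1")
    config.center(center)  # KeyError for unknown centers
    ev = ChainEvolver(config)
    chain = ev.initial_chain()
    # dist: (state, count) -> probability
    dist: dict[tuple[JointState, int], float] = {
        (s, 0): w for s, w in chain.probabilities
    }
    for _ in range(M):
        nxt: dict[tuple[JointState, int], float] = {}
        for (state, count), w in dist.items():
            if w == 0.0:
                continue
            for donor_key, pd in ev.donor_groups.items():
                outcomes, loss = ev.cascade(state, donor_key)
                stay = w * pd * loss
                if stay:
                    key = (state, count)
                    nxt[key] = nxt.get(key, 0.0) + stay
                for cid, p, successor in outcomes:
                    key = (successor, count + 1 if cid == center else count)
                    nxt[key] = nxt.get(key, 0.0) + w * pd * p
        dist = nxt
    pmf = np.zeros(M + 1)
    for (_, count), w in dist.items():
        pmf[count] += w
    return CumulativeResult(
        center=center, method="exact", at_least=_tail(pmf)
    )


# ---------------------------------------------------------------------------
# independence / Bahadur engines

def _count_pmf(p: np.ndarray) -> np.ndarray:
    """Poisson-binomial pmf of sum of independent Bernoulli(p_t)."""
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # in-place reverse update: pmf[j] = pmf[j]*(1-pi) + pmf[j-1]*pi
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[0 : i + 1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def _tail(pmf: np.ndarray) -> np.ndarray:
    """at_least[k] = sum_{m >= k} pmf[m], with at_least[0] pinned to 1."""
    tail = np.cumsum(pmf[::-1])[::-1].copy()
    tail[0] = 1.0
    return tail


def _bahadur_pmf(law: AcceptanceSequenceLaw) -> tuple[np.ndarray, float]:
    """Second-order-corrected count pmf and total clipped mass.

    The correction to the count pmf is
    ``sum_{s<t} r_st E[1{count = m} z_s z_t]`` under independence, computed
    exactly by conditioning on (x_s, x_t) and convolving the remaining
    indicators.  Renormalization happens only if clipping removed mass, so a
    zero-correlation law reproduces the independence pmf bitwise.
    """
    p = law.marginals
    M = p.size
    base = _count_pmf(p)
    corr = np.zeros(M + 1)
    sd = np.sqrt(p * (1.0 - p))
    for s in range(M):
        for t in range(s + 1, M):
            r = law.correlations[s, t]
            if r == 0.0 or sd[s] == 0.0 or sd[t] == 0.0:
                continue
            rest = _count_pmf(np.delete(p, [s, t]))
            # E[z 1{x=a}] = +sd for a=1, -sd for a=0, for each of s and t
            for a in (0, 1):
                for b in (0, 1):
                    w = (sd[s] if a else -sd[s]) * (sd[t] if b else -sd[t])
                    corr[a + b : a + b + rest.size] += r * w * rest
    pmf = base + corr
    clipped = float(-pmf[pmf < 0].sum())
    if clipped > 0.0:
        pmf = np.clip(pmf, 0.0, None)
        pmf = pmf / pmf.sum()
    return pmf, clipped


def at_least_independent(law: AcceptanceSequenceLaw, k: int) -> float:
    """Poisson-binomial upper tail of independent indicators."""
    M = law.n_organs
    if k <= 0:
        return 1.0
    if k > M:
        return 0.0
    return float(_tail(_count_pmf(law.marginals))[k])


def at_least_bahadur(law: AcceptanceSequenceLaw, k: int) -> float:
    """Second-order Bahadur-corrected upper tail."""
    M = law.n_organs
    if k <= 0:
        return 1.0
    if k > M:
        return 0.0
    pmf, _ = _bahadur_pmf(law)
    return float(_tail(pmf)[k])


def cumulative_result(
    law: AcceptanceSequenceLaw, method: str, center: str | None = None
) -> CumulativeResult:
    """All-k :class:`CumulativeResult` for the independence/Bahadur engines."""
    if method == "independent":
        pmf, clipped = _count_pmf(law.marginals), 0.0
    elif method == "bahadur":
        pmf, clipped = _bahadur_pmf(law)
    else:
        raise ValueError(f"unknown law-based engine {method!r}")
    return CumulativeResult(
        center=center, method=method, at_least=_tail(pmf), clipped_mass=clipped
    )


# ---------------------------------------------------------------------------
# law extraction from the exact chain (or, for huge chains, from simulation)

def law_from_simulation(
    config: NationConfig, center: str, M: int, n_reps: int = 20_000, seed=0
) -> AcceptanceSequenceLaw:
    """Estimate the acceptance-sequence law by season simulation.

    Used when the exact chain's state space is too large.  Marginals carry
    binomial standard errors in ``standard_errors``; sample correlations are
    clipped to [-1, 1] and set to 0 for degenerate indicators.
    """
    from .monte_carlo import simulate_season

    config.center(center)
    X = np.zeros((n_reps, M))
    for rep in range(n_reps):
        trace = simulate_season(
            config, M, np.random.SeedSequence(seed, spawn_key=(rep,))
        )
        X[rep] = [1.0 if out.accepted_by == center else 0.0 for _, out in trace.organs]
    p = X.mean(axis=0)
    var = p * (1.0 - p)
    joint = (X.T @ X) / n_reps
    corr = np.eye(M)
    for s in range(M):
        for t in range(s + 1, M):
            if var[s] > 0 and var[t] > 0:
                corr[s, t] = corr[t, s] = (joint[s, t] - p[s] * p[t]) / sqrt(
                    var[s] * var[t]
                )
    return AcceptanceSequenceLaw(
        marginals=p,
        correlations=np.clip(corr, -1.0, 1.0),
        standard_errors=np.sqrt(var / n_reps),
    )


def law_from_chain(
    config: NationConfig,
    center: str,
    M: int,
    state_cap: int | None = None,
    mc_reps: int = 20_000,
    seed=0,
) -> AcceptanceSequenceLaw:
    """Marginals and pairwise correlations of the center's acceptance
    indicators, computed exactly from the joint-state chain.

    Pairwise joints ``P(accept at s and at t)`` come from propagating the
    unnormalized accept-at-``s`` measure forward through the chain.  If the
    reachable state space exceeds the cap, the law is instead estimated by
    Monte Carlo (:func:`law_from_simulation`) with ``mc_reps`` seasons and
    reported standard errors.
    """
    if M < 1:
        raise ConfigValidationError("M must be >= 1")
    config.center(center)
    try:
        return _law_from_chain_exact(config, center, M, state_cap)
    except StateSpaceOverflowError:
        return law_from_simulation(config, center, M, n_reps=mc_reps, seed=seed)


def _law_from_chain_exact(
    config: NationConfig, center: str, M: int, state_cap: int | None
) -> AcceptanceSequenceLaw:
    from .nth_organ import DEFAULT_STATE_CAP

    ev = ChainEvolver(config, state_cap=state_cap or DEFAULT_STATE_CAP)

    def accept_prob(state: JointState) -> float:
        total = 0.0
        for donor_key, pd in ev.donor_groups.items():
            outcomes, _ = ev.cascade(state, donor_key)
            for cid, p, _succ in outcomes:
                if cid == center:
                    total += pd * p
        return total

    def step(measure: dict[JointState, float], accepted_only: bool):
        """One organ forward; optionally keep only accept-by-target mass."""
        out: dict[JointState, float] = {}
        for state, w in measure.items():
            if w == 0.0:
                continue
            for donor_key, pd in ev.donor_groups.items():
                outcomes, loss = ev.cascade(state, donor_key)
                if not accepted_only:
                    stay = w * pd * loss
                    if stay:
                        out[state] = out.get(state, 0.0) + stay
                for cid, p, successor in outcomes:
                    if accepted_only and cid != center:
                        continue
                    out[successor] = out.get(successor, 0.0) + w * pd * p
        return out

    # chain distributions at each organ index
    chains: list[dict[JointState, float]] = []
    cur = dict(ev.initial_chain().probabilities)
    for _ in range(M):
        chains.append(cur)
        cur = step(cur, accepted_only=False)

    # exact marginal p_t: accept probability averaged over the chain at t
    p = np.array(
        [sum(w * accept_prob(s) for s, w in chain.items()) for chain in chains]
    )

    joint = np.zeros((M, M))
    for s in range(M):
        mu = step(chains[s], accepted_only=True)  # mass P(state at s+1, X_s=1)
        for t in range(s + 1, M):
            joint[s, t] = sum(w * accept_prob(st) for st, w in mu.items())
            if t < M - 1:
                mu = step(mu, accepted_only=False)
        # joint is symmetric
    joint = joint + joint.T
    np.fill_diagonal(joint, p)

    corr = np.eye(M)
    var = p * (1.0 - p)
    for s in range(M):
        for t in range(s + 1, M):
            if var[s] > 0 and var[t] > 0:
                corr[s, t] = corr[t, s] = (joint[s, t] - p[s] * p[t]) / sqrt(
                    var[s] * var[t]
                )
            # degenerate indicators: correlation 0 by convention
    corr = np.clip(corr, -1.0, 1.0)
    return AcceptanceSequenceLaw(marginals=np.clip(p, 0.0, 1.0), correlations=corr)
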