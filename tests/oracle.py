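"""Independent brute-force oracle for the allocation models.

Re-implements the cascade and strip rotation with plain list manipulation,
then computes exact probabilities by enumerating, for every organ, every
donor region and every full accept/refuse decision vector over all centers.
Deliberately shares no code with the package engines.
"""

from __future__ import annotations

import itertools

import numpy as np


def _uniq(seq):
    out = []
    for x in seq:
        if x not in out:
            out.append(x)
    return out


def oracle_allocate(config, arrangements, donor_region, accept_set):
    """(acceptor or None, new arrangements dict) for one organ.

    ``arrangements`` maps macroarea id -> tuple arrangement; ``accept_set``
    is the set of centers that would accept if queried.
    """
    donor = config.region(donor_region)
    home = donor.macroarea
    away = [ma.id for ma in config.macroareas if ma.id != home][0]
    order = [(home, c) for c in _uniq(arrangements[home]) if c != donor.center]
    if config.fallback_mode == "head_only":
        order += [(away, c) for c in _uniq(arrangements[away])[:1]]
    else:
        order += [(away, c) for c in _uniq(arrangements[away])]
    refused: list[tuple[str, str]] = []
    for ma_id, c in order:
        if c in accept_set:
            arr = list(arrangements[ma_id])
            move_idx = sorted(
                {arr.index(x) for m, x in refused if m == ma_id} | {arr.index(c)}
            )
            kept = [x for i, x in enumerate(arr) if i not in move_idx]
            moved = [arr[i] for i in move_idx]
            new = dict(arrangements)
            new[ma_id] = tuple(kept + moved)
            return c, new
        refused.append((ma_id, c))
    return None, dict(arrangements)


def enumerate_exact(config, M, target):
    """Exact per-organ allocation probabilities and count distribution.

    Enumerates every (donor region, full decision vector) combination for
    every organ, propagating the joint law of (strip arrangements, number of
    organs obtained by ``target``).  Returns ``(per_organ, count_pmf)`` where
    ``per_organ[t]`` maps center id (or ``"LOST"``) to the probability of
    obtaining organ ``t+1``.
    """
    total = sum(r.production for r in config.regions)
    donors = [(r.name, r.production / total) for r in config.regions if r.production]
    centers = [c.id for c in config.centers]
    rates = [c.acceptance_rate for c in config.centers]

    decision_atoms = []  # (probability, accept set) for each decision vector
    for bits in itertools.product((0, 1), repeat=len(centers)):
        pb = 1.0
        for rate, b in zip(rates, bits):
            pb *= rate if b else 1.0 - rate
        if pb > 0.0:
            decision_atoms.append(
                (pb, frozenset(c for c, b in zip(centers, bits) if b))
            )

    init = tuple(sorted((ma.id, tuple(ma.strip)) for ma in config.macroareas))
    dist = {(init, 0): 1.0}
    alloc_memo = {}
    per_organ = []
    for _ in range(M):
        organ_probs: dict[str, float] = {}
        new: dict[tuple, float] = {}
        for (arrs_key, cnt), w in dist.items():
            for region, pr in donors:
                for pb, accepts in decision_atoms:
                    memo_key = (arrs_key, region, accepts)
                    hit = alloc_memo.get(memo_key)
                    if hit is None:
                        acceptor, new_arr = oracle_allocate(
                            config, dict(arrs_key), region, accepts
                        )
                        hit = (acceptor, tuple(sorted(new_arr.items())))
                        alloc_memo[memo_key] = hit
                    acceptor, new_key = hit
                    mass = w * pr * pb
                    label = acceptor if acceptor is not None else "LOST"
                    organ_probs[label] = organ_probs.get(label, 0.0) + mass
                    nc = cnt + (1 if acceptor == target else 0)
                    new[(new_key, nc)] = new.get((new_key, nc), 0.0) + mass
        per_organ.append(organ_probs)
        dist = new
    count_pmf = np.zeros(M + 1)
    for (_, cnt), w in dist.items():
        count_pmf[cnt] += w
    return per_organ, count_pmf
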