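"""Exact Markov-chain enumeration of the lattice binding walk on tiny lattices.

Independent oracle for the stochastic simulator: the three-phase update
rule (move, bind, release) is expanded into an exact joint transition
matrix for two ligates and one channel on a small lattice, and the
stationary distribution obtained by eigen-decomposition.  Everything here
works on explicit probability distributions — no sampling.
"""

from __future__ import annotations

import itertools

import numpy as np

BOUND = None  # sentinel index assigned in build


def site_index(x, y, z, n):
    return (x * n + y) * n + z


def build_transition(n, ch_xyz, p_bind, p_unbind, attraction):
    """Joint transition matrix for 2 ligates, 1 channel on an n^3 lattice.

    Ligate micro-state: 0..n^3-1 = free at that site, n^3 = bound (at the
    channel site).  Joint states exclude double binding.
    """
    nsites = n**3
    bound = nsites
    ch = site_index(*ch_xyz, n)
    coords = [(x, y, z) for x in range(n) for y in range(n) for z in range(n)]

    def move_row(s):
        """Distribution over destination sites for a free ligate at s.

        The attraction boost applies to the channel site whether or not
        the channel is occupied.
        """
        x, y, z = coords[s]
        targets, weights = [], []
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = (x + dx, y + dy, z + dz)
            if not all(0 <= c < n for c in q):
                continue
            t = site_index(*q, n)
            w = attraction if t == ch else 1.0
            targets.append(t)
            weights.append(w)
        w = np.array(weights) / np.sum(weights)
        return list(zip(targets, w))

    states = [
        (a, b)
        for a in range(nsites + 1)
        for b in range(nsites + 1)
        if not (a == bound and b == bound)
    ]
    index = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))

    for (a, b) in states:
        occ0 = a == bound or b == bound  # occupancy snapshot at step start
        # phase 1: independent moves of free ligates
        moves_a = [(a, 1.0)] if a == bound else move_row(a)
        moves_b = [(b, 1.0)] if b == bound else move_row(b)
        for (a1, pa), (b1, pb1) in itertools.product(moves_a, moves_b):
            p1 = pa * pb1
            # phase 2: binding in index order (ligate a first)
            outcomes = []  # (a2, b2, prob)
            if occ0:
                outcomes.append((a1, b1, 1.0))
            else:
                a_at = a1 == ch and a1 != bound
                b_at = b1 == ch and b1 != bound
                if a_at and b_at:
                    outcomes.append((bound, b1, p_bind))
                    outcomes.append((a1, bound, (1 - p_bind) * p_bind))
                    outcomes.append((a1, b1, (1 - p_bind) ** 2))
                elif a_at:
                    outcomes.append((bound, b1, p_bind))
                    outcomes.append((a1, b1, 1 - p_bind))
                elif b_at:
                    outcomes.append((a1, bound, p_bind))
                    outcomes.append((a1, b1, 1 - p_bind))
                else:
                    outcomes.append((a1, b1, 1.0))
            # phase 3: release of any bound ligate (including newly bound)
            for a2, b2, p2 in outcomes:
                if p2 == 0.0:
                    continue
                rel_a = [(a2, 1.0)] if a2 != bound else [(ch, p_unbind), (bound, 1 - p_unbind)]
                rel_b = [(b2, 1.0)] if b2 != bound else [(ch, p_unbind), (bound, 1 - p_unbind)]
                for (a3, pra), (b3, prb) in itertools.product(rel_a, rel_b):
                    p = p1 * p2 * pra * prb
                    if p > 0:
                        T[index[(a, b)], index[(a3, b3)]] += p

    assert np.allclose(T.sum(axis=1), 1.0)
    return T, states, index


def stationary_distribution(T):
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def expected_bound_count(n, ch_xyz, p_bind, p_unbind, attraction):
    """Stationary mean number of bound ligates (0, 1) for the 2-ligate chain."""
    T, states, _ = build_transition(n, ch_xyz, p_bind, p_unbind, attraction)
    pi = stationary_distribution(T)
    bound = n**3
    b = np.array([(a == bound) + (c == bound) for a, c in states], dtype=float)
    return float(pi @ b)
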