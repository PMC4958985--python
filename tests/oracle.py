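"""Naive reference implementations used as independent test oracles.

Everything here is deliberately written with plain python dicts, sets and
loops — no numpy, no networkx, no code shared with the package — so that
agreement with the package is meaningful.  Complexity is ignored; these
run only on tiny alignments.
"""

from __future__ import annotations

import random
from itertools import combinations

GAP = "-"


def occurrence_sets(seqs, sites, gap=GAP):
    """element -> set of record positions, elements as (site, residue)."""
    occ = {}
    for i, seq in enumerate(seqs):
        for site in sites:
            c = seq[site - 1]
            if c == gap:
                continue
            occ.setdefault((site, c), set()).add(i)
    return occ


def dice(sa, sb):
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_force_pairs(seqs, sites, threshold=0.7, min_count=1, gap=GAP):
    """Every qualifying element pair, scored exhaustively.

    Returns {((sa, ra), (sb, rb)): (n_a, n_b, n_ab)} with sa < sb.
    """
    occ = occurrence_sets(seqs, sites, gap)
    out = {}
    for a, b in combinations(sorted(occ), 2):
        if a[0] == b[0]:
            continue
        sa, sb = occ[a], occ[b]
        if len(sa) < min_count or len(sb) < min_count:
            continue
        if dice(sa, sb) >= threshold:
            out[(a, b)] = (len(sa), len(sb), len(sa & sb))
    return out


def brute_force_confirmed(pairs):
    """Keep pairs at site pairs connected by >= 2 qualifying pairs."""
    tally = {}
    for (a, b) in pairs:
        key = (a[0], b[0])
        tally[key] = tally.get(key, 0) + 1
    return {k: v for k, v in pairs.items() if tally[(k[0][0], k[1][0])] >= 2}


def _components(nodes, edges):
    """Flood-fill connected components; returns sorted lists."""
    nodes = set(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        if a in nodes and b in nodes:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for n in sorted(nodes):
        if n in seen:
            continue
        comp, stack = set(), [n]
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        comps.append(sorted(comp))
    return comps


def _prune_once(elements, occ, threshold, min_size):
    """Simulate the degree-pruning dynamics on one element set."""
    current = sorted(elements)
    while True:
        if len(current) < min_size:
            return None
        degrees = {}
        for e in current:
            vals = []
            for f in current:
                if f == e:
                    continue
                vals.append(0.0 if f[0] == e[0] else dice(occ[e], occ[f]))
            degrees[e] = sum(vals) / (len(current) - 1)
        d_m = min(degrees.values())
        if d_m < threshold:
            tied = [e for e in current if degrees[e] == d_m]
            # same tie-break as documented: largest site, then largest residue
            victim = max(tied)
            current.remove(victim)
            continue
        dup_sites = {}
        for e in current:
            dup_sites.setdefault(e[0], []).append(e)
        dup = None
        for site in sorted(dup_sites):
            if len(dup_sites[site]) > 1:
                worst = min(degrees[e] for e in dup_sites[site])
                dup = max(e for e in dup_sites[site] if degrees[e] == worst)
                break
        if dup is not None:
            current.remove(dup)
            continue
        return current


def brute_force_patterns(seqs, sites, purity_threshold=0.7, degree_threshold=0.7,
                         min_count=1, min_size=3, gap=GAP):
    """Full tandem-model reference: returns a set of frozensets of elements."""
    occ = occurrence_sets(seqs, sites, gap)
    pairs = brute_force_confirmed(brute_force_pairs(seqs, sites, purity_threshold, min_count, gap))
    edges = list(pairs)
    nodes = {e for pair in edges for e in pair}

    def harvest(elements):
        if len(elements) < min_size:
            return []
        surv = _prune_once(elements, occ, degree_threshold, min_size)
        if surv is None:
            return []
        comps = _components(surv, edges)
        if len(comps) == 1:
            return [frozenset(surv)]
        out = []
        for comp in comps:
            out.extend(harvest(comp))
        return out

    patterns = []
    for comp in _components(nodes, edges):
        patterns.extend(harvest(comp))
    # drop duplicates and proper subsets
    unique = set(patterns)
    return {p for p in unique if not any(p < q for q in unique)}


def random_alignment(rng: random.Random, max_sites=10, max_seqs=30, alphabet="ACGT"):
    """Small random alignment with occasional planted column couplings."""
    L = rng.randint(2, max_sites)
    n = rng.randint(4, max_seqs)
    cols = []
    for _ in range(L):
        k = rng.randint(1, min(3, len(alphabet)))
        letters = rng.sample(alphabet, k)
        cols.append([rng.choice(letters) for _ in range(n)])
    # couple a few column pairs to create genuine covariance
    for _ in range(rng.randint(0, L // 2)):
        a, b = rng.randrange(L), rng.randrange(L)
        if a == b:
            continue
        mapping = {}
        for i in range(n):
            src = cols[a][i]
            if src not in mapping:
                mapping[src] = rng.choice(alphabet)
            if rng.random() < 0.9:
                cols[b][i] = mapping[src]
    # sprinkle gaps
    for j in range(L):
        for i in range(n):
            if rng.random() < 0.05:
                cols[j][i] = GAP
    seqs = ["".join(cols[j][i] for j in range(L)) for i in range(n)]
    return seqs
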