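"""Statistical-parsimony haplotype network construction.

Unique mitotypes are connected one mutational step at a time, TCS-style:
pairs of haplotypes are joined in order of increasing distance, inserting
unsampled median (inferred) nodes along multi-step connections, and a
connection limit caps how many steps apart two haplotypes may be before
homoplasy makes the parsimonious interpretation untrustworthy.  The limit
is the largest number of observed differences j for which the probability
that they arose by exactly j mutations (no superimposed hits) still
reaches the requested confidence — 0.95 in the classic "95% connection
limit".

Alignment gaps are handled by simple indel coding: each distinct
contiguous gap run (unique start and end) becomes one presence/absence
character, so a shared deletion counts as a single step regardless of its
length, and a haplotype whose own gap strictly contains another's run is
scored missing for that character.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import poisson

from .repeat_typing import HaplotypeSet

__all__ = [
    "IndelCharacterMatrix",
    "code_indels",
    "pairwise_steps",
    "parsimony_probability",
    "connection_limit",
    "build_network",
]

_STANDARD = set("ACGT")


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters per haplotype (1/0/None = carrier/absent/missing)."""

    characters: list  # [(start, end), ...] aligned coordinates
    states: dict      # hap_id -> tuple of 1/0/None per character


def code_indels(haplotypes: dict) -> IndelCharacterMatrix:
    """Simple indel coding of an aligned haplotype dict (id -> sequence).

    Each distinct gap run is one binary character.  A haplotype bearing
    exactly that run scores 1; one with no gap overlapping it scores 0;
    one whose gap strictly contains the run is missing.  Characters
    without both a 1-carrier and a 0-carrier are dropped as uninformative.
    """
    lengths = {len(s) for s in haplotypes.values()}
    if len(lengths) > 1:
        raise ValueError("indel coding requires equal-length aligned sequences")
    runs_by_hap = {h: _gap_runs(s) for h, s in haplotypes.items()}
    all_runs = sorted({r for runs in runs_by_hap.values() for r in runs})

    characters, states = [], {h: [] for h in haplotypes}
    for run in all_runs:
        s, e = run
        col = {}
        for h, runs in runs_by_hap.items():
            if run in runs:
                col[h] = 1
            elif any(not (re_ <= s or e <= rs) for rs, re_ in runs):
                # own gap strictly contains (or partially overlaps) the run
                col[h] = None
            else:
                col[h] = 0
        vals = set(col.values())
        if 1 in vals and 0 in vals:
            characters.append(run)
            for h in haplotypes:
                states[h].append(col[h])
        # else: uninformative, dropped
    return IndelCharacterMatrix(
        characters=characters,
        states={h: tuple(v) for h, v in states.items()},
    )


def pairwise_steps(
    seq1: str,
    seq2: str,
    states1: tuple = (),
    states2: tuple = (),
) -> int:
    """Mutational steps between two aligned haplotypes.

    Substitutions are counted at columns where neither sequence is gapped;
    ambiguous (non-ACGT) bases never count as a difference.  Indel
    characters contribute one step per determinate state difference
    (missing states are skipped).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must come from the same alignment")
    subs = sum(
        1
        for a, b in zip(seq1.upper(), seq2.upper())
        if a != "-" and b != "-" and a != b and a in _STANDARD and b in _STANDARD
    )
    indels = sum(
        1
        for x, y in zip(states1, states2)
        if x is not None and y is not None and x != y
    )
    return subs + indels


def _log_stirling2_column(j: int, m_max: int) -> np.ndarray:
    """log S2(M, j) for M = 0..m_max via the standard recurrence, in log space."""
    neg = -np.inf
    prev = np.full(m_max + 1, neg)
    prev[0] = 0.0  # S2(0,0) = 1
    for q in range(1, j + 1):
        cur = np.full(m_max + 1, neg)
        for M in range(q, m_max + 1):
            a = math.log(q) + cur[M - 1] if cur[M - 1] > neg else neg
            cur[M] = np.logaddexp(a, prev[M - 1])
        prev = cur
    return prev


def parsimony_probability(j: int, aligned_length: int) -> float:
    """P(exactly j mutations | j observed differing sites).

    Mutations are modelled as a Poisson number of hits spread uniformly
    over ``aligned_length`` sites, with the Poisson mean moment-matched so
    the expected number of hit sites equals j.  The returned probability
    is that none of the j observed differences hides a superimposed hit.
    """
    m = aligned_length
    if j <= 0:
        return 1.0
    if j >= m:
        return 0.0
    lam = -m * math.log1p(-j / m)
    m_max = j + max(80, int(lam + 10 * math.sqrt(lam)))
    log_s2 = _log_stirling2_column(j, m_max)
    log_fact_j = math.lgamma(j + 1)
    log_m = math.log(m)
    ms = np.arange(j, m_max + 1)
    log_w = poisson.logpmf(ms, lam) + log_fact_j + log_s2[j:] - ms * log_m
    log_w -= log_w.max()
    w = np.exp(log_w)
    return float(w[0] / w.sum())


def connection_limit(aligned_length: int, conf: float = 0.95) -> int:
    """Largest j with parsimony probability >= conf (the connection limit)."""
    if aligned_length < 1:
        raise ValueError("aligned_length must be >= 1")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    j = 0
    while j + 1 < aligned_length and parsimony_probability(j + 1, aligned_length) >= conf:
        j += 1
    return j


def build_network(
    hset: HaplotypeSet,
    limit: int,
    indels: IndelCharacterMatrix | None = None,
) -> nx.Graph:
    """Agglomerative TCS-style network over a haplotype set.

    Haplotype pairs are visited in ascending distance (ties broken by
    lexicographic id pair) and connected only if no path of at most that
    many steps already joins them; a d-step connection inserts d-1 median
    nodes.  Pairs further apart than ``limit`` are never joined, so the
    result may have several components.  Node attributes: ``count``
    (observed individuals; 0 for medians), ``inferred`` flag, ``sequence``
    for observed haplotypes.
    """
    if indels is None:
        indels = code_indels({h.hap_id: h.sequence for h in hset})
    g = nx.Graph()
    for h in hset:
        g.add_node(h.hap_id, count=h.count, inferred=False, sequence=h.sequence)

    pairs = []
    for h1, h2 in itertools.combinations(sorted(hset, key=lambda h: h.hap_id), 2):
        d = pairwise_steps(
            h1.sequence,
            h2.sequence,
            indels.states.get(h1.hap_id, ()),
            indels.states.get(h2.hap_id, ()),
        )
        pairs.append((d, h1.hap_id, h2.hap_id))
    pairs.sort()

    median_counter = itertools.count(1)
    for d, a, b in pairs:
        if d > limit:
            continue
        if d == 0:
            continue  # identical haplotypes should have been collapsed
        if nx.has_path(g, a, b) and nx.shortest_path_length(g, a, b) <= d:
            continue
        chain = [a]
        for _ in range(d - 1):
            mid = f"med{next(median_counter)}"
            g.add_node(mid, count=0, inferred=True)
            chain.append(mid)
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v)
    return g
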