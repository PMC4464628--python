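"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as naively as possible and shares no
code path with the package implementation.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb

import numpy as np
from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# interval clustering: pairwise union-find


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def union_find_clusters(intervals, min_overlap: int = 1):
    """Connected components over intervals (key, start, end) where two
    intervals link iff same key and overlap >= min_overlap.  Returns a set of
    frozensets of indices."""
    n = len(intervals)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            ki, si, ei = intervals[i]
            kj, sj, ej = intervals[j]
            if ki == kj and min(ei, ej) - max(si, sj) >= min_overlap:
                uf.union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# N50 via the direct definition


def n50_oracle(lengths) -> int:
    """Largest member length L with sum(x for x >= L) >= total / 2."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = L
            break
    return best


# ---------------------------------------------------------------------------
# interval union length by per-base marking


def covered_length_oracle(intervals) -> int:
    marked = set()
    for start, end in intervals:
        marked.update(range(start, end))
    return len(marked)


# ---------------------------------------------------------------------------
# six-frame ORF enumeration on Biopython-translated peptides

_FRAMES = (1, 2, 3, -1, -2, -3)


def best_orf_oracle(seq: str, min_aa: int):
    """Enumerate every (frame, start, stop) candidate run and pick the best.

    Returns (aa, frame, fwd_start, fwd_end, has_start, has_stop) or None,
    plus a flag telling whether the optimal aa value is unique.
    """
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    candidates = []
    for rank, frame in enumerate(_FRAMES):
        working = seq if frame > 0 else rc
        offset = abs(frame) - 1
        usable = working[offset : offset + 3 * ((n - offset) // 3)]
        peptide = str(Seq(usable).translate())
        # segment boundaries at stops; for every candidate start (edge of the
        # first segment, or any first-M per segment) run to the next stop
        stops = [i for i, aa in enumerate(peptide) if aa == "*"]
        bounds = [-1] + stops + [len(peptide)]
        for b_idx in range(len(bounds) - 1):
            seg_start = bounds[b_idx] + 1
            seg_end = bounds[b_idx + 1]  # exclusive: position of stop or len
            has_stop = seg_end < len(peptide)
            starts = []
            if b_idx == 0 and seg_start < seg_end:
                starts.append((seg_start, peptide[seg_start] == "M"))
            for i in range(seg_start, seg_end):
                if peptide[i] == "M":
                    if not (b_idx == 0 and i == seg_start):
                        starts.append((i, True))
                    break
            for aa_start, has_start in starts:
                aa = seg_end - aa_start
                if aa < min_aa or aa == 0:
                    continue
                local_start = offset + 3 * aa_start
                local_end = offset + 3 * seg_end + (3 if has_stop else 0)
                if frame > 0:
                    fwd = (local_start, local_end)
                else:
                    fwd = (n - local_end, n - local_start)
                candidates.append((-aa, rank, local_start, frame, fwd, has_start, has_stop))
    if not candidates:
        return None, True
    candidates.sort()
    neg_aa, rank, local_start, frame, fwd, has_start, has_stop = candidates[0]
    unique = sum(1 for c in candidates if c[0] == neg_aa) == 1
    return (-neg_aa, frame, fwd[0], fwd[1], has_start, has_stop), unique


# ---------------------------------------------------------------------------
# Benjamini-Hochberg literal step-up


def bh_oracle(p_values):
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for pos, i in enumerate(order, start=1):
        adjusted[i] = min(
            min(m * p[order[k - 1]] / k for k in range(pos, m + 1)), 1.0
        )
    return adjusted


# ---------------------------------------------------------------------------
# conditional binomial tail enumeration (dispersion 0, single replicates)


def conditional_binomial_p(y_a: int, y_b: int) -> float:
    """Exact two-sided minimum-likelihood p for a 1-vs-1 Poisson split."""
    s = y_a + y_b
    pmf = [Fraction(comb(s, k), 2**s) for k in range(s + 1)]
    obs = pmf[y_a]
    return float(sum(q for q in pmf if q <= obs))


# ---------------------------------------------------------------------------
# PROSITE -> regex translation


def prosite_regex_oracle(pattern_text: str):
    """Compile a PROSITE pattern to a lazy-quantifier regex and return a
    scanner yielding (start, end) shortest matches per start position."""
    text = pattern_text.strip().rstrip(".")
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    parts = []
    for token in text.split("-"):
        m = re.fullmatch(r"(?P<body>x|\[[A-Z]+\]|\{[A-Z]+\}|[A-Z])(\((?P<n>\d+)(,(?P<m>\d+))?\))?", token)
        assert m, token
        body = m.group("body")
        if body == "x":
            rx = f"[{AA20}X]"
        elif body.startswith("["):
            rx = f"[{body[1:-1]}]"
        elif body.startswith("{"):
            allowed = "".join(c for c in AA20 if c not in body[1:-1])
            rx = f"[{allowed}]"
        else:
            rx = body
        if m.group("n"):
            lo = m.group("n")
            hi = m.group("m") or lo
            rx += "{%s,%s}?" % (lo, hi) if lo != hi else "{%s}" % lo
        parts.append(rx)
    body_rx = "".join(parts) + (r"\Z" if anchored_end else "")
    compiled = re.compile(body_rx)

    def scan(peptide: str):
        hits = []
        starts = [0] if anchored_start else range(len(peptide) + 1)
        for pos in starts:
            m = compiled.match(peptide, pos)
            if m:
                hits.append((pos, m.end()))
        return hits

    return scan


def random_prosite_pattern(rng: np.random.Generator) -> str:
    """Draw a random pattern from a constrained generator."""
    n_elements = int(rng.integers(3, 9))
    parts = []
    for _ in range(n_elements):
        kind = rng.choice(["literal", "class", "negated", "wildcard"], p=[0.35, 0.3, 0.1, 0.25])
        if kind == "literal":
            body = AA20[rng.integers(0, 20)]
        elif kind == "wildcard":
            body = "x"
        else:
            k = int(rng.integers(2, 5))
            residues = "".join(sorted(rng.choice(list(AA20), size=k, replace=False)))
            body = f"[{residues}]" if kind == "class" else "{%s}" % residues
        roll = rng.random()
        if roll < 0.15:
            body += f"({int(rng.integers(2, 4))})"
        elif roll < 0.3:
            lo = int(rng.integers(1, 3))
            body += f"({lo},{lo + int(rng.integers(1, 3))})"
        parts.append(body)
    pattern = "-".join(parts)
    if rng.random() < 0.15:
        pattern = "<" + pattern
    if rng.random() < 0.15:
        pattern = pattern + ">"
    return pattern + "."


def random_peptide(rng: np.random.Generator, pattern_text: str, length: int = 40) -> str:
    """Random peptide; with probability 1/2 a pattern exemplar is embedded."""
    letters = list(AA20 + "X")
    pep = "".join(rng.choice(letters, p=[0.048] * 20 + [0.04], size=length))
    if rng.random() < 0.5:
        from unigene.prosite import parse_prosite, pattern_exemplar

        motif = pattern_exemplar(parse_prosite(pattern_text))
        if len(motif) < length:
            at = int(rng.integers(0, length - len(motif)))
            pep = pep[:at] + motif + pep[at + len(motif):]
    return pep
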