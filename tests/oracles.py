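"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: segment search is
exhaustive O(n*m), interval unions use boolean arrays, statistics use
permutation/Monte-Carlo sampling, and sequence scans are naive Python.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


# ---------------------------------------------------------------------------
# ungapped alignment oracle


def _trim(match: list[bool], i: int, j: int, anchor: int) -> tuple[int, int]:
    changed = True
    while changed and i < j:
        changed = False
        run = 0
        while i + run < j and match[i + run]:
            run += 1
        if run < anchor:
            i += run
            while i < j and not match[i]:
                i += 1
            changed = True
        run = 0
        while j - 1 - run >= i and match[j - 1 - run]:
            run += 1
        if run < anchor:
            j -= run
            while j > i and not match[j - 1]:
                j -= 1
            changed = True
    return i, j


def oracle_segments(match: list[bool], anchor=8, min_len=24, min_identity=97.0):
    """Greedy maximal-scoring segment decomposition by exhaustive search over
    all (start, end) pairs; +1 match / -2 mismatch; ties prefer the smaller
    end then the smaller start; extracted spans are masked."""
    n = len(match)
    usable = [True] * n
    out = []
    while True:
        best = None  # (score, end, start)
        for i in range(n):
            if not usable[i]:
                continue
            score = 0
            for j in range(i, n):
                if not usable[j]:
                    break
                score += 1 if match[j] else -2
                cand = (score, j + 1, i)
                if best is None or (
                    cand[0] > best[0]
                    or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
                ):
                    best = cand
        if best is None or best[0] <= 0:
            break
        score, end, start = best
        for p in range(start, end):
            usable[p] = False
        ts, te = _trim(match, start, end, anchor)
        if te - ts < min_len:
            continue
        nm = sum(match[ts:te])
        if nm * 100.0 >= min_identity * (te - ts) - 1e-9:
            out.append((ts, te, nm))
    out.sort()
    return out


def oracle_hsps(query: str, subject: str, min_identity=97.0, min_len=24, anchor=8):
    """All ungapped HSP coordinates over every diagonal and both strands.

    Returns tuples (t_start, t_end, s_start, s_end, strand, n_match)."""
    results = set()
    lq, ls = len(query), len(subject)
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        for diag in range(-(lq - 1), ls):
            i0 = max(0, -diag)
            i1 = min(lq, ls - diag)
            if i1 - i0 < min_len:
                continue
            match = [
                q[i] == subject[i + diag] and q[i] in "ACGT" for i in range(i0, i1)
            ]
            for s, e, nm in oracle_segments(match, anchor, min_len, min_identity):
                q0, q1 = i0 + s, i0 + e
                s0, s1 = q0 + diag, q1 + diag
                if strand == "+":
                    t0, t1 = q0, q1
                else:
                    t0, t1 = lq - q1, lq - q0
                results.add((t0, t1, s0, s1, strand, nm))
    return results


# ---------------------------------------------------------------------------
# misc oracles


def interval_union_length(intervals, length: int) -> int:
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    return int(covered.sum())


def naive_gc_windows(seq: str, window=3, step=2):
    out = []
    for start in range(0, len(seq) - window + 1, step):
        chunk = seq[start : start + window]
        if any(c not in "ACGT" for c in chunk):
            continue
        gc = sum(c in "GC" for c in chunk) / window
        out.append((start + (window - 1) / 2.0, gc))
    return out


def naive_orf_coverage(seq: str, min_orf_len=300) -> float:
    n = len(seq)
    covered = np.zeros(n, dtype=bool)
    stops = {"TAA", "TAG", "TGA"}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            pos = frame
            orf_start = None
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if codon == "ATG" and orf_start is None:
                    orf_start = pos
                elif codon in stops:
                    if orf_start is not None and pos + 3 - orf_start >= min_orf_len:
                        a, b = orf_start, pos + 3
                        if strand == "+":
                            covered[a:b] = True
                        else:
                            covered[n - b : n - a] = True
                    orf_start = None
                pos += 3
    return covered.sum() / n


def hamming_motif_scan(window: str, motif: str):
    """(offset, mismatches) for every placement of motif in window."""
    out = []
    for off in range(len(window) - len(motif) + 1):
        mism = sum(a != b for a, b in zip(window[off : off + len(motif)], motif))
        out.append((off, mism))
    return out


def permutation_rank_test(a, b, n_perm=10000, seed=0) -> float:
    """Two-sided permutation p-value on the rank-sum statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled, kind="stable"), kind="stable") + 1.0
    # midranks for ties
    order = np.sort(pooled)
    rank_of = {}
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and order[j] == order[i]:
            j += 1
        for _ in range(i, j):
            rank_of[order[i]] = (i + 1 + j) / 2.0
        i = j
    ranks = np.array([rank_of[v] for v in pooled])
    na = len(a)
    obs = abs(ranks[:na].sum() - na * (len(pooled) + 1) / 2.0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        stat = abs(ranks[perm[:na]].sum() - na * (len(pooled) + 1) / 2.0)
        if stat >= obs - 1e-9:
            count += 1
    return count / n_perm


def chisq_two_cell(obs_scrambled: int, n: int, fraction: float) -> float:
    exp_s = n * fraction
    exp_n = n - exp_s
    return (obs_scrambled - exp_s) ** 2 / exp_s + (n - obs_scrambled - exp_n) ** 2 / exp_n


def mc_chi2_sf(stat: float, n_draws=100000, seed=0) -> float:
    """Monte-Carlo survival function of chi-square(1) via squared normals."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(n_draws) ** 2
    return float(np.mean(draws >= stat))
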