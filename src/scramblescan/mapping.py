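"""Transcript deduplication and ungapped transcript-to-scaffold mapping.

The aligner reports ungapped local alignments (HSPs) at a configurable
identity floor (default 97%), on both strands, with 0-based half-open
coordinates in both the transcript and the scaffold. Its canonical semantics
are defined per diagonal of the transcript x scaffold dot-plot:

1. score each position +1 (match) / -2 (mismatch);
2. greedily extract maximal-scoring segments (highest score first; ties go
   to the smaller end, then the smaller start; extracted segments are masked
   and extraction repeats while a positive-scoring segment remains);
3. trim each segment end to an exact-match anchor run of at least
   ``anchor`` bp (default 8), so segment ends are never propped up by
   isolated chance matches beyond a true homology boundary;
4. keep segments of length >= ``min_hsp_len`` (default 24 bp) and identity
   >= ``min_identity``.

Seeding uses exact k-mers (default k=15) over both transcript strands; the
scaffold is sampled every ``min_hsp_len - seed_k + 1`` positions, which
still guarantees a seed inside every reportable segment (any segment of
length >= 24 at >= 97% identity contains an exact run of >= 24 bp).
Precomputed 12-column tabular hits can be substituted via
:func:`scramblescan.io.read_hits`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, ParameterError
from .sequtil import encode, merge_intervals, reverse_complement, union_length

MATCH_SCORE = 1
MISMATCH_PENALTY = 2
_MASK = -(10**9)


@dataclass
class Hsp:
    """An ungapped local alignment segment (equal-length intervals)."""

    transcript_id: str
    scaffold_id: str
    t_start: int
    t_end: int
    s_start: int
    s_end: int
    strand: str
    percent_identity: float
    length: int

    def __post_init__(self) -> None:
        if self.t_end - self.t_start != self.s_end - self.s_start:
            raise InputError("Hsp intervals must be equal length (ungapped)")


@dataclass
class MdsCandidate(Hsp):
    """An HSP retained after containment chaining, ranked along the transcript."""

    order_index_on_transcript: int = 0
    retained: bool = True


def _trim_to_anchors(match: np.ndarray, start: int, end: int, anchor: int):
    """Shrink [start, end) until both ends begin with >= ``anchor`` matches."""
    while start < end:
        run = 0
        i = start
        while i < end and match[i]:
            run += 1
            i += 1
        if run >= anchor:
            break
        start = i
        while start < end and not match[start]:
            start += 1
    while end > start:
        run = 0
        i = end - 1
        while i >= start and match[i]:
            run += 1
            i -= 1
        if run >= anchor:
            break
        end = i + 1
        while end > start and not match[end - 1]:
            end -= 1
    return start, end


def max_scoring_segments(
    match: np.ndarray,
    anchor: int = 8,
    min_len: int = 24,
    min_identity: float = 97.0,
) -> list[tuple[int, int, int]]:
    """Canonical segment decomposition of one diagonal's match vector.

    Returns (start, end, n_matches) tuples after anchor trimming and
    identity/length filtering. This is the single definition both the seeded
    aligner and any exhaustive scan must reproduce.
    """
    n = len(match)
    if n == 0:
        return []
    scores = np.where(match, MATCH_SCORE, -MISMATCH_PENALTY).astype(np.int64)
    out = []
    while True:
        prefix = np.concatenate(([0], np.cumsum(scores)))
        minpref = np.minimum.accumulate(prefix[:-1])
        cand = prefix[1:] - minpref
        j = int(np.argmax(cand))  # first max -> smallest end
        if cand[j] <= 0:
            break
        end = j + 1
        target = minpref[j]
        start = int(np.flatnonzero(prefix[: j + 1] == target)[0])
        scores[start:end] = _MASK
        ts, te = _trim_to_anchors(match, start, end, anchor)
        seg_len = te - ts
        if seg_len < min_len:
            continue
        n_match = int(np.count_nonzero(match[ts:te]))
        if n_match * 100.0 >= min_identity * seg_len - 1e-9:
            out.append((ts, te, n_match))
    out.sort()
    return out


def _diagonal_segments(qarr, sarr, diag, **kw):
    """Run the canonical decomposition on one (query, subject) diagonal.

    ``diag`` is s_pos - q_pos. Yields (q_start, q_end, n_matches)."""
    lq, ls = len(qarr), len(sarr)
    q0 = max(0, -diag)
    q1 = min(lq, ls - diag)
    if q1 - q0 <= 0:
        return []
    m = qarr[q0:q1] == sarr[q0 + diag : q1 + diag]
    # ambiguous bases (code 4 on both sides would compare equal) never match
    m &= qarr[q0:q1] < 4
    return [(q0 + s, q0 + e, nm) for s, e, nm in max_scoring_segments(m, **kw)]


class _QueryIndex:
    """Exact k-mer index over both orientations of a set of query sequences."""

    def __init__(self, queries: dict[str, str], k: int):
        self.k = k
        self.index: dict[str, list[tuple[int, int]]] = {}
        self.names: list[str] = []
        for qid, seq in queries.items():
            qi = len(self.names)
            self.names.append(qid)
            for strand_bit, s in ((0, seq), (1, reverse_complement(seq))):
                code = qi * 2 + strand_bit
                add = self.index.setdefault
                for pos in range(0, len(s) - k + 1):
                    kmer = s[pos : pos + k]
                    if "N" in kmer:
                        continue
                    add(kmer, []).append((code, pos))

    def lookup(self, kmer: str):
        return self.index.get(kmer)


def map_ungapped(
    transcripts: dict[str, str],
    scaffolds: dict[str, str],
    min_identity: float = 97.0,
    seed_k: int = 15,
    min_hsp_len: int = 24,
    anchor: int = 8,
) -> list[Hsp]:
    """Map every transcript onto every scaffold, both strands.

    Minus-strand HSPs carry forward-strand coordinates in both systems; the
    transcript interval always refers to the transcript as given.
    """
    if seed_k < 8:
        raise ParameterError("seed_k must be >= 8")
    if not transcripts or not scaffolds:
        raise InputError("map_ungapped requires non-empty transcripts and scaffolds")
    if min_hsp_len < seed_k:
        stride = 1
    else:
        stride = min_hsp_len - seed_k + 1

    idx = _QueryIndex(transcripts, seed_k)
    tnames = list(transcripts)
    tarrs = {
        (tid, "+"): encode(seq) for tid, seq in transcripts.items()
    }
    tarrs.update(
        {(tid, "-"): encode(reverse_complement(seq)) for tid, seq in transcripts.items()}
    )
    kw = dict(anchor=anchor, min_len=min_hsp_len, min_identity=min_identity)

    hsps: list[Hsp] = []
    for sid in scaffolds:
        sseq = scaffolds[sid]
        sarr = encode(sseq)
        ls = len(sseq)
        diags: dict[int, set] = {}
        for pos in range(0, ls - seed_k + 1, stride):
            hits = idx.lookup(sseq[pos : pos + seed_k])
            if not hits:
                continue
            for code, qpos in hits:
                diags.setdefault(code, set()).add(pos - qpos)
        for code, dset in sorted(diags.items()):
            qi, strand = code // 2, "-" if code % 2 else "+"
            tid = tnames[qi]
            qarr = tarrs[(tid, strand)]
            lq = len(qarr)
            for diag in sorted(dset):
                for q0, q1, nm in _diagonal_segments(qarr, sarr, diag, **kw):
                    s0, s1 = q0 + diag, q1 + diag
                    if strand == "+":
                        t0, t1 = q0, q1
                    else:
                        t0, t1 = lq - q1, lq - q0
                    hsps.append(
                        Hsp(
                            transcript_id=tid,
                            scaffold_id=sid,
                            t_start=t0,
                            t_end=t1,
                            s_start=s0,
                            s_end=s1,
                            strand=strand,
                            percent_identity=100.0 * nm / (q1 - q0),
                            length=q1 - q0,
                        )
                    )
    # seeding can reach the same segment from several seeds/diagonals only via
    # identical coordinates; dedupe for a canonical result
    seen = set()
    unique = []
    for h in sorted(
        hsps,
        key=lambda h: (h.transcript_id, h.scaffold_id, h.t_start, h.t_end, h.s_start, h.strand),
    ):
        key = (h.transcript_id, h.scaffold_id, h.t_start, h.t_end, h.s_start, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return unique


def dedup_transcripts(
    transcripts: dict[str, str],
    min_identity: float = 98.0,
    min_frac_len: float = 0.75,
    seed_k: int = 15,
) -> dict[str, str]:
    """Greedy longest-first redundancy removal.

    A transcript is dropped iff it aligns to an already retained, longer (or
    equal-length, earlier-retained) transcript at > ``min_identity`` over
    >= ``min_frac_len`` of its own length (union of ungapped hits on either
    strand).
    """
    order = sorted(transcripts, key=lambda t: (-len(transcripts[t]), t))
    k = seed_k
    kw = dict(anchor=8, min_len=k, min_identity=min_identity)
    # incremental forward-strand k-mer index over retained transcripts
    index: dict[str, list[tuple[int, int]]] = {}
    arrs: list[np.ndarray] = []
    retained: set[str] = set()
    for tid in order:
        seq = transcripts[tid]
        covered: list[tuple[int, int]] = []
        for strand, q in (("+", seq), ("-", reverse_complement(seq))):
            qarr = encode(q)
            diags: dict[int, set] = {}
            for pos in range(0, len(q) - k + 1):
                for ri, rpos in index.get(q[pos : pos + k], ()):
                    diags.setdefault(ri, set()).add(rpos - pos)
            for ri, dset in diags.items():
                rarr = arrs[ri]
                for diag in dset:
                    for q0, q1, nm in _diagonal_segments(qarr, rarr, diag, **kw):
                        if nm * 100.0 > min_identity * (q1 - q0):
                            if strand == "+":
                                covered.append((q0, q1))
                            else:
                                covered.append((len(q) - q1, len(q) - q0))
        if union_length(covered) >= min_frac_len * len(seq):
            continue
        ri = len(arrs)
        arrs.append(encode(seq))
        for pos in range(0, len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append((ri, pos))
        retained.add(tid)
    return {tid: transcripts[tid] for tid in transcripts if tid in retained}


def transcript_coverage(hsps: list[Hsp], transcript_lengths: dict[str, int]) -> dict[str, float]:
    """Fraction of each transcript covered by the union of its HSP intervals
    across all scaffolds."""
    by_t: dict[str, list[tuple[int, int]]] = {}
    for h in hsps:
        by_t.setdefault(h.transcript_id, []).append((h.t_start, h.t_end))
    return {
        tid: union_length(iv) / transcript_lengths[tid]
        for tid, iv in by_t.items()
        if tid in transcript_lengths
    }


def coverage_filter(
    hsps: list[Hsp],
    transcript_lengths: dict[str, int],
    min_coverage: float = 0.60,
) -> tuple[dict[str, list[Hsp]], list[str]]:
    """Partition transcripts into mapped (coverage >= bound, inclusive) and
    unmapped. Returns ({mapped transcript: its hsps}, unmapped ids)."""
    cov = transcript_coverage(hsps, transcript_lengths)
    by_t: dict[str, list[Hsp]] = {}
    for h in hsps:
        by_t.setdefault(h.transcript_id, []).append(h)
    mapped = {
        tid: by_t[tid]
        for tid in by_t
        if cov.get(tid, 0.0) >= min_coverage - 1e-12
    }
    unmapped = [t for t in transcript_lengths if t not in mapped]
    return mapped, unmapped


def coverage_sweep(
    hsps: list[Hsp],
    transcript_lengths: dict[str, int],
    thresholds=(0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90),
) -> dict[float, list[str]]:
    """Mapped transcript sets across a range of coverage thresholds."""
    cov = transcript_coverage(hsps, transcript_lengths)
    return {
        th: sorted(t for t, c in cov.items() if c >= th - 1e-12)
        for th in thresholds
    }


def chain_to_mds(hsps: list[Hsp]) -> list[MdsCandidate]:
    """Resolve one transcript's HSPs into ordered MDS candidates.

    HSPs contained (in both coordinate systems, same scaffold) within a
    longer HSP are dropped; survivors are ranked by transcript start with
    ties broken by longer length, lexicographic scaffold id, scaffold start.
    """
    ranked = sorted(
        hsps, key=lambda h: (h.t_start, -h.length, h.scaffold_id, h.s_start)
    )
    kept: list[Hsp] = []
    for h in ranked:
        contained = False
        for other in ranked:
            if other is h or other.scaffold_id != h.scaffold_id:
                continue
            t_in = other.t_start <= h.t_start and h.t_end <= other.t_end
            s_in = other.s_start <= h.s_start and h.s_end <= other.s_end
            if t_in and s_in:
                if other.length > h.length:
                    contained = True
                    break
                if other.length == h.length and (
                    (other.t_start, other.t_end, other.s_start, other.s_end, other.strand)
                    == (h.t_start, h.t_end, h.s_start, h.s_end, h.strand)
                    and ranked.index(other) < ranked.index(h)
                ):
                    contained = True
                    break
        if not contained:
            kept.append(h)
    out = []
    for rank, h in enumerate(kept):
        out.append(
            MdsCandidate(
                transcript_id=h.transcript_id,
                scaffold_id=h.scaffold_id,
                t_start=h.t_start,
                t_end=h.t_end,
                s_start=h.s_start,
                s_end=h.s_end,
                strand=h.strand,
                percent_identity=h.percent_identity,
                length=h.length,
                order_index_on_transcript=rank,
                retained=True,
            )
        )
    return out


def support_counts(mapped: dict[str, list[Hsp]]) -> dict[str, int]:
    """Number of mapped transcripts touching each scaffold."""
    counts: dict[str, set] = {}
    for tid, hsps in mapped.items():
        for h in hsps:
            counts.setdefault(h.scaffold_id, set()).add(tid)
    return {sid: len(tids) for sid, tids in counts.items()}


def parse_stage(transcript_id: str, known=("veg", "div", "conj")) -> str:
    """Life-stage prefix of a transcript name, or 'unknown'."""
    head = transcript_id.split("_", 1)[0].split("|")[-1]
    return head if head in known else "unknown"


def mapped_share(n_mapped: int, n_total: int) -> float:
    """Share of the transcriptome mapped to the germline assembly."""
    if n_total <= 0:
        raise ParameterError("n_total must be > 0")
    return n_mapped / n_total
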