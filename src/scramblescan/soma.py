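"""Somatic-scaffold removal and germline triage.

Somatic nanochromosomes are telomere-capped: any scaffold with a telomeric
motif (CCCCAAACCCC or AAACCCCAAA by default) within its terminal 30 bp,
allowing one mismatch, is classed somatic. Remaining scaffolds are triaged
by length (>= 10 kbp), predicted-ORF coverage (< 20% of positions covered by
ATG->stop open reading frames >= 300 bp in any of six frames), and mapped
transcript support (>= 3 transcripts for "supported" status).

Both strands are scanned for the telomere motifs so assembly orientation
cannot hide a cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, IntegrityError, ParameterError
from .sequtil import encode, merge_intervals, reverse_complement

DEFAULT_TELOMERE_MOTIFS = ("CCCCAAACCCC", "AAACCCCAAA")

SOMATIC = "somatic"
PUTATIVE = "putative_germline"
SUPPORTED = "supported_germline"
EXCLUDED = "excluded"


@dataclass
class TelomereCall:
    end: str  # five_prime | three_prime
    motif: str
    offset: int  # bp from the scaffold end to the match start
    mismatches: int
    strand: str  # strand the motif matched on


@dataclass
class TelomereScan:
    call: str  # none | five_prime | three_prime | both
    matches: list[TelomereCall] = field(default_factory=list)


@dataclass
class ScaffoldRecord:
    id: str
    sequence: str
    telomere_call: str = "none"
    orf_coverage: float = 0.0
    n_supporting_transcripts: int = 0
    triage: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def _scan_window(window: str, motifs, max_mismatch: int) -> list[tuple[str, int, int, str]]:
    """Brute-force Hamming scan of every motif over every offset of a short
    terminal window, on both strands. Returns (motif, offset, mismatches, strand)."""
    hits = []
    for motif in motifs:
        for query, strand in ((motif, "+"), (reverse_complement(motif), "-")):
            m = len(query)
            for off in range(0, len(window) - m + 1):
                mism = sum(a != b for a, b in zip(window[off : off + m], query))
                if mism <= max_mismatch:
                    hits.append((motif, off, mism, strand))
    return hits


def detect_telomere(
    sequence: str,
    motifs: tuple[str, ...] = DEFAULT_TELOMERE_MOTIFS,
    terminal_window: int = 30,
    max_mismatch: int = 1,
) -> TelomereScan:
    """Scan both scaffold ends for telomeric motifs.

    Scaffolds shorter than the terminal window are scanned whole (both ends
    then see the same window).
    """
    if not sequence:
        raise InputError("detect_telomere: empty sequence")
    if terminal_window < 1:
        raise ParameterError("terminal_window must be >= 1")
    seq = sequence.upper()
    w = min(terminal_window, len(seq))
    matches: list[TelomereCall] = []
    for motif, off, mism, strand in _scan_window(seq[:w], motifs, max_mismatch):
        matches.append(TelomereCall("five_prime", motif, off, mism, strand))
    tail = seq[-w:]
    tail_base = len(seq) - w
    for motif, off, mism, strand in _scan_window(tail, motifs, max_mismatch):
        # offset measured from the 3' end to the nearest edge of the match
        end_off = len(seq) - (tail_base + off + len(motif))
        matches.append(TelomereCall("three_prime", motif, end_off, mism, strand))
    ends = {m.end for m in matches}
    if ends == {"five_prime", "three_prime"}:
        call = "both"
    elif ends:
        call = next(iter(ends))
    else:
        call = "none"
    return TelomereScan(call, matches)


_STOP_CODONS = np.array([48, 50, 56])  # TAA, TAG, TGA with A=0 C=1 G=2 T=3
_ATG_CODON = 14


def _orf_intervals_one_strand(codes: np.ndarray, min_orf_len: int) -> list[tuple[int, int]]:
    """ATG->stop ORFs of >= min_orf_len bp in the three frames of one strand,
    as intervals in the coordinates of ``codes``."""
    out: list[tuple[int, int]] = []
    n = len(codes)
    for frame in range(3):
        ncod = (n - frame) // 3
        if ncod <= 0:
            continue
        v = codes[frame : frame + ncod * 3]
        cod = v[0::3].astype(np.int32) * 16 + v[1::3] * 4 + v[2::3]
        valid = np.all(v.reshape(-1, 3) < 4, axis=1)
        stops = np.flatnonzero(np.isin(cod, _STOP_CODONS) & valid)
        atgs = np.flatnonzero((cod == _ATG_CODON) & valid)
        if len(stops) == 0 or len(atgs) == 0:
            continue
        region_start = np.concatenate(([0], stops[:-1] + 1))
        first_atg = np.searchsorted(atgs, region_start)
        ok = first_atg < len(atgs)
        starts = atgs[np.minimum(first_atg, len(atgs) - 1)]
        ok &= starts <= stops
        lengths = (stops - starts + 1) * 3
        ok &= lengths >= min_orf_len
        for s_cod, e_cod in zip(starts[ok], stops[ok]):
            out.append((frame + 3 * int(s_cod), frame + 3 * (int(e_cod) + 1)))
    return out


def orf_coverage(sequence: str, min_orf_len: int = 300) -> float:
    """Fraction of scaffold positions covered by the union of six-frame
    ATG->stop open reading frames of at least ``min_orf_len`` bp.

    Opposite-strand ORFs over the same interval count once (union semantics).
    """
    if min_orf_len <= 0:
        raise ParameterError("min_orf_len must be > 0")
    if not sequence:
        return 0.0
    n = len(sequence)
    fwd = encode(sequence)
    rev = encode(reverse_complement(sequence))
    intervals = _orf_intervals_one_strand(fwd, min_orf_len)
    for s, e in _orf_intervals_one_strand(rev, min_orf_len):
        intervals.append((n - e, n - s))
    merged = merge_intervals(intervals)
    return sum(e - s for s, e in merged) / n


def triage_scaffolds(
    scaffolds: dict[str, str],
    mapped_support: dict[str, int] | None = None,
    min_len: int = 10000,
    max_orf_cov: float = 0.20,
    min_transcripts: int = 3,
    min_orf_len: int = 300,
    telomere_motifs: tuple[str, ...] = DEFAULT_TELOMERE_MOTIFS,
    terminal_window: int = 30,
    max_mismatch: int = 1,
) -> list[ScaffoldRecord]:
    """Partition scaffolds into somatic / excluded / putative / supported.

    Telomeric scaffolds are somatic regardless of other features; short
    (< min_len) or ORF-dense (>= max_orf_cov covered) scaffolds are excluded;
    the rest are putative germline, upgraded to supported when at least
    ``min_transcripts`` mapped transcripts back them. Labels are invariant to
    input order.
    """
    mapped_support = mapped_support or {}
    unknown = set(mapped_support) - set(scaffolds)
    if unknown:
        raise IntegrityError(
            f"mapped_support names unknown scaffold(s): {sorted(unknown)[:5]}"
        )
    records = []
    for sid, seq in sorted(scaffolds.items()):
        rec = ScaffoldRecord(id=sid, sequence=seq)
        rec.telomere_call = detect_telomere(
            seq, telomere_motifs, terminal_window, max_mismatch
        ).call
        rec.n_supporting_transcripts = mapped_support.get(sid, 0)
        if rec.telomere_call != "none":
            rec.triage = SOMATIC
        elif rec.length < min_len:
            rec.triage = EXCLUDED
        else:
            rec.orf_coverage = orf_coverage(seq, min_orf_len)
            if rec.orf_coverage >= max_orf_cov:
                rec.triage = EXCLUDED
            elif rec.n_supporting_transcripts >= min_transcripts:
                rec.triage = SUPPORTED
            else:
                rec.triage = PUTATIVE
        records.append(rec)
    return records


def write_triage_tsv(records: list[ScaffoldRecord], path: str) -> str:
    with open(path, "w") as fh:
        fh.write(
            "#id\tlength\ttelomere_call\torf_coverage\tn_supporting_transcripts\ttriage\n"
        )
        for r in records:
            fh.write(
                f"{r.id}\t{r.length}\t{r.telomere_call}\t{r.orf_coverage:.4f}"
                f"\t{r.n_supporting_transcripts}\t{r.triage}\n"
            )
    return path
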