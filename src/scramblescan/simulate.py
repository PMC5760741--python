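"""Synthetic germline/somatic dataset generator with full ground truth.

Emulates a ciliate germline assembly in which each somatic gene (observed as
a transcript) is encoded by one germline locus whose macronuclear-destined
sequences (MDSs) may be reordered and/or inverted (scrambled), separated by
GC-poor internally eliminated sequences (IESs), with identical short direct
repeats (pointers) at each junction. Somatic contamination is emulated as
short telomere-capped scaffolds. Every planted feature is recorded in a
:class:`LocusTruth` so downstream stages can be scored exactly.

The emitted transcript is the descrambled, pointer-deduplicated,
intron-spliced concatenation of its MDSs; :func:`reconstruct_transcript`
recovers it from the truth records and the scaffold sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import (
    LogNormalLength,
    PerCategory,
    PointerLengthDist,
    ShiftedGeometricCount,
)
from .exceptions import IntegrityError, ParameterError
from .sequtil import random_sequence, reverse_complement

STAGES = ("veg", "div", "conj")

NONSCRAMBLED = "nonscrambled"
SCRAMBLED = "scrambled"
ALT_PROCESSED = "alt_processed"
MULTI_SCAFFOLD = "multi_scaffold"


def _default_count_dist() -> PerCategory:
    return PerCategory(
        nonscrambled=ShiftedGeometricCount(2.46, minimum=1),
        scrambled=ShiftedGeometricCount(3.29, minimum=2),
    )


def _default_mds_len_dist() -> PerCategory:
    return PerCategory(
        nonscrambled=LogNormalLength(212.20, 179, minimum=40),
        scrambled=LogNormalLength(160.96, 133, minimum=40),
    )


def _default_pointer_dist() -> PerCategory:
    return PerCategory(
        nonscrambled=PointerLengthDist(6),
        scrambled=PointerLengthDist(8),
    )


def _default_ies_dist() -> PerCategory:
    return PerCategory(
        nonscrambled=LogNormalLength(136.78, 104, minimum=20, maximum=50000),
        scrambled=LogNormalLength(1454.89, 805, minimum=20, maximum=50000),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable study conditions for the generator.

    Distribution defaults reproduce the printed per-category means/medians
    for MDS counts, MDS lengths, pointer lengths, and inter-MDS separations;
    compartment GC defaults are 0.41 (MDS) and 0.29 (IES).
    """

    n_loci: int = 100
    scrambled_fraction: float = 0.31
    mds_count_dist: PerCategory = field(default_factory=_default_count_dist)
    mds_len_dist: PerCategory = field(default_factory=_default_mds_len_dist)
    pointer_len_dist: PerCategory = field(default_factory=_default_pointer_dist)
    ies_len_dist: PerCategory = field(default_factory=_default_ies_dist)
    gc_mds: float = 0.41
    gc_ies: float = 0.29
    inversion_prob: float = 0.35
    n_somatic_contaminants: int = 10
    telomere_repeat: str = "CCCCAAA"
    alt_processing_prob: float = 0.05
    multi_scaffold_prob: float = 0.05
    intron_prob: float = 0.10
    mds_dropout_prob: float = 0.0
    scaffold_len_range: tuple[int, int] = (10500, 13000)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "scrambled_fraction",
            "inversion_prob",
            "alt_processing_prob",
            "multi_scaffold_prob",
            "intron_prob",
            "mds_dropout_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("gc_mds", "gc_ies"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.n_loci < 0:
            raise ParameterError("n_loci must be >= 0")
        if self.n_somatic_contaminants < 0:
            raise ParameterError("n_somatic_contaminants must be >= 0")
        if not self.telomere_repeat or set(self.telomere_repeat) - set("ACGT"):
            raise ParameterError("telomere_repeat must be a nonempty ACGT string")
        lo, hi = self.scaffold_len_range
        if lo < 1000 or hi < lo:
            raise ParameterError("scaffold_len_range must satisfy 1000 <= lo <= hi")


@dataclass
class MdsSegmentTruth:
    """One planted alignment segment (an MDS, or an intron-split piece of one)."""

    transcript_id: str
    order_index: int  # 1-based position of the MDS along the transcript
    sub_index: int  # piece index within the MDS (0 unless intron-split)
    t_start: int
    t_end: int
    scaffold_id: str
    s_start: int
    s_end: int
    strand: str
    dropout: bool = False

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass
class PointerTruth:
    """A planted pointer: identical direct repeat at two germline junctions."""

    between: tuple[int, int]  # (order n, n+1)
    length: int
    sequence: str
    left_scaffold_id: str
    left_start: int
    left_end: int
    right_scaffold_id: str
    right_start: int
    right_end: int


@dataclass
class LocusTruth:
    locus_id: str
    scaffold_ids: list[str]
    transcript_ids: list[str]
    mds_records: list[MdsSegmentTruth]
    pointer_records: list[PointerTruth]
    intron_records: list[tuple[str, int, int]]
    category: str
    transcript_labels: dict[str, str]  # per-transcript scrambled/nonscrambled
    transcript_stage: dict[str, str]


@dataclass
class SyntheticDataset:
    scaffolds: dict[str, str]
    transcripts: dict[str, str]
    truth: list[LocusTruth]
    family_truth: dict[str, str]

    def scrambled_fraction(self) -> float:
        labels = [
            lab for t in self.truth for lab in t.transcript_labels.values()
        ]
        if not labels:
            return 0.0
        return sum(1 for v in labels if v == SCRAMBLED) / len(labels)


# ---------------------------------------------------------------------------
# locus construction


def _t_to_scaffold(pieces, t0: int, t1: int) -> tuple[str, int, int]:
    """Map a transcript subinterval lying inside one planted piece to
    scaffold coordinates (forward-strand, half-open)."""
    for p in pieces:
        if p.t_start <= t0 and t1 <= p.t_end:
            if p.strand == "+":
                off = p.s_start - p.t_start
                return p.scaffold_id, t0 + off, t1 + off
            # minus strand: transcript runs antiparallel to the scaffold
            return p.scaffold_id, p.s_end - (t1 - p.t_start), p.s_end - (t0 - p.t_start)
    raise IntegrityError(f"transcript interval [{t0},{t1}) not inside any planted piece")


def _arrangement_entries(pieces) -> list[tuple[str, int, str]]:
    """(scaffold_id, s_start, strand) per MDS in transcript order, using the
    first piece of each MDS."""
    by_order: dict[int, MdsSegmentTruth] = {}
    for p in pieces:
        cur = by_order.get(p.order_index)
        if cur is None or p.sub_index < cur.sub_index:
            by_order[p.order_index] = p
    out = []
    for n in sorted(by_order):
        p = by_order[n]
        out.append((p.scaffold_id, p.s_start, p.strand))
    return out


def arrangement_is_scrambled(entries: list[tuple[str, int, str]]) -> bool:
    """Order/strand criterion on (scaffold_id, s_start, strand) triples given
    in transcript order.

    Per scaffold chain: a single strand with scaffold positions strictly
    ascending (plus strand) or strictly descending (minus strand, the
    reverse-complement of an ordered locus) is nonscrambled; anything else —
    permuted positions or mixed strands — is scrambled.
    """
    chains: dict[str, list[tuple[int, str]]] = {}
    for sid, start, strand in entries:
        chains.setdefault(sid, []).append((start, strand))
    for chain in chains.values():
        strands = {st for _, st in chain}
        if len(strands) > 1:
            return True
        starts = [s for s, _ in chain]
        if strands == {"+"}:
            if starts != sorted(starts) or len(set(starts)) != len(starts):
                return True
        else:
            if starts != sorted(starts, reverse=True) or len(set(starts)) != len(starts):
                return True
    return False


class _LocusBuilder:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator, index: int):
        self.cfg = config
        self.rng = rng
        self.index = index

    def build(self):
        cfg, rng = self.cfg, self.rng
        scrambled = rng.random() < cfg.scrambled_fraction
        k = int(cfg.mds_count_dist.for_category(scrambled).sample(rng, 1)[0])
        if scrambled:
            k = max(k, 2)
        lens = cfg.mds_len_dist.for_category(scrambled).sample(rng, k)
        lens = np.maximum(lens, 40)
        ptr = cfg.pointer_len_dist.for_category(scrambled).sample(rng, max(k - 1, 0))
        for j in range(k - 1):
            ptr[j] = min(ptr[j], min(lens[j], lens[j + 1]) // 2)
        # transcript-coordinate MDS intervals; adjacent MDSs overlap by the
        # pointer length so the repeat is present once at each germline junction
        a = np.zeros(k, dtype=int)
        b = np.zeros(k, dtype=int)
        a[0], b[0] = 0, int(lens[0])
        for j in range(1, k):
            a[j] = b[j - 1] - int(ptr[j - 1])
            b[j] = a[j] + int(lens[j])
        t_len = int(b[-1])
        T = random_sequence(rng, t_len, cfg.gc_mds)

        # optional intron inside one MDS: present in the germline copy (and
        # the unspliced somatic form) but absent from the emitted transcript
        intron_mds = -1
        intron_pos = intron_seq = None
        if rng.random() < cfg.intron_prob:
            candidates = [j for j in range(k) if lens[j] >= 120]
            if candidates:
                intron_mds = int(rng.choice(candidates))
                for _ in range(50):
                    pos = int(rng.integers(a[intron_mds] + 30, b[intron_mds] - 30))
                    # the GT...AG ends must not extend the flanking alignments
                    if T[pos] != "G" and T[pos - 1] != "G":
                        intron_pos = pos
                        break
                if intron_pos is None:
                    intron_mds = -1
                else:
                    ilen = int(rng.integers(50, 151))
                    intron_seq = "GT" + random_sequence(rng, ilen - 4, cfg.gc_ies) + "AG"

        germs: list[str] = []  # germline sequence of each MDS, transcript orientation
        piece_spans: list[list[tuple[int, int, int, int]]] = []  # (t0,t1,g0,g1)
        dropouts = []
        for j in range(k):
            seg = T[a[j] : b[j]]
            if j == intron_mds:
                cut = intron_pos - a[j]
                germ = seg[:cut] + intron_seq + seg[cut:]
                spans = [
                    (int(a[j]), intron_pos, 0, cut),
                    (intron_pos, int(b[j]), cut + len(intron_seq), len(germ)),
                ]
            else:
                germ = seg
                spans = [(int(a[j]), int(b[j]), 0, len(germ))]
            drop = rng.random() < cfg.mds_dropout_prob
            if drop:
                germ = random_sequence(rng, len(germ), cfg.gc_mds)
            germs.append(germ)
            piece_spans.append(spans)
            dropouts.append(drop)

        multi = (not scrambled) and k >= 2 and rng.random() < cfg.multi_scaffold_prob
        locus_id = f"locus{self.index:05d}"
        stage = STAGES[int(rng.integers(0, len(STAGES)))]
        tid = f"{stage}_{locus_id}"

        scaffolds: dict[str, str] = {}
        pieces: list[MdsSegmentTruth] = []
        introns: list[tuple[str, int, int]] = []

        def assemble(part: list[int], strands: dict[int, str], sid: str) -> None:
            """Place MDSs (given as transcript-order indices in scaffold
            placement order) on one scaffold with IES separations and padding."""
            n_sep = len(part) - 1
            seps = cfg.ies_len_dist.for_category(scrambled).sample(rng, n_sep) if n_sep else []
            content = sum(len(germs[j]) for j in part) + int(np.sum(seps))
            target = int(rng.integers(*cfg.scaffold_len_range))
            pad_total = max(400, target - content)
            left = int(rng.integers(200, pad_total - 199))
            right = pad_total - left
            parts = [random_sequence(rng, left, cfg.gc_ies)]
            pos = left
            for m, j in enumerate(part):
                germ = germs[j]
                placed = germ if strands[j] == "+" else reverse_complement(germ)
                s0, s1 = pos, pos + len(placed)
                for si, (t0, t1, g0, g1) in enumerate(piece_spans[j]):
                    if strands[j] == "+":
                        ps, pe = s0 + g0, s0 + g1
                    else:
                        ps, pe = s1 - g1, s1 - g0
                    pieces.append(
                        MdsSegmentTruth(
                            transcript_id=tid,
                            order_index=j + 1,
                            sub_index=si,
                            t_start=t0,
                            t_end=t1,
                            scaffold_id=sid,
                            s_start=ps,
                            s_end=pe,
                            strand=strands[j],
                            dropout=dropouts[j],
                        )
                    )
                if j == intron_mds:
                    ivals = sorted(
                        (p.s_start, p.s_end)
                        for p in pieces
                        if p.scaffold_id == sid and p.order_index == j + 1
                    )
                    introns.append((sid, ivals[0][1], ivals[1][0]))
                parts.append(placed)
                pos = s1
                if m < len(part) - 1:
                    sep = int(seps[m])
                    parts.append(random_sequence(rng, sep, cfg.gc_ies))
                    pos += sep
            parts.append(random_sequence(rng, right, cfg.gc_ies))
            scaffolds[sid] = "".join(parts)

        if multi:
            split = int(rng.integers(1, k))
            strands = {j: "+" for j in range(k)}
            assemble(list(range(split)), strands, f"scaf{self.index:05d}a")
            assemble(list(range(split, k)), strands, f"scaf{self.index:05d}b")
            category = MULTI_SCAFFOLD
        elif not scrambled:
            sid = f"scaf{self.index:05d}"
            if k >= 1 and rng.random() < 0.10:
                # reverse-complemented flavor of an ordered locus: descending
                # placement, all minus — still nonscrambled
                strands = {j: "-" for j in range(k)}
                assemble(list(range(k - 1, -1, -1)), strands, sid)
            else:
                strands = {j: "+" for j in range(k)}
                assemble(list(range(k)), strands, sid)
            category = NONSCRAMBLED
        else:
            sid = f"scaf{self.index:05d}"
            for _ in range(200):
                order = [int(x) for x in rng.permutation(k)]
                strands = {
                    j: ("-" if rng.random() < cfg.inversion_prob else "+")
                    for j in range(k)
                }
                pieces_before = len(pieces)
                introns_before = len(introns)
                assemble(order, strands, sid)
                if arrangement_is_scrambled(_arrangement_entries(pieces)):
                    break
                del pieces[pieces_before:]
                del introns[introns_before:]
                scaffolds.pop(sid, None)
            else:  # deterministic fallback: reversed order on the plus strand
                order = list(range(k - 1, -1, -1))
                strands = {j: "+" for j in range(k)}
                assemble(order, strands, sid)
            category = SCRAMBLED

        pointers: list[PointerTruth] = []
        for j in range(k - 1):
            plen = int(ptr[j])
            if plen <= 0:
                continue
            seq = T[a[j + 1] : b[j]]
            lsid, ls, le = _t_to_scaffold(
                [p for p in pieces if p.order_index == j + 1], int(b[j]) - plen, int(b[j])
            )
            rsid, rs, re_ = _t_to_scaffold(
                [p for p in pieces if p.order_index == j + 2], int(a[j + 1]), int(a[j + 1]) + plen
            )
            pointers.append(
                PointerTruth((j + 1, j + 2), plen, seq, lsid, ls, le, rsid, rs, re_)
            )

        transcripts = {tid: T}
        labels = {
            tid: SCRAMBLED
            if arrangement_is_scrambled(_arrangement_entries(pieces))
            else NONSCRAMBLED
        }
        stages = {tid: stage}

        # alternative processing: a second somatic product skipping one
        # interior MDS of a scrambled locus
        if category == SCRAMBLED and k >= 3 and rng.random() < cfg.alt_processing_prob:
            for d in rng.permutation(np.arange(1, k - 1)):
                d = int(d)
                shift = int(a[d + 1]) - int(b[d - 1])
                alt_pieces = []
                for p in pieces:
                    if p.order_index == d + 1:
                        continue
                    q = replace(p, transcript_id="", )
                    if p.order_index > d + 1:
                        q.t_start -= shift
                        q.t_end -= shift
                        q.order_index -= 1
                    alt_pieces.append(q)
                if arrangement_is_scrambled(_arrangement_entries(alt_pieces)):
                    stage2 = STAGES[int(rng.integers(0, len(STAGES)))]
                    tid2 = f"{stage2}_{locus_id}alt"
                    for q in alt_pieces:
                        q.transcript_id = tid2
                    T2 = T[: int(b[d - 1])] + T[int(a[d + 1]) :]
                    transcripts[tid2] = T2
                    pieces.extend(alt_pieces)
                    labels[tid2] = SCRAMBLED
                    stages[tid2] = stage2
                    category = ALT_PROCESSED
                    break

        self._enforce_boundary_identifiability(
            scaffolds, pieces, transcripts, introns
        )

        truth = LocusTruth(
            locus_id=locus_id,
            scaffold_ids=sorted(scaffolds),
            transcript_ids=list(transcripts),
            mds_records=pieces,
            pointer_records=pointers,
            intron_records=introns,
            category=category,
            transcript_labels=labels,
            transcript_stage=stages,
        )
        return scaffolds, transcripts, truth

    def _enforce_boundary_identifiability(
        self, scaffolds, pieces, transcripts, introns
    ) -> None:
        """Constrain the scaffold base adjacent to each planted segment so the
        planted alignment is the maximal one (a matching neighbour base would
        make the true boundary unidentifiable by any aligner). Bases inside
        planted introns (the GT/AG dinucleotides) are left untouched; those
        junctions are constrained via the intron insertion point instead."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        protected = {
            (sid, pos) for sid, i0, i1 in introns for pos in (i0, i0 + 1, i1 - 2, i1 - 1)
        }
        forbidden: dict[tuple[str, int], set[str]] = {}

        def forbid(sid: str, pos: int, base: str) -> None:
            if pos < 0 or pos >= len(scaffolds[sid]) or (sid, pos) in protected:
                return
            forbidden.setdefault((sid, pos), set()).add(base)

        for p in pieces:
            if p.dropout:
                continue
            T = transcripts[p.transcript_id]
            if p.strand == "+":
                if p.t_start > 0:
                    forbid(p.scaffold_id, p.s_start - 1, T[p.t_start - 1])
                if p.t_end < len(T):
                    forbid(p.scaffold_id, p.s_end, T[p.t_end])
            else:
                if p.t_start > 0:
                    forbid(p.scaffold_id, p.s_end, comp[T[p.t_start - 1]])
                if p.t_end < len(T):
                    forbid(p.scaffold_id, p.s_start - 1, comp[T[p.t_end]])

        edits: dict[str, dict[int, str]] = {}
        for (sid, pos), bad in forbidden.items():
            cur = scaffolds[sid][pos]
            if cur not in bad:
                continue
            choices = [b for b in "ACGT" if b not in bad]
            edits.setdefault(sid, {})[pos] = choices[int(self.rng.integers(0, len(choices)))]
        for sid, subs in edits.items():
            seq = list(scaffolds[sid])
            for pos, base in subs.items():
                seq[pos] = base
            scaffolds[sid] = "".join(seq)


def _scrub_telomere_ends(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Regenerate terminal padding until neither end carries a chance
    telomere-like motif (the germline contract is telomere-free ends)."""
    from .soma import detect_telomere  # deferred: soma does not import simulate

    for _ in range(100):
        if detect_telomere(seq, terminal_window=30, max_mismatch=1).call == "none":
            return seq
        seq = (
            random_sequence(rng, 40, cfg.gc_ies)
            + seq[40:-40]
            + random_sequence(rng, 40, cfg.gc_ies)
        )
    return seq


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a paired scaffold/transcript dataset with planted truth.

    Deterministic for a fixed ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    scaffolds: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    truths: list[LocusTruth] = []
    for i in range(config.n_loci):
        sc, tr, truth = _LocusBuilder(config, rng, i).build()
        for sid, seq in sc.items():
            scaffolds[sid] = _scrub_telomere_ends(seq, config, rng)
        transcripts.update(tr)
        truths.append(truth)

    cap = config.telomere_repeat * max(1, -(-25 // len(config.telomere_repeat)))
    for i in range(config.n_somatic_contaminants):
        interior = random_sequence(rng, int(rng.integers(800, 4500 - 2 * len(cap))), 0.35)
        scaffolds[f"somatic{i:03d}"] = cap + interior + reverse_complement(cap)

    # null gene-family truth: membership independent of scrambling status
    tids = list(transcripts)
    order = [tids[int(j)] for j in rng.permutation(len(tids))]
    fam_sizes = ShiftedGeometricCount(3.0, minimum=1)
    family_truth: dict[str, str] = {}
    fam_no = 0
    pos = 0
    while pos < len(order):
        size = int(fam_sizes.sample(rng, 1)[0])
        fam_no += 1
        for t in order[pos : pos + size]:
            family_truth[t] = f"fam{fam_no:05d}"
        pos += size
    return SyntheticDataset(scaffolds, transcripts, truths, family_truth)


def reconstruct_transcript(
    truth: LocusTruth,
    scaffolds: dict[str, str],
    transcript_id: str | None = None,
    splice_introns: bool = True,
) -> str:
    """Rebuild a somatic sequence from planted germline coordinates.

    MDS pieces are extracted in transcript order, reverse-complemented on the
    minus strand, and concatenated with the second copy of each pointer
    removed. With ``splice_introns=False`` the intron-bearing (unspliced)
    somatic form is returned instead of the emitted transcript.
    """
    tid = transcript_id or truth.transcript_ids[0]
    pieces = sorted(
        (p for p in truth.mds_records if p.transcript_id == tid),
        key=lambda p: (p.t_start, p.sub_index),
    )
    if not pieces:
        raise IntegrityError(f"no planted segments for transcript {tid!r}")
    out: list[str] = []
    prev = None
    for p in pieces:
        if p.scaffold_id not in scaffolds:
            raise IntegrityError(f"unknown scaffold {p.scaffold_id!r} in truth")
        scaf = scaffolds[p.scaffold_id]
        if not (0 <= p.s_start <= p.s_end <= len(scaf)):
            raise IntegrityError(
                f"segment [{p.s_start},{p.s_end}) outside scaffold {p.scaffold_id!r}"
            )
        seq = scaf[p.s_start : p.s_end]
        if p.strand == "-":
            seq = reverse_complement(seq)
        if prev is not None:
            if (
                not splice_introns
                and p.order_index == prev.order_index
                and p.scaffold_id == prev.scaffold_id
            ):
                if p.strand == "+":
                    out.append(scaf[prev.s_end : p.s_start])
                else:
                    out.append(reverse_complement(scaf[p.s_end : prev.s_start]))
            overlap = prev.t_end - p.t_start
            if overlap > 0:
                seq = seq[overlap:]
        out.append(seq)
        prev = p
    return "".join(out)


# ---------------------------------------------------------------------------
# on-disk round trip

_TRUTH_COLUMNS = [
    "locus_id",
    "record",
    "transcript_id",
    "scaffold_id",
    "scaffold2_id",
    "t_start",
    "t_end",
    "s_start",
    "s_end",
    "s2_start",
    "s2_end",
    "strand",
    "order_index",
    "sub_index",
    "length",
    "sequence",
    "category",
    "label",
    "stage",
    "dropout",
]


def _row(**kw) -> str:
    return "\t".join(str(kw.get(c, ".")) for c in _TRUTH_COLUMNS)


def write_dataset(ds: SyntheticDataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write scaffolds.fasta, transcripts.fasta, truth.tsv, families.tsv.

    truth.tsv is tab-separated with 0-based half-open scaffold coordinates,
    strand in {+,-}, one row per record (transcript / mds / pointer / intron)
    and a leading '#'-prefixed header line. Round-trips losslessly.
    """
    from .io import write_fasta

    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "scaffolds": os.path.join(out, "scaffolds.fasta"),
        "transcripts": os.path.join(out, "transcripts.fasta"),
        "truth": os.path.join(out, "truth.tsv"),
        "families": os.path.join(out, "families.tsv"),
    }
    write_fasta(paths["scaffolds"], ds.scaffolds)
    write_fasta(paths["transcripts"], ds.transcripts)
    with open(paths["truth"], "w") as fh:
        fh.write("#" + "\t".join(_TRUTH_COLUMNS) + "\n")
        for t in ds.truth:
            for tid in t.transcript_ids:
                fh.write(
                    _row(
                        locus_id=t.locus_id,
                        record="transcript",
                        transcript_id=tid,
                        category=t.category,
                        label=t.transcript_labels[tid],
                        stage=t.transcript_stage[tid],
                    )
                    + "\n"
                )
            for p in t.mds_records:
                fh.write(
                    _row(
                        locus_id=t.locus_id,
                        record="mds",
                        transcript_id=p.transcript_id,
                        scaffold_id=p.scaffold_id,
                        t_start=p.t_start,
                        t_end=p.t_end,
                        s_start=p.s_start,
                        s_end=p.s_end,
                        strand=p.strand,
                        order_index=p.order_index,
                        sub_index=p.sub_index,
                        dropout=int(p.dropout),
                    )
                    + "\n"
                )
            for ptr in t.pointer_records:
                fh.write(
                    _row(
                        locus_id=t.locus_id,
                        record="pointer",
                        scaffold_id=ptr.left_scaffold_id,
                        scaffold2_id=ptr.right_scaffold_id,
                        s_start=ptr.left_start,
                        s_end=ptr.left_end,
                        s2_start=ptr.right_start,
                        s2_end=ptr.right_end,
                        order_index=ptr.between[0],
                        length=ptr.length,
                        sequence=ptr.sequence,
                    )
                    + "\n"
                )
            for sid, i0, i1 in t.intron_records:
                fh.write(
                    _row(
                        locus_id=t.locus_id,
                        record="intron",
                        scaffold_id=sid,
                        s_start=i0,
                        s_end=i1,
                    )
                    + "\n"
                )
    with open(paths["families"], "w") as fh:
        fh.write("#transcript_id\tfamily_id\n")
        for tid, fam in ds.family_truth.items():
            fh.write(f"{tid}\t{fam}\n")
    return paths


def read_truth(path: str | os.PathLike) -> list[LocusTruth]:
    loci: dict[str, LocusTruth] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            vals = dict(zip(_TRUTH_COLUMNS, line.rstrip("\n").split("\t")))
            lid = vals["locus_id"]
            t = loci.get(lid)
            if t is None:
                t = loci[lid] = LocusTruth(lid, [], [], [], [], [], "", {}, {})
            rec = vals["record"]
            if rec == "transcript":
                tid = vals["transcript_id"]
                t.transcript_ids.append(tid)
                t.category = vals["category"]
                t.transcript_labels[tid] = vals["label"]
                t.transcript_stage[tid] = vals["stage"]
            elif rec == "mds":
                t.mds_records.append(
                    MdsSegmentTruth(
                        transcript_id=vals["transcript_id"],
                        order_index=int(vals["order_index"]),
                        sub_index=int(vals["sub_index"]),
                        t_start=int(vals["t_start"]),
                        t_end=int(vals["t_end"]),
                        scaffold_id=vals["scaffold_id"],
                        s_start=int(vals["s_start"]),
                        s_end=int(vals["s_end"]),
                        strand=vals["strand"],
                        dropout=bool(int(vals["dropout"])),
                    )
                )
                if vals["scaffold_id"] not in t.scaffold_ids:
                    t.scaffold_ids.append(vals["scaffold_id"])
            elif rec == "pointer":
                n = int(vals["order_index"])
                t.pointer_records.append(
                    PointerTruth(
                        (n, n + 1),
                        int(vals["length"]),
                        vals["sequence"],
                        vals["scaffold_id"],
                        int(vals["s_start"]),
                        int(vals["s_end"]),
                        vals["scaffold2_id"],
                        int(vals["s2_start"]),
                        int(vals["s2_end"]),
                    )
                )
            elif rec == "intron":
                t.intron_records.append(
                    (vals["scaffold_id"], int(vals["s_start"]), int(vals["s_end"]))
                )
    for t in loci.values():
        t.scaffold_ids = sorted(t.scaffold_ids)
    return list(loci.values())


def read_families(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tid, fam = line.rstrip("\n").split("\t")
            out[tid] = fam
    return out
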