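"""Locus models: pointers, IES/intron gaps, scrambled-locus classification,
per-category statistics, and germline genome-size estimation.

A locus model is one transcript's reconstruction on the germline assembly:
its retained MDS candidates in transcript order, the pointer (identical
short direct repeat) at each MDS junction, the germline-limited gaps between
consecutive MDSs, and a category:

* nonscrambled — scaffold order of the MDSs strictly follows transcript
  order on a single strand (a consistently descending minus-strand chain is
  the reverse complement of an ordered locus and also nonscrambled);
* scrambled — permuted scaffold order and/or MDSs on both strands;
* a chain spanning two or more scaffolds is flagged multi-scaffold and
  classified by applying the order/strand criteria per scaffold chain;
* two transcripts sharing part of one germline footprint while differing in
  MDS content form an alternative-processing event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import IntegrityError, ParameterError
from .mapping import MdsCandidate
from .sequtil import gc_fraction, reverse_complement
from .simulate import arrangement_is_scrambled

NONSCRAMBLED = "nonscrambled"
SCRAMBLED = "scrambled"

#: Table-style per-category features
FEATURES = (
    "mds_count",
    "mds_length",
    "pointer_length",
    "mds_ies_gc",
    "inter_pointer_distance",
)


@dataclass
class Pointer:
    transcript_id: str
    between: tuple[int, int]  # transcript-order ranks (n, n+1), 1-based
    length: int
    sequence: str
    left_scaffold_id: str
    left_start: int
    left_end: int
    right_scaffold_id: str
    right_start: int
    right_end: int


@dataclass
class GapAnnotation:
    scaffold_id: str
    start: int
    end: int
    kind: str  # IES | intron | ambiguous
    pointer_present: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusModel:
    transcript_id: str
    mds: list[MdsCandidate]
    pointers: list[Pointer] = field(default_factory=list)
    gaps: list[GapAnnotation] = field(default_factory=list)
    category: str = ""
    multi_scaffold: bool = False
    alt_processed: bool = False

    @property
    def scaffold_ids(self) -> list[str]:
        return sorted({m.scaffold_id for m in self.mds})

    @property
    def mds_count(self) -> int:
        return len(self.mds)


def _segment_in_transcript_orientation(m: MdsCandidate, scaffolds) -> str:
    seq = scaffolds[m.scaffold_id][m.s_start : m.s_end]
    return reverse_complement(seq) if m.strand == "-" else seq


def _junction_interval(m: MdsCandidate, length: int, side: str) -> tuple[int, int]:
    """Scaffold interval of the terminal ``length`` bp of an MDS, at its
    transcript-orientation 'end' or 'start' side."""
    if side == "end":
        return (m.s_end - length, m.s_end) if m.strand == "+" else (m.s_start, m.s_start + length)
    return (m.s_start, m.s_start + length) if m.strand == "+" else (m.s_end - length, m.s_end)


def detect_pointers(mds: list[MdsCandidate], scaffolds: dict[str, str]) -> list[Pointer]:
    """Pointers between adjacent (by transcript coordinate) MDS candidates.

    The candidate pointer length is the transcript-interval overlap of the
    pair; a pointer is emitted only when the germline sequence at the two
    junction copies is identical. Zero overlap means no pointer.
    """
    ordered = sorted(mds, key=lambda m: (m.t_start, m.t_end))
    pointers: list[Pointer] = []
    for i in range(len(ordered) - 1):
        left, right = ordered[i], ordered[i + 1]
        overlap = left.t_end - right.t_start
        if overlap <= 0:
            continue
        left_seq = _segment_in_transcript_orientation(left, scaffolds)[-overlap:]
        right_seq = _segment_in_transcript_orientation(right, scaffolds)[:overlap]
        if left_seq != right_seq:
            continue
        l0, l1 = _junction_interval(left, overlap, "end")
        r0, r1 = _junction_interval(right, overlap, "start")
        pointers.append(
            Pointer(
                transcript_id=left.transcript_id,
                between=(i + 1, i + 2),
                length=overlap,
                sequence=left_seq,
                left_scaffold_id=left.scaffold_id,
                left_start=l0,
                left_end=l1,
                right_scaffold_id=right.scaffold_id,
                right_start=r0,
                right_end=r1,
            )
        )
    return pointers


def discriminate_gap(gap_sequence: str, pointer_present: bool) -> str:
    """IES vs intron call for one inter-MDS gap, read on the coding strand.

    IES: pointer present and the gap is not bounded by canonical GT...AG
    intron dinucleotides. Intron: no pointer and GT...AG. Anything else is
    ambiguous and excluded from IES statistics.
    """
    gt_ag = len(gap_sequence) >= 4 and gap_sequence.startswith("GT") and gap_sequence.endswith("AG")
    if pointer_present and not gt_ag:
        return "IES"
    if not pointer_present and gt_ag:
        return "intron"
    return "ambiguous"


def annotate_gaps(
    mds: list[MdsCandidate],
    pointers: list[Pointer],
    scaffolds: dict[str, str],
) -> list[GapAnnotation]:
    """Germline gaps between consecutive-by-transcript MDSs on one scaffold."""
    ordered = sorted(mds, key=lambda m: (m.t_start, m.t_end))
    with_pointer = {p.between[0] - 1 for p in pointers}
    gaps: list[GapAnnotation] = []
    for i in range(len(ordered) - 1):
        a, b = ordered[i], ordered[i + 1]
        if a.scaffold_id != b.scaffold_id:
            continue
        lo = min(a.s_end, b.s_end)
        hi = max(a.s_start, b.s_start)
        if hi <= lo:
            continue  # scaffold-overlapping segments leave no gap
        seq = scaffolds[a.scaffold_id][lo:hi]
        if a.strand == "-" and b.strand == "-":
            seq = reverse_complement(seq)
        kind = discriminate_gap(seq, i in with_pointer)
        gaps.append(GapAnnotation(a.scaffold_id, lo, hi, kind, i in with_pointer))
    return gaps


def classify_locus(model: LocusModel) -> str:
    """Order/strand classification of one locus model (sets category and the
    multi-scaffold flag in place and returns the category)."""
    if not model.mds:
        raise IntegrityError(
            f"locus {model.transcript_id!r} has no retained MDS candidates"
        )
    ordered = sorted(model.mds, key=lambda m: (m.t_start, m.t_end))
    entries = [(m.scaffold_id, m.s_start, m.strand) for m in ordered]
    model.multi_scaffold = len({m.scaffold_id for m in ordered}) > 1
    model.category = SCRAMBLED if arrangement_is_scrambled(entries) else NONSCRAMBLED
    return model.category


def build_locus_models(
    mapped: dict[str, list],
    scaffolds: dict[str, str],
) -> list[LocusModel]:
    """Chain, pointer-annotate, gap-annotate and classify every mapped
    transcript."""
    from .mapping import chain_to_mds

    models = []
    for tid in sorted(mapped):
        cands = chain_to_mds(mapped[tid])
        if not cands:
            continue
        model = LocusModel(transcript_id=tid, mds=cands)
        model.pointers = detect_pointers(cands, scaffolds)
        model.gaps = annotate_gaps(cands, model.pointers, scaffolds)
        classify_locus(model)
        models.append(model)
    return models


def detect_alt_processing(models: list[LocusModel]) -> list[tuple[str, str]]:
    """Alternative-processing events among locus models.

    Two transcripts form an event iff, on some shared scaffold, at least one
    pair of their MDS intervals overlaps reciprocally by >= 50% while their
    germline MDS footprints differ. Identical footprints are duplicates, not
    events. Returns sorted transcript-id pairs; flags the models involved.
    """

    footprints = [
        sorted((x.scaffold_id, x.s_start, x.s_end, x.strand) for x in m.mds)
        for m in models
    ]
    by_scaffold: dict[str, list[int]] = {}
    for i, m in enumerate(models):
        for sid in m.scaffold_ids:
            by_scaffold.setdefault(sid, []).append(i)
    pairs = {
        (i, j)
        for idxs in by_scaffold.values()
        for k1, i in enumerate(idxs)
        for j in idxs[k1 + 1 :]
    }
    events = []
    for i, j in sorted(pairs):
        a, b = models[i], models[j]
        fa, fb = footprints[i], footprints[j]
        if fa == fb:
            continue
        shared = False
        for sid_a, s0a, s1a, _ in fa:
            for sid_b, s0b, s1b, _ in fb:
                if sid_a != sid_b:
                    continue
                ov = min(s1a, s1b) - max(s0a, s0b)
                if ov <= 0:
                    continue
                if ov >= 0.5 * (s1a - s0a) and ov >= 0.5 * (s1b - s0b):
                    shared = True
                    break
            if shared:
                break
        if shared:
            a.alt_processed = b.alt_processed = True
            events.append(tuple(sorted((a.transcript_id, b.transcript_id))))
    return sorted(set(events))


# ---------------------------------------------------------------------------
# statistics


def _locus_features(model: LocusModel, scaffolds: dict[str, str], ies_flank: int = 40):
    ordered = sorted(model.mds, key=lambda m: (m.t_start, m.t_end))
    mds_lens = [m.length for m in ordered]
    ptr_lens = [p.length for p in model.pointers]
    inter = [g.length for g in model.gaps]
    # GC over each MDS plus its adjacent germline flanks (up to ies_flank bp),
    # the boundary-window framing of the composition profile
    gc_vals = []
    for m in ordered:
        scaf = scaffolds[m.scaffold_id]
        lo = max(0, m.s_start - ies_flank)
        hi = min(len(scaf), m.s_end + ies_flank)
        gc_vals.append(gc_fraction(scaf[lo:hi]))
    return {
        "mds_count": float(len(ordered)),
        "mds_length": float(np.mean(mds_lens)) if mds_lens else np.nan,
        "pointer_length": float(np.mean(ptr_lens)) if ptr_lens else np.nan,
        "mds_ies_gc": 100.0 * float(np.mean(gc_vals)) if gc_vals else np.nan,
        "inter_pointer_distance": float(np.mean(inter)) if inter else np.nan,
    }


@dataclass
class CategoryStats:
    """Per-category feature summaries (means and medians, Table-1 style)."""

    n_transcripts: dict[str, int]
    mean: dict[str, dict[str, float]]  # category -> feature -> mean
    median: dict[str, dict[str, float]]
    samples: dict[str, dict[str, list[float]]]
    p_values: dict[str, float] = field(default_factory=dict)


def summarize_categories(
    models: list[LocusModel],
    scaffolds: dict[str, str],
    ies_flank: int = 40,
) -> CategoryStats:
    """Per-category means/medians of MDS count/length, pointer length,
    MDS+flank GC, and the scaffold-coordinate distance between consecutive
    (by transcript order) MDSs on the same scaffold."""
    samples: dict[str, dict[str, list[float]]] = {}
    counts: dict[str, int] = {}
    for model in models:
        feats = _locus_features(model, scaffolds, ies_flank)
        cat = model.category
        counts[cat] = counts.get(cat, 0) + 1
        bucket = samples.setdefault(cat, {f: [] for f in FEATURES})
        for f in FEATURES:
            if not np.isnan(feats[f]):
                bucket[f].append(feats[f])
    mean: dict[str, dict[str, float]] = {}
    median: dict[str, dict[str, float]] = {}
    for cat, bucket in samples.items():
        mean[cat] = {}
        median[cat] = {}
        for f, vals in bucket.items():
            if vals:
                mean[cat][f] = float(np.mean(vals))
                median[cat][f] = float(np.median(vals))
    for cat in (NONSCRAMBLED, SCRAMBLED):
        if cat not in counts:
            warnings.warn(f"no loci in category {cat!r}; stats omitted", stacklevel=2)
    return CategoryStats(counts, mean, median, samples)


def compare_categories(stats: CategoryStats) -> dict[str, float]:
    """Two-sided Mann-Whitney U per feature between scrambled and
    nonscrambled samples (exact null distribution for small untied samples,
    normal approximation otherwise). All-tied samples give p = 1."""
    out: dict[str, float] = {}
    a_all = stats.samples.get(SCRAMBLED, {})
    b_all = stats.samples.get(NONSCRAMBLED, {})
    for f in FEATURES:
        a, b = a_all.get(f, []), b_all.get(f, [])
        if len(a) < 2 or len(b) < 2:
            continue
        if len(set(a) | set(b)) == 1:
            out[f] = 1.0
            continue
        method = "exact" if (len(a) < 20 and len(b) < 20 and len(set(a + b)) == len(a) + len(b)) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out[f] = float(res.pvalue)
    stats.p_values = out
    return out


def category_shares(counts: dict[str, int]) -> dict[str, float]:
    """Fraction of mapped loci per category (e.g. scrambled 1544 of 5019)."""
    total = sum(counts.values())
    if total <= 0:
        raise ParameterError("category_shares requires a positive total")
    return {cat: n / total for cat, n in counts.items()}


@dataclass
class GenomeSizeEstimate:
    low_mbp: float
    high_mbp: float
    genes_per_mbp: float


def estimate_genome_size(
    n_mapped_genes: int,
    mapped_mbp: float,
    gene_count_range: tuple[float, float],
) -> GenomeSizeEstimate:
    """Gene-density extrapolation of germline genome size.

    density = mapped genes / mapped Mbp; the size bounds are the assumed
    total gene count bounds divided by that density. Bounds are returned in
    ascending order.
    """
    if n_mapped_genes <= 0:
        raise ParameterError("n_mapped_genes must be > 0")
    if mapped_mbp <= 0:
        raise ParameterError("mapped_mbp must be > 0")
    lo, hi = sorted(float(g) for g in gene_count_range)
    if lo <= 0:
        raise ParameterError("gene_count_range entries must be > 0")
    density = n_mapped_genes / mapped_mbp
    return GenomeSizeEstimate(lo / density, hi / density, density)
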