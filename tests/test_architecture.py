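"""Pointer detection, gap discrimination, classification, statistics."""

import numpy as np
import pytest
from scipy import stats as sps

import scramblescan as ss
from scramblescan.architecture import (
    CategoryStats,
    LocusModel,
    annotate_gaps,
    classify_locus,
    compare_categories,
    detect_alt_processing,
    detect_pointers,
    discriminate_gap,
    estimate_genome_size,
    summarize_categories,
)
from scramblescan.mapping import MdsCandidate
from scramblescan.sequtil import random_sequence, reverse_complement

from .oracles import permutation_rank_test


def _cand(t0, t1, s0, s1, sid="s", strand="+", tid="t"):
    return MdsCandidate(tid, sid, t0, t1, s0, s1, strand, 100.0, t1 - t0)


def _planted_pointer_scaffold(ptr_len=6, seed=0):
    """Two MDSs whose transcript intervals overlap by ptr_len; the pointer
    appears once at the end of MDS1's copy and once at the start of MDS2's."""
    rng = np.random.default_rng(seed)
    T = random_sequence(rng, 200, 0.4)
    m1, m2 = T[:100], T[100 - ptr_len :]
    ies = random_sequence(rng, 50, 0.3)
    scaf = "TT" + m1 + ies + m2 + "TT"
    c1 = _cand(0, 100, 2, 102)
    c2 = _cand(100 - ptr_len, 200, 102 + 50, 102 + 50 + len(m2))
    return T, scaf, c1, c2


def test_pointer_detected_with_length_and_sequence():
    T, scaf, c1, c2 = _planted_pointer_scaffold(6)
    ptrs = detect_pointers([c1, c2], {"s": scaf})
    assert len(ptrs) == 1
    p = ptrs[0]
    assert p.length == 6
    assert p.sequence == T[94:100]
    assert scaf[p.left_start : p.left_end] == scaf[p.right_start : p.right_end]


def test_abutting_intervals_have_no_pointer():
    c1 = _cand(0, 100, 0, 100)
    c2 = _cand(100, 200, 150, 250)
    assert detect_pointers([c1, c2], {"s": "A" * 300}) == []


def test_mismatched_junction_copies_suppress_pointer():
    T, scaf, c1, c2 = _planted_pointer_scaffold(6)
    # corrupt the second copy
    pos = c2.s_start
    scaf = scaf[:pos] + ("A" if scaf[pos] != "A" else "C") + scaf[pos + 1 :]
    assert detect_pointers([c1, c2], {"s": scaf}) == []


def test_planted_pointers_recovered_from_simulator(small_dataset, small_result):
    by_tid = {m.transcript_id: m for m in small_result.models}
    for truth in small_dataset.truth:
        model = by_tid.get(truth.transcript_ids[0])
        if model is None:
            continue
        detected = {(p.length, p.sequence) for p in model.pointers}
        for pt in truth.pointer_records:
            assert (pt.length, pt.sequence) in detected


@pytest.mark.parametrize(
    "gap,pointer,expected",
    [
        ("GTAAGTCCTTTTAG", False, "intron"),
        ("AACCTGGGGGTAA", True, "IES"),
        ("GTAAGTCCTTTTAG", True, "ambiguous"),
        ("AACCTGGGGGTAA", False, "ambiguous"),
    ],
)
def test_gap_discrimination(gap, pointer, expected):
    assert discriminate_gap(gap, pointer) == expected


def test_minus_strand_gap_read_on_coding_strand():
    """A gap between two minus-strand MDSs is GT...AG on the coding strand,
    i.e. CT...AC on the scaffold."""
    gap = reverse_complement("GTAAGCCTTAG")
    scaf = "A" * 50 + gap + "A" * 50
    a = _cand(0, 40, 50 + len(gap), 50 + len(gap) + 40, strand="-")
    b = _cand(40, 80, 10, 50, strand="-")
    gaps = annotate_gaps([a, b], [], {"s": scaf})
    assert len(gaps) == 1
    assert gaps[0].kind == "intron"


def _model(cands):
    return LocusModel(transcript_id="t", mds=cands)


def test_consecutive_plus_strand_is_nonscrambled():
    m = _model([_cand(0, 100, 0, 100), _cand(95, 200, 200, 305), _cand(195, 300, 400, 505)])
    assert classify_locus(m) == "nonscrambled"
    assert not m.multi_scaffold


def test_permuted_order_is_scrambled():
    m = _model([_cand(0, 100, 0, 100), _cand(95, 200, 400, 505), _cand(195, 300, 200, 305)])
    assert classify_locus(m) == "scrambled"


def test_inverted_mds_is_scrambled():
    m = _model([_cand(0, 100, 0, 100), _cand(95, 200, 200, 305, strand="-")])
    assert classify_locus(m) == "scrambled"


def test_descending_all_minus_is_nonscrambled():
    """A consistently descending minus-strand chain is the reverse
    complement of an ordered locus."""
    m = _model(
        [_cand(0, 100, 400, 500, strand="-"), _cand(95, 200, 200, 305, strand="-")]
    )
    assert classify_locus(m) == "nonscrambled"


def test_multi_scaffold_chains_classified_per_scaffold():
    m = _model(
        [
            _cand(0, 100, 0, 100, sid="sA"),
            _cand(95, 200, 200, 305, sid="sA"),
            _cand(195, 300, 50, 155, sid="sB"),
        ]
    )
    assert classify_locus(m) == "nonscrambled"
    assert m.multi_scaffold


def test_classification_invariant_to_input_order():
    rng = np.random.default_rng(0)
    cands = [
        _cand(0, 100, 0, 100),
        _cand(95, 200, 400, 505),
        _cand(195, 300, 200, 305),
    ]
    base = classify_locus(_model(list(cands)))
    for _ in range(5):
        perm = [cands[i] for i in rng.permutation(3)]
        assert classify_locus(_model(perm)) == base


def test_classification_invariant_to_scaffold_reverse_complement():
    """Reverse-complementing a scaffold flips strands and coordinates but
    preserves the category."""
    L = 1000
    for cands in (
        [_cand(0, 100, 0, 100), _cand(95, 200, 200, 305)],
        [_cand(0, 100, 200, 300), _cand(95, 200, 0, 105)],
        [_cand(0, 100, 0, 100), _cand(95, 200, 200, 305, strand="-")],
    ):
        flipped = [
            _cand(
                c.t_start,
                c.t_end,
                L - c.s_end,
                L - c.s_start,
                strand="-" if c.strand == "+" else "+",
            )
            for c in cands
        ]
        assert classify_locus(_model(flipped)) == classify_locus(_model(cands))


def test_empty_locus_is_integrity_error():
    with pytest.raises(ss.IntegrityError):
        classify_locus(_model([]))


# ---------------------------------------------------------------------------
# alternative processing


def test_alt_processing_shared_prefix_detected():
    a = _model([_cand(0, 100, 0, 100, tid="t1"), _cand(95, 200, 200, 305, tid="t1"),
                _cand(195, 300, 400, 505, tid="t1")])
    b = LocusModel(
        transcript_id="t2",
        mds=[_cand(0, 100, 0, 100, tid="t2"), _cand(95, 200, 200, 305, tid="t2")],
    )
    a.transcript_id = "t1"
    events = detect_alt_processing([a, b])
    assert events == [("t1", "t2")]
    assert a.alt_processed and b.alt_processed


def test_disjoint_footprints_no_event():
    a = LocusModel("t1", [_cand(0, 100, 0, 100, tid="t1")])
    b = LocusModel("t2", [_cand(0, 100, 5000, 5100, tid="t2")])
    assert detect_alt_processing([a, b]) == []


def test_identical_footprints_are_duplicates_not_events():
    a = LocusModel("t1", [_cand(0, 100, 0, 100, tid="t1")])
    b = LocusModel("t2", [_cand(0, 100, 0, 100, tid="t2")])
    assert detect_alt_processing([a, b]) == []


def test_simulated_alt_isoforms_detected_without_dedup():
    """With redundancy removal disabled, planted alternative-processing
    isoforms surface as events on their shared germline locus."""
    ds = ss.simulate_dataset(
        ss.SimulationConfig(
            n_loci=40, scrambled_fraction=1.0, alt_processing_prob=1.0, rng_seed=9
        )
    )
    alt_loci = [t for t in ds.truth if t.category == "alt_processed"]
    assert alt_loci
    res = ss.run_pipeline(
        ss.PipelineConfig(dedup=False), ds.scaffolds, ds.transcripts, truth=ds.truth
    )
    paired = {tid for ev in res.alt_events for tid in ev}
    for t in alt_loci:
        assert set(t.transcript_ids) <= paired


# ---------------------------------------------------------------------------
# statistics


def test_single_locus_mean_median():
    scaf = "G" * 400
    m = _model([_cand(0, 100, 0, 100), _cand(100, 300, 150, 350)])
    classify_locus(m)
    stats = summarize_categories([m], {"s": scaf})
    assert stats.mean["nonscrambled"]["mds_length"] == pytest.approx(150.0)
    assert stats.median["nonscrambled"]["mds_length"] == pytest.approx(150.0)
    assert stats.mean["nonscrambled"]["mds_count"] == 2


def test_missing_category_warns_and_is_omitted():
    m = _model([_cand(0, 100, 0, 100)])
    classify_locus(m)
    with pytest.warns(UserWarning, match="scrambled"):
        stats = summarize_categories([m], {"s": "G" * 200})
    assert "scrambled" not in stats.mean


def _stats_from_samples(a, b, feature="mds_length"):
    samples = {
        "scrambled": {feature: list(a)},
        "nonscrambled": {feature: list(b)},
    }
    return CategoryStats({"scrambled": len(a), "nonscrambled": len(b)}, {}, {}, samples)


def test_identical_samples_not_significant():
    s = _stats_from_samples([1.0, 2.0, 3.0] * 10, [1.0, 2.0, 3.0] * 10)
    p = compare_categories(s)["mds_length"]
    assert p > 0.05


def test_all_tied_samples_give_p_one():
    s = _stats_from_samples([2.0] * 5, [2.0] * 5)
    assert compare_categories(s)["mds_length"] == 1.0


def test_shifted_samples_highly_significant_and_match_permutation_oracle():
    rng = np.random.default_rng(1)
    a = rng.lognormal(3, 0.4, 100)
    b = 5.0 * rng.lognormal(3, 0.4, 100)
    s = _stats_from_samples(a, b)
    p = compare_categories(s)["mds_length"]
    assert p < 1e-3
    a30, b30 = a[:15], b[:15] / 5 * 1.8  # moderate shift, n<=30
    s30 = _stats_from_samples(a30, b30)
    p_mw = compare_categories(s30)["mds_length"]
    p_perm = permutation_rank_test(a30, b30, n_perm=10000, seed=2)
    assert abs(p_mw - p_perm) < 3 * np.sqrt(p_perm * (1 - p_perm) / 10000) + 0.01


def test_tiny_samples_use_exact_distribution():
    s = _stats_from_samples([1.0, 2.0], [3.0, 4.0])
    p = compare_categories(s)["mds_length"]
    # full enumeration: C(4,2)=6 assignments, the observed split is the most
    # extreme in both directions -> two-sided p = 2/6
    assert p == pytest.approx(2 / 6)


def test_inter_pointer_distance_is_scaffold_gap(small_dataset, small_result):
    """The distance feature equals the planted inter-MDS separation."""
    by_tid = {m.transcript_id: m for m in small_result.models}
    checked = 0
    for truth in small_dataset.truth:
        if truth.category != "nonscrambled" or truth.intron_records:
            continue
        model = by_tid.get(truth.transcript_ids[0])
        if model is None or len(model.mds) < 2:
            continue
        ordered = sorted(model.mds, key=lambda c: c.t_start)
        gaps = [g.length for g in model.gaps]
        expected = [
            (b.s_start - a.s_end) if a.strand == "+" else (a.s_start - b.s_end)
            for a, b in zip(ordered, ordered[1:])
            if a.scaffold_id == b.scaffold_id
        ]
        assert gaps == expected
        checked += 1
    assert checked > 0


# ---------------------------------------------------------------------------
# genome size


def test_genome_size_printed_inputs():
    est = estimate_genome_size(5019, 32.7, (15000, 22500))
    assert est.genes_per_mbp == pytest.approx(153.49, abs=0.01)
    assert est.low_mbp == pytest.approx(97.73, abs=0.05)
    assert est.high_mbp == pytest.approx(146.59, abs=0.05)


def test_genome_size_identity_case():
    est = estimate_genome_size(100, 1.0, (100, 100))
    assert (est.low_mbp, est.high_mbp) == (1.0, 1.0)


def test_genome_size_bounds_reordered():
    est = estimate_genome_size(5019, 32.7, (22500, 15000))
    assert est.low_mbp < est.high_mbp


def test_genome_size_invalid_inputs():
    with pytest.raises(ss.ParameterError):
        estimate_genome_size(0, 32.7, (1, 2))
    with pytest.raises(ss.ParameterError):
        estimate_genome_size(10, 0.0, (1, 2))
    with pytest.raises(ss.ParameterError):
        estimate_genome_size(10, 1.0, (0, 2))
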