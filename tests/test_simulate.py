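"""Generator contract: planted architecture, determinism, round trips."""

import numpy as np
import pytest
from scipy import stats as sps

import scramblescan as ss
from scramblescan.distributions import (
    FixedLength,
    LogNormalLength,
    PerCategory,
    PointerLengthDist,
    ShiftedGeometricCount,
)
from scramblescan.simulate import MdsSegmentTruth, LocusTruth


def all_labels(ds):
    return [lab for t in ds.truth for lab in t.transcript_labels.values()]


@pytest.mark.parametrize(
    "fraction,expected",
    [(0.0, {"nonscrambled"}), (1.0, {"scrambled"})],
)
def test_degenerate_scrambled_fraction(fraction, expected):
    ds = ss.simulate_dataset(
        ss.SimulationConfig(n_loci=10, scrambled_fraction=fraction, rng_seed=1)
    )
    assert len(ds.truth) == 10
    assert set(all_labels(ds)) == expected


def test_scrambled_fraction_within_binomial_ci():
    """At n=1000 the planted scrambled share stays inside the 99% binomial
    interval around the configured fraction."""
    n, p = 1000, 0.31
    ds = ss.simulate_dataset(
        ss.SimulationConfig(n_loci=n, scrambled_fraction=p, rng_seed=7)
    )
    n_scr = sum(1 for t in ds.truth if t.category in ("scrambled", "alt_processed"))
    lo, hi = sps.binom.ppf([0.005, 0.995], n, p)
    assert lo <= n_scr <= hi


def test_roundtrip_reconstruction_matches_emitted_transcripts(small_dataset):
    ds = small_dataset
    for t in ds.truth:
        for tid in t.transcript_ids:
            assert (
                ss.reconstruct_transcript(t, ds.scaffolds, tid)
                == ds.transcripts[tid]
            )


def test_unspliced_form_retains_introns(small_dataset):
    ds = small_dataset
    with_intron = [t for t in ds.truth if t.intron_records]
    assert with_intron, "fixture should plant introns"
    for t in with_intron:
        tid = t.transcript_ids[0]
        mac = ss.reconstruct_transcript(t, ds.scaffolds, tid, splice_introns=False)
        spliced = ss.reconstruct_transcript(t, ds.scaffolds, tid)
        extra = sum(i1 - i0 for _, i0, i1 in t.intron_records)
        assert len(mac) == len(spliced) + extra
        assert spliced == ds.transcripts[tid]


def _toy_truth(scaffold, segments, tid="veg_t0"):
    recs = [
        MdsSegmentTruth(tid, i + 1, 0, t0, t1, "s0", s0, s1, strand)
        for i, (t0, t1, s0, s1, strand) in enumerate(segments)
    ]
    return LocusTruth(
        "locus0", ["s0"], [tid], recs, [], [], "nonscrambled",
        {tid: "nonscrambled"}, {tid: "veg"},
    )


def test_reconstruct_single_mds_is_verbatim_substring():
    scaf = "ACGTACGTGGCCTTAAGGCATG"
    truth = _toy_truth(scaf, [(0, 10, 5, 15, "+")])
    assert ss.reconstruct_transcript(truth, {"s0": scaf}) == scaf[5:15]


def test_reconstruct_pointer_dedup_arithmetic():
    """Two MDSs overlapping by a 6-bp pointer concatenate to L1+L2-6."""
    rng = np.random.default_rng(0)
    from scramblescan.sequtil import random_sequence

    T = random_sequence(rng, 194, 0.4)  # 100 + 100 - 6
    m1, m2 = T[:100], T[94:]
    scaf = "TTTT" + m1 + "GGGGGGGG" + m2 + "TTTT"
    truth = _toy_truth(
        scaf,
        [(0, 100, 4, 104, "+"), (94, 194, 112, 212, "+")],
    )
    rec = ss.reconstruct_transcript(truth, {"s0": scaf})
    assert len(rec) == 100 + 100 - 6
    assert rec == T


def test_reconstruct_inverted_mds_uses_reverse_complement():
    from scramblescan.sequtil import reverse_complement

    scaf = "AAAA" + "ACGGTTCAGGTCAACGTTGGCCATTGCAGT" + "AAAA"
    truth = _toy_truth(scaf, [(0, 30, 4, 34, "-")])
    assert ss.reconstruct_transcript(truth, {"s0": scaf}) == reverse_complement(
        scaf[4:34]
    )


def test_reconstruct_out_of_bounds_raises():
    truth = _toy_truth("ACGT" * 10, [(0, 30, 20, 50, "+")])
    with pytest.raises(ss.IntegrityError):
        ss.reconstruct_transcript(truth, {"s0": "ACGT" * 10})


def test_seed_determinism(tmp_path):
    cfg = ss.SimulationConfig(n_loci=15, rng_seed=42)
    p1 = ss.write_dataset(ss.simulate_dataset(cfg), tmp_path / "a")
    p2 = ss.write_dataset(ss.simulate_dataset(cfg), tmp_path / "b")
    for key in p1:
        assert open(p1[key]).read() == open(p2[key]).read()


def test_write_read_write_is_byte_identical(tmp_path, small_dataset):
    paths = ss.write_dataset(small_dataset, tmp_path / "one")
    truth_back = ss.read_truth(paths["truth"])
    rebuilt = ss.SyntheticDataset(
        small_dataset.scaffolds,
        small_dataset.transcripts,
        truth_back,
        small_dataset.family_truth,
    )
    paths2 = ss.write_dataset(rebuilt, tmp_path / "two")
    assert open(paths["truth"]).read() == open(paths2["truth"]).read()


def test_empty_dataset_round_trip(tmp_path):
    cfg = ss.SimulationConfig(n_loci=0, n_somatic_contaminants=0, rng_seed=0)
    ds = ss.simulate_dataset(cfg)
    paths = ss.write_dataset(ds, tmp_path)
    truth = ss.read_truth(paths["truth"])
    assert truth == []
    assert open(paths["truth"]).readline().startswith("#")


def test_single_locus_dataset_files(tmp_path):
    ds = ss.simulate_dataset(
        ss.SimulationConfig(n_loci=1, scrambled_fraction=0.0, n_somatic_contaminants=0, rng_seed=3)
    )
    paths = ss.write_dataset(ds, tmp_path)
    assert len(paths) == 4
    lines = [l for l in open(paths["truth"]) if not l.startswith("#")]
    assert sum(1 for l in lines if l.split("\t")[1] == "transcript") == 1


def test_planted_moments_within_three_se():
    """Empirical per-category MDS count/length and pointer length stay
    within 3 standard errors of the configured distribution means."""
    cfg = ss.SimulationConfig(n_loci=600, rng_seed=3)
    ds = ss.simulate_dataset(cfg)
    for scrambled in (False, True):
        cats = ("scrambled", "alt_processed") if scrambled else ("nonscrambled", "multi_scaffold")
        loci = [t for t in ds.truth if t.category in cats]
        base = [t.transcript_ids[0] for t in loci]
        counts = [
            len({r.order_index for r in t.mds_records if r.transcript_id == tid})
            for t, tid in zip(loci, base)
        ]
        mds_lens = []
        for t, tid in zip(loci, base):
            spans = {}
            for r in t.mds_records:
                if r.transcript_id != tid:
                    continue
                lo, hi = spans.get(r.order_index, (r.t_start, r.t_end))
                spans[r.order_index] = (min(lo, r.t_start), max(hi, r.t_end))
            mds_lens.extend(hi - lo for lo, hi in spans.values())
        ptr_lens = [p.length for t in loci for p in t.pointer_records]
        for sample, dist in (
            (counts, cfg.mds_count_dist.for_category(scrambled)),
            (mds_lens, cfg.mds_len_dist.for_category(scrambled)),
            (ptr_lens, cfg.pointer_len_dist.for_category(scrambled)),
        ):
            arr = np.asarray(sample, dtype=float)
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - dist.mean) <= 3 * se + 1e-9, (
                dist,
                arr.mean(),
            )


def test_lognormal_matches_printed_mean_and_median():
    d = LogNormalLength(1454.89, 805, minimum=1)
    rng = np.random.default_rng(0)
    draws = d.sample(rng, 200000).astype(float)
    assert np.isclose(draws.mean(), 1454.89, rtol=0.02)
    assert np.isclose(np.median(draws), 805, rtol=0.02)


def test_invalid_config_names_field():
    with pytest.raises(ss.ParameterError, match="scrambled_fraction"):
        ss.SimulationConfig(scrambled_fraction=1.5)
    with pytest.raises(ss.ParameterError, match="gc_mds"):
        ss.SimulationConfig(gc_mds=0.0)
    with pytest.raises(ss.ParameterError, match="telomere_repeat"):
        ss.SimulationConfig(telomere_repeat="CCCX")
    with pytest.raises(ss.ParameterError):
        ShiftedGeometricCount(1.0, minimum=1)
    with pytest.raises(ss.ParameterError):
        LogNormalLength(100, 200)
    with pytest.raises(ss.ParameterError):
        FixedLength(0)
    with pytest.raises(ss.ParameterError):
        PointerLengthDist(1)


def test_truth_transcripts_and_scaffolds_exist(small_dataset):
    ds = small_dataset
    for t in ds.truth:
        for tid in t.transcript_ids:
            assert tid in ds.transcripts
        for sid in t.scaffold_ids:
            assert sid in ds.scaffolds
        for rec in t.mds_records:
            assert 0 <= rec.s_start < rec.s_end <= len(ds.scaffolds[rec.scaffold_id])


def test_mds_intervals_tile_with_pointer_overlaps(small_dataset):
    """Consecutive MDS transcript intervals overlap by exactly the planted
    pointer length; scaffold intervals are mutually disjoint per scaffold."""
    for t in small_dataset.truth:
        tid = t.transcript_ids[0]
        spans = {}
        for r in t.mds_records:
            if r.transcript_id != tid:
                continue
            lo, hi = spans.get(r.order_index, (r.t_start, r.t_end))
            spans[r.order_index] = (min(lo, r.t_start), max(hi, r.t_end))
        ptr = {p.between[0]: p.length for p in t.pointer_records}
        orders = sorted(spans)
        for n in orders[:-1]:
            overlap = spans[n][1] - spans[n + 1][0]
            assert overlap == ptr.get(n, 0)
        by_scaffold = {}
        for r in t.mds_records:
            if r.transcript_id == tid:
                by_scaffold.setdefault(r.scaffold_id, []).append((r.s_start, r.s_end))
        for ivals in by_scaffold.values():
            ivals.sort()
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                assert a1 <= b0


def test_scrambled_truth_satisfies_order_strand_criterion(small_dataset):
    for t in small_dataset.truth:
        for tid, label in t.transcript_labels.items():
            recs = sorted(
                (r for r in t.mds_records if r.transcript_id == tid),
                key=lambda r: (r.t_start, r.sub_index),
            )
            first = {}
            for r in recs:
                first.setdefault(r.order_index, r)
            entries = [
                (r.scaffold_id, r.s_start, r.strand)
                for r in sorted(first.values(), key=lambda r: r.t_start)
            ]
            assert ss.arrangement_is_scrambled(entries) == (label == "scrambled")
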