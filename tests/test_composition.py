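"""GC windows, boundary profiles and the extreme-GC scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scramblescan as ss
from scramblescan.composition import (
    BoundaryContext,
    boundary_profile,
    boundary_shift,
    extreme_gc_scan,
    gc_windows,
)
from scramblescan.sequtil import random_sequence, reverse_complement

from .oracles import naive_gc_windows


def test_all_g_windows_are_one():
    assert all(gc == 1.0 for _, gc in gc_windows("GGGGGG"))


def test_hand_enumerated_windows():
    assert gc_windows("ATGCAT", 3, 2) == [(1.0, pytest.approx(1 / 3)), (3.0, pytest.approx(2 / 3))]


def test_ambiguous_windows_skipped():
    out = gc_windows("ATNTA", 3, 2)
    assert out == []  # both windows contain the N
    assert gc_windows("ATNTAGG", 3, 2) == [(5.0, pytest.approx(2 / 3))]


def test_sequence_shorter_than_window_is_empty():
    assert gc_windows("AT", 3, 2) == []


def test_invalid_window_params():
    with pytest.raises(ss.ParameterError):
        gc_windows("ACGT", 0, 2)
    with pytest.raises(ss.ParameterError):
        gc_windows("ACGT", 3, 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGTN", min_size=0, max_size=60),
    st.integers(1, 6),
    st.integers(1, 4),
)
def test_gc_windows_match_naive_oracle(seq, window, step):
    assert gc_windows(seq, window, step) == naive_gc_windows(seq, window, step)


# ---------------------------------------------------------------------------
# boundary profiles


def _step_boundaries(n, mds="G" * 40, ies="A" * 40):
    scaffolds = {f"b{i}": mds + ies for i in range(n)}
    bounds = [BoundaryContext(f"b{i}", len(mds), "left") for i in range(n)]
    return scaffolds, bounds


def test_step_profile_from_planted_compartments():
    scaffolds, bounds = _step_boundaries(5)
    prof = boundary_profile(bounds, scaffolds)
    mds_side = prof.mean_gc[prof.rel_positions < 0]
    ies_side = prof.mean_gc[prof.rel_positions > 0]
    assert np.all(mds_side == 1.0)
    assert np.all(ies_side == 0.0)
    assert boundary_shift(prof) == pytest.approx(1.0)


def test_profile_requires_two_boundaries():
    scaffolds, bounds = _step_boundaries(1)
    with pytest.raises(ss.InputError):
        boundary_profile(bounds[:1], scaffolds)


def test_window_means_match_naive_recomputation():
    """Each reported window mean is the arithmetic mean of the per-boundary
    window values."""
    rng = np.random.default_rng(5)
    scaffolds = {
        f"b{i}": random_sequence(rng, 40, 0.6) + random_sequence(rng, 40, 0.2)
        for i in range(20)
    }
    bounds = [BoundaryContext(sid, 40, "left") for sid in scaffolds]
    prof = boundary_profile(bounds, scaffolds)
    for rel, mean in zip(prof.rel_positions, prof.mean_gc):
        start = int(rel + 39.5 - 1)  # window center -> local start (window=3)
        vals = []
        for sid in scaffolds:
            win = scaffolds[sid][start : start + 3]
            vals.append(sum(c in "GC" for c in win) / 3)
        assert mean == pytest.approx(np.mean(vals))


def test_ci_halfwidth_scales_with_boundary_count():
    """Quadrupling the number of boundaries halves the mean CI half-width."""
    rng = np.random.default_rng(7)
    def make(n, tag):
        scaffolds = {
            f"{tag}{i}": random_sequence(rng, 40, 0.41) + random_sequence(rng, 40, 0.29)
            for i in range(n)
        }
        bounds = [BoundaryContext(sid, 40, "left") for sid in scaffolds]
        return boundary_profile(bounds, scaffolds)

    small = make(500, "s")
    big = make(2000, "b")
    hw_small = np.mean(small.ci95_high - small.ci95_low)
    hw_big = np.mean(big.ci95_high - big.ci95_low)
    assert hw_small / hw_big == pytest.approx(2.0, rel=0.15)


def test_profile_symmetry_under_reverse_complement():
    """Reverse-complementing every scaffold and flipping orientation flags
    yields the mirrored profile exactly."""
    rng = np.random.default_rng(9)
    scaffolds = {
        f"b{i}": random_sequence(rng, 100, 0.5) for i in range(15)
    }
    bounds = [BoundaryContext(sid, 50, "left") for sid in scaffolds]
    prof = boundary_profile(bounds, scaffolds, flank=30)
    rc = {sid: reverse_complement(seq) for sid, seq in scaffolds.items()}
    rc_bounds = [BoundaryContext(sid, 50, "right") for sid in scaffolds]
    prof_rc = boundary_profile(rc_bounds, rc, flank=30)
    assert np.allclose(prof.rel_positions, prof_rc.rel_positions)
    assert np.allclose(prof.mean_gc, prof_rc.mean_gc)
    assert np.allclose(prof.ci95_low, prof_rc.ci95_low)


def test_truncated_flank_flagged():
    scaffolds = {"b0": "G" * 10 + "A" * 40, "b1": "G" * 40 + "A" * 40}
    bounds = [BoundaryContext("b0", 10, "left"), BoundaryContext("b1", 40, "left")]
    prof = boundary_profile(bounds, scaffolds)
    assert prof.truncated_boundaries == 1


def test_profile_plot_and_tsv_written(tmp_path):
    from scramblescan.composition import plot_profile, write_profile_tsv

    scaffolds, bounds = _step_boundaries(4)
    prof = boundary_profile(bounds, scaffolds)
    png = plot_profile(prof, str(tmp_path / "profile.png"))
    tsv = write_profile_tsv(prof, str(tmp_path / "profile.tsv"))
    assert (tmp_path / "profile.png").stat().st_size > 0
    rows = [l for l in open(tsv) if not l.startswith("#")]
    assert len(rows) == len(prof.rel_positions)


def test_bootstrap_ci_contains_mean():
    scaffolds, bounds = _step_boundaries(30, mds="GGAT" * 10, ies="AATT" * 10)
    prof = boundary_profile(bounds, scaffolds, ci="bootstrap", n_boot=200, seed=1)
    assert np.all(prof.ci95_low <= prof.mean_gc + 1e-12)
    assert np.all(prof.mean_gc <= prof.ci95_high + 1e-12)


def test_planted_shift_recovery_small():
    rng = np.random.default_rng(3)
    scaffolds = {
        f"b{i}": random_sequence(rng, 40, 0.41) + random_sequence(rng, 40, 0.29)
        for i in range(2000)
    }
    bounds = [BoundaryContext(sid, 40, "left") for sid in scaffolds]
    prof = boundary_profile(bounds, scaffolds)
    assert 100 * boundary_shift(prof) == pytest.approx(12.0, abs=1.5)


# ---------------------------------------------------------------------------
# extreme GC scan


def test_uniform_gc_scaffold_has_no_regions():
    res = extreme_gc_scan({"s": "ACGT" * 2000})
    assert res.high == [] and res.low == []


def test_planted_high_island_detected_within_one_window():
    rng = np.random.default_rng(13)
    island = random_sequence(rng, 120, 0.92)
    scaf = random_sequence(rng, 4000, 0.40) + island + random_sequence(rng, 4000, 0.40)
    res = extreme_gc_scan({"s": scaf})
    assert res.high
    top = res.high[0]
    assert top.start <= 4000 + 40 and top.end >= 4120 - 40
    assert abs(top.start - 4000) <= 40 and abs(top.end - 4120) <= 40
    assert top.z_score > 2


def test_short_island_rejected_by_length_rule():
    rng = np.random.default_rng(17)
    island = random_sequence(rng, 30, 0.95)
    scaf = random_sequence(rng, 3000, 0.40) + island + random_sequence(rng, 3000, 0.40)
    res = extreme_gc_scan({"s": scaf})
    assert not any(r.start <= 3000 < r.end for r in res.high)


def test_low_gc_regions_found_symmetrically():
    rng = np.random.default_rng(19)
    island = random_sequence(rng, 150, 0.02)
    scaf = random_sequence(rng, 4000, 0.45) + island + random_sequence(rng, 4000, 0.45)
    res = extreme_gc_scan({"s": scaf})
    assert res.low and res.low[0].direction == "low"
    assert res.low[0].start <= 4040 and res.low[0].end >= 4110


def test_scan_invariant_to_scaffold_order():
    rng = np.random.default_rng(23)
    scaffolds = {
        "a": random_sequence(rng, 3000, 0.4) + random_sequence(rng, 100, 0.95),
        "b": random_sequence(rng, 3000, 0.4),
    }
    res1 = extreme_gc_scan(scaffolds)
    res2 = extreme_gc_scan(dict(reversed(list(scaffolds.items()))))
    key = lambda rs: [(r.scaffold_id, r.start, r.end, r.direction) for r in rs]
    assert key(res1.high) == key(res2.high)
    assert key(res1.low) == key(res2.low)
    assert res1.assembly_mean_gc == res2.assembly_mean_gc


def test_mask_excludes_windows_and_warns_when_total():
    rng = np.random.default_rng(29)
    scaf = random_sequence(rng, 2000, 0.4)
    with pytest.warns(UserWarning, match="mask"):
        res = extreme_gc_scan({"s": scaf}, mask={"s": [(0, 2000)]})
    assert res.n_windows == 0
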