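"""GC composition at germline-soma boundaries and across scaffolds.

Boundary profiling lays each MDS-IES boundary out in a common orientation
(MDS side left, IES side right, reading in the transcript's coding
direction), takes ``flank`` bp on each side (default 40), computes GC in a
sliding window (default 3 bp, 2-bp step) anchored at the boundary, and
aggregates per relative window position across boundaries with a 95%
confidence interval (normal approximation by default; percentile bootstrap
optional).

The genome-wide scan flags maximal runs of scan windows whose GC deviates
from the assembly mean by more than ``z_threshold`` standard deviations,
keeps merged regions longer than 40 bp, and ranks them by length for export
to external homology searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, ParameterError
from .sequtil import encode, reverse_complement


@dataclass
class BoundaryContext:
    """One MDS-IES boundary on a scaffold.

    ``position`` is the first germline-limited (IES-side) base when the MDS
    lies left of the boundary on the forward strand (``mds_side='left'``);
    with ``mds_side='right'`` the extracted window is reverse-complemented so
    the MDS side still ends up on the left of the profile axis.
    """

    scaffold_id: str
    position: int
    mds_side: str = "left"  # 'left' | 'right' on the forward strand


@dataclass
class GcProfile:
    rel_positions: np.ndarray  # window centers relative to the boundary
    mean_gc: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_per_window: np.ndarray
    n_boundaries: int
    window: int
    step: int
    truncated_boundaries: int = 0


def gc_windows(sequence: str, window: int = 3, step: int = 2) -> list[tuple[float, float]]:
    """Sliding-window GC over a sequence, left to right.

    Returns (center, gc) pairs; windows containing ambiguous bases are
    skipped. A sequence shorter than the window yields an empty list.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    if step < 1:
        raise ParameterError("step must be >= 1")
    codes = encode(sequence)
    out = []
    for start in range(0, len(sequence) - window + 1, step):
        chunk = codes[start : start + window]
        if np.any(chunk >= 4):
            continue
        gc = float(np.count_nonzero((chunk == 1) | (chunk == 2))) / window
        out.append((start + (window - 1) / 2.0, gc))
    return out


def _boundary_window_gcs(
    seq_local: str, boundary_local: int, window: int, step: int
) -> list[tuple[float, float]]:
    """Window grid anchored at the boundary so relative centers line up
    across boundaries: left-side windows end at the boundary walking left,
    right-side windows start at it walking right."""
    codes = encode(seq_local)
    out = []

    def emit(start: int) -> None:
        chunk = codes[start : start + window]
        if np.any(chunk >= 4):
            return
        gc = float(np.count_nonzero((chunk == 1) | (chunk == 2))) / window
        center = start + (window - 1) / 2.0
        out.append((center - (boundary_local - 0.5), gc))

    start = boundary_local - window
    while start >= 0:
        emit(start)
        start -= step
    start = boundary_local
    while start + window <= len(seq_local):
        emit(start)
        start += step
    return out


def boundary_profile(
    boundaries: list[BoundaryContext],
    scaffolds: dict[str, str],
    flank: int = 40,
    window: int = 3,
    step: int = 2,
    ci: str = "normal",
    n_boot: int = 1000,
    seed: int = 0,
) -> GcProfile:
    """Aggregate GC profile across aligned MDS-IES boundaries.

    Negative relative positions are the MDS side, positive the IES side.
    Boundaries whose flank runs off the scaffold contribute truncated
    windows and are counted in ``truncated_boundaries``.
    """
    if len(boundaries) < 2:
        raise InputError("boundary_profile requires >= 2 boundaries")
    if ci not in ("normal", "bootstrap"):
        raise ParameterError("ci must be 'normal' or 'bootstrap'")
    per_boundary: list[dict[float, float]] = []
    truncated = 0
    for b in boundaries:
        if b.scaffold_id not in scaffolds:
            raise InputError(f"unknown scaffold {b.scaffold_id!r} in boundary")
        scaf = scaffolds[b.scaffold_id]
        lo = max(0, b.position - flank)
        hi = min(len(scaf), b.position + flank)
        if hi - lo < 2 * flank:
            truncated += 1
        local = scaf[lo:hi]
        boundary_local = b.position - lo
        if b.mds_side == "right":
            local = reverse_complement(local)
            boundary_local = len(local) - boundary_local
        elif b.mds_side != "left":
            raise ParameterError("mds_side must be 'left' or 'right'")
        per_boundary.append(dict(_boundary_window_gcs(local, boundary_local, window, step)))

    positions = sorted({p for d in per_boundary for p in d})
    means, lows, highs, ns = [], [], [], []
    rng = np.random.default_rng(seed)
    for pos in positions:
        vals = np.array([d[pos] for d in per_boundary if pos in d])
        n = len(vals)
        m = float(vals.mean())
        if n < 2:
            lo_ci = hi_ci = m
        elif ci == "normal":
            se = float(vals.std(ddof=1)) / np.sqrt(n)
            lo_ci, hi_ci = m - 1.96 * se, m + 1.96 * se
        else:
            idx = rng.integers(0, n, size=(n_boot, n))
            boot = vals[idx].mean(axis=1)
            lo_ci, hi_ci = np.percentile(boot, [2.5, 97.5])
        means.append(m)
        lows.append(max(0.0, min(lo_ci, m)))
        highs.append(min(1.0, max(hi_ci, m)))
        ns.append(n)
    return GcProfile(
        rel_positions=np.array(positions),
        mean_gc=np.array(means),
        ci95_low=np.array(lows),
        ci95_high=np.array(highs),
        n_per_window=np.array(ns),
        n_boundaries=len(boundaries),
        window=window,
        step=step,
        truncated_boundaries=truncated,
    )


def boundary_shift(profile: GcProfile, span: float = 20.0) -> float:
    """Mean window GC over the ``span`` bp on the MDS side minus the same on
    the IES side, in GC-fraction units (multiply by 100 for percentage
    points). Windows straddling the boundary are not produced by the anchored
    grid, so both sides are pure-compartment."""
    rel = profile.rel_positions
    mds = profile.mean_gc[(rel < 0) & (rel >= -span)]
    ies = profile.mean_gc[(rel > 0) & (rel <= span)]
    if len(mds) == 0 or len(ies) == 0:
        raise InputError("profile has no windows within the requested span")
    return float(mds.mean() - ies.mean())


@dataclass
class ExtremeRegion:
    scaffold_id: str
    start: int
    end: int
    mean_gc: float
    direction: str  # high | low
    z_score: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExtremeGcScanResult:
    high: list[ExtremeRegion]
    low: list[ExtremeRegion]
    assembly_mean_gc: float
    assembly_sd_gc: float
    n_windows: int


def _window_gc_array(codes: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes)
    if n < window:
        return np.empty(0, dtype=int), np.empty(0)
    gc_mask = ((codes == 1) | (codes == 2)).astype(np.int64)
    ambig = (codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(gc_mask)))
    ca = np.concatenate(([0], np.cumsum(ambig)))
    starts = np.arange(0, n - window + 1, step)
    gcs = (cs[starts + window] - cs[starts]) / window
    n_amb = ca[starts + window] - ca[starts]
    keep = n_amb == 0
    return starts[keep], gcs[keep]


def extreme_gc_scan(
    scaffolds: dict[str, str],
    mask: dict[str, list[tuple[int, int]]] | None = None,
    min_len: int = 41,
    z_threshold: float = 2.0,
    scan_window: int = 40,
    scan_step: int = 20,
    top_n: int = 250,
) -> ExtremeGcScanResult:
    """Rank regions whose GC deviates from the assembly mean by more than
    ``z_threshold`` SD of scan-window GC.

    ``mask`` intervals (e.g. annotated MDSs) exclude overlapping windows.
    Adjacent or overlapping extreme windows of one direction merge into a
    region; regions shorter than ``min_len`` are dropped; the ``top_n``
    longest per direction are returned, ranked by length descending.
    """
    import warnings

    mask = mask or {}
    per_scaffold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_gcs = []
    for sid in sorted(scaffolds):
        codes = encode(scaffolds[sid])
        starts, gcs = _window_gc_array(codes, scan_window, scan_step)
        if sid in mask and len(starts):
            keep = np.ones(len(starts), dtype=bool)
            for m0, m1 in mask[sid]:
                keep &= (starts + scan_window <= m0) | (starts >= m1)
            starts, gcs = starts[keep], gcs[keep]
        per_scaffold[sid] = (starts, gcs)
        all_gcs.append(gcs)
    flat = np.concatenate(all_gcs) if all_gcs else np.empty(0)
    if len(flat) == 0:
        warnings.warn("extreme_gc_scan: no scannable windows (mask covers everything?)", stacklevel=2)
        return ExtremeGcScanResult([], [], float("nan"), float("nan"), 0)
    mean = float(flat.mean())
    sd = float(flat.std(ddof=0))
    high: list[ExtremeRegion] = []
    low: list[ExtremeRegion] = []
    if sd < 1e-12:
        return ExtremeGcScanResult([], [], mean, sd, len(flat))
    for sid in sorted(per_scaffold):
        starts, gcs = per_scaffold[sid]
        z = (gcs - mean) / sd
        for direction, out in (("high", high), ("low", low)):
            extreme = z > z_threshold if direction == "high" else z < -z_threshold
            i = 0
            while i < len(starts):
                if not extreme[i]:
                    i += 1
                    continue
                j = i
                while (
                    j + 1 < len(starts)
                    and extreme[j + 1]
                    and starts[j + 1] <= starts[j] + scan_window
                ):
                    j += 1
                # trim the partially-diluted overlap at each end: the extreme
                # windows certify only the inner core of the merged run
                trim = max(0, scan_window - scan_step)
                r0 = int(starts[i]) + trim
                r1 = int(starts[j]) + scan_window - trim
                if r1 - r0 >= min_len:
                    seq = scaffolds[sid][r0:r1]
                    from .sequtil import gc_fraction

                    region_gc = gc_fraction(seq)
                    out.append(
                        ExtremeRegion(
                            sid, r0, r1, region_gc, direction, (region_gc - mean) / sd
                        )
                    )
                i = j + 1
    key = lambda r: (-r.length, r.scaffold_id, r.start)
    high.sort(key=key)
    low.sort(key=key)
    return ExtremeGcScanResult(high[:top_n], low[:top_n], mean, sd, len(flat))


def write_profile_tsv(profile: GcProfile, path: str) -> str:
    with open(path, "w") as fh:
        fh.write("#rel_position\tmean_gc\tci95_low\tci95_high\tn\n")
        for p, m, lo, hi, n in zip(
            profile.rel_positions,
            profile.mean_gc,
            profile.ci95_low,
            profile.ci95_high,
            profile.n_per_window,
        ):
            fh.write(f"{p:.1f}\t{m:.5f}\t{lo:.5f}\t{hi:.5f}\t{n}\n")
    return path


def plot_profile(profile: GcProfile, path: str) -> str:
    """Boundary-profile figure: sliding-window mean GC with the 95% CI band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile.rel_positions, profile.mean_gc, color="black", lw=1.2)
    ax.fill_between(
        profile.rel_positions,
        profile.ci95_low,
        profile.ci95_high,
        color="red",
        alpha=0.35,
        lw=0,
    )
    ax.axvline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("position relative to MDS-IES boundary (bp)")
    ax.set_ylabel("GC fraction")
    ax.set_title(f"{profile.n_boundaries} boundaries")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def boundaries_from_models(models, scaffolds) -> list[BoundaryContext]:
    """MDS-IES boundary contexts from annotated locus models: both germline
    junctions of every IES gap.

    GC content is reverse-complement invariant, so the orientation flag only
    needs to record which physical side of the boundary is the MDS; the
    profiler then lays every MDS out on the left of the axis."""
    out: list[BoundaryContext] = []
    for model in models:
        has_left = {(m.scaffold_id, m.s_end) for m in model.mds}
        has_right = {(m.scaffold_id, m.s_start) for m in model.mds}
        for gap in model.gaps:
            if gap.kind != "IES":
                continue
            if (gap.scaffold_id, gap.start) in has_left:
                out.append(BoundaryContext(gap.scaffold_id, gap.start, "left"))
            if (gap.scaffold_id, gap.end) in has_right:
                out.append(BoundaryContext(gap.scaffold_id, gap.end, "right"))
    return out
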