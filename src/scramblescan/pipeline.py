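"""End-to-end pipeline: soma filtering -> transcript dedup -> ungapped
mapping -> coverage filtering -> scaffold triage -> locus architecture ->
composition -> gene families, with optional truth-based recovery scoring.

Every run is deterministic for a fixed configuration and seed; with an
output directory the run writes per-stage tables plus a manifest of
SHA-256 hashes, stage counts and the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

from . import architecture as arch
from . import composition as comp
from . import genefamily as gf
from . import mapping as mp
from . import soma
from .exceptions import InputError, ParameterError, PipelineError
from .io import write_fasta, write_hits
from .simulate import LocusTruth, SCRAMBLED


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds, at the published defaults."""

    min_identity: float = 97.0
    min_coverage: float = 0.60
    dedup: bool = True
    dedup_identity: float = 98.0
    dedup_frac_len: float = 0.75
    seed_k: int = 15
    min_hsp_len: int = 24
    anchor: int = 8
    telomere_window: int = 30
    telomere_mismatch: int = 1
    telomere_motifs: tuple[str, ...] = soma.DEFAULT_TELOMERE_MOTIFS
    min_scaffold_len: int = 10000
    max_orf_cov: float = 0.20
    min_orf_len: int = 300
    min_transcripts: int = 3
    flank: int = 40
    window: int = 3
    step: int = 2
    ci_method: str = "normal"
    z_threshold: float = 2.0
    min_region_len: int = 41
    top_regions: int = 250
    scan_window: int = 40
    scan_step: int = 20
    gene_count_range: tuple[float, float] = (15000.0, 22500.0)
    ies_flank: int = 40
    run_gc_scan: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("min_identity", 0 < self.min_identity <= 100),
            ("min_coverage", 0 < self.min_coverage <= 1),
            ("dedup_identity", 0 < self.dedup_identity <= 100),
            ("dedup_frac_len", 0 < self.dedup_frac_len <= 1),
            ("seed_k", self.seed_k >= 8),
            ("min_hsp_len", self.min_hsp_len >= 1),
            ("telomere_window", self.telomere_window >= 1),
            ("telomere_mismatch", self.telomere_mismatch >= 0),
            ("min_scaffold_len", self.min_scaffold_len >= 0),
            ("max_orf_cov", 0 < self.max_orf_cov <= 1),
            ("min_transcripts", self.min_transcripts >= 0),
            ("flank", self.flank > 0),
            ("window", self.window >= 1),
            ("step", self.step >= 1),
            ("z_threshold", self.z_threshold > 0),
            ("min_region_len", self.min_region_len > 0),
            ("ci_method", self.ci_method in ("normal", "bootstrap")),
        ]
        for name, ok in checks:
            if not ok:
                raise ParameterError(f"{name} outside its documented domain")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["telomere_motifs"] = list(self.telomere_motifs)
        d["gene_count_range"] = list(self.gene_count_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "telomere_motifs" in d:
            d["telomere_motifs"] = tuple(d["telomere_motifs"])
        if "gene_count_range" in d:
            d["gene_count_range"] = tuple(d["gene_count_range"])
        return cls(**d)


@dataclass
class RecoveryReport:
    """Accuracy of the pipeline against simulator ground truth."""

    n_truth_transcripts: int
    n_analyzed: int
    classification_accuracy: float
    pointer_exact_match_rate: float
    mds_boundary_exact_match_rate: float
    scrambled_fraction_estimate: float
    stage_runtimes: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    triage: list[soma.ScaffoldRecord]
    hsps: list[mp.Hsp]
    models: list[arch.LocusModel]
    stats: arch.CategoryStats
    p_values: dict[str, float]
    alt_events: list[tuple[str, str]]
    profile: comp.GcProfile | None
    gc_scan: comp.ExtremeGcScanResult | None
    genome_size: arch.GenomeSizeEstimate | None
    family_results: list[gf.EnrichmentResult]
    family_summary: gf.FamilySummary | None
    recovery: RecoveryReport | None
    counts: dict[str, int]
    manifest: dict | None = None

    def scrambled_fraction(self) -> float:
        if not self.models:
            return 0.0
        n = sum(1 for m in self.models if m.category == arch.SCRAMBLED)
        return n / len(self.models)


def _status_map(models: list[arch.LocusModel]) -> dict[str, str]:
    return {m.transcript_id: m.category for m in models}


def run_pipeline(
    config: PipelineConfig,
    scaffolds: dict[str, str],
    transcripts: dict[str, str],
    truth: list[LocusTruth] | None = None,
    families: list[gf.GeneFamily] | dict[str, str] | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; see the module docstring."""
    runtimes: dict[str, float] = {}
    counts: dict[str, int] = {
        "scaffolds_in": len(scaffolds),
        "transcripts_in": len(transcripts),
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                runtimes[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("soma_filter"):
        somatic_ids = {
            sid
            for sid, seq in scaffolds.items()
            if soma.detect_telomere(
                seq, config.telomere_motifs, config.telomere_window, config.telomere_mismatch
            ).call
            != "none"
        }
        non_somatic = {s: q for s, q in scaffolds.items() if s not in somatic_ids}
        counts["somatic_scaffolds"] = len(somatic_ids)

    with stage("dedup"):
        if config.dedup:
            core = mp.dedup_transcripts(
                transcripts, config.dedup_identity, config.dedup_frac_len, config.seed_k
            )
        else:
            core = dict(transcripts)
        counts["core_transcripts"] = len(core)

    with stage("mapping"):
        if not core or not non_somatic:
            raise InputError(
                "mapping requires a non-empty core transcriptome and non-somatic scaffolds"
            )
        hsps = mp.map_ungapped(
            core,
            non_somatic,
            min_identity=config.min_identity,
            seed_k=config.seed_k,
            min_hsp_len=config.min_hsp_len,
            anchor=config.anchor,
        )
        counts["hsps"] = len(hsps)

    tlens = {t: len(s) for t, s in core.items()}
    with stage("coverage_filter"):
        mapped, unmapped = mp.coverage_filter(hsps, tlens, config.min_coverage)
        counts["mapped_transcripts"] = len(mapped)
        counts["unmapped_transcripts"] = len(unmapped)

    with stage("triage"):
        support = mp.support_counts(mapped)
        triage = soma.triage_scaffolds(
            scaffolds,
            {s: n for s, n in support.items() if s in scaffolds},
            min_len=config.min_scaffold_len,
            max_orf_cov=config.max_orf_cov,
            min_transcripts=config.min_transcripts,
            min_orf_len=config.min_orf_len,
            telomere_motifs=config.telomere_motifs,
            terminal_window=config.telomere_window,
            max_mismatch=config.telomere_mismatch,
        )
        germline_ids = {
            r.id for r in triage if r.triage in (soma.PUTATIVE, soma.SUPPORTED)
        }
        counts["germline_scaffolds"] = len(germline_ids)

    with stage("architecture"):
        germ_hsps = [h for h in hsps if h.scaffold_id in germline_ids]
        germ_mapped, _ = mp.coverage_filter(germ_hsps, tlens, config.min_coverage)
        models = arch.build_locus_models(germ_mapped, scaffolds)
        alt_events = arch.detect_alt_processing(models)
        counts["loci"] = len(models)
        counts["scrambled_loci"] = sum(
            1 for m in models if m.category == arch.SCRAMBLED
        )
        counts["alt_events"] = len(alt_events)

    with stage("statistics"):
        stats = arch.summarize_categories(models, scaffolds, config.ies_flank)
        p_values = arch.compare_categories(stats) if len(stats.samples) >= 2 else {}

    profile = None
    gc_scan = None
    with stage("composition"):
        boundaries = comp.boundaries_from_models(models, scaffolds)
        counts["ies_boundaries"] = len(boundaries)
        if len(boundaries) >= 2:
            profile = comp.boundary_profile(
                boundaries,
                scaffolds,
                flank=config.flank,
                window=config.window,
                step=config.step,
                ci=config.ci_method,
                seed=config.rng_seed,
            )
        if config.run_gc_scan:
            mask: dict[str, list[tuple[int, int]]] = {}
            for m in models:
                for c in m.mds:
                    mask.setdefault(c.scaffold_id, []).append((c.s_start, c.s_end))
            germ = {s: scaffolds[s] for s in sorted(germline_ids)}
            if germ:
                gc_scan = comp.extreme_gc_scan(
                    germ,
                    mask,
                    min_len=config.min_region_len,
                    z_threshold=config.z_threshold,
                    scan_window=config.scan_window,
                    scan_step=config.scan_step,
                    top_n=config.top_regions,
                )

    with stage("genome_size"):
        mapped_mbp = sum(len(scaffolds[s]) for s in germline_ids) / 1e6
        genome_size = (
            arch.estimate_genome_size(len(models), mapped_mbp, config.gene_count_range)
            if models and mapped_mbp > 0
            else None
        )

    family_results: list[gf.EnrichmentResult] = []
    family_summary = None
    with stage("families"):
        fams: list[gf.GeneFamily] | None = None
        if isinstance(families, dict):
            fams = gf.families_from_truth(families)
        elif families is not None:
            fams = families
        if fams:
            gf.assign_status(fams, _status_map(models))
            family_summary = gf.family_size_stats(fams)
            frac = (
                counts["scrambled_loci"] / counts["loci"] if counts["loci"] else 0.0
            )
            if 0.0 < frac < 1.0:
                family_results = gf.scramble_enrichment(fams, frac)

    recovery = None
    if truth is not None:
        with stage("recovery"):
            recovery = score_recovery(models, truth)
            recovery.stage_runtimes = dict(runtimes)

    result = PipelineResult(
        config=config,
        triage=triage,
        hsps=hsps,
        models=models,
        stats=stats,
        p_values=p_values,
        alt_events=alt_events,
        profile=profile,
        gc_scan=gc_scan,
        genome_size=genome_size,
        family_results=family_results,
        family_summary=family_summary,
        recovery=recovery,
        counts=counts,
    )
    if out_dir is not None:
        result.manifest = write_outputs(result, scaffolds, out_dir, runtimes)
    return result


def score_recovery(models: list[arch.LocusModel], truth: list[LocusTruth]) -> RecoveryReport:
    """Score classification, pointer and MDS-boundary recovery against the
    planted truth, over the transcripts that survived to analysis."""
    by_tid = {m.transcript_id: m for m in models}
    truth_tids = [tid for t in truth for tid in t.transcript_ids]

    n_class = n_class_ok = 0
    for t in truth:
        for tid, label in t.transcript_labels.items():
            model = by_tid.get(tid)
            if model is None:
                continue
            n_class += 1
            if model.category == label:
                n_class_ok += 1

    n_ptr = n_ptr_ok = 0
    for t in truth:
        base = t.transcript_ids[0]
        model = by_tid.get(base)
        if model is None:
            continue
        detected = {
            (p.left_scaffold_id, p.left_start, p.left_end, p.length, p.sequence)
            for p in model.pointers
        }
        for pt in t.pointer_records:
            n_ptr += 1
            if (
                pt.left_scaffold_id,
                pt.left_start,
                pt.left_end,
                pt.length,
                pt.sequence,
            ) in detected:
                n_ptr_ok += 1

    n_seg = n_seg_ok = 0
    for t in truth:
        for seg in t.mds_records:
            model = by_tid.get(seg.transcript_id)
            if model is None or seg.dropout:
                continue
            n_seg += 1
            found = any(
                c.scaffold_id == seg.scaffold_id
                and c.s_start == seg.s_start
                and c.s_end == seg.s_end
                and c.t_start == seg.t_start
                and c.t_end == seg.t_end
                and c.strand == seg.strand
                for c in model.mds
            )
            n_seg_ok += found

    n_scr = sum(1 for m in models if m.category == arch.SCRAMBLED)
    return RecoveryReport(
        n_truth_transcripts=len(truth_tids),
        n_analyzed=len(models),
        classification_accuracy=(n_class_ok / n_class) if n_class else 0.0,
        pointer_exact_match_rate=(n_ptr_ok / n_ptr) if n_ptr else 0.0,
        mds_boundary_exact_match_rate=(n_seg_ok / n_seg) if n_seg else 0.0,
        scrambled_fraction_estimate=(n_scr / len(models)) if models else 0.0,
    )


def coverage_sweep_report(
    config: PipelineConfig,
    scaffolds: dict[str, str],
    transcripts: dict[str, str],
    truth: list[LocusTruth],
    thresholds=(0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90),
) -> dict[float, dict[str, int]]:
    """Mapped-transcript counts across coverage thresholds, split by the
    planted scrambled/nonscrambled label (the coverage-threshold sweep)."""
    somatic_ids = {
        sid
        for sid, seq in scaffolds.items()
        if soma.detect_telomere(
            seq, config.telomere_motifs, config.telomere_window, config.telomere_mismatch
        ).call
        != "none"
    }
    non_somatic = {s: q for s, q in scaffolds.items() if s not in somatic_ids}
    core = (
        mp.dedup_transcripts(transcripts, config.dedup_identity, config.dedup_frac_len)
        if config.dedup
        else dict(transcripts)
    )
    hsps = mp.map_ungapped(
        core, non_somatic, config.min_identity, config.seed_k, config.min_hsp_len, config.anchor
    )
    tlens = {t: len(s) for t, s in core.items()}
    labels = {
        tid: lab for t in truth for tid, lab in t.transcript_labels.items()
    }
    sweep = mp.coverage_sweep(hsps, tlens, thresholds)
    out = {}
    for th, tids in sweep.items():
        out[th] = {
            "mapped": len(tids),
            "scrambled": sum(1 for t in tids if labels.get(t) == SCRAMBLED),
            "nonscrambled": sum(
                1 for t in tids if labels.get(t, SCRAMBLED) != SCRAMBLED
            ),
        }
    return out


# ---------------------------------------------------------------------------
# output writing


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_locus_tsv(models: list[arch.LocusModel], path: str) -> str:
    with open(path, "w") as fh:
        fh.write(
            "#transcript_id\tcategory\tmulti_scaffold\talt_processed\tn_mds\t"
            "n_pointers\tn_ies\tn_introns\tn_ambiguous\tscaffolds\n"
        )
        for m in models:
            kinds = [g.kind for g in m.gaps]
            fh.write(
                f"{m.transcript_id}\t{m.category}\t{int(m.multi_scaffold)}\t"
                f"{int(m.alt_processed)}\t{m.mds_count}\t{len(m.pointers)}\t"
                f"{kinds.count('IES')}\t{kinds.count('intron')}\t"
                f"{kinds.count('ambiguous')}\t{','.join(m.scaffold_ids)}\n"
            )
    return path


def write_locus_bed(models: list[arch.LocusModel], path: str) -> str:
    rows = []
    for m in models:
        ordered = sorted(m.mds, key=lambda c: (c.t_start, c.t_end))
        for i, c in enumerate(ordered, 1):
            rows.append(
                (c.scaffold_id, c.s_start, c.s_end, f"{m.transcript_id}:{i}:{m.category}", 0, c.strand)
            )
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


def write_category_stats_tsv(stats: arch.CategoryStats, p_values: dict[str, float], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("#feature\tcategory\tmean\tmedian\tn\tp_value\n")
        for f in arch.FEATURES:
            for cat in sorted(stats.mean):
                if f in stats.mean[cat]:
                    p = p_values.get(f)
                    fh.write(
                        f"{f}\t{cat}\t{stats.mean[cat][f]:.4f}\t{stats.median[cat][f]:.4f}\t"
                        f"{len(stats.samples[cat][f])}\t{'' if p is None else f'{p:.3g}'}\n"
                    )
    return path


def write_outputs(
    result: PipelineResult,
    scaffolds: dict[str, str],
    out_dir: str,
    runtimes: dict[str, float],
) -> dict:
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    paths["triage.tsv"] = soma.write_triage_tsv(
        result.triage, os.path.join(out_dir, "triage.tsv")
    )
    paths["hits.tsv"] = write_hits(os.path.join(out_dir, "hits.tsv"), result.hsps)
    paths["loci.tsv"] = write_locus_tsv(result.models, os.path.join(out_dir, "loci.tsv"))
    paths["loci.bed"] = write_locus_bed(result.models, os.path.join(out_dir, "loci.bed"))
    paths["category_stats.tsv"] = write_category_stats_tsv(
        result.stats, result.p_values, os.path.join(out_dir, "category_stats.tsv")
    )
    if result.profile is not None:
        paths["gc_profile.tsv"] = comp.write_profile_tsv(
            result.profile, os.path.join(out_dir, "gc_profile.tsv")
        )
    if result.gc_scan is not None:
        bed = os.path.join(out_dir, "extreme_gc.bed")
        with open(bed, "w") as fh:
            for r in result.gc_scan.high + result.gc_scan.low:
                fh.write(
                    f"{r.scaffold_id}\t{r.start}\t{r.end}\t{r.direction}\t{r.z_score:.2f}\t+\n"
                )
        paths["extreme_gc.bed"] = bed
        fasta = {
            f"{r.scaffold_id}:{r.start}-{r.end}:{r.direction}": scaffolds[r.scaffold_id][r.start : r.end]
            for r in result.gc_scan.high + result.gc_scan.low
        }
        paths["extreme_gc.fasta"] = write_fasta(
            os.path.join(out_dir, "extreme_gc.fasta"), fasta
        )
    if result.recovery is not None:
        p = os.path.join(out_dir, "recovery.json")
        rec = result.recovery.to_dict()
        rec.pop("stage_runtimes", None)  # timings stay out of hashed outputs
        with open(p, "w") as fh:
            json.dump(rec, fh, indent=1, sort_keys=True)
        paths["recovery.json"] = p

    manifest = {
        "config": result.config.to_dict(),
        "counts": result.counts,
        "files": {name: _sha256(p) for name, p in sorted(paths.items())},
        "runtimes_s": {k: round(v, 3) for k, v in runtimes.items()},
    }
    if result.genome_size is not None:
        manifest["genome_size_mbp"] = [
            result.genome_size.low_mbp,
            result.genome_size.high_mbp,
        ]
        manifest["genes_per_mbp"] = result.genome_size.genes_per_mbp
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
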