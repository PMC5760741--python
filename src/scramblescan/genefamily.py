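"""Gene-family ingestion and scrambling-enrichment statistics.

Families arrive as an OrthoMCL-style groups file ("FAM: taxon|gene
taxon|gene ...") or as a two-column transcript/family table. Member status
(scrambled / nonscrambled / unmapped) is joined from the architecture
output, and each multimember family's observed scrambled count is compared
against the expectation under the genome-wide scrambled fraction with a
two-cell chi-square test (df = 1, no continuity correction; families with an
expected cell below 5 are flagged).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from scipy import stats as sps

from .exceptions import IntegrityError, ParameterError
from .mapping import parse_stage

SCRAMBLED = "scrambled"
NONSCRAMBLED = "nonscrambled"
UNMAPPED = "unmapped"


@dataclass
class GeneFamily:
    family_id: str
    members: list[str]
    status: dict[str, str] = field(default_factory=dict)  # member -> status

    def mapped_members(self) -> list[str]:
        return [m for m in self.members if self.status.get(m, UNMAPPED) != UNMAPPED]

    def n_scrambled(self) -> int:
        return sum(1 for m in self.members if self.status.get(m) == SCRAMBLED)

    @property
    def size(self) -> int:
        """Transcript diversity: number of unique members."""
        return len(self.members)


def parse_groups(path: str | os.PathLike) -> list[GeneFamily]:
    """Parse an OrthoMCL-dialect groups file; taxon prefixes are stripped.

    A transcript appearing in two families raises an integrity error naming
    the transcript. Blank lines are skipped.
    """
    families: list[GeneFamily] = []
    seen: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise IntegrityError(f"{path}:{lineno}: expected 'FAMILY: members...'")
            fam_id, body = line.split(":", 1)
            fam_id = fam_id.strip()
            members = []
            for token in body.split():
                tid = token.split("|")[-1]
                if tid in seen:
                    raise IntegrityError(
                        f"transcript {tid!r} assigned to both {seen[tid]!r} and {fam_id!r}"
                    )
                seen[tid] = fam_id
                if tid not in members:
                    members.append(tid)
            families.append(GeneFamily(fam_id, members))
    return families


def families_from_truth(family_truth: dict[str, str]) -> list[GeneFamily]:
    """Build GeneFamily records from a transcript -> family mapping."""
    by_fam: dict[str, list[str]] = {}
    for tid, fam in family_truth.items():
        by_fam.setdefault(fam, []).append(tid)
    return [GeneFamily(fam, sorted(members)) for fam, members in sorted(by_fam.items())]


def assign_status(families: list[GeneFamily], status_map: dict[str, str]) -> None:
    """Join per-transcript scrambled/nonscrambled status; members absent from
    the map are unmapped."""
    for fam in families:
        fam.status = {m: status_map.get(m, UNMAPPED) for m in fam.members}


@dataclass
class FamilySummary:
    n_families: int
    n_transcripts: int
    mean_members: float
    mean_members_scrambled_families: float | None
    mean_members_nonscrambled_families: float | None


def mean_members_per_family(n_transcripts: int, n_families: int, digits: int | None = 2) -> float:
    """Mean family size from totals (e.g. 12467 transcripts / 4153 families)."""
    if n_families <= 0 or n_transcripts < 0:
        raise ParameterError("need n_families > 0 and n_transcripts >= 0")
    mean = n_transcripts / n_families
    return round(mean, digits) if digits is not None else mean


def family_size_stats(families: list[GeneFamily], digits: int | None = None) -> FamilySummary:
    """Family-size summary, split by whether a family contains at least one
    scrambled mapped member."""
    if not families:
        raise ParameterError("family_size_stats requires >= 1 family")
    n_fam = len(families)
    n_tr = sum(f.size for f in families)
    scram = [f.size for f in families if f.n_scrambled() >= 1]
    non = [f.size for f in families if f.n_scrambled() == 0]

    def _mean(vals):
        if not vals:
            return None
        m = sum(vals) / len(vals)
        return round(m, digits) if digits is not None else m

    mean_all = n_tr / n_fam
    if digits is not None:
        mean_all = round(mean_all, digits)
    return FamilySummary(n_fam, n_tr, mean_all, _mean(scram), _mean(non))


@dataclass
class EnrichmentResult:
    family_id: str  # a family id or "overall"
    n_mapped: int
    n_scrambled_observed: int
    n_scrambled_expected: float
    chi_square: float
    p_value: float
    global_fraction: float
    small_expected_cell: bool = False


def _two_cell_chisq(obs_scrambled: int, n: int, fraction: float) -> tuple[float, float, bool]:
    exp_s = n * fraction
    exp_n = n * (1.0 - fraction)
    chi = (obs_scrambled - exp_s) ** 2 / exp_s + ((n - obs_scrambled) - exp_n) ** 2 / exp_n
    p = float(sps.chi2.sf(chi, df=1))
    return float(chi), p, (exp_s < 5 or exp_n < 5)


def scramble_enrichment(
    families: list[GeneFamily],
    global_scrambled_fraction: float,
    min_mapped_members: int = 2,
) -> list[EnrichmentResult]:
    """Per-family and overall chi-square tests of scrambled-member excess.

    Expected scrambled counts come from the genome-wide scrambled fraction;
    unmapped members are excluded. Families with fewer than
    ``min_mapped_members`` mapped members are skipped (degenerate expected
    counts); the pooled "overall" result covers all tested families.
    """
    if not 0.0 < global_scrambled_fraction < 1.0:
        raise ParameterError("global_scrambled_fraction must be in (0, 1)")
    results: list[EnrichmentResult] = []
    tot_n = tot_obs = 0
    for fam in families:
        mapped = fam.mapped_members()
        if len(mapped) < min_mapped_members:
            continue
        n = len(mapped)
        obs = sum(1 for m in mapped if fam.status.get(m) == SCRAMBLED)
        chi, p, small = _two_cell_chisq(obs, n, global_scrambled_fraction)
        results.append(
            EnrichmentResult(
                fam.family_id, n, obs, n * global_scrambled_fraction, chi, p,
                global_scrambled_fraction, small,
            )
        )
        tot_n += n
        tot_obs += obs
    if tot_n:
        chi, p, small = _two_cell_chisq(tot_obs, tot_n, global_scrambled_fraction)
        results.append(
            EnrichmentResult(
                "overall", tot_n, tot_obs, tot_n * global_scrambled_fraction, chi, p,
                global_scrambled_fraction, small,
            )
        )
    return results


def stage_composition(families: list[GeneFamily]) -> dict[str, dict[str, float]]:
    """Per-family life-stage counts as proportions of family membership.

    Transcript names carry their life-cycle stage as a prefix; unknown
    prefixes are tallied under 'unknown'.
    """
    out: dict[str, dict[str, float]] = {}
    for fam in families:
        counts: dict[str, int] = {}
        for m in fam.members:
            stage = parse_stage(m)
            counts[stage] = counts.get(stage, 0) + 1
        total = sum(counts.values())
        out[fam.family_id] = {s: c / total for s, c in sorted(counts.items())}
    return out


def write_family_tsv(
    families: list[GeneFamily],
    enrichment: list[EnrichmentResult],
    path: str,
) -> str:
    enr = {e.family_id: e for e in enrichment}
    stages = stage_composition(families)
    with open(path, "w") as fh:
        fh.write(
            "#family_id\tsize\tn_mapped\tn_scrambled\tn_unmapped\tchi_square\tp_value\tstages\n"
        )
        for fam in families:
            e = enr.get(fam.family_id)
            chi = f"{e.chi_square:.4f}" if e else "."
            p = f"{e.p_value:.3g}" if e else "."
            stage_str = ",".join(f"{s}:{v:.2f}" for s, v in stages[fam.family_id].items())
            n_unmapped = fam.size - len(fam.mapped_members())
            fh.write(
                f"{fam.family_id}\t{fam.size}\t{len(fam.mapped_members())}\t"
                f"{fam.n_scrambled()}\t{n_unmapped}\t{chi}\t{p}\t{stage_str}\n"
            )
    return path
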