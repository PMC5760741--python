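# Methods

This note documents the models, conventions and numerical choices behind
`scramblescan`, and what its synthetic benchmark does and does not show.

## The analysis model

A germline (micronuclear) locus is modelled as a set of MDS segments placed
on one or two scaffolds, separated by germline-limited gaps, whose
concatenation — after reordering, strand correction, removal of the second
copy of each pointer, and intron splicing — yields a somatic transcript.
The observable evidence is the set of ungapped local alignments between a
transcript and the germline assembly. From those the package derives:

* **Pointers.** For adjacent (by transcript coordinate) MDS candidates, the
  candidate pointer length is the overlap of their transcript intervals. A
  pointer is reported only when the germline sequences at the two junction
  copies are identical strings; zero overlap means none. This is the
  operational definition of the short direct repeats that guide
  unscrambling.
* **Gap kinds.** The germline gap between consecutive MDSs is an IES when a
  pointer is present and the gap, read on the coding strand, is not bounded
  by the canonical `GT…AG` intron dinucleotides; it is an intron when
  `GT…AG` holds without a pointer. Conflicting evidence (pointer *and*
  `GT…AG`) is labelled ambiguous and excluded from both IES and intron
  statistics.
* **Classification.** Per scaffold chain, a locus is nonscrambled when its
  MDS scaffold positions follow transcript order strictly on a single
  strand; a consistently descending all-minus chain is the reverse
  complement of an ordered locus and is also nonscrambled. Permuted
  positions and/or mixed strands make the locus scrambled. Chains spanning
  two or more scaffolds are flagged multi-scaffold and classified by the
  same criteria applied per chain, then broken out in reports.
* **Alternative processing.** Two transcripts form an event when, on a
  shared scaffold, at least one pair of their MDS intervals overlaps
  reciprocally by ≥50% while their footprints differ; identical footprints
  are duplicates (assembly redundancy), not events.

## Aligner semantics

Because different ungapped aligners disagree at segment ends, the package
fixes one canonical semantics and uses it everywhere (including the
brute-force oracle in the test suite). Per diagonal of the transcript ×
scaffold comparison, positions score +1 (match) / −2 (mismatch); maximal-
scoring segments are extracted greedily (ties: smaller end, then smaller
start; extracted spans are masked); each segment end is then trimmed back
to an exact-match anchor run of ≥8 bp; finally segments shorter than 24 bp
or below 97% identity are dropped. The anchor trim stops isolated chance
matches from propping up a segment end beyond a true homology boundary.
Seeding uses exact 15-mers over both transcript strands with the scaffold
sampled every `min_hsp_len − k + 1` positions; any reportable segment
(≥24 bp at ≥97% identity) necessarily contains an exact run of ≥24 bp, so
sampled seeding finds every diagonal the exhaustive scan would. Precomputed
tabular hits in the 12-column dialect can replace the internal aligner;
exact dialect equivalence with other tools is not promised — the contract
is the identity/ungapped/strand semantics.

Transcript redundancy removal is greedy longest-first: a transcript is
dropped when it aligns at >98% identity over ≥75% of its own length to an
already retained, longer transcript (union of hits on either strand).

## Statistics

* Per-category feature comparisons use the two-sided Mann–Whitney U test
  (distribution-free; the features are skewed counts and lengths), with the
  exact null distribution for untied samples below n=20 per group and the
  normal approximation otherwise; fully tied samples report p = 1.
* The "% GC of MDS-IES" feature is computed as the GC of an MDS plus up to
  40 bp of adjacent germline flank on each side, matching the
  boundary-window framing of the composition profile; the denominator is a
  package convention, stated here because the quantity is otherwise
  underdefined.
* Inter-MDS ("distance between pointers") distances are scaffold-coordinate
  gaps between consecutive-by-transcript MDSs on the same scaffold.
* Gene-family enrichment uses a two-cell chi-square (df = 1, no continuity
  correction) of observed vs expected scrambled members, the expectation
  being family mapped-member count × genome-wide scrambled fraction
  (computed over mapped transcripts). Families with fewer than two mapped
  members are skipped; families with an expected cell below five are
  flagged. The pooled "overall" test aggregates all tested families.
* Boundary-profile CIs are mean ± 1.96·SE across boundaries by default; a
  seeded percentile bootstrap (1,000 replicates) is available because the
  original figure does not state which was used.
* Genome size is the assumed total gene count divided by observed gene
  density (mapped transcripts per Mbp of germline scaffold). With the
  worked inputs 5,019 genes / 32.7 Mbp / 15,000–22,500 genes the unrounded
  bounds are 97.7–146.6 Mbp; the commonly quoted ~99–149 Mbp follows from
  the rounded inputs (~5,000 genes, ~33 Mbp). The package reports unrounded
  bounds.

## Composition scanning

GC windows tile left to right (default 3 bp window, 2 bp step); windows
containing ambiguous bases are skipped rather than counted as AT. For
boundary profiles the window grid is anchored at the boundary (left-side
windows walk left from it, right-side windows walk right), so relative
window positions align across boundaries and no window straddles the
boundary; profiles are laid out MDS side left. GC content is reverse-
complement invariant, so orientation flags only record which physical side
of a boundary is the MDS.

The extreme-GC scan computes 40-bp/20-bp-step window GC over unannotated
scaffold sequence, standardizes against the assembly-wide window mean and
SD (ddof = 0; an assembly with zero window variance yields no calls), and
merges adjacent extreme windows of one direction. Each merged run is
trimmed by `window − step` per side — overlapping windows are partially
diluted by neighbouring sequence, and only the inner core is certified
extreme — after which regions must exceed 40 bp (default `min_len` 41).
This trim is what lets a planted 120-bp island resolve to its exact extent
while a 30-bp island is correctly rejected by the length rule. The top 250
regions per direction, ranked by length, are exported as FASTA for external
homology searches (running those searches is out of scope: hit counts
depend on the database version).

## The synthetic generator

The generator is the package's benchmark instrument: it emulates a germline
assembly whose loci follow the published per-category feature table, and
records complete ground truth.

* **Distributions.** MDS counts are shifted-geometric parameterized by the
  category mean (2.46 nonscrambled, support ≥1; 3.29 scrambled, support ≥2
  — a scrambled locus needs at least two MDSs). MDS lengths and inter-MDS
  separations are log-normal pinned jointly to the printed mean and median
  (sigma = √(2 ln(mean/median))): 212.20/179 and 160.96/133 bp for MDS
  lengths, 136.78/104 and 1,454.89/805 bp for separations. Pointer lengths
  use a small empirical integer offset distribution anchored at the
  category median (6 and 8 bp) with mean ≈ median + 0.49, emulating the
  printed mean/median gaps; a degenerate `FixedLength` variant supports
  fixed-pointer benchmarks. The scrambled MDS-count table entry has median
  (4) above its mean (3.29), which no geometric family can reproduce; the
  mean is honoured, giving median 3.
* **Compartment GC** defaults to 0.41 (MDS/transcript) and 0.29
  (IES/padding), the planted contrast behind the ~12-point boundary shift.
* **Arrangements.** Scrambled loci draw a random permutation and per-MDS
  inversions (probability 0.35) rejection-sampled until the order/strand
  criterion actually holds; one in ten nonscrambled loci is planted as its
  reverse complement (descending, all-minus) to exercise that rule.
  Multi-scaffold loci (probability 0.05, nonscrambled only) split the chain
  across two scaffolds; alternative processing (probability 0.05, scrambled
  loci with ≥3 MDSs) adds a second transcript skipping one interior MDS,
  resampled until the isoform remains scrambled. Introns (probability 0.10
  per locus, 50–150 bp, `GT…AG`, no pointer) are present in the germline
  and spliced from the emitted transcript; `reconstruct_transcript(...,
  splice_introns=False)` returns the unspliced somatic form.
* **Boundary identifiability.** After placement, the single scaffold base
  adjacent to each planted segment end is constrained to differ from the
  base that would extend the alignment (intron `GT`/`AG` dinucleotides are
  preserved; their junctions are constrained via the insertion point
  instead). Without this, ~25% of planted boundaries per end would be
  genuinely unidentifiable — the true maximal alignment would extend past
  them by chance — and exact-coordinate recovery would be ill-posed rather
  than hard. Terminal scaffold padding is regenerated if it ever contains a
  chance telomere-like motif, keeping the somatic/germline partition
  noise-free by construction.
* **Scale.** Germline scaffolds are padded to 10.5–13 kbp (clearing the
  10-kbp triage floor), MDS lengths floor at 40 bp (above the 24-bp minimum
  HSP length, so every planted segment is recoverable), IES lengths are
  clamped to [20, 50,000] bp. Somatic contaminants are 0.8–4.5-kbp scaffolds
  capped on both ends with the `CCCCAAA` telomeric repeat. Family truth
  assigns transcripts to families independently of scrambling status
  (geometric sizes, mean 3), giving a null for the enrichment test's type-I
  behaviour. An optional per-MDS dropout probability (default 0) erases a
  segment's germline copy to erode transcript coverage; it drives the
  coverage-threshold sweep behaviour (higher thresholds remove
  disproportionately more of the more-fragmented scrambled loci) and is the
  only non-noise-free knob.

**What passing synthetic tests show — and not.** Noise-free recovery at
100% demonstrates that the algorithms are exact inverses of the generative
model: coordinates, pointers, categories and planted moments are recovered
perfectly, and the statistical machinery is calibrated against brute-force
oracles. The generator does not emulate sequencing error, amplification
bias or chimerism, assembly collapse of repeats, diverged paralogs, or
pointer repeats arising by chance in unrelated sequence; on real
assemblies, mapping noise and assembly artefacts will blur boundaries and
depress recovery below these ceilings.

## Pipeline conventions and sizes

Stages run in the published order (soma filter → dedup → mapping →
coverage → triage → architecture → statistics → composition → genome size →
families), each wrapped so a failure aborts with the stage name while
earlier outputs are kept. Coordinates are 0-based half-open with explicit
strand everywhere in memory; the tabular hit dialect (1-based inclusive,
reversed subject interval for minus strand) is converted only at the I/O
boundary. Runs are deterministic given the configuration seed; output
directories include a manifest with SHA-256 hashes of every table (stage
timings are reported separately and excluded from hashed files). The
configuration serializes to JSON and round-trips losslessly.

The bundled benchmark sizes — 1,000 loci (~12 Mbp of scaffold) for
fraction recovery, 5,000 boundaries for the composition profile, 300 loci
for pointer medians, 200 loci for the noise-free property suite — were
chosen so each quantity's sampling error is small relative to the effect it
measures while a full run stays in the tens of seconds on one core.

## Known limitations

* The aligner is strictly ungapped; an indel inside an MDS splits it into
  two candidates separated by a zero-pointer gap rather than being absorbed.
* Pointer detection requires exact junction-copy identity; a single
  mismatch between germline copies suppresses the pointer (and can thereby
  reclassify the gap as ambiguous).
* `GT…AG` testing uses the two terminal dinucleotides only; the fuller
  `GT-YAG` splice context is not modelled.
* Per-family chi-square tests on small families are approximate; the
  small-expected-cell flag marks them, and no multiple-testing correction
  is applied across families (the pooled overall test is the headline
  number).
* Genome-size extrapolation inherits every bias of its inputs (transcript
  completeness, assembly redundancy, assumed gene count) and is a
  density argument, not an assembly-based measurement.
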