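# Methods

## The assay this package models

2C-ChIP (carbon copy ChIP) quantifies ChIP signal over predefined genomic
regions by ligation-mediated amplification (LMA). For each probed position, a
forward and a reverse oligonucleotide anneal contiguously on the same strand
of immunoprecipitated DNA; a nick-sealing ligase joins only correctly
juxtaposed pairs, so the amount of each ligation product reports the local
abundance of the immunoprecipitated template. All products carry universal
tails (a T3-complement on forwards, a P1-key-complement on reverses) so one
primer pair amplifies the whole library, and an 8-nt barcode placed so it is
sequenced first multiplexes many libraries per run. Enrichment is expressed
as the ratio of normalized ChIP signal to normalized input signal per probe.

The package covers the computational arm end to end: panel design, expected
product reference construction, a ground-truth read simulator, two-step read
assignment with demultiplexing, the normalization chain, and QC/validation
statistics. Wet-lab steps are out of scope.

## Panel design

Tiling is a greedy left-to-right scan. At each candidate junction the forward
homology grows leftward and the reverse rightward from the minimum homology
length (22 nt) to the maximum (34 nt); the shortest lengths passing all
checks are accepted and the scan advances so junctions are at least
`target_spacing` apart (`"max-density"` = as dense as the constraints allow).
The procedure is a pure function of (genome, interval, constraints, spacing),
so panels are byte-reproducible.

Per-primer checks and their defaults:

| rule | default | meaning |
|---|---|---|
| homology length | 22–34 nt | the assay's design window |
| GC content | 0.40–0.60 | amplification uniformity |
| uniqueness | exact count == 1 | the homology occurs exactly once in the supplied genome sequence (self-contained stand-in for a genome-wide alignment check) |
| self-complementarity | no run ≥ 6 nt | fail if any ≥6-nt substring's reverse complement also occurs in the oligo — a simple proxy for self-annealing/hairpins |

Homologies are stored in sequenced-read orientation (sense strand of the
emitted product); both primers anneal to the antisense strand. Coordinates
are 0-based half-open everywhere internally and in BED/bedGraph output.
`reaction_molarity` converts fmol/µl to pM (0.34 fmol in 10 µl = 34 pM, the
standard per-primer annealing concentration).

Barcodes default to 8 nt with pairwise Hamming distance ≥ 2; 8 nt is
consistent with the smallest expected product being 50 nt (8-nt barcode +
20-nt forward tail + 22-nt minimum forward homology).

## Reference assemblies

Two assemblies drive assignment:

1. **Full products** — every barcode × F_i × R_j combination,
   `n_barcodes × n_pairs²` sequences. `i == j` is *on-diagonal* (a designed
   probe); `i != j` is *off-diagonal*, the non-specific ligation artifact
   class. Off-diagonal products are enumerated explicitly so they are
   first-class countable categories rather than a post-hoc label.
2. **Unpaired** — barcode+tail+F, tail+F, and R+tail sequences, which absorb
   truncated or unligated material.

The constant reverse tail is excluded from reference sequences by default:
reads are decided before reaching it and it adds no discriminative power
(`include_reverse_tail=True` restores it for long-read setups). The n²
enumeration is tractable at study scale (160 pairs × a few barcodes); a
configurable cap with seeded off-diagonal sampling protects pathological
inputs.

## Simulator

The generator emulates the data the pipeline consumes, not the chemistry:

- **Genome**: i.i.d. bases at a requested GC fraction.
- **Profile**: background occupancy (default 1.0) with `n_peaks` contiguous
  probe runs (width uniform in 2–6 probes) raised to `peak_height` (default
  8.0) — the peak/valley structure of real ChIP tracks. The optional
  multiplicative log-normal `jitter` (default 0) models the fact that real
  occupancy varies continuously between probes; rank-based recovery checks
  use `jitter=0.5`, since a strictly two-valued profile has an intrinsic
  Spearman ceiling (~0.75 at typical peak fractions) from tied ranks alone,
  regardless of pipeline quality.
- **Reads**: each read is an on-diagonal product of probe i with probability
  `1 − off_diagonal_rate − truncation_rate` (i drawn ∝ profile), a uniform
  off-diagonal product with probability `off_diagonal_rate`, or a uniform
  barcode-forward fragment with probability `truncation_rate`. Per-base
  substitutions at `error_rate`; constant quality string; reads begin at the
  barcode (instrument key consumed upstream) and end at the reverse homology
  (adapter-trimmed), so noiseless reads equal reference sequences exactly.
  PCR amplification is absorbed into `n_reads` (jackpotting not modeled);
  size selection is an optional min/max read-length filter. Indels and
  homopolymer errors are not modeled — passing tests therefore bound
  substitution robustness only.
- **Titration**: `titration_response` maps template mass to
  (n_reads, off-diagonal rate, yield) phenomenologically: yield rises
  linearly and saturates hard at `saturation_ng` (default 1.6 ng), and the
  off-diagonal rate grows as `base · (1 + halfpoint/amount)` when template
  becomes scarce. This is a stated stand-in with a known breakpoint for
  testing linearity assessment, not a kinetic model.

Truth bookkeeping is exact: every emitted read's origin (category and
reference id) is recorded, and the noiseless pipeline must reproduce those
counts identically.

## Read assignment

The two mapping word sizes (50 for full products, 22 for unpaired — each the
smallest expected sequence in its assembly) are reinterpreted as minimum
aligned-length gates plus an identity gate on an infix alignment contract:
reference r hits read q iff the best semi-global (infix) edit distance d of r
within q gives identity `1 − d/len(r) ≥ min_identity` (default 0.95, a
package default surfaced in config, not a published value), with score
`len(r) − d`. Alignment uses edlib's banded infix mode with the band set by
the identity budget, so non-matching references reject quickly.

Assignment is two-step: pass 1 against full products (gate 50); a unique
top-scoring product wins. Ties and misses fall to pass 2 against the
unpaired assembly (gate 22); a unique best hit yields its unpaired category.
Remaining ties are ambiguous; reads with no hit anywhere are unmapped (a
step-1 tie with no step-2 hit is ambiguous, not unmapped — the read did match
products). Barcodes come from the matched reference, so demultiplexing
happens after mapping and tolerates barcode errors up to the identity gate.

Performance shortcut: full products are grouped by their shared
barcode+tail+forward prefix. An infix alignment of prefix+suffix contains an
infix alignment of the prefix at no greater cost, so `d(read, prefix)` lower
bounds `d(read, product)` and groups over budget are skipped. This is
outcome-preserving by construction and verified against a brute-force
single-pass dynamic-programming aligner (Biopython `PairwiseAligner`, global
mode with free end gaps on the read; an independent engine from edlib) on
200 randomized instances.

Off-diagonal and ambiguous reads are excluded from probe signal but retained
in QC tallies; count tables conserve reads exactly across categories.

## Normalization

For one library, `value_i = count_i / base × 10⁶ × seq_dilution ×
linearity_dilution`, with ChIP libraries additionally multiplied by
`input_fraction` (default 0.10 — only a tenth of the input is processed; the
factor is applied multiplicatively on the ChIP side, a direction choice that
cancels in any comparison between tracks and is logged). `base` is the
library's mapped on-diagonal product reads by default (artifact reads are
excluded from depth), switchable to the library total (`norm_base`). The
track is the per-probe ChIP/input ratio; zero-input probes are dropped and
logged rather than pseudocounted (an optional pseudocount exists, default
off). All steps are multiplicative, so ordering is immaterial; depth
invariance and factor linearity hold to machine precision. bedGraph values
are written with 6 significant digits, which defines the round-trip
tolerance.

## QC and validation statistics

- `run_qc`: composition fractions; the off-diagonal fraction is reported both
  over all reads and over "unexpected" reads (everything not an on-diagonal
  product) — the latter is the usual artifact statistic.
- `window_average`: unweighted mean of probes whose interval midpoint falls
  in a window (default 1 kb) — the qPCR-amplicon comparison; membership is
  configurable to any-overlap since the edge convention is a design choice.
- `spearman`: average-rank Spearman (scipy), with opt-in exclusion of
  zero-valued pairs (logged) as used in cross-platform comparisons; ≥3
  retained pairs required.
- `chipseq_overlap_score`: reads overlapping each probed interval under
  half-open semantics (abutting ≠ overlapping), checked against a quadratic
  all-pairs oracle; containment vs overlap is configurable at the caller
  level by filtering reads.
- `assess_linearity`: over all contiguous sub-series of ≥3 titration points,
  least-squares fit of log yield vs log amount; the widest window with
  r² ≥ 0.98 and slope in [0.8, 1.2] wins (ties: larger log-span, then
  leftmost). The gates are package defaults — the published linear range was
  reported without an explicit criterion — and are config-exposed. Returns a
  no-range result instead of raising.
- `replicate_correlation`: squared Pearson correlation over shared probes.

## Problem sizes and determinism

Test and acceptance runs use desk-scale instances chosen to make the
statistical checks sharp: 20-pair panels × 2 barcodes × 10⁴ reads for exact
noiseless round-trips, 40 pairs × 3 libraries × 10⁵ reads each for noisy
recovery (Spearman ≥ 0.99 against truth; off-diagonal estimate within 3
binomial σ), 200 random ≤5-pair instances for oracle equivalence. All
randomness flows through explicit integer seeds; identical seeds give
byte-identical FASTQ, panels, and tables.

## Known limitations

- Substitution-only error model; no indels, homopolymer noise, or duplicate
  reads — mapping robustness to those is untested.
- Uniqueness checking is exact-match on the forward strand of the supplied
  sequence, not a genome-wide alignment; repeat-rich targets need an external
  screen.
- No thermodynamic model (Tm/ΔG); primer quality beyond GC and the
  self-complementarity proxy is not assessed.
- The titration model is phenomenological; its breakpoint is an input, so
  titration tests validate the assessment procedure, not reaction chemistry.
- Off-diagonal products are assumed to amplify and sequence like on-diagonal
  ones; length-dependent amplification bias is not modeled.
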