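# Methods

## Scope and model

`dmsmap` analyzes DMS-MaPseq chemical-probing data for a small set of
amplicon-sequenced transcripts (the intended use case is chloroplast mRNAs
plus the 16S rRNA as a structure-known control). Dimethyl sulfate methylates
nucleotides that are single-stranded *and* solvent-accessible; the adducts
are read out as mismatches and deletions introduced during reverse
transcription, so the per-position mutation rate is the raw reactivity. The
package turns per-position mutation-count tables into normalized
reactivities, validates them against a reference structure, summarizes
structure per region (start codon, Shine–Dalgarno window, translation
initiation region, coding region), scores Shine–Dalgarno strength by
anti-SD hybridization free energy, and exports soft-constraint files for
external folding engines.

## Reactivity pipeline

1. **Raw rates.** `raw = (sub_count + del_count) / coverage` at every
   position with coverage ≥ `min_coverage` (default 2500 reads) that is not
   inside a PCR-primer range, not a known RNA-editing site (editing looks
   like a constitutive mutation) and not a known modified rRNA nucleotide.
   When several mask reasons apply, precedence is primer > editing >
   modified > low coverage; the run log's exclusion counts partition the
   total position count. A duplicated (transcript, position) row is an
   error, not a silent overwrite.
2. **Two-channel normalization.** A/C and G/U positions are normalized
   separately because DMS modifies G/U far more weakly. Within each
   transcript and channel the divisor is the mean raw rate of the
   90th–99th percentile window. Window semantics (our convention, exposed
   via `ReactivityParams.percentile_window`): percentiles by linear
   interpolation; a value belongs to the window if it is strictly above the
   90th percentile and at or below the 99th. If ties make that exclusive
   window empty (e.g. an all-constant channel) the lower edge becomes
   inclusive, so a constant channel normalizes to 1 rather than failing.
   Channels with fewer than 20 usable positions, or a zero-mean window, are
   flagged unnormalizable (`profile.attrs["normalization"]`) and left
   unscaled — never silently divided. By construction the window mean of
   the normalized values is exactly 1 and normalization is invariant to
   positive rescaling of a channel's raw rates.
3. **Winsorization.** Per transcript, channels pooled, normalized values
   above the 99th percentile are capped at it (upper side only; nothing is
   removed). The cap is the largest data value at or below the percentile
   rank (`numpy` percentile `method="lower"`), which makes the operation
   idempotent; an interpolated cap would creep downward on re-application.

Normalization is per sample: replicates are processed independently and
summarized afterwards (mean of region metrics per condition, plus a
between-replicate Pearson correlation table), since no pooling rule is
assumed.

## Region definitions

Coordinates are 1-based and inclusive. Regions are anchored on the first
nucleotide of the start codon (+1) with **no relative position 0** (−1
abuts +1); this is the only reading under which −25..+5 spans a round
30 nt:

| region | relative window | length |
|---|---|---|
| start codon | +1..+3 | 3 |
| SD search window | −22..−2 | 21 |
| translation initiation region (TIR) | −25..+5 | 30 |
| CDS | +1..stop-codon end | varies |

Windows running off the transcript are truncated and flagged, never
silently clipped. Start-codon mean reactivity uses adenosines only (the
most reliably probed base); SD and TIR metrics use A/C; an ACGU option
exists for all-nucleotide Gini values. The CDS Gini is computed from the
start codon to the end of the stop codon inclusive — whether the TIR
overlap should be excluded is ambiguous, and we deliberately do not
exclude it.

## Structure statistics

**Gini index.** For reactivities x₁..xₙ (n ≥ 2, mean > 0),
G = Σᵢⱼ |xᵢ − xⱼ| / (2 n² x̄) (population mean-absolute-difference form;
computed via the sorted-rank identity, O(n log n)). A sample-corrected
form with denominator 2 n (n−1) x̄ is available as `form="sample"`; both
are tested against explicit pairwise summation. Higher Gini = more
structured (reactivity concentrated in few positions). Masked positions
are excluded, never imputed as zero.

**ROC validation.** Truth labels come from a reference structure plus a
per-position solvent-accessibility mask (an input artifact — computed
externally from a ribosome crystal structure; all-accessible when absent):
positive iff unpaired **and** accessible. The AUC is computed by the exact
Mann–Whitney rank formula (average ranks; ties count one half), which
equals the trapezoidal area under the interpolated ROC curve
(`sklearn.metrics.roc_curve` supplies the curve for plotting). The exact
rank formula was chosen so the statistic agrees bit-for-bit with
concordant-pair counting.

## Shine–Dalgarno hybridization

The anti-SD 5′-CCUCCU-3′ is hybridized antiparallel and ungapped at every
offset against the −22..−2 window (partial overlaps of ≥ 2 nt allowed at
the edges). Each offset scores the **best single contiguous complementary
run** (Watson–Crick or G·U wobble; runs of fewer than 2 pairs form no
duplex): ΔG(T) = Σ stack (ΔH − T·ΔS/1000) + duplex initiation + one
terminal penalty per helix end closed by A·U or G·U. Default temperature
293.15 K (20 °C); temperature enters only through ΔH − T·ΔS/1000.

Parameters are shipped as a human-readable TSV
(`src/dmsmap/data/rna_stack_turner2004.tsv`): the Turner 2004 RNA–RNA
nearest-neighbor set (Xia et al. 1998 Watson–Crick stacks, Mathews et al.
1999/2004 G·U wobble stacks, duplex initiation ΔG₃₇ = 4.10 / ΔH = 3.61,
terminal A·U penalty ΔG₃₇ = 0.50 / ΔH = 3.72 kcal/mol). ΔS values were
reconstructed as (ΔH − ΔG₃₇)/310.15 × 1000 cal/(mol·K); an integrity test
verifies every stack's reconstructed 37 °C ΔG against the published value
to 0.1 kcal/mol, and that every stack is more stable at 20 °C.

Classification of the minimum ΔG over offsets: strong < −6 kcal/mol;
weak −6 ≤ ΔG < 0; none ΔG ≥ 0 or no duplex. The published thresholds
leave −6 and 0 ambiguous; boundary values are assigned to the weaker
class (a documented convention, `classify_sd`).

Limitations: the contiguous-helix duplex model has no bulges, internal
loops or dangling ends, so it can overestimate ΔG (underestimate binding)
by roughly 1–2 kcal/mol for imperfect SDs relative to co-folding methods.
It is accurate for the long perfect GGAGG-type matches that define strong
SDs; "weak vs none" calls near the 0 kcal/mol boundary are the least
robust.

## Reactivity-guided folding stand-in

`nussinov_fold` / `guided_fold` implement a maximum-pairing interval DP
(Watson–Crick + G·U, hairpin loops ≥ `min_loop` = 3, optional maximum
pairing distance, default off). The guided objective is
(#pairs) − λ·#(paired A/C endpoints with normalized reactivity > θ), with
θ = 0.4 and λ = 2 by default; masked and G/U positions carry no penalty,
and λ → ∞ reproduces a hard constraint. Traceback tie-break: the leftmost
position pairs with the smallest admissible partner, so output is
deterministic; every output is re-validated (nesting, uniqueness,
min-loop) before it is returned. This folder is deliberately **not** a
thermodynamic engine — its role is to make the constraint logic testable
and to produce arc tables; the exported SHAPE-style constraint files
(position, value; −999 = no data; A/C reactivities only) are the supported
path to external minimum-free-energy engines.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes and
nothing more:

- **Rates.** A position gets its channel's unpaired rate iff it is
  unpaired AND solvent-accessible, else the paired rate. Defaults:
  unpaired A/C 0.02, paired A/C 0.002, unpaired G/U 0.006, paired G/U
  0.002, sequencing/RT error 0.001 — chosen once so the A/C channel
  separates strongly and G/U only weakly, mirroring the relative
  reliability of the two channels; they are working values, not estimates
  of measured per-nucleotide rates. Declared editing sites get a fixed
  apparent rate of 0.15 regardless of structure.
- **Counts.** Coverage ~ negative binomial with mean 5000 and size 50
  (CV ≈ 15%, the smooth within-amplicon variation typical of targeted
  RT-PCR sequencing); primer ranges get coverage 0; mutations ~
  Binomial(coverage, rate + error); the mutation count is split 80/20 into
  substitutions and deletions (downstream sums them again). Everything is
  deterministic under a fixed seed; condition/replicate seeds are spawned
  from one master seed.
- **Fixtures.** `rrn16_like` builds a ~1.5 kb hairpin-rich transcript with
  a known pairing map and accessibility mask (unpaired positions are
  accessible with probability 0.85, paired with 0.5, so the negative class
  contains unpaired-but-buried positions, as in a ribosome).
  `footprint_fixture` builds a 120-nt mRNA whose start codon is buried in
  a 9-bp stem that a protein footprint releases in vivo
  (`release_footprint` removes every pair touching the footprint and marks
  the freed positions accessible), with an SD in the −22..−2 window.

What the generator does **not** emulate: read-level effects (PCR
amplification bias, reverse-transcription drop-off, multi-adduct reads),
sequence-dependent modification preferences within a channel, and
correlated noise between neighboring positions. Passing tests therefore
demonstrate that the analysis recovers the signal it is defined to
recover; they do not validate the chemistry model against real libraries.

## Numerical and degenerate-input conventions

- Divisor of zero (all-zero channel) or an undersized channel flags the
  channel instead of producing infinities.
- Region means with zero contributing positions are missing values, never 0.
- Gini requires n ≥ 2 and positive mean; otherwise an error (or `None`
  from the region wrapper).
- ROC requires at least one positive and one negative; otherwise an error.
- Dot-bracket parsing is nested-only; CT files may contain crossing pairs
  and are validated for partner symmetry on read.
- All analysis is deterministic: randomness exists only in the simulator.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the control-transcript
simulation at ~1.5 kb × coverage 5000 over 3 seeds, the footprint scenario
at 120 nt over 20 seeds, brute-force Gini checks on 1000 vectors (n ≤ 200),
pair-counting ROC checks on 100 instances (n ≤ 50) and exhaustive folding
enumeration on 200 sequences (n ≤ 12) — sizes at which the independent
oracles are exact and the whole suite completes in seconds.
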