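# Methods

## Screen model

The fluorescence screen is modelled as an affine bracket.  Each batch pairs
sample wells with a 0% reference (reporter codon encodes a non-fluorogenic
amino acid; residual cell/media fluorescence) and a 100% reference (reporter
codon encodes the fluorogenic amino acid).  Reassignment efficiency is the
sample's position in that bracket, in percent; it is deliberately not
clipped to [0, 100], so noisy replicates retain their audit trail.
Replicates aggregate as arithmetic mean and sample standard deviation
(n−1 denominator; sd = 0 for a single replicate).

Censoring uses a limit of detection of **0.2%** (set by residual
fluorescence) with a strict comparison: a mean exactly at the LOD counts as
detected.  The boundary case never arises in the reference dataset (its
smallest reported value is 0.27%), so the convention is free; strictness
keeps "censored" synonymous with "strictly below what the assay resolves".
Reference pairing defaults to per-batch (a `batch` column in the screen
table); without one, all wells form a single batch.

## Discrimination ratios

`raw_fraction = RE_U / (RE_U + RE_C)` is converted to integer shares by
rounding the U share half-up and taking the C share as the complement.
Round-half-up (not banker's rounding) reproduces every printed ratio we
check (55:45, 68:32, 56:44, 59:41, 52:48, 91:9, 76:24, ≥95:5).  The
statistic is computed from aggregated means, not per replicate, and is
invariant under common rescaling of both efficiencies.

When RE_C is censored, the **floor** substitutes the LOD itself for RE_C:
`RE_U / (RE_U + 0.2)`.  For any true RE_C below the LOD this understates
the U share, so the reported value is a genuine lower bound, displayed with
a `≥` prefix.

One known discrepancy is tolerated rather than absorbed: the
Leu-targeting anticodon's tabulated means (4.3, 1.5) give 74:26 while the
narrative reports 76:24 — consistent with the narrative using unrounded
upstream means.  The regression test for that single anticodon uses a
±2-share-point band; all other ratios are checked exactly.

## Detectability model

The model assumes linear mixing: a fraction f_I of inosine-modified
molecules decodes the C-ending codon at `RE_C = f_I · RE_U` (I34/C3
pairing taken as strong as A34/U3, A34/C3 as negligible).  Modification is
"detectable as anomalous" when RE_C reaches `k · LOD`.  The detection
multiple **k = 2** (effective 0.4%) is a calibrated constant: it is the
unique value consistent with both stated anchors (2% modification visible
at RE_U = 20%, 40% required at RE_U = 1%), and it encodes the practical
rule that anomalous decoding should clear the detection limit with margin
rather than sit on it.  Both `k` and the LOD are configurable.

## Trace quantification

Orientation: the sequenced cDNA strand is the reverse complement of the
tRNA, so the anticodon triplet reads out as the DNA spelling of the
targeted codon and tRNA position 34 is the **third** base of that triplet
in sequencing order.  Localization is reference-driven: the reference cDNA
marks the triplet in lowercase; 12 bases of flanking context on each side
are matched exactly (with the triplet wildcarded, since its third base is
the very position under test), falling back to an edit-distance alignment
(edlib, unit costs, default cap 5 edits) when flank bases are miscalled.
Zero or multiple context matches are errors, not guesses.

Peak quantification integrates each channel trapezoidally over a window
centred on the called peak, extending half the local inter-peak spacing on
each side.  The per-channel baseline is the 5th percentile of that channel
over the whole trace, subtracted per sample with negatives clamped before
integration.  Peak-height measurement is available as an alternative
(`method="height"`); areas are the default because they are less sensitive
to peak-shape differences between dyes.

The modified fraction is `C / (C + T)` area at the position-34 peak.  A
modification call requires both gates: fraction ≥ 0.05 (the level clearly
evident by eye in a chromatogram) and fraction ≥ background mean + 3·sd,
where the background statistics come from the same `C/(C+T)` measurement at
every unambiguous called-T position elsewhere in the same trace.  The
second gate prevents calling modification on a noisy baseline.

Numerical notes.  With the default synthetic noise (below), the 5th
percentile under-subtracts the baseline by roughly 1.6 noise-sd per sample,
which inflates small fractions by ~2–3 percentage points (a 15% mixture is
typically estimated at 17–18%) and places the background fraction near
0.03.  Consequently the 5%/3-sigma call gates sit about 3 sigma above the
background: a borderline false positive on an unmodified trace is possible
at roughly the few-percent level per 15-trace batch (observed at some
seeds), which matches the semi-quantitative character of chromatogram-based
inosine detection.  Noise-free, unquantized traces are recovered exactly
(to 1e-6), which the property tests assert.

## Synthetic data

`simulate_trace` renders each base as a Gaussian peak (default spacing 12
samples, sigma 2.5, amplitude 1000) on its channel, splits amplitude at
mixed positions, adds a flat baseline (20) and Gaussian noise (sd 10),
clips at zero and by default quantizes to integer counts; defaults mimic a
typical analyzed capillary trace and make ABIF round-trips lossless.
Called bases are the majority base per position and peak locations the true
centres — base-calling itself is out of scope.  Not emulated: dye blobs,
mobility shifts, peak-width drift along the read, or quality values;
passing tests therefore demonstrate correctness of the quantification
arithmetic and plumbing, not robustness to real-world trace artifacts.

`simulate_screen` draws per-replicate efficiencies around the true value
with sd 0.5% (n = 12 replicates by default, matching the study's typical
replication; the sd is chosen to respect the reported spread of ≈0.1–1.1%)
and emits the paired reference wells at their exact anchor values — noise
is attributed to the sample measurement, keeping the reference bracket a
fixed coordinate system.

The packaged reference dataset carries the 15 anticodons with their
efficiencies at U/C/A/G-ending codons (censored cells flagged, unevaluated
cells marked), and the sequencing-observed modification fractions encoded
from the study's own wording: fully modified ACG = 1.0, the "nearly 1:1"
AUG = 0.5, the "approximately 15%" AAG = 0.15, all others 0.  The cDNA
flanks around the anticodon triplet are a synthetic stand-in body (the real
tRNA sequence is not part of the packaged data); localization is
reference-driven, so only uniqueness matters.

## Concordance classification

The measured decoded set is the codons above the LOD.  Precedence:
`inosine_like` (U- and C-ending decoded, with sequencing evidence of
modification) over `two_out_of_three` (strong box, two G/C prefix bases,
decoded at U, C and G or better) over `wobble_consistent` (exactly the
original-rules singleton U-ending prediction); anything else is
`anomalous`.  Modification evidence outranks pairing-only explanations
because an I34 anticodon explains C-ending decoding regardless of box
strength.  The "notable tendency to decode the C-ending codon" shading of
the original figure is not quantified anywhere; the classifier therefore
uses LOD membership only and reports raw ratios for human judgment.

## Scales used

All computations are desk-scale: ratio statistics operate on the 15-row
reference table; synthetic traces are ~50 bases (~600 samples); synthetic
screens use 12 replicates per condition.  The full test suite and the
acceptance script each run in a few seconds on one CPU.

## Known limitations

- The rule engine is ordinal (preference order only); no pairing
  thermodynamics, and inosine is the only modified base represented.
- Trace analysis trusts the supplied base calls and peak locations; no
  mobility correction or re-calling.
- Ratios carry no confidence intervals (none are defined for the study's
  statistic); replicate sds are propagated to the RE table only.
- The detectability model's k-multiple detection criterion is a
  reconstruction of "detected as anomalous"; it is exposed as a parameter
  rather than asserted as mechanism.
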