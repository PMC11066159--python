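# wobblescan

Quantitative analysis of wobble-position decoding by orthogonal tRNAs with
unmodified adenosine at anticodon position 34 (A34), as measured in an
*E. coli* sense-codon reassignment screen.

## The scientific problem

Nearly every tRNA gene encoded with A34 is post-transcriptionally deaminated
to inosine (I34), so the *in vivo* decoding behaviour of authentic A34
anticodons is almost unobservable in natural tRNA sets.  Orthogonal
tRNA/synthetase pairs sidestep this: an introduced tRNA can be engineered
with any anticodon and its decoding of each codon in a box measured with a
fluorescent reporter.  Three quantitative questions arise, and this package
implements the analysis for each:

1. **Reassignment efficiency (RE).**  A sample's mean per-cell fluorescence
   is bracketed between a 0% and a 100% reference construct:

   `RE = 100 · (F_sample − F_ref0) / (F_ref100 − F_ref0)`  [percent]

   Replicates are aggregated as mean ± sample sd; efficiencies below the
   screen's limit of detection (LOD, 0.2%) are censored.

2. **U3:C3 discrimination ratio.**  How a single tRNA splits decoding
   between the U- and C-ending codons of its box, independent of absolute
   activity:

   `ratio = RE_U / (RE_U + RE_C)`, reported as integer shares of 100
   (e.g. `55:45`).  When RE_C is censored the LOD is substituted, giving a
   lower bound displayed as `≥95:5`.  A linear-mixing detectability model
   (`f_min = k·LOD / RE_U`, k = 2) states how much inosine modification
   would be visible as anomalous C-ending decoding.

3. **A-to-I quantification from Sanger traces.**  Reverse transcriptase
   reads inosine as G and incorporates C; unmodified A templates only T.
   On the sequenced strand (the reverse complement of the tRNA) the
   anticodon reads out as the DNA form of the targeted codon, with
   position 34 as the triplet's third base.  The inosine-modified fraction
   is the C share of baseline-subtracted T+C peak area at that position,
   called modified when it clears both a 5% visibility threshold and a
   3-sigma gate over the trace's own background.

A wobble-rule engine (original rules, expanded A34 preference U > C > G > A,
inosine rules, two-out-of-three for strong codon boxes) classifies each
anticodon's measured decoded set as `wobble_consistent`, `two_out_of_three`,
`inosine_like`, or `anomalous`.

## Worked example

The packaged reference dataset holds the 15-anticodon study measurements;
the ratio stage reproduces its printed discrimination ratios:

```python
from wobblescan import pipeline as pl, synthetic_data as sd

table = sd.reference_re_table()     # packaged per-anticodon efficiencies
ratios = pl.ratios_from_re_table(table)
print(ratios[ratios.anticodon.isin(["ACG", "AUG", "ACA"])][
    ["anticodon", "codon_u", "re_u", "re_c", "ratio"]].to_string(index=False))
```

```
anticodon codon_u  re_u  re_c ratio
      AUG     CAU   6.1   2.9 68:32
      ACA     UGU   3.6   NaN ≥95:5
      ACG     CGU   7.6   6.1 55:45
```

The His-targeting tRNA (anticodon AUG) decodes CAU twice as often as CAC
(68:32); the Cys-targeting tRNA's C-ending decoding is censored, so only a
lower bound (≥95:5) is reported.  Trace quantification on a synthetic
chromatogram generated at 15% modification recovers that level:

```python
chrom, ref = sd.simulate_reference_trace("AAG", 0.15, seed=42)
call = pl.analyze_trace(chrom, ref)
print(f"estimated inosine fraction: {call.fraction:.3f}  modified: {call.modified}")
```

```
estimated inosine fraction: 0.174  modified: True
```

## Command line

```sh
wobblescan simulate -o demo --seed 7      # synthetic screen + 15 .ab1 traces
wobblescan all -c demo/config.yaml        # re_table, ratios, calls, concordance
```

Reports land in `demo/reports/` as TSV plus `summary.json`; with seed 7 the
summary counts exactly three modified anticodons (AAG, AUG, ACG) and
classifies ACG as `inosine_like`.  Exit codes: 0 ok, 1 data errors, 2
config errors.

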