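# crowdtpp

Analysis pipeline for thermal proteome profiling (TPP) experiments that
measure how macromolecular crowding agents (Ficoll, dextran, PEG) change
protein stability across a whole proteome.

In a TPP experiment, aliquots of a lysate are heated to a gradient of
temperatures (here 30, 34, 38, 43, 47, 52, 56, 60, 66, 70 °C), aggregated
protein is removed, and the soluble remainder is quantified per protein by
TMT-multiplexed mass spectrometry. Comparing a no-crowder control against
treatments containing a crowding reagent at ~150 mg/mL asks, protein by
protein, whether a crowded environment stabilizes or destabilizes the native
fold — and whether the pattern across reagents favours an excluded-volume /
viscosity mechanism or a preferential-exclusion mechanism.

## The model

Reporter intensities are normalized to the lowest temperature, giving fold
changes FC(T) = I(T) / I(30 °C). Each protein-condition curve is fitted with
the three-parameter sigmoid

```
f(T) = (1 − p) / (1 + exp(b − a/T)) + p
```

with T in °C, shape parameter a > 0, offset b > 0, and post-transition
plateau p ∈ [0, 0.5) (the soluble fraction that never aggregates). The
melting temperature — where half the protein is still soluble — has the
closed form

```
Tm = a / (b + ln(1 − 2p))
```

and the curve slope at Tm is df/dT = −(1/2)(1/2 − p) a / ((1 − p) Tm²).
Fits pass "highest stringency" QC when both curves of a (control,
treatment) pair have R² ≥ 0.8 and slope ≤ −0.06 /°C and the control plateau
is < 0.3.

Per treatment, stability shifts ΔTm = Tm(treatment) − Tm(control) of all
QC-passing proteins are standardized to z-scores (sample sd), and
|z| ≥ 1.96 calls a protein significantly stabilized (z ≥ 1.96) or
destabilized (z ≤ −1.96). Downstream stages summarize cross-crowder
concordance, dataset-level QC (Spearman correlations, PCA, Mann–Whitney
comparisons of Tm/slope/plateau distributions), regress per-crowder
stability summaries on reagent physico-chemical descriptors (molecular
weight, intrinsic viscosity, polar atom fraction, hydrophobicity index),
and test sequence features (GRAVY, molecular weight, Fisher-exact keyword
enrichment with Benjamini–Hochberg control) against the call classes.

A synthetic-data generator emulates the full design — control plus six
crowders, sigmoid melting with exact injected ΔTm shifts in a minority of
proteins, multiplicative log-normal intensity noise — so every stage is
testable with known ground truth.

## Worked example

```python
from crowdtpp import SimConfig, generate_experiment, analyze_quants, truth_evaluation

config = SimConfig(n_proteins=100, seed=11)          # control + 6 crowders
experiment = generate_experiment(config)
result = analyze_quants(experiment.quants, control_condition="control")

fits = result.fits
print(f"fitted {len(fits)} curves, {int(fits['qc_pass'].sum())} pass stringency QC")
calls = result.calls
sig = calls[calls["call"] != "null"]
print(f"{len(sig)} significant protein-crowder pairings "
      f"({(calls['call'] == 'stabilized').sum()} stabilized, "
      f"{(calls['call'] == 'destabilized').sum()} destabilized)")
metrics = truth_evaluation(calls, experiment.truth)
print(f"sensitivity {metrics['sensitivity']:.2f}, "
      f"specificity {metrics['specificity']:.3f}, "
      f"sign accuracy {metrics['sign_accuracy']:.2f}")
```

prints

```
fitted 700 curves, 700 pass stringency QC
24 significant protein-crowder pairings (15 stabilized, 9 destabilized)
sensitivity 0.96, specificity 1.000, sign accuracy 0.96
```

i.e. all 100 proteins × 7 conditions yield QC-passing melting curves; the
z-score rule recovers almost every truly shifted protein-crowder pair with
the correct direction, while the ~1% of false calls reflects the 5% two-sided
tail of the calling rule concentrated by the per-treatment standardization.

The same pipeline runs from the shell on TSV inputs:

```
crowdtpp simulate --seed 1 --n-proteins 300 --out experiment/
crowdtpp fit --experiment-dir experiment/ --out fits.tsv
crowdtpp call --fits fits.tsv --out-dir called/
crowdtpp evaluate --calls called/calls.tsv --truth experiment/truth.tsv --out metrics.json
```

or end to end from a YAML config with `crowdtpp run --config config.yaml`,
which writes fits.tsv, calls.tsv, concordance.tsv, qc_correlations.tsv,
pca.tsv, param_tests.tsv, mechanism.tsv, biophysics.tsv, enrichment.tsv and
a run manifest. Real MaxQuant proteinGroups-style tables are read with a
user-supplied channel→temperature map (`crowdtpp.read_quant_table`).

## Layout

| module | role |
| --- | --- |
| `crowdtpp.quant_io` | TSV/FASTA/YAML readers and writers, channel maps, results export |
| `crowdtpp.melt_model` | sigmoid model, closed-form Tm/slope, bounded least-squares fitting, stringency QC |
| `crowdtpp.stability_calling` | ΔTm, per-treatment z-scores, significance calls, concordance |
| `crowdtpp.profiles_qc` | Spearman matrices, PCA, Mann–Whitney comparisons, aggregation profiles |
| `crowdtpp.mechanism` | per-crowder stability summaries and descriptor regressions |
| `crowdtpp.feature_analysis` | GRAVY, protein mass, keyword enrichment, class comparisons |
| `crowdtpp.synthetic_data` | ground-truth experiment generator and call evaluation |
| `crowdtpp.cli` | pipeline orchestration and the `crowdtpp` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
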