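# snvconsensus

Category-aware, calibrated consensus prediction of deleterious
single-nucleotide variants (SNVs).

## The problem

Variant-effect predictors (CADD-, DANN-, FATHMM-style tools) emit raw
scores on incomparable scales, without fixed decision thresholds or
interpretable confidences.  Worse, an SNV's genomic context matters: the
score distributions such tools produce for regulatory, splicing, missense,
synonymous and nonsense variants differ substantially, so one global
cutoff is systematically miscalibrated for some categories.  This package
is for anyone who has per-variant scores from several such tools and wants
a single calibrated answer: it never runs the external tools itself —
their scores are inputs.

The framework:

1. **Categorizes** each SNV into one of five genomic categories —
   regulatory, splicing, missense, synonymous, nonsense — from gene models
   (GFF3/GTF) and a reference FASTA, by codon translation and splice-site
   proximity, with severity precedence across overlapping transcripts.
2. **Learns category-optimal thresholds** per tool: the cutoff *t*
   maximizing the normalized (balanced) accuracy on training data,

   NACC = (sensitivity + specificity) / 2,

   searched over midpoints of consecutive distinct scores (ties break
   toward sensitivity).
3. **Calibrates confidences**: training scores are sorted and cut into up
   to 66 equal-size bins; per-bin fractions of deleterious labels are
   smoothed by an 11-bin centered moving average; a query score is mapped
   (by interpolation between bin centers) to the observed accuracy of its
   own prediction side, yielding a uniform confidence c ∈ {0, …, 99}.
4. **Votes**: with vᵢ = +1 (deleterious) or −1 (neutral) and weights
   wᵢ = cᵢ/100, the consensus score is S = Σwᵢvᵢ / Σwᵢ ∈ [−1, +1].
   S is then re-thresholded and re-calibrated exactly like a raw tool
   score.  Per category, every tool subset of size ≥ 2 is evaluated on
   training data and the best one selected, since weak tools can drag the
   vote down.
5. **Builds leakage-controlled datasets**: 1:1 matching of each
   deleterious variant to its nearest unused neutral neighbor, overlap
   filtering against disease sets, date-based train/test splits, and —
   for coding variants — greedy 50%-identity protein clustering so similar
   proteins never straddle the split.

## Worked example

Train and evaluate on the built-in synthetic study (five categories, five
tools — four informative, one pure noise — with category-shifted score
scales):

```python
from snvconsensus import default_spec, simulate_scores, train_bundle, predict
from snvconsensus.evaluation import confusion_metrics

spec = default_spec(seed=1, n_per_class=500)
datasets, scores = simulate_scores(spec)
bundle = train_bundle({c: d["train"] for c, d in datasets.items()}, spec.tools)

for category, cm in sorted(bundle.consensus.items()):
    test = datasets[category]["test"]
    preds = predict(test.variants, scores, bundle)
    m = confusion_metrics([p.consensus_prediction for p in preds],
                          [v.label for v in test.variants])
    print(f"{category:11s} tools={','.join(cm.tools):24s} "
          f"best_single={cm.best_single_tool}:{cm.best_single_tool_accuracy:.3f} "
          f"test_nacc={m.normalized_accuracy:.3f}")
```

prints

```
missense    tools=alpha,beta,gamma         best_single=alpha:0.932 test_nacc=0.956
nonsense    tools=alpha,gamma              best_single=alpha:0.916 test_nacc=0.978
regulatory  tools=alpha,gamma              best_single=alpha:0.924 test_nacc=0.940
splicing    tools=alpha,beta,delta,gamma   best_single=alpha:0.928 test_nacc=0.966
synonymous  tools=alpha,gamma              best_single=alpha:0.922 test_nacc=0.958
```

Per category you see the selected tool subset (the noise tool is never
chosen), the strongest individual tool with its training accuracy, and the
consensus normalized accuracy on held-out data — consistently above the
best single tool.  Each `Prediction` carries the per-tool votes, e.g.
`('1', 31000, 'A', 'G') synonymous D 71 {'alpha': ('D', 78), 'gamma':
('D', 90)}`: both selected tools vote deleterious and the calibrated
consensus reports confidence 71.

The same workflow is available from the shell: `snvconsensus simulate`,
`categorize`, `build`, `train`, `predict`, `evaluate` (see `--help`).

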