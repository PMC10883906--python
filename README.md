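# guideoff

Interpretable prediction of CRISPR Cas-9 **off-target** cleavage from
sequence alone. Given a single-guide RNA and a candidate genomic site as
a pair of 23-mers (20-nt spacer + NGG PAM, up to six substitution
mismatches), `guideoff` answers: *will Cas-9 cut here anyway?* — and then
explains which positions and mismatches drove the call.

It is aimed at computational biologists who need an off-target classifier
they can train, tune and *audit* on their own guide/site tables, without
GPUs or deep-learning frameworks: the whole stack runs on NumPy.

## What is inside

* **Pair encoding** — the guide and site are one-hot encoded over
  channels (A, T, C, G) and superposed with a logical OR, so a match
  activates one channel per position and a mismatch two; an optional
  fifth channel records the mismatch direction under the precedence
  A > T > C > G. Position 21 is the wildcard N (all-zero row).
* **Recurrent classifier** — a generic parameterized network (vanilla
  RNN / LSTM / GRU; 1–2 layers, optionally bidirectional; a dense head
  whose widths halve from the hidden size; ReLU + dropout; 2-unit softmax
  output), exposed as a scikit-learn style estimator
  (`RecurrentOffTargetClassifier` with `fit` / `predict_proba` /
  `get_params`). Training uses Adam + cross-entropy with **balanced
  bootstrapping**: every mini-batch holds equal class counts, negatives
  without replacement (one pass = one epoch), positives resampled — the
  antidote to the field's ~1:230 class imbalance. Model selection
  optimizes AUPRC (step-wise average precision).
* **Elitist genetic algorithm** — hyperparameter search over the
  discrete 8-gene space (72 000 combinations before the hidden-layer
  gene), population 20, 4 elites, binary tournaments, per-gene crossover
  p=0.3 and mutation p=0.2, 20 generations, with full replay histories.
* **Integrated-gradients interpretation** — per-channel attributions of
  the class log-odds along a zero-baseline path (completeness checked),
  L1-normalized per sample and aggregated into ranked
  (position, base-pair) feature tables, region summaries over PAM
  (21–23) / PAM-proximal seed (16–20) / seed core (11–15) / PAM-distal
  (1–10), neuron-level conductance rankings and activation heatmaps.
* **Synthetic benchmark generator** — 23-mer pairs with an NGG PAM,
  configurable imbalance and label noise, and a *planted* positional
  rule, so every stage is testable end to end without external data.

See `docs/methods.md` for the model, the training protocol and every
numerical choice.

## Worked example

Train a compact bidirectional LSTM on a synthetic benchmark whose hidden
rule is *"off-target iff the PAM is intact and positions 16–20 are
mismatch-free"*, then ask the attribution stage where the model looks:

```python
from guideoff.experiments import planted_rule_recovery

study = planted_rule_recovery(n_records=6000, imbalance_ratio=9, seed=0,
                              steps=32)
print(f"AUPRC {study['metrics'].auprc:.3f}")
print(f"top-10 on 16-20: {study['top_on_rule_positions']}/10")
print(study["top_features"][["position", "sgrna_base", "dna_base", "kind",
                             "score_positive"]].to_string(index=False))
```

prints

```
AUPRC 0.999
top-10 on 16-20: 8/10
 position sgrna_base dna_base  kind  score_positive
       20          T        T match       -0.021853
       19          A        A match       -0.021669
       18          C        C match       -0.021371
       16          C        C match       -0.020427
       18          A        A match       -0.020315
       15          T        T match       -0.020081
       19          C        C match       -0.019529
       22          G        G match       -0.019223
       17          G        G match       -0.018902
       16          T        T match       -0.018842
```

The classifier separates the classes almost perfectly (held-out AUPRC
0.999), and 8 of its 10 highest-magnitude positive-aggregate features sit
on the planted rule positions 16–20: the interpretation stage
re-discovers, from gradients alone, the seed-region rule that generated
the labels. (`score_positive` is the mean normalized attribution of the
class log-odds over positive samples; features rank by magnitude, so
strong negative correlates count as top contributors too.)

The same pipeline is scriptable from a shell:

```bash
guideoff simulate --n 6000 --ratio 9 --seed 0 --out pairs.tsv
guideoff train --data pairs.tsv --genome genome.json --seed 0 --out run/
guideoff interpret --checkpoint run/model.ckpt.npz --data pairs.tsv --out report/
```

Real benchmark tables (columns `sgrna`, `dna`, `label`; TSV or CSV,
arbitrary column names via a mapping) are read with
`guideoff.io.read_dataset`, which quarantines malformed rows into a
rejects report instead of dropping them.

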