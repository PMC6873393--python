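# ruleforge

Interpretable threshold-rule induction for expression data, with the
evaluation stack used to benchmark such classifiers: per-study
diagnostic accuracy statistics, Mantel–Haenszel pooling for multi-class
confusion matrices, fixed-effect summary-ROC meta-analysis, a
leave-one-out cross-validation harness with tuning grids, and a
synthetic expression-data generator with planted threshold rules.

## How it works

Training proceeds in three phases:

1. **Latticization** — every continuous feature is discretized by
   greedy entropy-minimizing midpoint cutoffs (half-open bins,
   `value <= cutoff` belongs to the lower bin) and each sample is
   encoded as one long bit string using inverse only-one coding (all
   bits 1 except a 0 at the bin position).
2. **Implicant generation** — per class (one-vs-rest), uncovered
   samples seed fully specific bit patterns that are generalized
   greedily: first removing the premise bits whose removal covers the
   most additional same-class samples, then pruning every remaining
   bit the false-positive bound still allows (least discriminative
   first), repeating to a fixpoint.  Every implicant respects the
   `max_error` false-positive fraction.
3. **Rule generation** — contiguous runs of admitted bins become
   threshold conditions (`x <= t`, `x > t`, `a < x <= b`); each rule
   carries its covering `C(r)` (own-class fraction captured) and error
   `E(r)` (other-class fraction captured).  Prediction is a
   covering-weighted vote over fired rules; when nothing fires the
   largest training class wins.

Rule and variable relevance follow `R(c) = dE(c) * C(r)` and
`R_v = 1 - prod(1 - R(c))`; rules with `C(r)(1 - E(r)) <= 10%` are
flagged as likely outlier-catchers.

The meta-analysis layer pools per-study `(log OR, variance)` pairs by
inverse-variance weighting into a summary odds ratio `sOR`, evaluates
the summary ROC curve `sROC(x) = x*sOR/(x*sOR + 1 - x)` and its
closed-form area `sAUC = sOR/(sOR-1) - sOR*log(sOR)/(sOR-1)^2`.

## Command line

```sh
# generate a synthetic dataset with planted single-condition rules
ruleforge simulate --seed 1 --n-per-class 20 --features 200 --out-dir data/

# train a rule model and render its rules
ruleforge train --matrix data/matrix.tsv --labels data/labels.tsv \
    --max-error 0.05 --out model.json

# classify new samples
ruleforge predict --model model.json --matrix data/matrix.tsv --out pred.tsv

# leave-one-out benchmark (method x metric percent report)
ruleforge crossval --matrix data/matrix.tsv --labels data/labels.tsv \
    --methods llm,dt,knn --out report.tsv

# accuracy statistics for a labelled confusion table
ruleforge evaluate --confusion cm.tsv --reference HC

# pool per-study odds ratios into a summary ROC report
ruleforge sroc --studies studies.tsv --out sroc.tsv --curve curve.tsv
```

Matrices are delimited text (TSV/CSV) with samples in rows, a header of
feature ids and the sample id in the first column (`--orientation
genes-in-rows` transposes); labels are two-column (sample id, class)
files; models are JSON.

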