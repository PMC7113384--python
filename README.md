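# afpscan

Identify antifreeze proteins (AFPs) from evolutionary sequence information.

AFPs bind ice and inhibit ice-crystal growth and recrystallization, which
makes them valuable in cryopreservation, de-icing and food storage — but they
are rare, structurally diverse across taxa, and hard to find by homology
search alone. `afpscan` implements a classification pipeline that works
directly from each protein's position-specific scoring matrix (PSSM), the
per-position substitution-score profile produced by an iterative PSI-BLAST
search, on the premise that the *conservation pattern* of a protein — which
residues resist replacement, and by what — carries the signal that raw
sequence similarity misses.

## Method

Given a protein of length *n* and its *n* × 20 log-odds PSSM:

1. **PSSM-400 encoding.** Rows sharing the same query residue *X* are summed
   into a 20 × 20 matrix whose (*X*, *Z*) entry accumulates the score for
   replacing *X* by residue *Z*; flattening gives a 400-feature vector. A
   strongly negative *X*–*Z* entry means the replacement is rarer than chance
   — residue *X* is conserved at those positions.
2. **MWMOTE balancing.** AFPs are heavily outnumbered, so the minority class
   is augmented with the Majority Weighted Minority Oversampling TEchnique:
   informative borderline AFP samples are weighted by closeness and density
   factors relative to the nearby non-AFP samples, and synthetic AFP vectors
   are interpolated strictly inside observed AFP clusters, up to a target
   minority:majority ratio (default 0.78).
3. **Ensemble mRMR ranking.** Features are discretized (3 states at
   μ ± σ) and ranked by greedy minimum-redundancy–maximum-relevance using
   plug-in mutual information, aggregated over stratified bootstrap resamples
   by mean rank position.
4. **Parsimonious incremental selection.** Ranked features are added one at a
   time to an RBF-kernel SVM; the model preceding the first drop of the
   monitored metric (default AUC) on the independent test partition is kept.
5. **Evaluation and interpretation.** Models report ACC, SN, SP, a
   pair-counting AUC (ties ½) and MCC; a PCA of the selected key features
   quantifies each feature's contribution to component *j* as
   r²ᵢⱼ / Σᵢ r²ᵢⱼ, with rᵢⱼ the Pearson correlation between feature *i* and
   the component scores (uniform contributions = 1/p for *p* features).

A synthetic-data module generates PSSM profiles with a planted class signal —
by default depressed C→A, W→M, G→A, R→S and R→R replacement scores in the
positive class, plus two configurable extras — so every stage is testable
without external sequence databases.

## Worked example

```python
from afpscan import classify, encoding, feature_selection, resampling
from afpscan.synthetic import SimulationConfig, simulate_pssm_profiles

config = SimulationConfig(n_pos=200, n_neg=800, delta=8.0, noise_sd=2.0, seed=42)
profiles, labels = simulate_pssm_profiles(config)
table = encoding.encode_dataset(profiles, labels)
train, test = classify.stratified_split(table, train_fraction=0.8, seed=42)
balanced = resampling.mwmote_oversample(
    train, resampling.ResamplePlan(target_ratio=0.78, seed=42))
print(f"training rows: {train.n_samples} -> {balanced.n_samples} "
      f"(minority ratio {train.minority_ratio:.2f} -> {balanced.minority_ratio:.2f})")
ranking = feature_selection.ensemble_rank(balanced, n_ensemble=20, K=20, seed=42)
print("top substitution features:",
      ", ".join(table.feature_names[i] for i in ranking.order[:7]))
model = classify.train_svm(balanced, grid=classify.fast_grid(), seed=42,
                           feature_indices=ranking.order[:7])
report = classify.evaluate(test.labels, classify.decision_values(model, test))
print(f"independent test: ACC={report.acc:.2f} SN={report.sn:.2f} "
      f"SP={report.sp:.2f} AUC={report.auc:.2f} MCC={report.mcc:.2f}")
```

prints

```
training rows: 800 -> 1140 (minority ratio 0.25 -> 0.78)
top substitution features: K-Q, W-M, R-R, E-D, G-A, C-A, R-S
independent test: ACC=1.00 SN=1.00 SP=1.00 AUC=1.00 MCC=1.00
```

MWMOTE raises the AFP:non-AFP ratio of the training partition from 0.25 to
the 0.78 target; the consensus ranking surfaces exactly the seven planted
substitution pairs; and the seven-feature SVM classifies the untouched test
partition perfectly — the planted shift (δ = 8 score units per position,
noise σ = 2) makes the classes cleanly separable by design.

The same workflow is available from the shell:

```bash
afpscan simulate --npos 200 --nneg 800 --delta 8 --seed 42 --out-dir fixtures/
afpscan encode --fasta fixtures/sequences.fasta --pssm-dir fixtures/pssm \
               --labels labels.json --out table.csv
afpscan resample --in train.csv --ratio 0.78 --seed 42 --out balanced.csv
afpscan rank --in balanced.csv --ensemble 20 --seed 42 --out ranking.json
afpscan run --config run.json        # the whole pipeline from one JSON config
```

Real inputs are FASTA sequences plus one PSI-BLAST ASCII PSSM per sequence
(the documented invocation is `psiblast -db swissprot -num_iterations 3
-evalue 0.0001 -out_ascii_pssm <id>.pssm`; running the profile search itself
is outside this package's scope). Sequences containing the ambiguous letters
X, B, U or O are filtered out before encoding.

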