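# tcrpred

Clinical outcome prediction from T-cell receptor (TCR) repertoires.

The TCR beta-chain CDR3 region carries a readout of a patient's adaptive
immune history, but repertoires are unstructured — each individual holds
thousands of unique amino-acid sequences with wildly varying abundances,
and two individuals share almost none of them.  `tcrpred` turns a cohort
of repertoires plus a clinical table into a risk prediction model by
combining two complementary representations of the repertoire:

* **extracted features** — amino-acid k-mer counts aggregated over the
  repertoire, with L1-penalized coefficients so the model names the
  predictive k-mers; and
* **hidden features** — everything the k-mers miss (structural motifs,
  long-range residue interactions), modeled non-parametrically through a
  repertoire-homology kernel and the representer theorem.

For individual *i* with outcome *Y_i*, covariates *X_i* and repertoire
*R_i* = {(a_ij, w_ij)} the model is

    E[Y_i] = pi( beta0 + X_i' beta + Z(R_i)' gamma + h(R_i) ),
    h(R_i) = K_i' alpha,

with identity or logistic link `pi`, penalties `lambda0 |gamma|_1 +
lambda1 ||h||^2` and the kernel

    k(R_i, R_i') = [ sum_j w_ij max_j' s(a_ij, a_i'j')
                   + sum_j' w_i'j' max_j s(a_ij, a_i'j') ]
                   / ( sum_j w_ij + sum_j' w_i'j' ),

where `s` is the self-normalized global alignment score under BLOSUM62 or
PAM250.  Estimation alternates an exactly-solved partially penalized
(weighted) lasso with a closed-form kernel update
`alpha = (lambda I + K)^(-1) (residual)`, `lambda = (p + r + 1)/n`,
computed in the kernel's leading eigenbasis.  `docs/methods.md` has the
full account, including the binary working-response iteration and the
synthetic-cohort generator.

Intended users: statistical-genetics / immunogenomics researchers with
AIRR-style rearrangement TSVs or simple per-clone CSVs and a per-patient
covariate table, who want covariate-adjusted risk prediction rather than
repertoire summaries.

## Worked example

Everything below runs on synthetic data generated in-process (no
downloads).  We simulate a binary cohort where six causal k-mers and a
kernel-structured hidden effect drive the outcome, fit the model on 150
training individuals, and score 150 held-out individuals:

```python
import numpy as np
import tcrpred as t
from tcrpred.model import fit_binary, predict

pool, _ = t.filter_repertoires(t.generate_pool(t.DESK_POOL_SPEC, seed=11))
cfg = t.SimulationConfig(n_train=150, n_test=150, c0=5.0, tau=5.0)
data = t.simulate_dataset(cfg, pool, seed=0)
tr, te = data.train_idx, data.test_idx

Z = t.screen_features(data.Z, data.y[tr], tr)       # 5% prevalence + SIS
K_fit = t.psd_project(data.K_raw.subset(tr))        # training kernel
model = fit_binary(data.y[tr], data.X[tr], Z.subset_rows(tr), K_fit,
                   random_state=0)
print("selected k-mers:", model.selected_features)
print("cross-entropy trace:", np.round(model.loss_trace, 4))

sel = [Z.feature_names.index(c) for c in model.selected_features]
pred = predict(model, data.X[te], Z_new=Z.values[te][:, sel],
               K_cross=data.K_raw.values[np.ix_(te, tr)])
report = t.evaluate(pred.probability, data.y[te], "binary")
print("test AUC = %.3f, classification error = %.3f"
      % (report.auc, report.classification_error))
```

Output:

```
selected k-mers: ['AFF', 'CGS', 'CLS', 'GSL', 'PSY', 'SEL', 'SPA', 'SPV', 'SQH', 'STS', 'STT', 'TEQ']
cross-entropy trace: [0.288  0.2729 0.2719 0.2714 0.2714]
test AUC = 0.807, classification error = 0.307
```

The selected set includes several of the V/J-motif k-mers that the
generator made causal (`AFF`, `CGS`, `CLS`; the generating coefficients
live in `data.causal_features` / `data.gamma`); the cross-entropy trace
shows the alternating fit converging in a handful of iterations; and the
held-out AUC of 0.81 reflects both signal channels.  Fitting the same
data with `tcr_lasso` (no kernel term) or `basic_glm` (covariates only)
through `t.run_benchmark` gives lower AUC — that ordering, averaged over
replicates, is the package's headline benchmark.

### Command line

The same pipeline is available as a console tool for file-based workflows:

```
tcrpred features reps.csv --covariates cov.csv -o Z.csv --k 3
tcrpred kernel   reps.csv -o K.csv --submatrix blosum62
tcrpred fit      reps.csv cov.csv -o model.json --k 3
tcrpred predict  model.json new_reps.csv --covariates new_cov.csv -o preds.csv
tcrpred simulate -o report.csv --replicates 10 --seed 1
```

Repertoires are read either as AIRR rearrangement TSV (`--format airr`,
columns `junction_aa` / `duplicate_count`) or as a simple CSV with columns
`individual_id,sequence,abundance`.  Every run writes a
`<output>.manifest.json` with the configuration and input checksums;
`tcrpred predict` refuses to run if the training-repertoire file no longer
matches the checksum stored in the model.

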