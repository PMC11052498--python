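# qsarkit

An open, tested toolkit for classical QSAR modelling of congeneric
inhibitor series — the kind of analysis traditionally run inside
commercial molecular-modelling suites, here reimplemented as a plain
Python library with scikit-learn-style estimators.

It was built around a published 65-compound imidazo[4,5-b]pyridine
Aurora-A kinase inhibitor series, whose experimental activities,
per-compound model predictions and external-validation reference
statistics ship as plain-text fixtures, and it covers the full workflow:

* **Molecular holograms** (`qsarkit.hologram`) — every connected
  heavy-atom fragment of 
  a molecule within a size window is canonicalized under *distinction
  flags* (atom A, bond B, connectivity C, hydrogens H, chirality Ch,
  donor/acceptor DA) and count-hashed into a prime-length vector
  (53 … 401). `HologramFingerprinter` is a scikit-learn transformer.
* **Lattice interaction fields** (`qsarkit.fields`) — CoMFA-style
  Lennard-Jones steric and Coulomb electrostatic probe energies
  (sp³ C⁺ probe, 1.52 Å/+1, ±30 kcal mol⁻¹ clamp, D(r) = r) and
  CoMSIA-style Gaussian similarity fields
  A(q) = −Σᵢ w_probe·w_i·exp(−0.3 r²) for S/E/H/D/A properties, on a
  2.0 Å lattice with a 4.0 Å margin around the Kabsch-aligned series.
* **PLS with leave-one-out validation** (`qsarkit.pls`) — a NIPALS PLS1
  regressor (`PLSRegressionNIPALS`) with q² = 1 − PRESS/SS from true
  per-fold refits, SEE = √(RSS/(n−N−1)), F statistics, and component
  selection by maximal LOO q².
* **R-group contributions and screening** (`qsarkit.rgroup`) — a
  congeneric series is cut at labeled single bonds into skeleton +
  Ra/Rb/Rc fragments; a PLS model over per-position fragment field
  vectors decomposes every prediction exactly into
  intercept + Σ fragment contributions, which drives library screening
  and candidate assembly.
* **External-validation battery** (`qsarkit.validation`) —
  r²_pred = 1 − PRESS/SD (SD about the *training* mean), RMSE, MAE, the
  concordance correlation coefficient, through-origin slopes k, k′ with
  r0², r0²′, and Roy's rm² = r²(1−√(r²−r0²)) pair, each judged against
  the standard thresholds (r²_pred > 0.6, 0.85 < k, k′ < 1.15,
  (r²−r0²)/r² < 0.1, rm² > 0.5, Δrm² < 0.2, CCC > 0.85).
* **Synthetic ground truth** (`qsarkit.synthetic`) — additive
  scaffold+R-group series (pIC50 = base + Σ contributions + N(0, σ))
  and valence-valid random molecular graphs, so every stage is testable
  against known answers.

A `qsar` command-line interface (subcommands `data`, `hqsar`, `fit`,
`validate`, `screen`, `synth`) wraps the library for shell use.

## Worked example

Validate the packaged Topomer CoMFA predictions of the Aurora-A series
against their 16-compound external test set, using the model's published
training r² = 0.971 for the rm² pair:

```python
from qsarkit.datasets import load_aurora_predictions, published_model_r2
from qsarkit.validation import PredictionTable, validate_predictions

df = load_aurora_predictions()
table = PredictionTable(ordinal=df.ordinal.values, y=df.pic50_exp.values,
                        y_pred=df["topomer"].values, role=df.role.values)
report = validate_predictions(table, r_sq_model=published_model_r2("topomer"))
print(report.to_frame().to_string(index=False))
```

```
     metric  value               criterion  passed
    r2_pred  0.855           r2_pred > 0.6    True
          k  0.984         0.85 < k < 1.15    True
    k_prime  1.012        0.85 < k' < 1.15    True
      r0_sq  0.860  (r^2 - r0^2)/r^2 < 0.1    True
r0_sq_prime  0.835 (r^2 - r0'^2)/r^2 < 0.1    True
      rm_sq  0.647              rm^2 > 0.5    True
rm_sq_prime  0.613             rm'^2 > 0.5    True
delta_rm_sq  0.034        delta rm^2 < 0.2    True
       rmse  0.443               RMSE -> 0    True
        mae  0.346                MAE -> 0    True
        ccc  0.920              CCC > 0.85    True
```

Reading the table: the model explains 85.5 % of the test-set deviance
about the training mean (r²_pred), predictions track experiment with
near-unit through-origin slopes, Roy's rm² of 0.647 clears the 0.5 bar,
and the 0.443 pIC50-unit RMSE corresponds to under a factor of 3 in
IC50. All eleven criteria pass, so the model is judged externally
predictive.

Note on the reference statistics: the published MAE values exceed the
published RMSE values, which is arithmetically impossible for residuals
of a single test set; when a reference column is supplied,
`validate_predictions` flags this (and the analogous r²_pred
inconsistency of the CoMSIA column) as warnings rather than reproducing
the impossible numbers.

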