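# Methods

This note documents the models and numerical conventions implemented in
qsarkit, the choices made where the underlying methods are
convention-dependent, and what the synthetic study conditions do and do
not establish.

## Data model

A congeneric series is a set of compounds sharing one scaffold and
differing at a few substitution positions. Activities are handled as
pIC50 = −log10(IC50 [M]); IC50 input must be molar unless an explicit
unit flag (`nM`, `uM`) says otherwise — magnitudes are never used to
guess units. The train/test split assigns every compound whose ordinal
number is ≡ `start` (mod `period`) to the test set (defaults 2 mod 4);
on the packaged 65-compound Aurora-A fixture this yields the published
49/16 partition. The fixture's SMILES are best-effort synthetic
reconstructions from substituent names and a drawn scaffold; they are
flagged non-authoritative and no numeric result depends on them — all
reproduced statistics use only the printed activities and predictions.

## Molecular holograms

Fragments are **connected vertex-induced subgraphs of the heavy-atom
graph**, counted once per distinct vertex set, enumerated by the ESU
scheme with an explicit cap (exceeding the cap raises; enumeration is
never silently truncated). Fragment size is measured in heavy atoms;
attached hydrogens are atom attributes (flag H), not vertices. Each
fragment's canonical key is a Weisfeiler–Lehman iterative-refinement
hash over the attributes selected by the distinction flags (element,
bond order, heavy-atom degree in the parent molecule, hydrogen count,
CIP chirality code, donor/acceptor indicators), prefixed with the
fragment size. Keys are binned by CRC-32 modulo one of the twelve
admissible prime lengths {53, 59, 61, 71, 83, 97, 151, 199, 257, 307,
353, 401}. Both WL hashing and CRC-32 are platform-independent, so
holograms are bit-reproducible. WL is not a complete graph invariant;
in the rare event two distinct fragments share a key they merge into
one bin, which is the same information loss hologram hashing already
accepts by design. The default window 2–4 with flags A/Ch and length
257 mirrors the best published hologram model for the fixture series;
commercial fragmentation grammars are proprietary, so their per-model
q²/r² values are reference context, not reproduction targets.

## Interaction fields

Molecules are rigidly superposed onto a scaffold template by Kabsch
least squares (≥ 3 non-collinear mapped atoms; no scaling). The lattice
is the union bounding box of the aligned series expanded by a 4.0 Å
margin, discretized at 2.0 Å inclusive of both ends (≥ 2 points per
axis); the top end is pushed outward to the next grid point when the
extent is not a spacing multiple.

CoMFA-style fields use an sp³ carbon probe (1.52 Å, +1 e, ε = 0.107
kcal/mol): steric = Σⱼ εⱼ[(Rⱼ/r)¹² − 2(Rⱼ/r)⁶] with Rⱼ = probe + atom
radius and εⱼ the geometric-mean well depth; electrostatic
= Σⱼ 332.0636 q_p qⱼ / r² — a distance-dependent dielectric D(r) = r,
the conventional choice where only "Coulomb" is specified. Both fields
are clamped to ±30 kcal/mol (the single published cutoff is applied to
both signs); a lattice point coinciding with an atom contributes
+cutoff sterically and sign(q_p qⱼ)·cutoff per electrostatic term, and
is listed in the block's singular-point metadata. vdW radii and well
depths are a small in-code table of standard literature values; partial
charges are Gasteiger (iterative partial equalization of orbital
electronegativity) with hydrogen charges folded onto heavy atoms so the
molecular charge is conserved.

CoMSIA-style similarity fields are A_k(q) = −Σᵢ w_probe,k·w_ik·
exp(−0.3 r²) with a 1 Å, all-weights-+1 probe and no distance cutoff.
Per-atom property weights: steric = (vdW radius)³ as a volume proxy,
electrostatic = Gasteiger charge, hydrophobic = Crippen atomic logP
contribution, donor/acceptor = {0,1} indicators (donor: N/O bearing H;
acceptor: N/O with non-positive formal charge — a deliberately simple,
documented perception rule). Columns with standard deviation below a
threshold can be dropped (default 2.0 kcal/mol for CoMFA energies, 0
for similarity indices); filtering is done once on the training block
and not re-run per cross-validation fold, which keeps folds comparable
at the cost of a small, uniform selection optimism.

Because the original study's conformers came from a commercial
force-field minimization, absolute field values are
convention-dependent; 3D embedding here is deterministic (ETKDG, fixed
seed) and no reproduced statistic depends on conformers.

## PLS and internal validation

PLS1 is fitted by NIPALS on centered (optionally autoscaled) data,
tolerance 1e−10, ≤ 500 iterations per component (one iteration suffices
for a univariate response); scores are mutually orthogonal and
predictions are reproducible from coefficients + intercept alone. At
full rank the solution coincides with ordinary least squares. A
zero-variance response degenerates to the intercept model with a
warning. Internal statistics follow the conventions of field QSAR
suites: r² is the squared correlation of fitted vs observed;
SEE = √(RSS/(n−N−1)) with the component-adjusted denominator;
F = (r²/N)/((1−r²)/(n−N−1)); q² = 1 − PRESS/Σ(yᵢ−ȳ)² with every
held-out prediction coming from a genuine refit and ȳ the full training
mean. Component count is chosen by maximizing LOO q² over 1..N_max,
ties toward the smaller model.

## R-group contributions and screening

A cut specification is a scaffold SMILES with numbered attachment
dummies marking acyclic single bonds; cutting partitions the heavy
atoms into core + per-position fragments (positions carrying only
hydrogen yield `*[H]`). Bare cores often have automorphisms, so every
match orientation is tried and, among orientations that route all
substituents through labeled anchors, the lexicographically smallest
fragment assignment is taken — deterministic and independent of atom
input order.

Each fragment gets a standard pose (deterministic embedding; attachment
vector along −x, the farthest off-axis atom rotated into the +y
half-plane) and a steric+electrostatic Gaussian field vector on a fixed
shared fragment lattice. A PLS model over the concatenation of the
per-position vectors is linear, so every prediction decomposes exactly
as intercept + Σ position contributions (the constant core term lives
in the intercept); swapping one fragment changes the prediction by
exactly the contribution difference. Fragment distance is the
root-sum-square difference of the two field vectors after scaling each
field block by its pooled (pair-wise) standard deviation — symmetric,
zero at identity, insensitive to the fields' different natural units.
The published screening workflow quotes a "topological distance" on an
undocumented scale; that scale is not reproducible and is not treated
as a target. Screening keeps library fragments within a distance cap of
the query and above a contribution floor, sorted by contribution
descending, ties by distance then SMILES (a deterministic total order).

## External validation battery

With test-set experimental y and predicted ŷ, training mean ȳ_tr:

* r²_pred = 1 − Σ(y−ŷ)² / Σ(y−ȳ_tr)². The deviance is about the
  **training** mean: this convention reproduces the published 0.814 /
  0.829 / 0.855 values exactly, where the test-mean variant does not.
* RMSE and MAE over test residuals (RMSE ≥ MAE is an identity).
* CCC with test-set means of both variables.
* k = Σyŷ/Σŷ², k′ = Σyŷ/Σy²; r0² = 1 − Σ(y−kŷ)²/Σ(y−ȳ_test)² and the
  primed analogue with roles swapped.
* rm² = r²(1−√(r²−r0²)) and rm²′ likewise; Δrm² = |rm²−rm²′|. The r²
  entering the pair is the model's **non-cross-validated training r²**
  supplied by the caller — this reproduces the published rm² values to
  3 decimals (e.g. 0.609/0.559/0.647), whereas the all-test-set variant
  is available by omitting the argument. The slope criteria
  (r²−r0²)/r² < 0.1 use the test-set squared correlation, the standard
  convention, under which all four packaged models pass every
  criterion.

Two published numbers are deliberately not reproduced: the printed MAE
values exceed the printed RMSE values (impossible for one residual set;
the generating formula is unrecoverable) and the printed CoMSIA r²_pred
of 0.758 is inconsistent with the printed per-compound predictions,
which give ≈ 0.79. When reference values are supplied the report
carries explicit warnings for both instead of silently matching them.

## Synthetic study conditions

The generator emulates exactly the structure the analysis assumes:
additive per-position contributions plus Gaussian noise on the pIC50
scale. Defaults, fixed once: a three-position fused aromatic core
(Ra/Rb/Rc topology), four small substituents per position (64
combinations), true contributions spanning ≈ 1.5 pIC50 units per
position (the scale of published R-group contribution values), base
pIC50 5.0, noise sd 0.1, n = 60 sampled without replacement, mandatory
integer seeds. The standard recovery experiment (20 seeds, n = 60,
sd 0.1) compares per-position mean-centered recovered contributions —
contributions are identifiable only up to a per-position constant —
against centered truth at a tolerance of 3·(sd/√n), and checks that the
predicted ranking of all 64 assemblies matches the true ranking
(Spearman ρ). These conditions establish that the pipeline recovers an
additive ground truth through the full fragment-field + PLS stack; they
do not establish anything about non-additive SAR, activity cliffs,
conformational effects, or assay noise structure in real series.

Random molecular graphs for property tests are valence-valid trees over
C/N/O with optional single ring closures, seed-reproducible and checked
through RDKit sanitization.

## Numerical and reporting conventions

All statistics are computed at full double precision and rounded to 3
decimals only at output. Reports embed the package version and a SHA-256
hash of the fully-resolved run configuration; identical configs yield
byte-identical outputs. Run configs are strict YAML — unknown keys are
rejected rather than ignored. The CLI exits 0 on success, 2 when data
processed cleanly but the model fails the validation criteria, and > 2
on errors.

## Known limitations

* No force-field minimization or conformer search; field values are
  convention-dependent and absolute field-model statistics from
  commercial suites are not reproduction targets.
* Donor/acceptor perception is intentionally minimal (no aromatic
  nitrogen lone-pair analysis, no tautomer handling).
* The fragment grammar of commercial hologram implementations is
  proprietary; only the structural properties of holograms
  (conservation, permutation invariance, reproducibility) are
  guaranteed, not their exact bin patterns.
* Screening assumes one substituent per labeled position and acyclic
  single-bond cuts; fused or multiply-attached R-groups are out of
  scope.
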