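# seqdyn

Sequence-based prediction of per-residue backbone amide transverse
relaxation rates (R2) for intrinsically disordered proteins (IDPs).

R2 from ¹⁵N spin relaxation is the NMR observable most sensitive to the
slow (tens of ns to µs) local dynamics of disordered chains, and the one
with the strongest sequence dependence: aromatic, Arg, and long branched
aliphatic residues form transient local contact clusters that slow motion
and raise R2, while Gly and short polar residues interrupt them. `seqdyn`
implements a compact mathematical model of this effect for NMR
spectroscopists and IDP biophysicists who want a per-residue dynamics
profile from sequence alone — no structure, no simulation.

## The model

The predicted rate at residue *n* of an *N*-residue chain is a product of
contributions from **every** residue *i* (the self term included):

```
R2(n) = Υ · ∏ᵢ f(i; n),      f(i; n) = 1 + (q(i) − 1) / (1 + b·s²),   s = |i − n|
```

* `q(aa)` — 20 amino-acid propensities for slowing local dynamics
  (dimensionless; q > 1 raises neighbouring R2, q < 1 lowers it),
* `b` — the coefficient of the Lorentzian distance attenuation, with
  correlation length `Lcorr = b^(−1/2)` (the separation at which a
  neighbour's influence has decayed halfway),
* `Υ` — one scale factor per protein (s⁻¹) absorbing temperature,
  magnetic field and viscosity, which rescale R2 uniformly along the
  sequence.

Training minimizes the sum over proteins of the mean squared error over
scored residues (Pro and unobserved positions are excluded — Pro has no
amide proton) using trust-region-reflective least squares with all
parameters bounded positive. Stable long helices tumble more slowly than
the short correlation length implies, so profiles can receive a helix
boost `1 + α·pHlx` (α = 0.5) inside PsiPred-predicted helices that survive
a strict filter (propensity ≥ 0.99 over ≥ 12 consecutive residues).

The package is organised as scikit-learn-style estimators
(`SeqDynRegressor`, `OneResidueRegressor`) plus thin functional wrappers
(`train`, `loocv`, `kfold_cv`, `sweep_fixed_lcorr`, …), a synthetic-data
generator with known ground truth, readers/writers for FASTA, R2 tables,
PsiPred ss2 and parameter files, and a `seqdyn` command-line tool.

## Worked example

Generate a synthetic dataset from known parameters, train on it, and
predict a profile:

```sh
$ seqdyn synth ds --n-proteins 8 --noise-sd 0.3 --seed 4
ds/manifest.yaml
$ seqdyn train ds/manifest.yaml -o fitted.params
INFO seqdyn: synth006: scale 1.4462 s^-1, in-sample RMSE 0.2735 s^-1
INFO seqdyn: synth007: scale 1.4728 s^-1, in-sample RMSE 0.2539 s^-1
INFO seqdyn: synth008: scale 1.6058 s^-1, in-sample RMSE 0.3182 s^-1
INFO seqdyn: cost 0.685247, Lcorr 5.66 residues
$ seqdyn predict ds/synth001.fasta fitted.params --scale 1.4 | head -6
protein	index	aa	r2
synth001	1	M	2.5908
synth001	2	Y	2.7257
synth001	3	C	2.8559
synth001	4	P	2.9884
synth001	5	I	3.1345
```

Eight noisy proteins already pin the correlation length near its
generating value of 5.6 residues; the in-sample RMSEs sit at the 0.3 s⁻¹
noise floor, and the predicted profile shows the characteristic terminal
falloff (residue 1 lower than the interior) because terminal residues have
neighbours on one side only. The same from Python:

```python
from seqdyn import SeqDynRegressor, SyntheticSpec, generate_dataset

data = generate_dataset(SyntheticSpec(seed=7))        # 20 proteins, noise 0.3
model = SeqDynRegressor().fit(data)
print(model.params_.lcorr)                            # ~5.6 residues
profile = model.predict(["MKVLAGSTWY"])[0]            # unscaled shape
```

`seqdyn table1` prints aggregate statistics over the bundled benchmark
table of 45 training and 9 test IDPs (mean per-protein sd of measured R2,
counts of proteins where the prediction beats the uniform null model, and
the test-set mean RMSE).

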