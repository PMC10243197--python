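# ccspec

Two-stage constituent-contribution prediction of UV-vis absorption spectra
for single molecules and multicomponent dye mixtures.

Data-hungry spectral models need thousands of measured spectra; bench
chemists rarely have more than a few hundred.  `ccspec` targets that
small-data regime for people who design dyes and need full absorption
spectra — and spectra of dye *mixtures* — from structure alone.  It encodes
chemistry into the features instead of hoping a large network discovers it:

* **Stage 1 (CGC — corrected group contribution).**  A molecule's SMILES
  plus a solvent-polarity scalar becomes a 151-dimensional vector: counts
  over a fixed fragment vocabulary (ring and non-ring groups, phenyl-attached
  variants, substitution-position slots for benzene / naphthalene /
  anthracene-like ring systems, Ar–Ar and bridging C=C linkages), the
  conjugation descriptors A (total conjugated double bonds) and B (largest
  conjugated system), a frozen block of E-state / MOE-VSA / topological /
  connectivity indices, and the solvent polarity.  Two Bayesian-regularized
  networks run in series: net A predicts the spectral characteristics
  (λ_peak, area S = Σλ A(λ), height H), net B maps the descriptors merged
  with those characteristics (154 inputs) to the full 58-point UV spectrum
  (230–401 nm, 3 nm steps, min–max normalized).

* **Stage 2 (MC — molecule contribution).**  Beer–Lambert additivity,
  L = Σᵢ Lᵢxᵢ, bends under intermolecular interactions.  The correction is
  pairwise: k_ij = c₁‖aᵢ−aⱼ‖₁ + c₂‖aᵢ−aⱼ‖₁² on the components' group
  vectors (k_ii = 0), entering as Σ_{i<j} (xᵢxⱼ/(xᵢ+xⱼ))·X(λ)·k_ij with a
  fixed transformation vector X.  A network learns this rule from
  two-component spectra only (two concentration-scaled 43-point spectra in,
  the mixed spectrum out), and transfers to 3- and 4-component systems by
  sequential virtual mixing — no multicomponent training data required.

* **Training.**  Both stages use Levenberg–Marquardt with Bayesian
  regularization: minimize F = β·E_D + α·E_W, re-estimating α, β and the
  effective parameter count γ = N_w − α·tr(H⁻¹) from the evidence after
  each accepted step.  This is what lets ~100-sample training sets work
  without overfitting.

A seeded synthetic-data generator (`ccspec.synth`) emulates the assumed
data structure — Gaussian band spectra tied to sparse group vectors,
near-additive mixing with a smooth pairwise correction — so the entire
pipeline trains and validates offline.  See `docs/methods.md` for the full
model description and conventions.

## Worked example

Featurize a hydroxylated 3-aryl-coumarin dye in water:

```python
from ccspec.molfeat import featurize, parse_molecule, count_groups, conjugation_descriptors

smi = "O=C1Oc2cc(O)ccc2C=C1c1ccc(O)cc1"   # 7-hydroxy-3-(4-hydroxyphenyl)coumarin
gv = count_groups(parse_molecule(smi))
print(gv.nonzero())
cd = conjugation_descriptors(parse_molecule(smi))
print(cd.A, cd.B)
d = featurize(smi, solvent_polarity=1.0)   # 1.0 = water on the ET scale
print(d.values.shape)
```

prints

```
{'N1(para-)': 1, 'N2(beta)': 2, 'Ar-Ar': 1, '>C=(Ring)': 4, '-CH=(Ring)': 8,
 '-O-(Ring)': 1, '>C=O(Ring)': 1, '>C=C<(1)': 1, '-OH(ph)': 2}
8 8
(151,)
```

Read: the coumarin bicycle is a two-fused ring system with both
substituents (the 7-OH and the 3-aryl link) at β positions — N2(beta)=2;
the phenol ring is para-disubstituted — N1(para-)=1; the inter-ring bond
gives Ar-Ar=1 and the C3=C4 bond bridging two aromatic rings gives
>C=C<(1)=1; the lactone contributes one ring C=O and one ring -O-; the two
phenolic OH groups are phenyl-attached; and all 8 double bonds form one
conjugated system (A=B=8).

The same works from the shell, end to end on synthetic data:

```bash
ccspec simulate --out data/ --n-train 400 --n-test 40 --seed 7
ccspec train-stage1 --features data/stage1_features.csv \
    --spectra-dir data/stage1_spectra --out model/
ccspec predict --model model/ --smiles-file molecules.csv --out spectra/
ccspec train-mix --manifest data/mixtures.csv --out mcmodel/
ccspec predict-mix --model mcmodel/ --codes "1.1 + 3.3" \
    --spectra-dir dyes/ --path avg --out mix.csv
```

Mixture codes follow the dataset convention: `1.1` is dye 1 at
0.75×10⁻⁴ mol/l, `1.2` (or bare `1`) at 1.0×10⁻⁴, `1.3` at 1.25×10⁻⁴, and
`+` joins components.

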