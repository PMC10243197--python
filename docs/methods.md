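# Methods

`ccspec` implements a two-stage constituent-contribution protocol for
absorption-spectrum prediction: a corrected group-contribution (CGC) model
for single molecules in solution, and a molecule-contribution (MC) model for
mixtures.  This note records the models, the conventions the implementation
fixes where the underlying methodology leaves freedom, the synthetic world
used for testing, and the known limitations.

## Stage 1: corrected group contribution

### Descriptor vector

A molecule plus a solvent-polarity scalar maps to a 151-dimensional vector:

| block | slots | content |
|---|---|---|
| group counts | 58 | fragment vocabulary counts + "Other groups" overflow |
| conjugation | 2 | A = total conjugated double bonds, B = largest conjugated system |
| electronic | 90 | E-state, MOE-type VSA, topological and connectivity indices |
| solvent | 1 | normalized solvent polarity (ET-scale, 0..1) |

The group vocabulary has 57 named entries: 10 position/linkage descriptors
(N1 ortho/meta/para for isolated aromatic rings, N2 alpha/beta for
naphthalene-like bicycles, N3 alpha/beta/gamma for anthracene-like linear
tricycles, Ar-Ar and Ar-R linkages), 15 ring-attributed groups and 32
non-ring groups, many in phenyl-attached "(ph)" variants.  The electronic
block is a frozen, versioned list of 90 RDKit descriptor names
(`molfeat.ELECTRONIC_DESCRIPTORS`); it closes the 151 budget exactly
(58 + 2 + 90 + 1).

### Featurization conventions

Group-contribution tables specify fragments but not an attribution
algorithm; the implementation fixes one, validated against a published
worked example (a hydroxylated 3-aryl-coumarin whose full count vector is
reproduced exactly, encoded as a golden test):

* **Ring systems** are fused clusters of pi-conjugated rings: every ring
  carbon aromatic or doubly bonded, heteroatoms exempt.  This folds
  carbonyl-containing quasi-aromatic rings (pyranones, chromenones) into
  their fused bicycle, which the worked example requires for the N2
  substituent positions and the ring C=O / ring -O- groups.
* **Fusion atoms** are carried by the fused-system descriptor itself and do
  not count as >C=(Ring); all other ring atoms take ring groups by element,
  hydrogen count and hybridization.
* **Position labels**: isolated six-rings emit one N1 slot per unordered
  substituent pair (ortho/meta/para by ring distance); fused systems emit
  one N2/N3 slot per substituent (alpha = adjacent to a fusion atom,
  gamma = on the middle ring of a linear tricycle).  Angular tricycles
  (phenanthrene-like) and systems of four or more fused rings are
  unsupported: their atoms fall into "Other groups" with a warning.
* **Bridging C=C**: a localized olefinic C=C bond whose two carbons both
  touch aromatic carbons counts as >C=C<(1), one-sided contact as
  >C=C<(2).  On ring bonds this is a pure linkage count (atoms keep their
  ring groups); on chain bonds it consumes both carbons (stilbene,
  styrene).  Kekule C=C bonds inside carbonyl-bearing rings flagged
  aromatic by the perception model are eligible; bonds touching plain
  aromatic rings are not.
* **(ph) variants** apply when the group's anchor atom bonds a carbon of
  any pi ring system.
* **Strict vocabulary**: fragments without a slot (chain CH2/CH, secondary
  amines, thiols, isolated chain C=C without aromatic contact, methane)
  go to "Other groups".  Every heavy atom is attributed exactly once; the
  attribution map is exposed and tested as a conservation invariant.
* **Conjugation counting** uses the canonical kekulized structure: two
  multiple bonds are conjugated when a single bond joins them (cumulated
  dienes are not); systems of at least two multiple bonds count toward A,
  and B is the largest system.  Parsing canonicalizes the SMILES first, so
  descriptors are bitwise independent of the input spelling.

### Tandem networks

Network A (151 -> hidden -> 3) predicts the three spectral characteristics:
peak wavelength lambda (nm, grid argmax, ties to the lowest wavelength),
area S (plain sum of absorbances), height H (absorbance at the peak if an
interior local maximum exists, else the absorbance at 250 nm).  Network B
(154 -> hidden -> 58) maps the descriptors merged with the characteristics
to the normalized UV spectrum on the 58-point grid 230 + 3k nm (k = 0..57;
the 401 nm endpoint is clamp-interpolated from 230-400 nm sources — 230-400
at 3 nm yields only 57 points, so the printed 58 forces this convention).
Network B trains with true characteristics (teacher forcing) and predicts
with network A's outputs; predictions are clipped at zero and not
re-normalized.  UV training spectra are min-max normalized (min 0, max
exactly 1); visible-range mixture spectra are kept on their raw 0-5
absorbance scale.

## Bayesian-regularized Levenberg-Marquardt training

Both stages use a single-hidden-layer tanh network with linear output,
trained to minimize F = beta*E_D + alpha*E_W (half sums of squared
residuals and weights) by damped Gauss-Newton steps
(beta*JtJ + (alpha + mu)I) dw = -grad F, with the evidence re-estimation

    gamma = Nw - alpha * tr(H^-1),   H = beta*JtJ + alpha*I
    alpha <- gamma / (2 E_W),        beta <- (N - gamma) / (2 E_D)

after each accepted step (MacKay's framework; with half-sum energies gamma
equals the sum of lambda/(lambda + alpha) over Hessian eigenvalues and lies
in [0, Nw] by construction).  alpha starts at 0, beta at 1; mu is adapted by
factors of 10 and training stops at max_epochs, at a damping ceiling, or
when the relative objective improvement falls below the tolerance — the
stop reason is recorded.  Inputs *and* targets are standardized with
training-set statistics stored in the model (network A's targets mix scales
of ~300 nm and ~1, which LM conditioning cannot absorb otherwise).  Fixed
seeds give bitwise-identical traces.  A `bayes=False` switch freezes
alpha = 0 (plain LM) as the unregularized baseline; on noisy data the
regularized network shows strictly lower held-out error in the median over
seeds.

## Stage 2: molecule-contribution mixing

Beer-Lambert additivity is corrected by a pairwise interaction term.  The
analytic form uses k_ij = c1*d + c2*d^2 with d the L1 distance between the
components' group vectors (k_ii = 0), entering as
sum_i L_i x_i + sum_{i<j} (x_i x_j/(x_i + x_j)) * k_ij * X(lambda), where X
is a fixed transformation vector (unit Gaussian, 560/60 nm by default) and
concentrations are expressed relative to the 1e-4 mol/l reference (the
concentration-code suffixes .1/.2/.3 denote 0.75/1.0/1.25 x 1e-4 mol/l).
Working in relative units is forced by dimensional analysis: with x in
mol/l both the linear term and the x_i x_j/(x_i+x_j) weight would be
O(1e-4), leaving no visible spectrum.

The learned model replaces the correction with an 86 -> 43 network over the
two concentration-scaled pure spectra; concentration enters only through
that Beer-Lambert pre-scaling because the 86-dimensional input leaves no
slot for explicit concentrations or group vectors.  Components are
canonically ordered (larger total absorbance first, lexicographic
tie-break), making predictions exactly exchange-symmetric.  Multicomponent
spectra are predicted by sequential virtual mixing: predict a pair, convert
the result to a pseudo-component whose concentration is the sum and whose
"pure spectrum" is the prediction rescaled to the reference concentration,
and continue.  Three path strategies are provided — record order,
decreasing concentration, and the ensemble average over all orderings —
since the original path choice is not recoverable; the ensemble is the
package's headline ternary predictor.  An optional training augmentation
with virtual self-mixtures (a dye mixed with itself is additive by
definition) anchors the rule at d = 0; it trades binary accuracy for
additive-limit fidelity and is off by default.

## Synthetic world

The generator provides ground-truth corpora so training and evaluation run
without downloads.  Each of G = 20 abstract groups contributes a Gaussian
band (centres uniform in the middle 80% of the working grid, widths
5-15% of the grid span, heights 0.08-0.30 per unit count); group vectors
are sparse (2-6 active slots, counts 1-8).  All bands red-shift by
4 nm per unit of B(a) = max count (a conjugation stand-in), by 2 nm per
unit of a latent per-molecule electronic factor e ~ N(0,1), and by 2 nm per
unit of centred solvent polarity.  Mixtures follow the analytic rule with
c1 = 0.01, c2 = 0.002 and the 560/60 nm bump; i.i.d. Gaussian measurement
noise (sigma = 0.01) is added to pure and mixed spectra.  Stage-1 descriptor
stand-ins pack [a | A, B | e and group summaries | polarity] into the
151-slot layout; the electronic sub-block is informative by design so that
descriptor-ablation comparisons are meaningful (with a zero pad, the
electronic-only variant would carry no information and the group-only
variant would equal the full model, making the ablation vacuous).

What the world does *not* emulate: chemically valid SMILES, correlated
(non-i.i.d.) instrument noise, baseline drift, band asymmetry, and any
direct correspondence between the 20 abstract groups and the real
vocabulary.  Passing synthetic tests therefore demonstrates that the
pipeline recovers the structure it assumes (banded spectra tied to sparse
group vectors, near-additive mixing with a smooth pairwise correction), not
that real spectra reach a particular accuracy.

## Validation protocol and reference problem sizes

Validation uses repeated random holdout: each repeat draws floor(0.1 n)
samples without replacement, trains on the rest and scores MAE/MSE/MRE/R^2
(spectrum errors average over wavelengths within a sample, then over
samples; R^2 is the pooled coefficient of determination, which can be
negative and is labelled as such in every report; MRE excludes targets
below 1e-8).  Over 50 repeats at 10% nearly every sample is held out at
least once, which suits small datasets better than k-fold splitting.

The reference benchmark configurations (in `ccspec.benchmarks`) are sized
for a single-CPU run: stage-1 recovery uses 130 records and 2 holdout
repeats with 8+8 hidden units and 30 epochs; mixture recovery uses 140
binary records, 2 repeats, 15 ternary mixtures, 10 hidden units and 40
epochs; the ablation comparison uses 10 seeds at 110 records with reduced
networks (8/5 hidden, 25 epochs).  On this protocol the synthetic stage-1
holdout error lands at MSE ~0.02 and R^2 ~0.8 on normalized spectra — the
same error regime the corresponding experimental UV benchmark reports — and
the ternary migration error stays within twice the binary held-out MAE,
i.e. migrating the binary mixing rule to three components does not enlarge
the prediction error.  Larger corpora and wider networks improve the
absolute numbers but not the qualitative picture; the Levenberg-Marquardt
cost grows with (rows x weights^2) per iteration, which sets the practical
ceiling.

## Numerical choices and degenerate inputs

* lambda ties break to the lowest wavelength; "no peak" means no interior
  grid point strictly above both neighbours.
* Min-max normalization rejects constant spectra; resampling rejects
  extrapolation except for the documented 401 nm clamp.
* Singular LM systems raise the damping rather than aborting; non-finite
  objectives raise immediately.
* alpha is clipped to [0, 1e8], beta to [1e-8, 1e12]; zero-variance feature
  columns standardize to zero.
* Unparsable SMILES, malformed concentration codes, grid mismatches and
  dimension mismatches raise ValueError with the offending item named.

## Known limitations

* The group-attribution conventions beyond the worked example are one
  defensible reading of the vocabulary; other readings (e.g. whether Ar-R
  overlaps >C=C<(2)) would change counts for some molecules.
* Only formal charges are considered; tautomers, conformers and 3D effects
  are out of scope.
* The visible-range peak-wavelength task uses the same featurizer as the UV
  task (experimental); a dedicated visible-range vocabulary is not
  implemented.
* Point predictions only: the Bayesian framework is used for
  regularization, not for posterior predictive uncertainty.
* The learned mixing model sees only two spectra; it cannot fully separate
  concentration from intrinsic absorptivity, which bounds how well the
  pairwise interaction can be inferred from data alone.
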