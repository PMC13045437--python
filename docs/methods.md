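# Methods

## The model

`uhsr` implements unsupervised hierarchical symbolic regression for
structure–property modeling, demonstrated on thin-layer-chromatography (TLC)
retardation factors. A TLC measurement is described by 23 chemically
intuitive features: five mobile-phase volume fractions (n-hexane, ethyl
acetate, dichloromethane, methanol, diethyl ether), sixteen functional-group
(FG) counts, the benzene-ring count and the dipole moment. The method has
three parts:

1. **Chemist-guided feature grouping.** The features are partitioned into
   named groups at three granularities: stage 1 separates solvent (5) from
   solute (18); stage 2 splits the solute into FG counts (16) and FG
   distribution features (NBen, DM); stage 3 splits the FG counts into five
   chemist-defined subgroups — {amide, carboxylic acid}, {phenolic OH,
   amine, alcoholic OH}, {nitro, ester}, {F, ether, ketone, aldehyde,
   cyano}, {methyl, Cl, Br, I}.

2. **Modular neural networks.** For each stage, every group feeds its own
   sub-model (an MLP with two hidden layers of 50 LeakyReLU units, no
   parameter sharing) that emits one scalar latent — a *retention index* —
   and a head maps the latent vector to Rf through a logistic output. By
   construction each latent depends only on its group (exact receptive-field
   restriction). The latents are the solvent index Ψ and solute index ξ
   (stage 1), the FG-distribution index α and FG index β (stage 2), and the
   subgroup indices γ₁…γ₅ (stage 3).

3. **Genetic-programming symbolic regression (GP-SR).** Expressions over
   {+, −, ×, protected ÷, exp, protected log} with named variables and real
   constants evolve under tournament selection, subtree crossover and
   mutation; constants are refined by local least squares; the best
   expression per complexity (node count) forms a Pareto front, and the
   simplest member within a relative parsimony tolerance Δ of the best loss
   is selected. The pipeline fits: logit(Rf) vs (Ψ, ξ); Ψ vs the solvent
   fractions; ξ vs (α, β); β vs (γ₁…γ₅).

The reference governing equations are kept as executable fixtures:
Rf = σ(5.15Ψ + 5.15ξ + 1.55); Ψ = −1.37·Hex − 0.20·EA − 1.02·DCM +
4.65·MeOH − 0.45·Et₂O; ξ = 0.37α − 0.35β − αβ + 0.69; and the sixteen
per-FG probe values of β (amide 1.43 down to iodine −2.97). The
finer-grained equations for α (from DM, NBen) and β (from γ₁…γ₅) are
transcribed from a typographically ambiguous source under one documented
reading, are marked *interpretive* in their docstrings, and are never used
as ground truth anywhere: the synthetic generator and every recovery test
use the unambiguous linear probe weights as the solute oracle instead.

## Key parameters

| parameter | default | notes |
|---|---|---|
| sub-model hidden layers | 2 × 50, LeakyReLU(0.01) | reference protocol |
| head hidden layers | 2 × 50; **stage 1 uses 0** (affine + sigmoid) | see below |
| optimizer | Adam, lr 0.01, batch 2048 | reference protocol |
| epochs / checkpoint | 1000, best validation epoch | validation split = seeded 10% of the training fold |
| latent gauge | mean 0 / var 1 on the training split, canonical signs | see below |
| GP population / generations | 1000 / 40 | sized so targets of complexity ≲ 20 are recovered at desk scale |
| tournament / crossover / mutation | 10 / 0.3 / 0.7 | mutation split across subtree, point, hoist and expand operators |
| max complexity / Δ | 30 / 0.01 | complexity = node count |
| protected ops | ÷ and log emit a 1e10 sentinel and worst-case fitness when \|den\| < 1e-9 or arg < 1e-9 | keeps fitness finite without rewriting expressions |

**Stage-1 head.** The head architecture is an open design point. Stage 1
uses the minimal head σ(w·z + b): the top-level governing relation is
sigmoid-affine in (Ψ, ξ), and the minimal head pins the two latents to an
affine gauge of the indices instead of letting a flexible head absorb
arbitrary monotone reparameterizations — which would survive training
unnoticed (same fit quality) but spoil the interpretability of the latents
that the whole method is for. Stages 2 and 3 keep MLP heads because their
latent-to-Rf maps are genuinely non-additive (ξ contains an αβ interaction).

**Latent gauge.** Latents are identified only up to affine
reparameterization (a change of units). The package fixes the gauge by
standardizing each latent to mean 0 / variance 1 on its training split and
canonicalizing signs against documented references: corr(Ψ, MeOH) ≥ 0,
corr(ξ, Rf) ≥ 0, corr(α, Rf) ≥ 0, corr(β, Rf) ≤ 0, corr(γⱼ, Rf) ≤ 0. The
β/γ convention encodes "more polar functional groups ⇒ larger index ⇒
stronger silica retention ⇒ lower Rf", matching both the sign of β's
coefficient in the ξ equation and the printed probe polarity order. Sign
canonicalization is idempotent and recorded; all reported equations live in
this gauge, with the affine transforms published in the report so raw-gauge
equations can be derived.

**Logit-scale fitting and saturation.** The Rf-target SR fit is done on the
logit scale so the inner expression is linear-recoverable, and σ(·) of the
selected expression is reported. Observations saturated outside
(0.01, 0.99) carry no logit-scale information — their clipped logits would
enter as a flattened, systematically curved target that the GP dutifully
fits with spurious nonlinear terms — so the SR fit uses the unsaturated
rows only. Held-out metrics are always computed on *all* test rows on the
Rf scale.

**Coefficient read-out on the composition simplex.** Solvent fractions sum
to one, so an intercept in a fitted solvent equation is indistinguishable
from a uniform shift of all five coefficients. Recovered solvent
coefficients are therefore reported in the zero-intercept gauge
(`simplex_coefficients`), which absorbs any intercept uniformly and equals
the expression's value at the pure-component vertex — the same
pure-component probe semantics used for the trained sub-models. Without
this gauge the printed coefficients are simply not identifiable from
simplex-constrained data.

**Equation selection.** `select` takes the minimum-complexity front member
with loss ≤ best·(1 + Δ) + 1e-12; the absolute epsilon makes exactly
representable targets (losses differing only in machine noise) count as
ties, so the simplest exact form wins.

## The synthetic generator

The generator emulates the benchmark's structure: three binary mobile-phase
systems; by default a fixed grid of 17 compositions (7 Hex/EA, 5 Hex/Et₂O,
5 MeOH/DCM with MeOH ≤ 0.10) tiled over the sample — the real study's 17
compositions are unpublished, so the grid is a stand-in whose marginals
approximate the published solvent means; FG counts as cap-3 Poisson draws
at the published marginal rates; NBen on {0..3} with mean 1.12; DM normal
(1.34, 0.74) truncated at zero. Ground truth is generated by the reference
fixtures themselves (no second implementation of the mechanism exists): Ψ
from the solvent equation, β as the standardized linear FG probe index, α
as a standardized affine composite 0.5·DM + 0.5·NBen (deliberately *not*
the interpretive α transcription, keeping the oracle unambiguous), ξ from
the ξ equation, Rf through the sigmoid link, and observation noise N(0, sd)
added on the logit scale (default sd 0.05, default n = 3000, comparable to
the real benchmark's 4944 rows at desk runtime).

What it does **not** emulate: inter-plate/temperature/humidity variability,
real covariance between functional groups within molecules, heteroscedastic
measurement error, and real SMILES (counts are drawn directly). Passing
recovery tests therefore demonstrate that the pipeline inverts its own
generating mechanism at realistic size and noise — not that the printed
equations are the true model of real TLC plates.

## Numerical choices and degenerate inputs

- Training is plain numpy with hand-written backpropagation and Adam;
  seeded runs are bit-reproducible (BLAS is pinned to a single thread
  during training and pipeline runs, since multi-threaded reductions are
  not bitwise deterministic). Non-finite losses abort with a diagnostic
  rather than propagating.
- Standardization guards zero-variance latents (scale 1, and sign
  canonicalization refuses zero-variance latents or references).
- Solvent rows must sum to 1 within 1e-6; strict mode rejects violations
  with row numbers, an opt-in normalize mode rescales and logs.
- Constant SR targets return a degenerate one-member front (the constant);
  constant optimization keeps the original constants when the local
  optimizer fails or would increase the loss.
- The logistic saturates to exactly 0/1 in floats roughly beyond |x| > 36;
  mathematical statements about the open interval (0, 1) hold up to that
  float resolution.

## Scale of the shipped experiments

Unit tests run the hierarchy at reduced size (n = 400–1200, tens to a few
hundred epochs, small GP budgets) chosen so the whole suite stays at
desk scale; the acceptance tests run the full reference conditions —
coefficient recovery from 500–2000 noiseless samples with the default GP
budget, and the complete pipeline at n = 3000, logit noise 0.05, 1000
epochs. These sizes are the package's own reference experiment definitions.

## Known limitations

- At the reference noise level the trained solvent latent deviates from an
  affine function of composition by ~2% variance while GP finds exact-fit
  nonlinear forms orders of magnitude closer, so Δ = 0.01 selection picks a
  non-affine Ψ-equation; the coefficient *ranking* (Hex < DCM < Et₂O < EA <
  MeOH) is instead verified through pure-component probes of the solvent
  sub-model. Real, noisier data would mask this and favor the linear form.
- The interpretive α/β/γ transcriptions are one reading of ambiguous
  typesetting and are not claimed to match the original equations.
- Pure-component probes of trained sub-models extrapolate outside the
  observed composition range (most visibly for methanol, capped at 0.10 in
  the data); probe magnitudes are meaningful only relative to one another.
- FG counting uses exclusive SMARTS priority rules (acid > ester > amide >
  aldehyde > ketone for carbonyl carbons; amide N excluded from amines;
  ester O excluded from ethers; methyl = CH₃ with one heavy neighbor);
  molecules outside the benchmark's chemistry (fused heteroaromatics,
  sp³-rich scaffolds) are out of the features' design range.
- The dipole moment is consumed as a provided column, never computed.
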