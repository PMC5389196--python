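# Methods

## Scope and model

`nanoqspr` implements a quantitative structure–property relationship (QSPR)
workflow for the adsorption energy ΔE_ads (kcal/mol) of halogenated
dibenzo-*p*-dioxin congeners (PXDDs, X = Br and/or Cl) on the C60 fullerene
surface.  The workflow is: symmetry-aware enumeration of all congeners →
descriptor table → Kennard–Stone calibration-subset selection → genetic-
algorithm descriptor selection with partial-least-squares regression
(GA-PLS) → internal (leave-one-out) and external validation → leverage-based
applicability-domain (AD) analysis → prediction for the full congener set.

Quantum chemistry is deliberately out of scope.  The descriptor block and
the adsorption energies that a quantum-chemistry campaign would supply are
emulated by a synthetic generator whose statistical structure matches what
the regression model assumes, so that the entire pipeline is testable
offline and its parameter-recovery behaviour is the package's empirical
surface.  A user-supplied descriptor/energy CSV (same header contract) can
replace the generator at any time.

## Congener enumeration

Dibenzo-*p*-dioxin has eight substitutable positions (1,2,3,4,6,7,8,9).  The
planar skeleton admits an order-4 symmetry group: identity, the mirror
across the long (x) axis (1 4)(2 3)(6 9)(7 8), the mirror across the short
in-plane (y) axis (1 9)(2 8)(3 7)(4 6), and the two-fold ring-swap rotation
(1 6)(2 7)(3 8)(4 9).  These are the only bijections whose position orbits
are the lateral set {2,3,7,8} and the axial set {1,4,6,9}.  A congener is a
symmetry orbit of {H,Cl,Br}^8; enumeration canonicalizes every raw pattern
to the lexicographic minimum of its orbit (ordering H < Cl < Br) and yields
1,701 distinct congeners, which Burnside's lemma confirms:
(3^8 + 3·3^4)/4 = 1,701 (76 for the {H,Cl} restriction).  Enumeration order
is lexicographic over canonical tuples, giving stable congener indices.

IUPAC-style names are generated from the orbit representative with the
lowest locant set (the canonical tuple prefers high positions, so e.g. the
canonical form of the 1,2,3,7,8-pentachloro congener is a 2,3,7,8,9-type
tuple; the name still uses 1,2,3,7,8).  Names are injective over the 1,701
congeners and are the join key for user-supplied tables and the WHO TEF
cross-tab.  SMILES strings come from a fixed dibenzo-*p*-dioxin ring
template with halogens substituted at mapped atoms.

## Synthetic descriptors and energies

Each congener gets 26 descriptors — the number mirrors the descriptor block
of a typical semi-empirical characterization campaign:

* `nH` — hydrogen count, 8 − (n_Cl + n_Br);
* `TE` — total molecular energy on an arbitrary a.u.-like scale, additive in
  composition: 12·a_C + 2·a_O + n_H·a_H + n_Cl·a_Cl + n_Br·a_Br with
  defaults a_C = −38.06, a_O = −75.00, a_H = −0.58, a_Cl = −460.15,
  a_Br = −2573.50 (rounded atomic ground-state energies, so Br/Cl
  composition dominates the scale);
* `Dx`, `Dy` — in-plane dipole components by bond-dipole vector addition
  over an idealized hexagonal geometry.  x is the long axis through both
  ring oxygens, y the short in-plane axis; positions 1,4,6,9 point along
  ±y and lateral positions 2,3,7,8 at ±30° from the x axis.  Bond-dipole
  magnitudes are μ_Cl = 1.6 > μ_Br = 1.3 (debye-like), following the
  electronegativity ordering Cl 3.16 > Br 2.96 (Pauling); C–H bonds
  contribute zero because halogen dipoles are referenced to C–H.  The
  vector set is equivariant under the symmetry group, so dipole magnitudes
  are orbit invariants and fully symmetric patterns have zero dipole;
* `d05`…`d26` — 22 nuisance descriptors, seeded standard-normal draws with
  configurable cross-correlation to the informative block (default 0).

The ground-truth adsorption energy is linear plus noise:

    E_ads = c0 + c1·nH + c2·TE + c3·Dx + c4·Dy + ε,   ε ~ N(0, σ²)

with defaults (c0…c4) = (2.2, −3.0, 4·10⁻⁴, 0.6, −0.4) and σ = 0.3
kcal/mol.  The defaults were fixed once, by construction rather than
calibration:

* the parent congener sits near −22 kcal/mol and the most halogenated
  congeners near +1, spanning the reported range of such complexes, with
  the convention that more negative = more favourable adsorption;
* the effective per-substituent increments (ΔCl ≈ +2.8, ΔBr ≈ +2.0
  kcal/mol relative to H) make hydrogen-rich, axially substituted congeners
  the strongest binders and laterally halogenated (2,3,7,8-type, i.e. the
  AhR-toxic motif) congeners weaker binders — the qualitative contrast the
  model is meant to expose;
* σ = 0.3 kcal/mol matches the low end of the error band quoted for the
  M06-2X functional on weak complexes (0.3–0.7 kcal/mol) and implies a
  calibration R² near 0.998 at the energy spread of this family.

Because `TE` here is composition-additive, isomers with the same Br/Cl
count differ only through their dipoles.  Real semi-empirical total
energies resolve isomers more finely; published isomer-resolved energy
orderings (e.g. a 2,3,7,8-tetrachloro value above the octachloro one)
cannot be reproduced by this generator, and passing tests say nothing about
that level of realism.  What the synthetic surface does establish is that
the pipeline recovers a planted linear signal: coefficients to 1e-8 at zero
noise, and the correct 4-descriptor subset from 26 candidates in ≥95% of
seeded runs at σ = 0.1.

## Kennard–Stone selection and splitting

The calibration subset (default 32 congeners ≈ 2% of 1,701) is chosen by
the Kennard–Stone maximin rule in the autoscaled space of all 26
descriptors (selection precedes descriptor selection in the workflow, so
the full block is the selection space).  Autoscaling uses ddof = 1; ties in
every argmax break toward the lowest row index, making the selection
deterministic.  The 24/8 train/validation split takes every fourth congener
of the Kennard–Stone selection order (ranks 4, 8, …, 32) for validation.
No selection rule for this sub-split is canonical; the every-k-th rule
keeps both sets spread across the selection order and is reproducible.
Everything unselected (1,669 congeners) forms the prediction set.

## GA-PLS

PLS1 is implemented as classical NIPALS with X-deflation; predictions
reduce to a regression vector B = W(PᵀW)⁻¹q on autoscaled descriptors,
re-expressed on the original scale with an intercept.  At full rank PLS
equals ordinary least squares, which the test suite exploits as an oracle
(together with an independent sklearn cross-check).  Per-LV explained
variance of the X and y blocks is computed from the rank-one score/loading
reconstructions.

Internal validation is leave-one-out: every fold re-autoscales on its 23
retained samples, refits, and predicts the held-out congener; Q²cv =
1 − PRESS/TSS about the full-training mean, RMSEcv = √(PRESS/n).  The
production implementation batches all folds through one vectorized NIPALS
recursion; a naive per-fold refit loop is kept in the tests as the oracle
(agreement to 1e-9 — the two orderings of floating-point operations differ
below that).  The latent-vector count is the minimizer of RMSEcv, ties
toward fewer.  External validation uses the Q²F1 convention (denominator
about the training mean) and RMSEp.

Descriptor selection is a binary-chromosome genetic algorithm: population
64, up to 100 generations with early stopping after 25 stalled generations,
tournament selection of size 2, single-point crossover at rate 0.8,
bit-flip mutation at rate 1/p, elitism 2, fitness memoized per chromosome.
The fitness of a subset is its LOO RMSEcv (at the CV-chosen LV count)
multiplied by a parsimony factor (1 + 0.8·k) for k retained descriptors.
The penalty is load-bearing: at n = 24 the LOO error of the best of 22
noise descriptors is routinely a few-to-~15 percent below the true model's,
so an unpenalized fitness admits chance correlates; a retained descriptor
must cut the error by roughly a sixth to pay its way, which genuinely
informative descriptors do by an order of magnitude at low noise while
chance correlates almost never do.  Elites survive unchanged, so the final
fitness can never be worse than the best initial chromosome.

## Applicability domain

Leverage h = xᵀ(XᵀX)⁻¹x is computed in the autoscaled space of the selected
descriptors (training statistics; Cholesky solve, no explicit inverse).  No
intercept column is appended — autoscaling already centers X — and the
"+1" lives in the critical-leverage formula h* = 3(p+1)/n, which gives the
conventional 0.625 at p = 4, n = 24.  Computing leverage in the raw
selected-descriptor space (not the LV-score space) is what makes that
arithmetic consistent.  Training leverages sum to p exactly.  The Insubria
table pairs every congener's leverage with its predicted ΔE_ads and
set label, which is the standard display for judging AD membership of a
prediction set that has no reference energies.

## Pipeline, seeds, and problem sizes

One master seed is expanded via `numpy.random.SeedSequence.spawn` into
child seeds (< 2³¹) for the descriptor table, the energy noise, and the GA;
a rerun with the same configuration reproduces every numeric artifact byte
for byte (the run log's timestamps excepted).  The default end-to-end run
covers the full 1,701-congener set and finishes in a few seconds on one
CPU; the heaviest test, the 20-run GA recovery experiment, takes about half
a minute.  Test and acceptance problem sizes (n = 24 calibration fits,
30×4 Kennard–Stone oracle instances, 200-replicate noise-floor Monte
Carlo) are the sizes at which the corresponding claims are stated.

## Known limitations

* The generator's linearity is an assumption, not a finding: it makes
  parameter recovery a meaningful test but cannot probe model
  mis-specification.
* Composition-additive TE leaves same-composition isomers distinguishable
  only by dipole; symmetric isomer pairs (e.g. 2,3,7,8- vs
  1,4,6,9-tetrachloro) receive identical descriptors and hence identical
  predictions.
* The WHO TEF cross-tab ships the seven printed fixture values (octachloro
  TEF 0.0003 as printed in the source table, which differs from some other
  WHO listings at 0.0001); it is a rank comparison, not a toxicity model.
* Leverage-based AD assumes the training block is full rank in the selected
  descriptors; collinear selections raise rather than silently
  pseudo-inverting.
* Reproduction of published validation statistics requires the original
  descriptor/energy tables supplied as a CSV; the synthetic generator is
  not expected to reproduce any printed isomer-resolved value.
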