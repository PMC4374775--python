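# Methods

This note documents the models implemented in `pkmech`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Speciation

Assay conditions for a kinase are stated in terms of the *complexed*
nucleotide (ADP-Mg, ADP-Mn) and the *free* divalent cation, while stocks
are totals.  `speciate` solves the single 1:1 equilibrium
`M + L ⇌ ML`, `Kd = [M][L]/[ML]`: the complex concentration is the physical
root of `c² − (M+L+Kd)c + ML = 0`, evaluated as
`c = 2ML / (b + √(b² − 4ML))` with `b = M+L+Kd`.  This form avoids the
catastrophic cancellation of the quadratic formula when `Kd ≪ M, L`, which
is the regime of interest (conditions span ~0.02–30 mM against sub-mM Kd).
`totals_for_design` inverts the problem in closed form.  Mass conservation
and the mass-action identity hold to 1e-10 relative across the fuzzed test
range.

The dissociation constants themselves are **configuration, not results**:
`ADP_MG_KD_MM = 0.76` and `ADP_MN_KD_MM = 0.053` are literature-magnitude
apparent constants (near-neutral pH, ~25 °C) provided as defaults and
flagged as assumptions; no asserted numerical result depends on them.
Competing equilibria (ATP, nucleotide protonation, ionic-strength
corrections) are out of scope — the module does the bookkeeping a worker
needs at the bench, not a general multi-ligand speciation solver.

The ionized (trianion) fraction of phosphoenolpyruvate follows
Henderson–Hasselbalch with pK 6.3.

## Rate laws and catalytic constants

All concentrations are mM internally; velocities are specific activities
(μmol·min⁻¹·mg⁻¹).  Implemented laws:

* rapid-equilibrium random order: `v = V·A·B/(KaKb + Ka·B + Kb·A + A·B)`;
* Hill: `v = V·Sⁿ/(K₀.₅ⁿ + Sⁿ)` — the denominator is parenthesized as the
  only reading consistent with saturation;
* linear dead-end inhibition: competitive
  `v = V·S/(Km(1+I/Ki) + S)`; noncompetitive/mixed
  `v = V·S/(Km(1+I/Ki) + S(1+I/(αKi)))` with α = 1 for NC; uncompetitive
  (intercept-only) is included to complete the Cleland family;
* ordered steady-state `v = V·A·B/(KiaKb + Kb·A + Ka·B + A·B)` and
  ping-pong `v = V·A·B/(Ka·B + Kb·A + A·B)`, provided as generator/oracle
  laws for the mechanism classifier, not as a general King–Altman engine.

`catalytic_constants` converts a specific activity to a turnover number
using the oligomer molar mass.  The basis is explicit
(`n_subunits`, default 4): for a homotetramer of 51,340 Da subunits,
183 μmol·min⁻¹·mg⁻¹ gives kcat ≈ 626 s⁻¹ (the per-monomer basis would give
≈ 157 s⁻¹).  Specificity constants are reported as log₁₀(kcat/Km) with Km
converted to molar, i.e. in M⁻¹s⁻¹.

## Global fitting

`fit_global` minimizes unweighted squared residuals on v over the entire
dataset at once (relative-error weighting by flag), using
Levenberg–Marquardt through lmfit with box bounds.  Initial values are
data-driven (Vmax from the velocity ceiling, Km-type constants from median
concentrations); the default 8-start strategy draws the remaining starts
log-uniformly within bounds under an explicit seed, guarding against the
multimodality of the Hill and mixed-inhibition surfaces at small n.  Bulk
simulation studies (bias, classification rates) use `n_starts=1` with the
data-driven init, which the replicate studies show is adequate on these
designs and keeps 500-replicate runs to seconds.

Standard errors come from the Jacobian at the optimum (Gauss–Newton); they
are *fit* standard errors, not across-experiment standard deviations —
both notions exist in practice and neither is asserted to equal published
error bars.  Model comparison uses AICc (residual-variance form, +1 for
the implicit σ²); candidates within Δ < 2 of the winner are reported as
ambiguous rather than silently dropped.  Identifiability is checked before
fitting: a two-substrate model demands ≥ 2 distinct levels of each
substrate, an inhibition model demands inhibitor variation, and an
inhibition *series* demands ≥ 3 inhibitor levels including zero.

## Pattern classification and mechanism inference

`double_reciprocal_pattern` works in reciprocal space because that is
where the classical patterns are defined, but all parameter estimates come
from untransformed global fits.  Naive 1/v regression is dominated by the
low-velocity points (variance of 1/v scales as var(v)/v⁴), so the line
fits average replicates and weight by v̄²; the common intersection of the
line pencil is estimated by least squares over all series and its
uncertainty by a delete-one-series jackknife.  Decision rules:

* **parallel** when the relative slope spread (sd/mean) is below 0.10 —
  well above the spread the weighted estimator shows on truly parallel
  (ping-pong) data and well below the spread any intersecting family
  produces on these designs;
* **ambiguous** when the jackknife SE of the intersection abscissa exceeds
  0.5·|x₀| (no single intersection point);
* **on the 1/S axis** when |y₀| ≤ max(0.05·min intercept, 2.5·SE(y₀)).
  The 5 % band makes the traditional visual judgement explicit; the SE
  branch prevents sampling noise from masquerading as an off-axis
  intersection.  At the default study conditions (5 % relative noise,
  5 replicates, the published 5×5 grid) this classifies ≥ 90 % of
  random-order datasets on-axis while keeping ordered generators
  (Kia ≠ Ka) off-axis;
* otherwise **left-above / left-below** by the sign of y₀.

`classify_inhibition` combines slope/intercept replots (line parameters
regressed on [I], t-test at 0.05) with AICc model selection.  The replot
rule is primary — C iff slope-only, UC iff intercept-only, NC/MT if both,
split by whether the mixed-fit α is within 2 SE of 1.  When the two
disagree, a tie within the AICc ambiguity band is resolved in favour of
the replots; outside the band a clean single-effect replot still wins
(the selected model's extra parameter is fitting noise the replots cannot
see), and the call is flagged inconsistent either way.  A flat response in
[I] is a *no-inhibition* call, not UC.

`infer_mechanism` applies the dead-end decision table: parallel ⇒
ping-pong; intersecting pattern with every analog competitive against its
own substrate and NC/MT against the co-substrate ⇒ rapid-equilibrium
random; an analog competitive against its own substrate but uncompetitive
against the co-substrate ⇒ ordered, with the co-substrate binding first.
An intersecting pattern with no inhibition evidence is deliberately
*ambiguous*: initial velocities alone cannot separate ordered steady-state
from random rapid-equilibrium.

## Structural interactions

Structures are parsed with Biopython behind a flat atom table; alternate
locations resolve to the highest-occupancy conformer (ties → altloc 'A')
and author 1-based residue numbering is preserved.  The PDB writer is a
plain fixed-width formatter used for fixtures and trajectories.

* **π–π**: ring centroid and least-squares ring plane over the ring member
  atoms (for ideal rings this is the exact plane); the angle is the acute
  interplane angle in [0°, 90°]; pairs reported once within a 7 Å centroid
  cutoff.
* **Salt bridges**: Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 against Asp
  OD1/OD2, Glu OE1/OE2 and C-terminal OXT within 4.0 Å; one record per
  residue pair at the minimum atom distance.
* **H-bonds**: heavy-atom N/O/S pairs within 3.4 Å — the structures of
  interest are crystal structures without hydrogens, so the criterion is
  distance-only — excluding intra-residue pairs, peptide-neighbour
  backbone pairs, and sub-1.8 Å (covalent) separations.
* **Interface contacts**: inter-domain atom pairs classified Polar (both
  atoms N/O, ≤ 3.35 Å) or Hydrophobic (≥ 1 carbon, ≤ 3.90 Å).  The cutoffs
  follow the LigPlot/Dimplot convention and are flags, since the original
  tool's thresholds are not documented alongside its output.  Domain
  definitions are inclusive author-numbered intervals; the published lid/
  body boundaries for the three enzymes are shipped as constants, and
  hinge-region exclusion is a user-supplied range list (hinge detection
  itself is out of scope).  Tetramers are analysed per chain with a
  minimum-over-chains aggregate, since deposited chains differ slightly.

All geometry is invariant under rigid motion (tested under random
rotations + translations).

## Native contacts (Q)

The native contact set is every Cα pair within 8 Å at sequence separation
≥ 3 (Carma-style defaults, all exposed as flags); per frame,
Q = fraction of native pairs within 1.2× their native distance.  Q = 1 is
the native state; trajectories are multi-MODEL PDB or plain coordinate
arrays in the reference Cα ordering.  Domain-restricted Q equals
whole-structure Q on the cropped structure.  An empty contact set scores
Q = 1 by convention.

## Alignment profiles

Reference positions (1-based, ungapped) map to alignment columns by
counting non-gap reference characters — the standard way positions are
quoted against a canonical enzyme numbering.  Frequencies are relative
over all sequences including gaps ('-' and '.'); covariation is the
fraction of anchor-matching sequences simultaneously satisfying every
partner constraint.  Published conservation percentages depend on the
original (undeposited) sequence set, so only the computation, not those
percentages, is testable.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the analyses assume*,
with the published study conditions as defaults:

* **Velocity tables**: exact rate-law values on the published
  concentration designs — the 5×5 PEP³⁻ × ADP-Mg grid (0.031–1.30 mM ×
  0.084–0.67 mM; the varied-axis lists are taken from the fixed-level
  lists of the complementary panel, the natural reading of a symmetric
  design) and the four dead-end inhibition designs (oxalate 0–40 μM vs
  PEP and vs ADP-Mg; AMP 0–16 mM vs PEP and 0–20 mM vs ADP-Mg) — plus
  Gaussian noise, default 5 % relative with 5 replicates, matching the
  visual scatter of replicated initial-rate assays.  Velocities truncate
  at zero, a slight bias source at very low rates (negligible on these
  designs: measured parameter bias < 2 %).  Real data additionally carry
  systematic errors (coupled-assay lags, enzyme-batch drift) that the
  generator does not emulate, so passing recovery tests demonstrates
  estimator correctness, not robustness to systematic error.
* **Structures**: idealized geometry (regular 1.39 Å aromatic hexagons,
  exact planted distances), which makes Table-style assertions exact; real
  side chains are never ideal, so detector *thresholds* should be read as
  conventions, not calibrations.
* **Trajectories**: contact loss on a prescribed schedule.  Contacts are
  broken in a seeded fixed order by radial displacement, which realizes
  the schedule exactly when contacts share no residues (the
  `make_contact_pair_reference` fixture); on dense references collateral
  breakage can overshoot, which is documented in the generator.  No
  force-field realism is attempted.
* **Alignments**: column frequencies realized *exactly* by
  largest-remainder allocation with one shared seeded permutation across
  columns, so planted joint motifs (for covariation) line up by
  construction and realized frequencies converge trivially as n grows.

Every generator is a bit-reproducible function of (specification, seed).

## Problem sizes and replication

Replicate studies use 500 seeded datasets for parameter-recovery bias and
per-family mechanism classification, 200 for the Hill-coefficient mean,
1000 fuzzed systems for speciation, and n = 10⁴ sequences for profile
convergence — sizes at which the Monte-Carlo error of each checked
statistic is an order of magnitude below its acceptance margin, while the
full suite stays interactive.

## Known limitations

* Only 1:1 binding in speciation; no ionic-strength or multi-equilibrium
  corrections.
* The mechanism classifier assumes the designs provide well-separated
  co-substrate levels; degenerate designs (e.g. ordered with Kia → 0)
  genuinely approach the parallel pattern and are classified as such.
* Uncompetitive inhibition is implemented but was not part of the original
  pattern set; it appears only in ordered-mechanism oracles.
* β-bridge/secondary-structure assignment and π-cation detection are not
  implemented (no published values to check against); listed for future
  work.
* The published crystal structures are not redistributed; geometry checks
  against printed distances require PDB 3QTG/2G50 locally or online.
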