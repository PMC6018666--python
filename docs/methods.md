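# Methods

This note documents the models implemented in `loopbind`, their
assumptions, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate.

## Atomic models and degrees of freedom

Models are flat atom tables (chain, residue, atom name, element, xyz in Å)
with 1-based PDB-style numbering; insertion codes and altlocs are rejected.
Chains are classified as protein or RNA from residue names.  Refinement
degrees of freedom are declared by a `RigidGroupPartition`: named rigid
residue groups plus individually flexible linker residues.  A linker torsion
rotates everything downstream of the residue (in a declared topological
order) about the CA(i)→CA(i+1) axis, which preserves all bond lengths along
the chain; rigid-group moves rotate about the group centroid.  Superposition
is closed-form least squares (Kabsch, via quaternions) with equal weights on
the selected backbone atoms (N, CA, C, O for protein; P, O5', C5', C4', C3',
O3' for RNA).

## SAXS forward model

Intensities come from the Debye equation over all atom pairs.  Vacuum form
factors are the 4-Gaussian Cromer–Mann parameterisation (IT92 coefficients
as tabulated by gemmi; f(0) equals the electron count).  The excluded
solvent is handled with Fraser-style Gaussian dummy atoms:
`f_eff(q) = f_vac(q) − ρ·V·exp(−q²V^{2/3}/4π)` with bulk density
ρ = 0.334 e/Å³ and per-element displaced volumes (C 16.44, N 2.49, O 9.13,
P 5.73, S 19.86, H 5.15 Å³).  No hydration-shell term is modelled — this is
a deliberate fidelity limit; absolute χ values against real data would be
optimistic without it.

The production engine optionally bins pair distances per element pair using
the exact mean distance of each occupied bin.  At 0.005 Å bins it agrees
with the exact double sum to better than 1e-6 relative over q ≤ 0.6 Å⁻¹
(tested); the annealing sampler uses 0.1 Å bins (≈3e-4 relative, far below
the 2 % data noise) for speed.

Restraint preparation fits the measured curve for q ≤ 0.5 Å⁻¹ with a
degree-16 polynomial — fitted in plain I vs q, on a q axis rescaled to
[−1, 1] for conditioning — and evaluates it on the regular grid
0.03–0.45 Å⁻¹ in 0.01 steps, giving 43 representative intensities.  The
model radius of gyration is weighted by each atom's zero-angle scattering
contrast (electron counts when no solvent correction is active), which is
what a Guinier analysis of the corresponding curve estimates; for the
elongated toy complex the Guinier window must be conservative (q·Rg ≲ 0.3)
before the two agree to 3 %.

## RDC model

An amide N–H coupling is `D = bᵀ S b` with b the unit bond vector and S the
traceless symmetric Saupe matrix.  The dipolar prefactor (gyromagnetic
constants × bond length) is folded into the fitted tensor scale, so
couplings stay in Hz and no N–H bond length has to be asserted.  Fitting is
linear least squares over the five independent components and requires a
rank-5 orientation design matrix (≥5 suitably diverse bonds).  Quality is
the Q-factor `sqrt(Σ(D_calc−D_exp)²/ΣD_exp²)` and the Pearson correlation.

The refinement restraint is linear in the correlation between (two-replica
averaged) calculated and experimental couplings, slope −20000 kJ/mol, so
perfect correlation contributes −20000 kJ/mol.  The single-trajectory
sampler evaluates the restraint on the instantaneous structure (formally,
two identical replicas); the two-replica average is exposed as its own
operation.  During refinement the alignment tensor is held fixed at the
generating tensor rather than refit per step — refitting per step would
make the restraint vacuous since SVD maximises the very correlation being
restrained.

## Hybrid energy

All energies are in kJ/mol; temperature enters only through Metropolis
acceptance with k_B = 0.0083144621 kJ/(mol·K).

* **Metainference SAXS term.**  Independent Gaussian likelihood per
  representative intensity: `E = Σᵢ (λ·s₀·fᵢ − dᵢ)²/(2σᵢ²) + Σᵢ log σᵢ`,
  where s₀ is a fixed calc→exp scale estimated once as the mean intensity
  ratio, λ carries a flat prior on [0.9, 1.1], and σᵢ is one uncertainty per
  data point.  σᵢ starts at 10× the nominal data error and is resampled by
  per-point Metropolis moves in log σ under a Jeffreys prior, so the data
  restraint force grows as the σᵢ shrink.  A fixed-σ mode exists for
  deterministic tests.  With one replica and zero standard error of the
  mean this is the inferential-structure-determination limit of
  metainference.
* **Structural restraints.**  One-sided harmonic walls, `E = k(x−x₀)²`
  above the centre, no ½ factor: four ring-centroid interface distances
  (centre 3.5 Å, k = 1000), two salt-bridge charged-group minimum distances
  between Arg side-chain N and Asp carboxylate O atoms (centre 4 Å,
  k = 1000), and per-segment superposed backbone RMSD to a reference
  (centre 0 Å, k = 10000) for the secondary-structure segments.
* **Surrogate physical term.**  Replaces the explicit-solvent force field
  (out of scope): harmonic springs on consecutive-atom distances along each
  chain (k = 1000 kJ/mol/Å², reference lengths from the restraint reference
  model) plus soft-sphere repulsion `k(d₀−r)²` (d₀ = 2.5 Å,
  k = 100 kJ/mol/Å²) between non-bonded pairs.  Pairs already within d₀ in
  the reference are treated as intentional contacts and excluded.  The
  reference topology must come from the reference model, never from a
  perturbed start — start-derived spring lengths would pin the perturbation
  in place.

## Annealing and selection

The sampler cycles the temperature in a triangular wave 300 K → 100 K →
300 K; one cycle is one full sweep.  The nominal 20 ps thermal period of an
MD implementation maps here to a step-count half-period (default 500 MC
steps, 300 cycles) — a deliberate re-interpretation, since this is a
Monte-Carlo sampler, not an integrator.  Moves are uniform single-torsion
perturbations of linker residues and rigid rotations/translations of the
selected domain group, amplitudes scaled by T/T_high.  Defaults are 10°
rotation, 1.5 Å translation and 10° torsion per move: smaller amplitudes
(5°/0.5 Å) stall on the ~8 Å recovery problem within a desk-scale step
budget, and at these energy scales (walls of 10³–10⁴ kJ/mol against
k_BT ≈ 2.5 kJ/mol) the sampler is effectively a stochastic descent, so
larger proposals change the optimisation rate, not the target.

The expensive data terms (SAXS, RDC) are refreshed every 10th step and held
between refreshes; structural terms are evaluated every step.  λ and σ
nuisance moves happen at the data stride on cached forward values.  The
refined structure is the snapshot with the lowest data-term
(metainference + RDC-correlation) energy among the 300 K samples of the
last 30 cycles, ties broken by the earliest step.  Defining the selection
metric as the sum of data terms keeps selection data-driven when one term
is disabled in an ablation.

Reported experiments use a scaled-down schedule — 30 cycles × 60 steps
(recovery, ablation) or 40 × 80 (the README run) — which recovers the toy
ground truth to well under 2 Å; the 300 × 1000 default is the faithful
configuration for larger problems.

## ITC

The one-site (Wiseman) isotherm in the "overfill" cell convention: after
cumulative injected volume dV, the working concentrations are
`M_t = M₀(1−dV/2V₀)/(1+dV/2V₀)` and `X_t = X₀(dV/V₀)/(1+dV/2V₀)`; the bound
fraction is the closed-form root of the binding quadratic and per-injection
heats are cumulative-heat differences with the standard displaced-plug
correction.  Consequences worth knowing: post-equivalence injections show a
small dilution heat of opposite sign, and per-injection totals under
re-binning agree only to ~1e-3 (the cumulative heat itself is exactly
conserved).  Fits run over (log N, log K_D, ΔH) by Levenberg–Marquardt;
derived quantities use R = 1.987 cal/(mol·K) and T = 298.15 K.  Heat of
dilution is either assumed pre-subtracted or removed as a constant offset
estimated from the last three injections.

Synthetic titrations use cell 20 µM / syringe 300 µM — the low end of the
plausible instrument ranges, appropriate for the high-affinity rows (the
12-mer interaction still sits at c ≈ 1300, above the classical fittable
window, which the fit reports as a warning; parameter recovery at 0.5 %
noise nevertheless stays within 5 %).

## NMR observables

CSP: `sqrt(ΔδH² + (0.2·ΔδN)²)` — the 0.2 nitrogen weight is the common
convention and configurable; exchange-broadened residues are carried as an
explicit category (NaN CSP, flag set), never as zeros.  Relaxation times
are per-residue least-squares fits of `I₀·e^{−t/T}`; duplicate delays give
an intensity-noise estimate that is propagated into the reported T
uncertainty.  PRE: the intensity-ratio model
`I_para/I_dia = R₂·e^{−Γ₂t}/(R₂+Γ₂)` is inverted numerically (bisection)
for Γ₂, and `r = (K_eff/Γ₂)^{1/6}` with K_eff from the standard nitroxide
electron–proton prefactor (1.23×10⁻³² cm⁶ s⁻²) and a configurable
correlation time (default 5 ns, 600 MHz).  Ratios above 0.98 become
lower-bound distances, below 0.02 upper bounds.  Absolute distances are
approximate by construction; profile comparison (per-residue differences
and an RMS summary) is the supported use.

## Synthetic data

The toy complex mirrors the tandem-RRM architecture: protein chain A,
residues 1–196 (domains 1–90 and 108–196, flexible linker 91–107), RNA
chain B of 12 nucleotides.  Domains are serpentine backbone traces (N, CA,
C, O and an amide H per residue) on a 3.8 Å grid — compact, chain-bonded,
and cheap — not folded domains.  The restraint-bearing chemistry is
represented by named pseudo-atoms: Phe rings and base rings as 1.4 Å-radius
hexagons stacked 3.4 Å apart (inside the 3.5 Å wall), Arg NH1 / Asp OD1–OD2
placed along the CA–CA lines so the salt-bridge distances are 3.5 Å (inside
the 4 Å wall).  Domain 2 is placed by a deterministic search over rotations
and interface gaps that maximises interdomain clearance subject to
salt-bridge reachability.  The ground truth therefore has exactly zero
restraint energy, and the perturbed start is built by scaled random linker
torsions (bond-preserving), bisected to the requested backbone RMSD (±10 %
band) and retried until clash-free.

One global seed expands into independent per-generator streams via a CRC of
the generator tag mixed into a `SeedSequence`, so adding generators never
shifts existing streams.  Zero-noise outputs of every simulator equal the
corresponding forward model exactly, and manifests record all ground-truth
parameters.

What passing these tests shows — and does not.  The recovery and ablation
experiments demonstrate that the estimator machinery is correctly wired:
the hybrid score has its minimum at the truth, annealing can find it from
8 Å away, and the SAXS term carries real information (ablating it degrades
the median refined RMSD from ≈0.16 Å to ≈0.41 Å over 5 seeds).  They do not
demonstrate force-field realism, hydration effects, RNA conformational
chemistry, or performance on experimental noise structure beyond i.i.d.
Gaussian.

## Numerical choices and degenerate inputs

Polynomial condensation warns (not errors) on rank-deficient fits; the
Guinier fit errors with fewer than 5 window points or a non-decaying curve;
tensor fitting errors below rank 5; the correlation restraint errors on
zero-variance inputs; ITC fitting rejects flat isotherms and experiments
with fewer than 10 injections, and warns outside c ∈ [1, 1000];
non-decaying relaxation series are flagged invalid rather than returned;
PRE ratios of exactly 1 give Γ₂ = 0 and a lower-bound record.  Upper walls
are continuous and once-differentiable at the centre.  Ties in refined-model
selection go to the earliest step.

## Known limitations

No hydration shell or explicit solvent; no replica exchange and no
gradient-based dynamics; a fixed alignment tensor during refinement; the
toy RNA has no internal flexibility (its halves ride with their domains, so
a domain displacement stretches one virtual backbone junction — a spring
that, like the real covalent connectivity it stands for, favours reuniting
the chain); and the deposited crystal structure and solution models of the
real complex are not reproduced here — the package validates the
methodology on synthetic ground truth instead.
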