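# loopbind

Integrative structure modelling and binding thermodynamics for a tandem-RRM
protein bound to single-stranded RNA.

The scientific setting is the 1:1 complex between UP1 — the tandem
RRM1–RRM2 fragment (residues 1–196) of hnRNP A1 — and a 12-nucleotide RNA
(5′-AGUAGAUUAGCA-3′) derived from the terminal loop of pri-mir-18a, in which
each RRM domain reads out one UAG motif. `loopbind` re-implements, at desk
scale, the computational machinery needed to determine and validate such a
model from solution data:

* **SAXS forward calculation** with the Debye equation,
  `I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ)`, with Cromer–Mann vacuum form
  factors corrected for the excluded solvent, plus restraint preparation
  (degree-16 polynomial fit of the measured curve, evaluated on the
  0.03–0.45 Å⁻¹ grid in 0.01 steps → 43 representative intensities) and
  Rg/Dmax/Guinier summaries.
* **RDC analysis**: the 5-parameter Saupe alignment tensor by linear
  least-squares (SVD), the Q-factor and Pearson r, and the replica-averaged
  linear-in-correlation restraint `E = −20000 · corr(D_calc, D_exp)` kJ/mol
  used during refinement.
* **Hybrid (metainference) scoring**: a Gaussian likelihood per SAXS data
  point with a sampled uncertainty σᵢ and a scale λ under a flat prior on
  [0.9, 1.1], combined with harmonic upper-wall restraints — ring-stacking
  interface distances (Phe17–A4, Phe59–G5, Phe108–A9, Phe150–G10; centre
  3.5 Å, k = 1000 kJ/mol), two inter-domain salt bridges (Arg75–Asp155,
  Arg88–Asp157; centre 4 Å), and a secondary-structure backbone-RMSD wall
  (centre 0, k = 10000 kJ/mol) — plus a surrogate physical term.
* **Simulated-annealing refinement** over rigid-domain and linker-torsion
  degrees of freedom, cycling 300 K ↔ 100 K, with the refined model selected
  as the lowest data-term energy among the 300 K samples of the last 30
  cycles.
* **ITC one-site thermodynamics**: the Wiseman isotherm with
  displaced-volume corrections, nonlinear fits for (N, K_D, ΔH), derived
  ΔG = RT ln K_D and ΔS = (ΔH − ΔG)/T with R = 1.987 cal/(mol·K), and the
  published titration table as presets.
* **NMR observables**: combined ¹H/¹⁵N chemical shift perturbations,
  exponential relaxation-time fits, and PRE intensity-ratio → r⁻⁶ distance
  inversion for a nitroxide label at residue 66.
* **Synthetic data with known ground truth** for every one of these inputs,
  so the whole pipeline is testable end to end without downloads.

## Worked example

Thermodynamic self-consistency of the titration presets — recompute K_D from
the calorimetric ΔH and ΔS of each interaction and compare with the listed
value:

```sh
$ loopbind itc-consistency
          interaction  Kd_listed_uM  Kd_from_dH_dS_uM   rel_dev
           RRM1+7-mer      20.40000         19.542037 -0.042057
           RRM2+7-mer       6.80000          7.659977  0.126467
            UP1+7-mer       3.40000          3.439580  0.011641
     UP1+17-mer(A35C)       3.10000          3.090339 -0.003116
      UP1+pri-mir-18a       0.14770          0.146982 -0.004859
           UP1+12-mer       0.01550          0.015062 -0.028253
      UP1+12-mer-mut1       0.15410          0.166445  0.080111
...
```

The high-affinity 12-mer interaction closes to within 3 % (K_D 15.1 nM
recomputed vs 15.5 nM listed); deviations track the printed precision of
ΔH/ΔS.  The 7-mer/12-mer ratio (3.4 µM / 15.5 nM ≈ 219) reproduces the
more-than-200-fold affinity gain from engaging both UAG motifs at once.

A full refine-and-validate run on the synthetic toy complex:

```sh
$ loopbind refine --seed 1 --out run1
run complete: run1
```

`run1/report.json` then contains, for this seed,

```
start_rmsd_to_truth  8.39 Å   ->   rmsd_to_truth  0.29 Å
rdc:  q_factor 0.34, pearson_r 0.940  (196 bonds, 5 % noise in the data)
saxs: chi 1.10 at scale 1.002         (120 points, 2 % noise)
```

i.e. annealing under SAXS + RDC metainference restraints pulls an 8 Å
domain-displaced start model back to sub-Å agreement with the ground truth;
the SAXS χ of ≈1 says the refined model fits the noisy curve to within its
errors, and the validation numbers come from an independent code path
(naive Debye sum, pseudo-inverse tensor fit), not from the scoring route.

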