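# fieldpmf

Analysis toolkit for electrostatics-aware enzyme reaction studies:
internal electric fields projected on reaction axes, umbrella-sampling
free-energy profiles with bootstrap errors, transition-state-theory
kinetics, Stark-effect barrier decomposition, and committor validation of
transition states — with synthetic generators that carry analytic ground
truth for every estimator.

## Who it is for

Computational enzymology groups that run biased QM/MM or classical MD
(the motivating system is PET depolymerisation by an engineered cutinase,
a serine hydrolase with a Ser/His/Asp triad) and need the *analysis*
layer to be reproducible and checkable: given window time series, charge
environments and field–energy scan tables, produce PMFs, barriers,
rates, field statistics and decompositions with explicit conventions and
seeded uncertainty estimates.

## What it computes

* **Internal electric field** at the midpoint of an ordered atom pair
  (a *reaction axis*), by bare Coulomb sum over a selected environment:
  `F(r0) = K Σ q_i (r0−r_i)/|r0−r_i|³`, reported in MV/cm with the axis
  unit vector running tail→head (K = 1439.96 MV/cm for 1 e at 1 Å).
* **WHAM**: self-consistent reconstruction of a 1-D PMF from harmonic
  umbrella windows (`U = k(x−x0)²`, AMBER convention, `half_k` switch),
  point-bootstrap uncertainties, adjacent-window overlap and
  half-split convergence diagnostics, persistence-based barrier
  extraction.
* **Eyring kinetics**: `k = κ(k_BT/h)exp(−ΔG‡/RT)` both ways, explicit
  temperature everywhere.
* **Stark decomposition**: per-state response `E(F) = e0 − μcF − ½αcF²`
  fitted from scan tables; the barrier change between a reactant-state
  field and a (shifted) transition-state field split exactly into a
  static part and a dynamic extra.
* **Committor**: BAOAB Langevin shooting on model potentials with Wilson
  intervals and an ensemble pass/fail verdict (median p in [0.4, 0.6]).
* **Pipeline**: all of the above from one YAML config into one
  deterministic JSON + Markdown report.

## Worked example

`examples/02_umbrella_wham.py` samples 21 harmonically biased windows
(k = 50 kcal mol⁻¹ Å⁻², centers −1.25…1.25 Å) exactly from the Boltzmann
density of a quartic double well with a 5 kcal/mol barrier at 343.15 K,
then reconstructs the profile:

```
windows: 21   occupied bins: 141
barrier: 4.999 +- 0.030 kcal/mol  (true: 5.0)
reaction free energy: +0.000 kcal/mol  (true: 0, symmetric well)
min adjacent window overlap: 0.401
half-split convergence |dPMF|max: 0.107 kcal/mol
```

The barrier recovers the generating potential within one bootstrap sigma;
the overlap and convergence numbers are the two diagnostics a defensible
umbrella-sampling study reports (overlap well above zero, half-split
drift well below the features of interest).

`examples/03_stark_decomposition.py` shows the field decomposition: with
a transition state whose axial dipole is 4 D more anti-aligned than the
reactant's, a −37.1 MV/cm reactant-state field lowers the barrier by
7.12 kcal/mol (static part), and the shift of the transition state's own
mean field to −52.5 MV/cm lowers it by a further 2.22 kcal/mol (dynamic
extra), total −9.34 kcal/mol — the two parts summing exactly.

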