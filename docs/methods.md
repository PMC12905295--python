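# Methods

This note documents the models, conventions and numerical choices behind
`fieldpmf`, and what its synthetic-data validation does and does not show.

## Internal electric fields (`efield`)

The scaffold field at a reaction axis is a bare Coulomb sum over the
selected environment atoms,

    F(r0) = K * sum_i q_i (r0 - r_i) / |r0 - r_i|^3,

with charges in elementary units, distances in angstrom, and
K = e / (4 pi eps0 (1e-10 m)^2) / (1e8 V m^-1 per MV cm^-1)
= 1439.9645478... MV/cm for a unit charge at 1 A (CODATA 2018 values,
stored to full double precision in `constants.py`). No distance cutoff,
reaction-field correction or periodic imaging is applied: a cutoff would
silently change reported MV/cm values, and the probe sits deep inside a
finite charge cloud in the intended use.

Conventions, fixed once and locked by unit tests:

* the axis unit vector runs **tail → head** in the order the axis is
  named ("O1–C1" means O1 → C1), so a negative axial component opposes
  the named direction;
* the probe point is the **instantaneous midpoint** of the two axis atoms,
  re-evaluated per frame — the only self-consistent reading when the axis
  atoms move;
* the two axis atoms are always excluded from the environment sum, on top
  of whatever the user's selection excludes (they belong to the reacting
  system, not the scaffold);
* the intended default environment is "all protein residues except the
  catalytic triad", expressed as an exclude-mode `Selection`; whether
  substrate, waters or ions count as environment is left to the user's
  selection because there is no universal convention.

Per-window statistics discard the leading half of each series by default
(`discard_fraction = 0.5`, the "last 15 ps of a 30 ps window" rule) and
report mean ± sample (n−1) s.d. Window-level and basin-pooled statistics
are distinct quantities; the API computes per-window statistics and leaves
pooling to the caller so the two are never conflated. Cross-axis coupling
is summarised by a plain Pearson correlation matrix on a common frame
grid; constant series are refused rather than silently yielding NaN.

## Umbrella sampling and WHAM (`wham`)

The restraint is `U(x) = k (x - x0)^2` **without** the 1/2 factor — the
AMBER convention — with a `half_k` flag per `BiasSpec` for the other
convention; the factor-of-two ambiguity is the single most common source
of silently wrong PMFs, so it is an explicit, tested switch.

The solver iterates the standard WHAM self-consistency equations in log
space (`scipy.special.logsumexp`) until the maximum absolute change of the
per-window offsets drops below `tolerance` (default 1e-5 kcal/mol,
default temperature 343.15 K, default bin width 0.02 A for bond-length
scale coordinates; 0.1 A is more appropriate for centre-of-mass distance
profiles). Optional fixed-point damping is available but defaults to 1.
The PMF is −RT ln p on occupied bins, min-shifted to zero; empty bins are
masked, never interpolated — interpolation would fabricate barrier
heights. In the single-window zero-bias limit the solve reduces exactly
to −RT ln(histogram).

Uncertainty is a seeded bootstrap (default 100 replicates) that resamples
the **retained points** of each window with replacement, window
identities fixed, re-solves on the full-data grid (warm-started from the
full-data offsets) and min-shifts each replicate before taking per-bin
standard deviations. Point resampling is the standard WHAM bootstrap;
block or window resampling would be preferable for strongly
autocorrelated data, which the exact sampler used in validation does not
produce — a real-trajectory caveat, flagged here deliberately. No
autocorrelation-based effective-sample-size correction is applied.

Barrier extraction pairs the global minimum of the occupied profile with
the local minimum of greatest topographic persistence (highest separating
ridge) and reports ridge − reactant basin and product basin − reactant
basin. Persistence pairing makes the extraction robust to shot-noise
dips and spikes in sparsely sampled tail bins; ties break toward the
reactant side.

Diagnostics: pairwise histogram overlap (sum of bin-wise minima of the
normalised window histograms; ~0.32 for two unit Gaussians 2 sigma apart)
with the minimum over adjacent pairs, and a first-half/second-half
convergence check reporting the maximum per-bin PMF difference. The
convergence comparison is restricted to the coordinate range spanned by
the bias centers: outside it only a handful of tail samples land, and
their histogram shot noise would swamp the drift signal the diagnostic is
meant to detect.

## Eyring kinetics (`kinetics`)

`k = kappa (k_B T / h) exp(-dG / RT)` with R = 1.987204e-3
kcal mol^-1 K^-1 and exact CODATA k_B, h. The temperature is a required
explicit argument everywhere. A documented quirk this module exists to
make visible: published rate↔barrier conversions are often made at
298.15 K even when the simulated system runs hotter (e.g. a thermophilic
enzyme at 343 K); at 298.15 K a 10.7 kcal/mol barrier gives ~1e5 1/s and
0.3–1.6 1/s map to 18.2–17.2 kcal/mol, whereas at 343 K the same inputs
give ~1e6 1/s and 21.0–19.9 kcal/mol. `STANDARD_TEMPERATURE` marks the
conventional choice; nothing is corrected silently.

## Stark response and the static/dynamic split (`stark`)

Each state's energy under an axial field F (MV/cm) is modelled as

    E(F) = e0 - mu c F - (1/2) alpha c F^2,

with mu in debye, alpha in D/(MV/cm) and c = 0.0480107... kcal/mol per
D·(MV/cm) derived from SI (1 D = 1e-21/c_light C·m). A dipole parallel to
a positive field is stabilising; F is positive along the axis tail→head
direction, consistent with `efield`. Fits are ordinary least squares on
the (1, −cF, −cF²/2) design with parameter sigmas from the residual
covariance; order 1 and 2 are supported because scan data rarely
constrain hyperpolarizability.

The barrier modulation between a reactant-state field F_R and a
transition-state field F_TS splits as

    static  = [E_TS(F_R)  - E_RC(F_R)] - [E_TS(0) - E_RC(0)]
    dynamic = E_TS(F_TS) - E_TS(F_R)
    total   = static + dynamic            (identically),

so "dynamic extra" is precisely the additional (de)stabilisation the
transition state gains by feeling its own, shifted mean field instead of
the reactant's. The package consumes field–energy scan tables; it does
not run quantum chemistry, so any literature decomposition can only be
reproduced given the corresponding scan tables as input — the algebra
itself is validated against hand-evaluated SI-unit oracles.

## Committor analysis (`committor`)

Shots are BAOAB-split Langevin trajectories (positions fixed at the
candidate, Maxwell–Boltzmann velocities resampled per shot) on explicit
1-D model potentials; basin entry is position-only, and timed-out shots
are excluded from p and counted separately. Defaults: T = 343.15 K,
friction 10 ps^-1, timestep 1 fs, mass 12 amu, 1e5 steps. The 95%
interval is Wilson (robust at small counts). An ensemble of candidates
"passes" when its median committor lies in [0.4, 0.6] — an artifact
choice for what "validated transition state" means at desk scale, made
explicit here because committor-validation protocols are rarely fully
specified. The quartic double well `V = h((x/w)^2 - 1)^2` has its basin
boundaries at the minima ±w by default; a committor start must lie
strictly between them.

## Synthetic data (`synthetic_data`)

Each generator carries its own ground truth and is a pure function of its
seed:

* **Point-charge environments** ship a companion field record computed by
  an independent scalar double loop (not the `efield` code path), giving a
  1e-10-relative two-route check on every generated frame. Charges avoid
  a 2 A sphere around the probe.
* **Prescribed-field trajectories** place a mirrored charge pair at
  ±3 A on the axis with magnitudes q = F d²/(2K) solved in closed form,
  so the axial field equals the schedule to machine precision; optional
  decoy charges sit in the perpendicular plane through the probe and
  contribute exactly zero axial field by geometry. Schedules exceeding
  |q| = 10 e are rejected as infeasible rather than silently clipped.
  The stock Gaussian schedules use state means of −37.1 ± 11.1 and
  −52.5 ± 10.2 MV/cm — the magnitude scale on which reactant-to-TS field
  shifts are reported for serine-hydrolase active sites.
* **Umbrella windows** are drawn exactly from the biased Boltzmann
  density via inverse-CDF on a 10^4-point grid — no Markov chain, hence
  no autocorrelation or burn-in — so WHAM accuracy is tested in
  isolation. A `stratified` option evaluates the inverse CDF at
  stratified uniforms, pinning the empirical histogram to the density;
  accuracy fixtures use it so that estimator error, not sampling noise,
  is what the analytic-recovery bounds measure. Densities that are not
  negligible at the support edges are rejected as unnormalisable.
* **The toy active site** is an 8-residue fixed-column PDB with residues
  165 (SER), 210 (ASP) and 242 (HIS) as a catalytic triad and uniform
  backbone-style charges, for selection and I/O tests; byte-identical per
  seed.

What passing on these fixtures does **not** show: behaviour under
autocorrelated, non-equilibrium or force-field-realistic data (charge
distributions, solvent structure, PET-chain geometry), window
time-series with slow drift, or multidimensional reaction coordinates.
The fixtures are statistical stand-ins that make the estimators'
correctness checkable, not imitations of molecular dynamics output.

## Validation problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the analytic bounds are decisive: 21 windows × 10^4 exact samples for
the double-well recovery (barrier 5.0 kcal/mol recovered within a
bootstrap sigma of ~0.03 kcal/mol; per-bin agreement with an independent
maximum-likelihood WHAM solve within 0.05 kcal/mol), 100 random 50-charge
frames for the Coulomb two-route check at 1e-10 relative, 400 Langevin
shots for the symmetric-barrier committor, and 2000-frame prescribed-field
trajectories for the window statistics.

## Known limitations

* 1-D profiles only; no 2-D WHAM or MBAR solver (a maximum-likelihood
  solve exists in the test suite purely as a cross-check oracle).
* No autocorrelation correction in the bootstrap (see above).
* The committor module works on model potentials, not on trajectory data.
* PDB writing is limited to what the toy generator needs; trajectory
  formats beyond the XYZQ dialect are out of scope.
* Pipeline stage stitching offsets are config inputs by design: how
  segments computed at different theory levels are referenced to a common
  zero is a reporting choice the tool records but cannot infer.
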