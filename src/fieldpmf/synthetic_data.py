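"""Synthetic inputs with analytically known ground truth.

Every generator here is a pure function of its spec (same seed, same
bytes), and each one carries its own truth: point-charge environments ship
the brute-force Coulomb field computed by an independent double loop;
prescribed-field trajectories place two axis charges whose magnitudes are
solved in closed form so the axial field *equals* the schedule; umbrella
windows are drawn exactly from the biased Boltzmann density by inverse-CDF
(no Markov chain, hence no autocorrelation or burn-in confounds); and the
toy active site is a minimal fixed-column PDB with a catalytic triad to
exercise selection bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .committor import ModelPotential
from .constants import COULOMB_FIELD_MV_CM, R_KCAL
from .efield import ReactionAxis
from .errors import InfeasibleScheduleError
from .structures_io import AtomRecord, ChargedFrame, WindowSeries
from .wham import BiasSpec, UmbrellaWindow

__all__ = [
    "GeneratorSpec",
    "FieldSchedule",
    "FieldRecord",
    "ToyActiveSite",
    "DEFAULT_AXIS",
    "gen_point_charges",
    "gen_prescribed_field_traj",
    "gaussian_field_schedule",
    "sample_umbrella_windows",
    "gen_toy_active_site",
]

#: default synthetic axis: tail atom of residue 1, head atom of residue 2,
#: 1 angstrom apart along +x, midpoint at the origin
DEFAULT_AXIS = ReactionAxis((1, "T"), (2, "H"), label="T–H")
_TAIL_POS = np.array([-0.5, 0.0, 0.0])
_HEAD_POS = np.array([0.5, 0.0, 0.0])


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs shared by the generators; the seed is part of every output."""

    seed: int = 0
    n_charges: int = 50
    n_decoys: int = 0
    box_size: float = 20.0          # A, cube side for random charges
    min_probe_distance: float = 2.0  # A, exclusion sphere around the probe
    charge_scale: float = 1.0        # e, charges drawn uniform in +-scale
    pair_distance: float = 3.0       # A, axis-charge offset for schedules
    dt: float = 0.001                # ps between frames / samples

    def __post_init__(self):
        if self.n_charges < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        if min(self.box_size, self.min_probe_distance, self.pair_distance, self.dt) <= 0:
            raise ValueError("geometry and time parameters must be positive")


@dataclass(frozen=True)
class FieldSchedule:
    """Per-frame target axial field (MV/cm) along a reaction axis."""

    values: np.ndarray
    axis: ReactionAxis = DEFAULT_AXIS

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scheduled fields must be finite")


@dataclass(frozen=True)
class FieldRecord:
    """Companion analytic field for a generated frame (MV/cm)."""

    field_vector: np.ndarray
    axial_component: float


def _axis_atoms(axis: ReactionAxis) -> list[AtomRecord]:
    return [
        AtomRecord(1, axis.tail_atom[1], "AXS", axis.tail_atom[0], _TAIL_POS.copy(), 0.0),
        AtomRecord(2, axis.head_atom[1], "AXS", axis.head_atom[0], _HEAD_POS.copy(), 0.0),
    ]


def _brute_force_field(positions, charges, probe) -> FieldRecord:
    # deliberately scalar double-loop arithmetic: the independent oracle
    ex = ey = ez = 0.0
    for (px, py, pz), q in zip(positions, charges):
        dx, dy, dz = probe[0] - px, probe[1] - py, probe[2] - pz
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        s = COULOMB_FIELD_MV_CM * q / (r * r * r)
        ex += s * dx
        ey += s * dy
        ez += s * dz
    u = _HEAD_POS - _TAIL_POS
    u = u / np.linalg.norm(u)
    vec = np.array([ex, ey, ez])
    return FieldRecord(field_vector=vec, axial_component=float(vec @ u))


def gen_point_charges(
    spec: GeneratorSpec,
    axis: ReactionAxis = DEFAULT_AXIS,
) -> tuple[ChargedFrame, FieldRecord]:
    """Random point charges in a box, plus their brute-force field record.

    Charges are uniform in the box but excluded from a sphere of
    ``min_probe_distance`` around the probe (the axis midpoint at the
    origin); the companion record is computed by the plain double loop, not
    by the efield module, so the two routes stay independent.
    """
    rng = np.random.default_rng(spec.seed)
    probe = 0.5 * (_TAIL_POS + _HEAD_POS)
    positions, charges = [], []
    half = spec.box_size / 2.0
    while len(positions) < spec.n_charges:
        p = rng.uniform(-half, half, size=3)
        if np.linalg.norm(p - probe) < spec.min_probe_distance:
            continue
        positions.append(p)
        charges.append(rng.uniform(-spec.charge_scale, spec.charge_scale))

    atoms = _axis_atoms(axis)
    for i, (p, q) in enumerate(zip(positions, charges)):
        atoms.append(AtomRecord(3 + i, "Q", "CHG", 10 + i, p, float(q)))
    frame = ChargedFrame(atoms=atoms, frame_time=0.0)
    return frame, _brute_force_field(positions, charges, probe)


def gaussian_field_schedule(
    mean: float, sd: float, n: int, seed: int = 0, axis: ReactionAxis = DEFAULT_AXIS
) -> FieldSchedule:
    """Gaussian axial-field schedule — the model for a state's field samples."""
    rng = np.random.default_rng(seed)
    return FieldSchedule(values=rng.normal(mean, sd, size=n), axis=axis)


def gen_prescribed_field_traj(
    schedule: FieldSchedule,
    spec: GeneratorSpec = GeneratorSpec(),
) -> list[ChargedFrame]:
    """Frames whose axial field at the probe equals the schedule exactly.

    Two charges sit on the axis line at ±pair_distance from the midpoint
    with magnitudes solved in closed form: a charge q at −d contributes
    +K q / d² to the axial field and its mirror −q at +d contributes the
    same, so q = F d² / (2 K).  Optional decoy charges are placed in the
    perpendicular plane through the probe and contribute exactly zero
    axial field by geometry.
    """
    d = spec.pair_distance
    rng = np.random.default_rng(spec.seed)
    u = (_HEAD_POS - _TAIL_POS) / np.linalg.norm(_HEAD_POS - _TAIL_POS)
    probe = 0.5 * (_TAIL_POS + _HEAD_POS)
    frames = []
    for i, f_target in enumerate(np.atleast_1d(schedule.values)):
        q = f_target * d * d / (2.0 * COULOMB_FIELD_MV_CM)
        if abs(q) > 10.0:
            raise InfeasibleScheduleError(
                f"frame {i}: field {f_target:.1f} MV/cm needs |q| = {abs(q):.2f} e "
                f"> 10 e at pair distance {d} A"
            )
        atoms = _axis_atoms(schedule.axis)
        atoms.append(AtomRecord(3, "QT", "FLD", 100, probe - d * u, float(q)))
        atoms.append(AtomRecord(4, "QH", "FLD", 101, probe + d * u, float(-q)))
        # decoys: perpendicular plane through the probe -> zero axial field
        for k in range(spec.n_decoys):
            theta = rng.uniform(0, 2 * math.pi)
            radius = rng.uniform(2.0, 5.0)
            offset = radius * (math.cos(theta) * np.array([0.0, 1.0, 0.0])
                               + math.sin(theta) * np.array([0.0, 0.0, 1.0]))
            atoms.append(
                AtomRecord(5 + k, "QD", "DCY", 200 + k, probe + offset,
                           float(rng.uniform(-1, 1)))
            )
        frames.append(ChargedFrame(atoms=atoms, frame_time=i * spec.dt))
    return frames


def sample_umbrella_windows(
    potential,
    biases: Sequence[BiasSpec],
    temperature: float,
    n_samples: int,
    spec: GeneratorSpec = GeneratorSpec(),
    support: tuple[float, float] | None = None,
    stratified: bool = False,
) -> list[UmbrellaWindow]:
    """Exact Boltzmann samples from each biased density by inverse-CDF.

    ``potential`` is a ModelPotential or a callable V(x) in kcal/mol.  The
    biased density exp(-(V + U_bias)/RT) is tabulated on a 10^4-point grid
    over ``support`` and sampled through its inverse CDF — either at i.i.d.
    uniforms (default) or at stratified uniforms (``stratified=True``),
    which pins the empirical histogram to the density and leaves estimator
    error, not sampling noise, as the only deviation downstream.
    """
    v = potential.energy if isinstance(potential, ModelPotential) else potential
    rt = R_KCAL * temperature
    if support is None:
        centers = [b.center for b in biases]
        support = (min(centers) - 5.0, max(centers) + 5.0)
    x = np.linspace(support[0], support[1], 10_001)
    vx = np.asarray(v(x), dtype=float)

    seeds = np.random.SeedSequence(spec.seed).spawn(len(biases))
    windows = []
    for bias, ss in zip(biases, seeds):
        logw = -(vx + bias.energy(x)) / rt
        logw -= logw.max()
        pdf = np.exp(logw)
        if max(pdf[0], pdf[-1]) > 1e-6:
            raise ValueError(
                f"biased density (center {bias.center}) is not negligible at the "
                "support edges; widen the support or add a confining bias"
            )
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(x))])
        cdf /= cdf[-1]
        rng = np.random.default_rng(ss)
        if stratified:
            u = (np.arange(n_samples) + 0.5) / n_samples
            rng.shuffle(u)
        else:
            u = rng.random(n_samples)
        samples = np.interp(u, cdf, x)
        series = WindowSeries(times=spec.dt * np.arange(1, n_samples + 1), values=samples)
        windows.append(UmbrellaWindow(bias=bias, series=series))
    return windows


# ---------------------------------------------------------------------------
# toy active site
# ---------------------------------------------------------------------------

#: backbone-style partial charges used for every toy residue
_TOY_CHARGES = {"N": -0.4157, "CA": 0.0337, "C": 0.5973, "O": -0.5679}

_TOY_RESIDUES = [
    (95, "ALA"), (120, "GLY"), (165, "SER"), (180, "VAL"),
    (210, "ASP"), (230, "LEU"), (242, "HIS"), (260, "THR"),
]


@dataclass(frozen=True)
class ToyActiveSite:
    pdb_text: str
    charge_table: dict
    triad_ids: tuple[int, int, int]
    axis: ReactionAxis
    seed: int


def gen_toy_active_site(spec: GeneratorSpec = GeneratorSpec()) -> ToyActiveSite:
    """An 8-residue mini-protein PDB with a Ser/His/Asp-style triad.

    Residues 165 (SER), 242 (HIS) and 210 (ASP) play the catalytic triad;
    the suggested reaction axis runs between the CA atoms of residues 165
    and 242.  Output is byte-identical for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    lines = []
    serial = 1
    for slot, (rid, resn) in enumerate(_TOY_RESIDUES):
        base = np.array([6.0 * (slot % 4), 6.0 * (slot // 4), 0.0])
        for aname in ("N", "CA", "C", "O"):
            pos = base + rng.uniform(-1.5, 1.5, size=3)
            lines.append(
                f"ATOM  {serial:>5d}  {aname:<4s}{resn:>3s} A{rid:>4d}    "
                f"{pos[0]:>8.3f}{pos[1]:>8.3f}{pos[2]:>8.3f}{1.00:>6.2f}{0.00:>6.2f}"
                f"          {aname[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    charge_table = {
        (resn, aname): q
        for _, resn in _TOY_RESIDUES
        for aname, q in _TOY_CHARGES.items()
    }
    return ToyActiveSite(
        pdb_text="\n".join(lines) + "\n",
        charge_table=charge_table,
        triad_ids=(165, 210, 242),
        axis=ReactionAxis((165, "CA"), (242, "CA"), label="SER165:CA–HIS242:CA"),
        seed=spec.seed,
    )
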