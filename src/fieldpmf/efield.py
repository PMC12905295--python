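"""Internal electric fields projected along reaction axes.

The protein scaffold's partial charges generate an electrostatic field at
the active site.  Here that field is evaluated by a bare Coulomb sum (no
cutoff, no periodic images) at the midpoint of a *reaction axis* — an
ordered atom pair such as N1–H1 — and projected onto the axis unit vector,
which points tail→head.  Negative axial values therefore mean the field
opposes the named direction.  Results are in MV/cm, the unit in which
enzyme internal fields are conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import COULOMB_FIELD_MV_CM
from .errors import (
    DegenerateAxisError,
    InsufficientDataError,
    SingularityError,
    UndefinedCorrelationError,
)
from .structures_io import ChargedFrame, Selection, resolve_selection

__all__ = [
    "ReactionAxis",
    "FieldSample",
    "FieldStatistics",
    "axial_field",
    "window_field_statistics",
    "field_correlation",
]

#: minimum probe–charge separation before the bare Coulomb sum is refused
_SINGULARITY_ANGSTROM = 1e-6


@dataclass(frozen=True)
class ReactionAxis:
    """Ordered atom pair defining a projection direction and probe midpoint.

    The unit vector runs from ``tail_atom`` to ``head_atom`` in the order
    the axis is named ("O1–C1" means O1→C1); the field probe sits at the
    instantaneous midpoint of the two atoms.
    """

    tail_atom: tuple[int, str]
    head_atom: tuple[int, str]
    label: str = ""

    def __post_init__(self):
        if tuple(self.tail_atom) == tuple(self.head_atom):
            raise DegenerateAxisError(f"axis {self.label!r}: tail equals head")

    def reversed(self) -> "ReactionAxis":
        lbl = "–".join(reversed(self.label.split("–"))) if "–" in self.label else self.label
        return ReactionAxis(self.head_atom, self.tail_atom, lbl)


@dataclass(frozen=True)
class FieldSample:
    """Field vector and its axial projection at one frame (MV/cm)."""

    frame_time: float
    field_vector: np.ndarray
    axial_component: float


@dataclass(frozen=True)
class FieldStatistics:
    """Mean ± sample s.d. of the axial field over a window tail (MV/cm)."""

    mean: float
    std: float
    n_samples: int
    discarded_fraction: float


def axial_field(
    frame: ChargedFrame,
    axis: ReactionAxis,
    environment: Selection,
) -> FieldSample:
    """Coulomb field at the axis midpoint, projected onto the axis.

    The field is ``K * sum_i q_i (r0 - r_i)/|r0 - r_i|^3`` with r0 the
    midpoint of the axis atoms, charges in elementary units, distances in
    angstrom, and K the single conversion constant to MV/cm
    (1439.9645... for a unit charge at 1 angstrom).  The axis atoms are
    always excluded from the sum regardless of ``environment``.
    """
    i_tail = frame.index_of(axis.tail_atom)
    i_head = frame.index_of(axis.head_atom)
    pos = frame.positions
    r_tail, r_head = pos[i_tail], pos[i_head]
    bond = r_head - r_tail
    norm = np.linalg.norm(bond)
    if norm < _SINGULARITY_ANGSTROM:
        raise DegenerateAxisError(f"axis {axis.label!r}: atoms coincident")
    u = bond / norm
    r0 = 0.5 * (r_tail + r_head)

    idx = [i for i in resolve_selection(frame, environment) if i not in (i_tail, i_head)]
    if not idx:
        vec = np.zeros(3)
        return FieldSample(frame.frame_time, vec, 0.0)

    q = frame.charges[idx]
    d = r0 - pos[idx]  # (n, 3)
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < _SINGULARITY_ANGSTROM):
        j = idx[int(np.argmin(dist))]
        a = frame.atoms[j]
        raise SingularityError(
            f"environment atom {a.residue_name}{a.residue_id}:{a.atom_name} "
            f"lies on the probe point"
        )
    vec = COULOMB_FIELD_MV_CM * np.sum(q[:, None] * d / dist[:, None] ** 3, axis=0)
    return FieldSample(frame.frame_time, vec, float(vec @ u))


def window_field_statistics(
    series: Sequence[FieldSample],
    discard_fraction: float = 0.5,
) -> FieldStatistics:
    """Mean and (n−1) s.d. of the axial field over the retained window tail.

    The leading ``discard_fraction`` of a time-ordered sample series is
    treated as equilibration and dropped (the conventional "last half of
    the window" rule for 30-ps umbrella windows).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n_skip = int(np.floor(discard_fraction * len(series)))
    tail = [s.axial_component for s in series[n_skip:]]
    if len(tail) < 2:
        raise InsufficientDataError(
            f"only {len(tail)} samples retained after discarding {discard_fraction:.0%}"
        )
    arr = np.asarray(tail, dtype=float)
    return FieldStatistics(
        mean=float(arr.mean()),
        std=0.0 if np.ptp(arr) == 0.0 else float(arr.std(ddof=1)),
        n_samples=len(arr),
        discarded_fraction=n_skip / len(series),
    )


def field_correlation(
    per_axis_series: Mapping[str, Sequence[float]],
) -> "pd.DataFrame":
    """Pearson correlation matrix between axial-field series on a common grid.

    A plain linear-correlation summary of how the fields along different
    reaction axes co-fluctuate.  Constant series are refused (undefined r).
    """
    import pandas as pd

    labels = list(per_axis_series)
    if len(labels) < 2:
        raise InsufficientDataError("need at least 2 axes to correlate")
    arrs = [np.asarray(per_axis_series[k], dtype=float) for k in labels]
    n = len(arrs[0])
    if n < 3 or any(len(a) != n for a in arrs):
        raise InsufficientDataError("series must share a common length >= 3")
    for k, a in zip(labels, arrs):
        if np.ptp(a) == 0.0:
            raise UndefinedCorrelationError(f"series {k!r} is constant")
    mat = np.corrcoef(np.vstack(arrs))
    return pd.DataFrame(mat, index=labels, columns=labels)
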