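"""Stark response of reaction states and the static/dynamic barrier split.

Each stationary state (reactant complex, transition state, intermediate…)
responds to an axial electric field F through

    E(F) = e0 - mu * c * F - (1/2) * alpha * c * F^2

with mu an axial dipole-difference coefficient in debye, alpha an axial
polarizability coefficient (D per MV/cm), and c the conversion from
D·(MV/cm) to kcal/mol (~0.048).  A dipole parallel to a positive field is
stabilising (negative energy), matching the tail→head positive-direction
convention of the efield module.

Because the mean axial field can differ between the reactant state and the
transition state, the field's effect on the barrier splits into

* a *static* part — both states evaluated at the reactant-state field; and
* a *dynamic extra* — the additional (de)stabilisation of the transition
  state from feeling its own, shifted field.

The two parts sum exactly to the total barrier modulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEBYE_MVCM_TO_KCAL
from .errors import FitError

__all__ = [
    "StateStarkModel",
    "StarkFit",
    "BarrierModulation",
    "fit_stark_model",
    "decompose_dynamic_shift",
    "barrier_vs_field_curve",
]


@dataclass(frozen=True)
class StateStarkModel:
    """Field response of one state: zero-field energy, dipole, polarizability."""

    label: str
    e0: float            # kcal/mol, relative scale
    mu: float            # D
    alpha: float = 0.0   # D per (MV/cm)

    def energy(self, f) -> float | np.ndarray:
        """State energy (kcal/mol) under axial field ``f`` (MV/cm)."""
        c = DEBYE_MVCM_TO_KCAL
        f = np.asarray(f, dtype=float)
        e = self.e0 - self.mu * c * f - 0.5 * self.alpha * c * f * f
        return float(e) if e.ndim == 0 else e


@dataclass(frozen=True)
class StarkFit:
    """A fitted StateStarkModel plus residual RMS and parameter sigmas."""

    model: StateStarkModel
    residual_rms: float
    param_std: tuple[float, ...]   # (e0, mu[, alpha]) one-sigma estimates


@dataclass(frozen=True)
class BarrierModulation:
    """Barrier change under a field, split into static + dynamic parts.

    Negative values mean the field *lowers* the barrier.  ``total`` equals
    ``static_part + dynamic_extra`` identically.
    """

    total: float
    static_part: float
    dynamic_extra: float
    f_reactant: float
    f_ts: float


def fit_stark_model(
    field_energy_table: Sequence[tuple[float, float]],
    order: int = 1,
    label: str = "",
) -> StarkFit:
    """Least-squares fit of (e0, mu[, alpha]) to a field–energy scan table.

    ``field_energy_table`` rows are (F in MV/cm, E in kcal/mol).  With
    exactly order+1 distinct points the fit interpolates; duplicated field
    values (rank deficiency) raise FitError.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    tab = np.asarray(field_energy_table, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise ValueError("table must be a sequence of (field, energy) pairs")
    f, e = tab[:, 0], tab[:, 1]
    n_params = order + 1
    if len(np.unique(f)) < n_params:
        raise FitError(
            f"need >= {n_params} distinct field values for an order-{order} fit, "
            f"got {len(np.unique(f))}"
        )
    c = DEBYE_MVCM_TO_KCAL
    cols = [np.ones_like(f), -c * f]
    if order == 2:
        cols.append(-0.5 * c * f * f)
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, e, rcond=None)
    if rank < n_params:
        raise FitError("rank-deficient Stark design matrix")
    resid = e - X @ beta
    dof = max(len(f) - n_params, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    model = StateStarkModel(
        label=label,
        e0=float(beta[0]),
        mu=float(beta[1]),
        alpha=float(beta[2]) if order == 2 else 0.0,
    )
    return StarkFit(
        model=model,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        param_std=tuple(np.sqrt(np.diag(cov))),
    )


def decompose_dynamic_shift(
    rc: StateStarkModel,
    ts: StateStarkModel,
    f_reactant: float,
    f_ts: float,
) -> BarrierModulation:
    """Split the field-induced barrier change into static + dynamic parts.

    static_part: barrier change if both states felt the reactant-state
    field.  dynamic_extra: the additional change because the transition
    state feels its own field ``f_ts`` instead.  total = static + dynamic.
    """
    static = (ts.energy(f_reactant) - rc.energy(f_reactant)) - (ts.energy(0.0) - rc.energy(0.0))
    dynamic = ts.energy(f_ts) - ts.energy(f_reactant)
    total = (ts.energy(f_ts) - rc.energy(f_reactant)) - (ts.energy(0.0) - rc.energy(0.0))
    return BarrierModulation(
        total=float(total),
        static_part=float(static),
        dynamic_extra=float(dynamic),
        f_reactant=float(f_reactant),
        f_ts=float(f_ts),
    )


def barrier_vs_field_curve(
    rc: StateStarkModel,
    ts: StateStarkModel,
    field_grid: Sequence[float],
) -> list[tuple[float, float]]:
    """Barrier change vs uniform field, same field applied to both states.

    Returns (F, dG‡(F) − dG‡(0)) pairs — the semantics of a barrier-vs-OEEF
    sweep where one external field acts on reactant and transition state
    alike.
    """
    grid = np.asarray(field_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("field grid must be nonempty")
    d0 = ts.energy(0.0) - rc.energy(0.0)
    dg = (ts.energy(grid) - rc.energy(grid)) - d0
    return [(float(f), float(v)) for f, v in zip(grid, np.atleast_1d(dg))]
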