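"""Joint parent-metabolite compartmental model for olanzapine and DMO.

The structural model is a pair of linked two-compartment mammillary systems:
olanzapine (parent) with first-order absorption from an oral depot, and
4'-N-desmethylolanzapine (DMO, the CYP1A2-formed metabolite) with its own
central/peripheral compartments.  Presystemic (first-pass) metabolite
formation is represented by splitting the systemically available fraction of
an oral dose between a parent depot and a metabolite depot; systemic
conversion is a unidirectional first-order mass transfer from the parent
central compartment to the metabolite central compartment at rate ``k_pm``.

All amounts are per body mass (ng/kg), volumes in L/kg, clearances in
L/h/kg, times in hours; concentrations are reported in ng/mL.  Total parent
plasma clearance ``CL`` includes the conversion route, so the partial
metabolic clearance to DMO is ``V1 * k_pm <= CL`` and the remaining
elimination proceeds at rate ``CL/V1 - k_pm``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "PKParameters",
    "DoseEvent",
    "DoseArm",
    "StateVector",
    "derived_parameters",
    "rhs",
    "apply_dose",
    "solve",
    "solve_amounts",
    "PKModelError",
    "IntegrationError",
]

NG_PER_MG = 1.0e6
ML_PER_L = 1.0e3

# state indices
DEPOT_P, CENT_P, PERI_P, DEPOT_M, CENT_M, PERI_M, ELIM_P, ELIM_M = range(8)
N_STATES = 8


class PKModelError(ValueError):
    """Invalid parameters or dosing."""


class IntegrationError(RuntimeError):
    """Numerical integration failed; carries the offending parameter set."""

    def __init__(self, message: str, params: "PKParameters"):
        super().__init__(f"{message} (parameters: {params.to_dict()})")
        self.params = params


@dataclass(frozen=True)
class PKParameters:
    """Structural parameter vector for one group (or one simulated animal).

    Attributes
    ----------
    ka, ka_dmo : first-order absorption rate constants (1/h) for parent and
        presystemically formed metabolite.
    V1, V2, Q, CL : parent central/peripheral volumes (L/kg),
        intercompartmental clearance and total plasma clearance (L/h/kg).
    V1_dmo, V2_dmo, Q_dmo, CL_dmo : same for the metabolite.
    k_pm : first-order parent->metabolite conversion rate constant (1/h).
    F_po_total : fraction of the oral dose systemically available as either
        parent or metabolite (F_po,O+DMO).
    F_d : fraction of the absorbed dose absorbed as parent.
    molar_mass_correction : if True, scale the k_pm mass transfer by the
        metabolite/parent molar-mass ratio (298.4/312.4).  Off by default:
        both compounds are assayed in mass units and the correction is a
        refinement, not part of the reference analysis.
    """

    ka: float
    ka_dmo: float
    V1: float
    V2: float
    Q: float
    CL: float
    V1_dmo: float
    V2_dmo: float
    Q_dmo: float
    CL_dmo: float
    k_pm: float
    F_po_total: float
    F_d: float
    molar_mass_correction: bool = False

    _POSITIVE = ("ka", "ka_dmo", "V1", "V2", "CL",
                 "V1_dmo", "V2_dmo", "CL_dmo")
    # zero disables distribution or conversion (one-compartment and
    # no-metabolite limits are legitimate reduced models)
    _NONNEGATIVE = ("Q", "Q_dmo", "k_pm")
    _FRACTIONS = ("F_po_total", "F_d")

    def __post_init__(self):
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not (v > 0) or not np.isfinite(v):
                raise PKModelError(f"{name} must be strictly positive, got {v!r}")
        for name in self._NONNEGATIVE:
            v = getattr(self, name)
            if not (v >= 0) or not np.isfinite(v):
                raise PKModelError(f"{name} must be nonnegative, got {v!r}")
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PKModelError(f"{name} must lie in [0, 1], got {v!r}")
        if self.k_pm > self.CL / self.V1 * (1 + 1e-12):
            raise PKModelError(
                "k_pm exceeds CL/V1: conversion is a component of total parent "
                f"elimination (k_pm={self.k_pm}, CL/V1={self.CL / self.V1})"
            )

    @property
    def mass_ratio(self) -> float:
        """Metabolite/parent molar-mass ratio applied to the k_pm transfer."""
        return 298.4 / 312.4 if self.molar_mass_correction else 1.0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PKParameters":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PKParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def with_(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)


class DoseArm(str, enum.Enum):
    PO_PARENT = "PO_parent"
    IV_PARENT = "IV_parent"
    IV_METABOLITE = "IV_metabolite"


@dataclass(frozen=True)
class DoseEvent:
    """A single bolus dose: `dose` in mg/kg administered at `time` (h)."""

    arm: DoseArm
    dose: float
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "arm", DoseArm(self.arm))
        if not self.dose > 0:
            raise PKModelError(f"dose must be > 0, got {self.dose!r}")
        if self.time < 0:
            raise PKModelError(f"dose time must be >= 0, got {self.time!r}")


@dataclass
class StateVector:
    """Amounts (ng/kg) in the six model compartments plus elimination ledgers."""

    depot_parent: float = 0.0
    central_parent: float = 0.0
    peripheral_parent: float = 0.0
    depot_metabolite: float = 0.0
    central_metabolite: float = 0.0
    peripheral_metabolite: float = 0.0
    cumulative_eliminated_parent: float = 0.0
    cumulative_eliminated_metabolite: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([
            self.depot_parent, self.central_parent, self.peripheral_parent,
            self.depot_metabolite, self.central_metabolite,
            self.peripheral_metabolite,
            self.cumulative_eliminated_parent,
            self.cumulative_eliminated_metabolite,
        ])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*map(float, y))

    def total(self) -> float:
        """Total mass on both ledgers (conserved between dose events)."""
        return float(np.sum(self.as_array()))


def derived_parameters(p: PKParameters) -> dict:
    """Derived exposure quantities.

    F_po -- absolute oral bioavailability of parent, F_po_total * F_d.
    F_po_dmo -- fraction of the oral dose systemically available as
        presystemically formed metabolite, F_po_total * (1 - F_d).
    CL_parent_to_dmo -- partial metabolic clearance to DMO, V1 * k_pm.
    fm -- fraction of systemic parent elimination routed through the
        metabolite, (V1 * k_pm) / CL.
    """
    return {
        "F_po": p.F_po_total * p.F_d,
        "F_po_dmo": p.F_po_total * (1.0 - p.F_d),
        "CL_parent_to_dmo": p.V1 * p.k_pm,
        "fm": p.V1 * p.k_pm / p.CL,
    }


def system_matrix(p: PKParameters) -> np.ndarray:
    """The 8x8 linear system matrix (amount space, includes elimination rows)."""
    A = np.zeros((N_STATES, N_STATES))
    A[DEPOT_P, DEPOT_P] = -p.ka
    A[CENT_P, DEPOT_P] = p.ka
    A[CENT_P, CENT_P] = -(p.CL / p.V1) - (p.Q / p.V1)
    A[CENT_P, PERI_P] = p.Q / p.V2
    A[PERI_P, CENT_P] = p.Q / p.V1
    A[PERI_P, PERI_P] = -p.Q / p.V2

    A[DEPOT_M, DEPOT_M] = -p.ka_dmo
    A[CENT_M, DEPOT_M] = p.ka_dmo
    A[CENT_M, CENT_P] = p.k_pm * p.mass_ratio
    A[CENT_M, CENT_M] = -(p.CL_dmo / p.V1_dmo) - (p.Q_dmo / p.V1_dmo)
    A[CENT_M, PERI_M] = p.Q_dmo / p.V2_dmo
    A[PERI_M, CENT_M] = p.Q_dmo / p.V1_dmo
    A[PERI_M, PERI_M] = -p.Q_dmo / p.V2_dmo

    A[ELIM_P, CENT_P] = p.CL / p.V1 - p.k_pm
    A[ELIM_M, CENT_M] = p.CL_dmo / p.V1_dmo
    return A


def rhs(state, t, p: PKParameters) -> np.ndarray:
    """Time derivative of the amount state (t is unused: the system is LTI)."""
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    return system_matrix(p) @ y


def apply_dose(state, event: DoseEvent, p: PKParameters):
    """Add a bolus dose (mg/kg -> ng/kg) to the compartment its arm targets.

    Oral parent doses are split presystemically: F_po_total*F_d of the dose
    enters the parent depot and F_po_total*(1-F_d) the metabolite depot; the
    non-bioavailable remainder never enters the system.  IV doses enter the
    respective central compartment in full.
    """
    as_state = isinstance(state, StateVector)
    y = state.as_array().copy() if as_state else np.asarray(state, float).copy()
    amt = event.dose * NG_PER_MG
    if event.arm is DoseArm.PO_PARENT:
        y[DEPOT_P] += amt * p.F_po_total * p.F_d
        y[DEPOT_M] += amt * p.F_po_total * (1.0 - p.F_d)
    elif event.arm is DoseArm.IV_PARENT:
        y[CENT_P] += amt
    elif event.arm is DoseArm.IV_METABOLITE:
        y[CENT_M] += amt
    else:  # pragma: no cover - enum is closed
        raise PKModelError(f"unknown dosing arm {event.arm!r}")
    return StateVector.from_array(y) if as_state else y


def _eig_propagate(A, y0, times):
    """Spectral solution y(t) = V exp(L t) V^-1 y0 for all times at once.

    Returns None when the eigenbasis is ill-conditioned (nearly defective
    system, e.g. coincident rate constants) so the caller can fall back to a
    stiff ODE integrator.
    """
    lam, V = np.linalg.eig(A)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e10:
        return None
    c = np.linalg.solve(V, y0.astype(complex))
    out = (V @ (np.exp(np.outer(lam, times)) * c[:, None])).real
    return out  # shape (n_states, n_times)


def solve_amounts(p: PKParameters, doses, times, method: str = "auto") -> np.ndarray:
    """Solve the amount system; returns array (n_times, 8) in ng/kg.

    `times` must be sorted and nonnegative.  Doses are bolus events; the
    system is linear time-invariant between events, so the default path
    propagates analytically through the eigendecomposition of the system
    matrix and superposes dose segments.  ``method='ivp'`` forces an
    adaptive stiff integrator (LSODA, rtol 1e-10).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise PKModelError("times must be one-dimensional")
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise PKModelError("times must be sorted and nonnegative")
    doses = list(doses)
    if not doses:
        return np.zeros((times.size, N_STATES))
    A = system_matrix(p)
    out = np.zeros((N_STATES, times.size))
    # superposition over dose events (linear system)
    for ev in doses:
        bolus = apply_dose(np.zeros(N_STATES), ev, p)
        after = times >= ev.time
        tau = times[after] - ev.time
        if tau.size == 0:
            continue
        seg = None
        if method in ("auto", "eig"):
            seg = _eig_propagate(A, bolus, tau)
            if seg is None and method == "eig":
                raise IntegrationError("eigendecomposition path unusable", p)
            if seg is None:
                # nearly defective eigensystem (coincident rate constants):
                # the matrix exponential is exact and unconditionally stable
                seg = np.column_stack([expm(A * t) @ bolus for t in tau])
        else:
            seg = _ivp_propagate(A, bolus, tau, p)
        # unidirectional coupling: a dose that puts nothing into the parent
        # subsystem can never produce parent amounts
        if bolus[DEPOT_P] == 0 and bolus[CENT_P] == 0 and bolus[PERI_P] == 0:
            seg[[DEPOT_P, CENT_P, PERI_P, ELIM_P], :] = 0.0
        out[:, after] += seg
    # amounts are nonnegative up to numerical noise; anything materially
    # negative signals an integration failure rather than roundoff
    scale = sum(ev.dose for ev in doses) * NG_PER_MG
    if np.any(out < -1e-6 * scale):
        raise IntegrationError("negative amounts beyond roundoff", p)
    np.clip(out, 0.0, None, out=out)
    return out.T


def _ivp_propagate(A, y0, tau, p):
    t_end = float(tau[-1]) if tau[-1] > 0 else 1.0
    sol = solve_ivp(
        lambda t, y: A @ y, (0.0, t_end), y0, t_eval=np.clip(tau, 0, t_end),
        method="LSODA", rtol=1e-10,
        atol=1e-10 * max(1.0, np.max(np.abs(y0))),
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}", p)
    return sol.y


def solve(p: PKParameters, doses, times, method: str = "auto") -> dict:
    """Plasma concentration curves (ng/mL) for parent and metabolite.

    Concentration = amount (ng/kg) / V_central (L/kg) / 1000 (mL/L) for the
    respective central compartment.
    """
    amounts = solve_amounts(p, doses, times, method=method)
    return {
        "time_h": np.asarray(times, dtype=float),
        "parent": amounts[:, CENT_P] / (p.V1 * ML_PER_L),
        "metabolite": amounts[:, CENT_M] / (p.V1_dmo * ML_PER_L),
    }


def auc_infinity(p: PKParameters, dose: DoseEvent) -> dict:
    """Closed-form AUC(0,inf) in h*ng/mL for parent and metabolite.

    For an IV parent bolus: AUC_parent = dose/CL and, by mass balance,
    AUC_metabolite = fm*dose/CL_dmo with fm = V1*k_pm/CL.  Oral doses scale
    by the bioavailable fractions of each depot.
    """
    amt = dose.dose * NG_PER_MG
    fm = p.V1 * p.k_pm / p.CL * p.mass_ratio
    if dose.arm is DoseArm.IV_PARENT:
        parent_in, met_in = amt, 0.0
    elif dose.arm is DoseArm.IV_METABOLITE:
        parent_in, met_in = 0.0, amt
    else:
        parent_in = amt * p.F_po_total * p.F_d
        met_in = amt * p.F_po_total * (1.0 - p.F_d)
    auc_parent = parent_in / p.CL / ML_PER_L
    auc_met = (fm * parent_in + met_in) / p.CL_dmo / ML_PER_L
    return {"parent": auc_parent, "metabolite": auc_met}
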