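"""Equilibrium-dialysis unbound fractions and brain-penetration ratios.

Rapid equilibrium dialysis (RED) pairs a plasma (or diluted brain
homogenate) chamber with a buffer chamber separated by a semipermeable
membrane; at equilibrium the buffer concentration equals the unbound
concentration in the matrix chamber.  The plasma unbound fraction is the
buffer/plasma concentration ratio.  Brain homogenate is assayed diluted, so
the measured free fraction must be corrected back to undiluted tissue:

    fu_brain = (1/D) / ((1/fu_diluted - 1) + 1/D)

with D the homogenate dilution factor.  Penetration ratios combine unbound
fractions with matrix AUCs:

    Kp_brain    = AUC_brain / AUC_plasma
    Kp_uu_brain = (fu_brain * AUC_brain) / (fu_plasma * AUC_plasma)

Kp,uu > 1 indicates net uptake into brain beyond passive equilibration.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

__all__ = [
    "MatrixKind",
    "DialysisMeasurement",
    "PenetrationResult",
    "fu_plasma",
    "fu_diluted",
    "fu_brain",
    "brain_penetration",
    "BindingError",
]

DEFAULT_BRAIN_DILUTION = 5.0


class BindingError(ValueError):
    pass


class MatrixKind(str, enum.Enum):
    PLASMA = "plasma"
    BRAIN_HOMOGENATE = "brain_homogenate"


@dataclass(frozen=True)
class DialysisMeasurement:
    """Paired chamber concentrations (ng/mL) from one RED well.

    ``dilution_factor`` is 1 for plasma and the homogenate fold-dilution
    (default 5, a typical RED brain protocol) for brain tissue.
    """

    c_buffer: float
    c_matrix: float
    kind: MatrixKind
    dilution_factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "kind", MatrixKind(self.kind))
        if self.c_buffer < 0 or self.c_matrix < 0:
            raise BindingError("chamber concentrations must be nonnegative")
        if self.dilution_factor < 1:
            raise BindingError("dilution factor must be >= 1")
        if self.kind is MatrixKind.PLASMA and self.dilution_factor != 1.0:
            raise BindingError("plasma measurements use dilution factor 1")
        if self.c_buffer > self.c_matrix:
            # binding systems cannot exceed unity at equilibrium; assay noise
            # can, and QC should see it
            warnings.warn(
                f"buffer chamber ({self.c_buffer}) exceeds matrix chamber "
                f"({self.c_matrix}); unbound fraction will exceed 1",
                stacklevel=2)


def _ratio(m: DialysisMeasurement) -> float:
    if m.c_matrix <= 0:
        raise BindingError("matrix-chamber concentration must be > 0")
    fu = m.c_buffer / m.c_matrix
    if fu > 1.0:
        warnings.warn(f"unbound fraction {fu:.3g} > 1 (assay noise); "
                      "reported as-is", stacklevel=3)
    return fu


def fu_plasma(m: DialysisMeasurement) -> float:
    """Plasma unbound fraction: c(buffer chamber) / c(plasma chamber)."""
    if m.kind is not MatrixKind.PLASMA:
        raise BindingError("fu_plasma requires a plasma measurement")
    return _ratio(m)


def fu_diluted(m: DialysisMeasurement) -> float:
    """Free fraction in the diluted brain homogenate (uncorrected)."""
    if m.kind is not MatrixKind.BRAIN_HOMOGENATE:
        raise BindingError("fu_diluted requires a brain-homogenate measurement")
    return _ratio(m)


def fu_brain(fu_dil: float, D: float = DEFAULT_BRAIN_DILUTION) -> float:
    """Correct a diluted-homogenate free fraction back to undiluted tissue.

    fu_brain = (1/D) / ((1/fu_dil - 1) + 1/D); the identity map when D = 1.
    """
    if not (0.0 < fu_dil <= 1.0):
        raise BindingError(f"fu_diluted must lie in (0, 1], got {fu_dil!r}")
    if D < 1:
        raise BindingError("dilution factor must be >= 1")
    return (1.0 / D) / ((1.0 / fu_dil - 1.0) + 1.0 / D)


def fu_diluted_from_brain(fu_b: float, D: float = DEFAULT_BRAIN_DILUTION) -> float:
    """Inverse of :func:`fu_brain` (used for round-trip checks)."""
    if not (0.0 < fu_b <= 1.0):
        raise BindingError(f"fu_brain must lie in (0, 1], got {fu_b!r}")
    return 1.0 / ((1.0 / fu_b - 1.0) / D + 1.0)


@dataclass(frozen=True)
class PenetrationResult:
    """Brain-penetration coefficients with the inputs that produced them."""

    kp_brain: float
    kp_uu_brain: float
    auc_brain: float
    auc_plasma: float
    fu_brain: float
    fu_plasma: float

    def __post_init__(self):
        expect = self.kp_brain * self.fu_brain / self.fu_plasma
        if abs(self.kp_uu_brain - expect) > 1e-12 * max(1.0, abs(expect)):
            raise BindingError("kp_uu_brain inconsistent with kp_brain * fu ratio")


def brain_penetration(auc_brain: float, auc_plasma: float,
                      fu_brain: float, fu_plasma: float) -> PenetrationResult:
    """Total and unbound brain-to-plasma partition coefficients.

    AUCs must share a time span; brain AUC in h*ng/g, plasma in h*ng/mL
    (the ratio treats 1 g tissue ~ 1 mL, the field's convention).
    """
    if auc_plasma <= 0:
        raise BindingError("plasma AUC must be > 0")
    if fu_plasma <= 0:
        raise BindingError("plasma unbound fraction must be > 0")
    if auc_brain < 0 or fu_brain < 0:
        raise BindingError("brain inputs must be nonnegative")
    kp = auc_brain / auc_plasma
    kp_uu = (fu_brain * auc_brain) / (fu_plasma * auc_plasma)
    return PenetrationResult(kp, kp_uu, auc_brain, auc_plasma, fu_brain, fu_plasma)
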