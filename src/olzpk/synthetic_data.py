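"""Synthetic endotoxemia PK studies with the trial's sparse-sampling design.

The generator emulates a two-group (LPS vs. saline control) mouse study
with three dosing arms per group:

* 4 mg/kg oral olanzapine, destructive sampling: 3 animals per schedule
  time over 12 times (predose 0 and 0.25-24 h), 2 samples per animal, the
  second at the animal's terminal (brain-harvest) time;
* 0.5 mg/kg IV olanzapine and 0.5 mg/kg IV DMO, serial sampling: 3 samples
  per animal over 11 times (3 min-6 h), the third terminal.

Between-animal variability is lognormal around the group median (fractions
on the logit scale), residual error is proportional with an optional
additive floor, and concentrations below the lower limit of quantification
are flagged.  Brain concentrations are generated proportional to the
animal's noise-free plasma curve with a configurable true partition ratio
(brain is not a structural model compartment), with independent residual
error.

Group-median parameter sets are fixtures: exposure-determining values match
published medians for this design (CL 2.84/1.85 L/h/kg, CL_O->DMO
0.26/0.135 L/h/kg, F_po 0.075/0.235, 1-F_d 0.26/0.14 for control/LPS);
volumes and rate constants are plausible mouse values documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .pk_model import DoseArm, DoseEvent, PKParameters, solve

__all__ = [
    "ArmDesign",
    "StudyDesign",
    "VariabilityModel",
    "CONTROL_MEDIANS",
    "LPS_MEDIANS",
    "default_design",
    "default_group_medians",
    "sample_individual_parameters",
    "simulate_study",
    "simulate_dialysis",
    "simulate_ct_table",
    "destructive_assignment",
    "serial_assignment",
    "DesignError",
]


class DesignError(ValueError):
    pass


# -- fixture group medians ---------------------------------------------------
# CL, k_pm (= CL_O->DMO / V1), F_po_total (= F_po / F_d) and F_d reproduce
# the published group medians; CL_dmo reproduces the published -79% LPS
# attenuation of metabolite clearance; volumes/rates are fixtures.
CONTROL_MEDIANS = PKParameters(
    ka=1.0, ka_dmo=1.0, V1=2.0, V2=4.0, Q=2.0, CL=2.84,
    V1_dmo=2.0, V2_dmo=3.0, Q_dmo=1.0, CL_dmo=0.60,
    k_pm=0.13, F_po_total=0.101, F_d=0.74,
)
LPS_MEDIANS = PKParameters(
    ka=1.0, ka_dmo=1.0, V1=2.0, V2=4.0, Q=2.0, CL=1.85,
    V1_dmo=2.0, V2_dmo=3.0, Q_dmo=1.0, CL_dmo=0.126,
    k_pm=0.0675, F_po_total=0.273, F_d=0.86,
)

PO_SCHEDULE = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 24.0)
IV_SCHEDULE = (0.05, 1 / 12, 1 / 6, 1 / 3, 2 / 3, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)


@dataclass(frozen=True)
class ArmDesign:
    """One dosing arm: dose, schedule and sampling mode.

    ``destructive``: animals are assigned a terminal time plus (optionally)
    one earlier sample, with equal per-time coverage.  ``serial``: each
    animal is assigned ``samples_per_animal`` consecutive schedule times
    (cyclically), the last being terminal.
    """

    name: str
    dose: DoseEvent
    schedule: tuple
    n_animals: int
    mode: str  # "destructive" | "serial"
    samples_per_animal: int

    def __post_init__(self):
        if self.mode not in ("destructive", "serial"):
            raise DesignError(f"unknown sampling mode {self.mode!r}")
        if self.samples_per_animal < 1:
            raise DesignError("samples_per_animal must be >= 1")
        if len(set(self.schedule)) != len(self.schedule):
            raise DesignError("schedule times must be distinct")


@dataclass(frozen=True)
class StudyDesign:
    """Full study layout: groups, arms, LLOQs and true brain partition."""

    groups: tuple = ("control", "LPS")
    arms: tuple = ()
    lloq_plasma: float = 0.1   # ng/mL
    lloq_brain: float = 0.2    # ng/g (published detection limit)
    brain_partition: dict = field(
        default_factory=lambda: {"parent": 6.0, "metabolite": 0.05})


@dataclass(frozen=True)
class VariabilityModel:
    """Between-animal and residual variability.

    ``bsv_cv`` is the lognormal coefficient of variation applied to every
    positive parameter (fractions use the same value as an SD on the logit
    scale); ``residual_cv`` is the proportional assay-error CV;
    ``additive_sd`` an optional additive error floor in ng/mL (ng/g).
    """

    bsv_cv: float = 0.3
    residual_cv: float = 0.15
    additive_sd: float = 0.0

    def __post_init__(self):
        if self.bsv_cv < 0 or self.residual_cv < 0 or self.additive_sd < 0:
            raise DesignError("variability magnitudes must be >= 0")


def default_design() -> StudyDesign:
    """The trial layout: 18 animals/group PO, 10/group per IV arm."""
    arms = (
        ArmDesign("PO_olanzapine", DoseEvent(DoseArm.PO_PARENT, 4.0),
                  PO_SCHEDULE, 18, "destructive", 2),
        ArmDesign("IV_olanzapine", DoseEvent(DoseArm.IV_PARENT, 0.5),
                  IV_SCHEDULE, 10, "serial", 3),
        ArmDesign("IV_DMO", DoseEvent(DoseArm.IV_METABOLITE, 0.5),
                  IV_SCHEDULE, 10, "serial", 3),
    )
    return StudyDesign(arms=arms)


def default_group_medians() -> dict:
    return {"control": CONTROL_MEDIANS, "LPS": LPS_MEDIANS}


# -- schedule assignment -----------------------------------------------------

def destructive_assignment(schedule, n_animals: int, samples_per_animal: int):
    """Deterministic destructive assignment with equal per-time coverage.

    Returns a list of per-animal sorted time tuples; the last entry of each
    is the animal's terminal time.  Total samples must be divisible by the
    number of schedule times.  With two samples per animal, the schedule is
    split in half and time j is paired with time j + J/2: every batch of
    animals shares a (pre-terminal, terminal) time pair, which is what lets
    the batch AUC estimator pool within-batch covariances across times.
    """
    times = sorted(schedule)
    total = n_animals * samples_per_animal
    if total % len(times):
        raise DesignError(
            f"{total} samples cannot cover {len(times)} times evenly")
    cap = total // len(times)
    if samples_per_animal == 1:
        out = []
        for t in times:
            out.extend([(t,)] * cap)
        return out
    if samples_per_animal != 2:
        raise DesignError("destructive mode supports 1 or 2 samples per animal")
    J = len(times)
    if J % 2:
        raise DesignError("paired destructive design needs an even number "
                          "of schedule times")
    assignments = []
    for j in range(J // 2):
        assignments.extend([(times[j], times[j + J // 2])] * cap)
    return assignments


def serial_assignment(schedule, n_animals: int, samples_per_animal: int):
    """Cyclic block assignment of consecutive schedule times.

    Animals are paired onto the same time triplet (animal pair m takes the
    block starting at index m*k mod J), so every sampling pattern is shared
    by two animals and the batch AUC estimator has within-pattern
    replication to pool.
    """
    times = sorted(schedule)
    J = len(times)
    if samples_per_animal > J:
        raise DesignError("more samples per animal than schedule times")
    out = []
    for i in range(n_animals):
        base = (i // 2) * samples_per_animal
        idx = [(base + j) % J for j in range(samples_per_animal)]
        out.append(tuple(sorted(times[k] for k in idx)))
    covered = {t for pat in out for t in pat}
    if covered != set(times):
        raise DesignError("serial assignment leaves schedule times uncovered; "
                          "increase n_animals or samples_per_animal")
    return out


def assign_schedule(arm: ArmDesign):
    if arm.mode == "destructive":
        return destructive_assignment(arm.schedule, arm.n_animals,
                                      arm.samples_per_animal)
    return serial_assignment(arm.schedule, arm.n_animals, arm.samples_per_animal)


# -- parameter sampling ------------------------------------------------------

_FRACTION_FIELDS = ("F_po_total", "F_d")


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def sample_individual_parameters(group_medians: PKParameters,
                                 v: VariabilityModel, n: int,
                                 rng) -> list:
    """Draw `n` individual parameter sets around the group medians.

    Positive parameters are lognormal with median preserved
    (sigma = sqrt(log(1 + cv^2))); fractions are normal on the logit scale
    with SD equal to the CV.  Draw order: animals outer, parameters inner in
    field declaration order.  `rng` is a seeded numpy Generator or an int.
    """
    if n < 1:
        raise DesignError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = float(np.sqrt(np.log1p(v.bsv_cv ** 2)))
    names = [f.name for f in fields(PKParameters) if f.type != "bool"]
    out = []
    for _ in range(n):
        d = group_medians.to_dict()
        for name in names:
            z = rng.standard_normal()
            if v.bsv_cv == 0:
                continue
            if name in _FRACTION_FIELDS:
                d[name] = float(_expit(_logit(d[name]) + v.bsv_cv * z))
            else:
                d[name] = float(d[name] * np.exp(sigma * z))
        # keep the conversion invariant k_pm <= CL/V1 under perturbation
        d["k_pm"] = min(d["k_pm"], 0.999 * d["CL"] / d["V1"])
        out.append(PKParameters.from_dict(d))
    return out


# -- study simulation --------------------------------------------------------

def _observe(true_conc, v: VariabilityModel, rng):
    eps = rng.standard_normal(np.shape(true_conc))
    obs = np.asarray(true_conc) * (1.0 + v.residual_cv * eps)
    if v.additive_sd > 0:
        obs = obs + v.additive_sd * rng.standard_normal(np.shape(true_conc))
    return np.clip(obs, 0.0, None)


def simulate_study(design: StudyDesign, group_medians: dict,
                   v: VariabilityModel, seed: int) -> pd.DataFrame:
    """Simulate one full study; returns the long-format record table.

    Columns: animal_id, group, arm, compound, matrix, time_h, conc, unit,
    blq_flag.  Plasma in ng/mL, brain in ng/g.  Predose (t = 0) records are
    structural zeros.  One seeded generator governs parameter draws and
    error draws, in documented order (groups in design order, arms in design
    order, animals in id order; per animal: parameter draws, then plasma
    errors, then brain errors).
    """
    rng = np.random.default_rng(seed)
    missing = set(design.groups) - set(group_medians)
    if missing:
        raise DesignError(f"no medians for groups: {sorted(missing)}")
    rows = []
    for group in design.groups:
        for arm in design.arms:
            schedules = assign_schedule(arm)
            if len(schedules) != arm.n_animals:
                raise DesignError("schedule/animal count mismatch")
            individuals = sample_individual_parameters(
                group_medians[group], v, arm.n_animals, rng)
            for i, (p, sched) in enumerate(zip(individuals, schedules)):
                animal = f"{group}-{arm.name}-{i:02d}"
                times = np.array(sched, dtype=float)
                curves = solve(p, [arm.dose], times)
                terminal = times[-1]
                for compound in ("parent", "metabolite"):
                    true_c = curves[compound]
                    obs = np.where(times > 0, _observe(true_c, v, rng), 0.0)
                    for t, c in zip(times, obs):
                        rows.append(_record(animal, group, arm.name, compound,
                                            "plasma", t, c, "ng/mL",
                                            design.lloq_plasma))
                # terminal brain sample, proportional to noise-free plasma
                for compound in ("parent", "metabolite"):
                    kp = design.brain_partition[compound]
                    true_b = curves[compound][-1] * kp
                    obs_b = float(_observe(true_b, v, rng)) if terminal > 0 else 0.0
                    rows.append(_record(animal, group, arm.name, compound,
                                        "brain", terminal, obs_b, "ng/g",
                                        design.lloq_brain))
    return pd.DataFrame(rows)


def _record(animal, group, arm, compound, matrix, t, conc, unit, lloq):
    return {
        "animal_id": animal, "group": group, "arm": arm,
        "compound": compound, "matrix": matrix, "time_h": float(t),
        "conc": float(conc), "unit": unit,
        "blq_flag": bool(conc < lloq),
    }


# -- auxiliary generators ----------------------------------------------------

def simulate_dialysis(true_fu: float, kind: str, n: int, rng,
                      dilution_factor: float = 5.0, c_total: float = 50.0,
                      assay_cv: float = 0.05) -> pd.DataFrame:
    """Paired RED chamber concentrations around a true unbound fraction.

    For brain homogenate, `true_fu` is the undiluted-tissue fraction; the
    generator computes the diluted-chamber fraction implied by the dilution
    factor and perturbs both chamber assays with proportional error.
    """
    from .binding import fu_diluted_from_brain

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if kind == "brain_homogenate":
        fu_chamber = fu_diluted_from_brain(true_fu, dilution_factor)
        D = dilution_factor
    elif kind == "plasma":
        fu_chamber, D = true_fu, 1.0
    else:
        raise DesignError(f"unknown matrix kind {kind!r}")
    rows = []
    for i in range(n):
        c_matrix = c_total * (1.0 + assay_cv * rng.standard_normal())
        c_buffer = c_total * fu_chamber * (1.0 + assay_cv * rng.standard_normal())
        rows.append({"measurement": i, "kind": kind,
                     "c_buffer": max(c_buffer, 0.0),
                     "c_matrix": max(c_matrix, 1e-9),
                     "dilution_factor": D})
    return pd.DataFrame(rows)


def simulate_ct_table(genes: dict, groups=("control", "LPS"),
                      times=(24.0, 30.0, 48.0), n_per_group: int = 6,
                      rng=None, reference: str = "Gapdh",
                      base_ct: float = 25.0, ref_ct: float = 18.0,
                      ct_sd: float = 0.15) -> pd.DataFrame:
    """Synthetic duplicate-well qPCR cycle thresholds.

    ``genes`` maps target gene -> fold change in the non-calibrator group
    (applied at every time); duplicates share a sample-level Ct perturbed by
    well noise.  Output columns: sample_id, group, time_h, gene, role,
    replicate, ct.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for group in groups:
        for t in times:
            for i in range(n_per_group):
                sample = f"{group}-t{t:g}-{i:02d}"
                ct_ref = ref_ct + 0.3 * rng.standard_normal()
                for rep in (1, 2):
                    rows.append({"sample_id": sample, "group": group,
                                 "time_h": t, "gene": reference,
                                 "role": "reference", "replicate": rep,
                                 "ct": ct_ref + ct_sd * rng.standard_normal()})
                for gene, fold in genes.items():
                    shift = -np.log2(fold) if group != groups[0] else 0.0
                    ct_g = base_ct + shift + 0.3 * rng.standard_normal()
                    for rep in (1, 2):
                        rows.append({"sample_id": sample, "group": group,
                                     "time_h": t, "gene": gene,
                                     "role": "target", "replicate": rep,
                                     "ct": ct_g + ct_sd * rng.standard_normal()})
    return pd.DataFrame(rows)
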