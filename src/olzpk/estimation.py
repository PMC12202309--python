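"""Pooled maximum-likelihood fitting of the joint parent-metabolite model.

One group's three dosing arms (PO parent, IV parent, IV metabolite) are
fitted jointly by naive-pooled maximum likelihood under lognormal residuals:
all non-censored post-dose observations enter one likelihood evaluated on
the group-typical parameter curve.  The IV-metabolite arm pins the
metabolite disposition (CL_dmo, V_dmo), the IV-parent arm separates CL from
bioavailability and informs k_pm through the metabolite it generates, and
the PO arm informs absorption and the presystemic split.

Population machinery with random effects (SAEM) is deliberately not part of
this module: with at most three observations per animal in this design, the
pooled fit targets the group-typical parameters the downstream contrasts
use, reproducibly and at desk scale.  Internally the conversion rate is
parameterized as k_pm = fm * CL/V1 with fm on the logit scale, so the
constraint that conversion is a component of total parent clearance holds
by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pk_model import (DoseArm, DoseEvent, PKParameters, derived_parameters,
                       solve)

__all__ = [
    "FitSpec",
    "FitResult",
    "fit_group",
    "pooled_objective",
    "contrast_groups",
    "welch_t_on_params",
    "UnderIdentifiedError",
    "EstimationError",
    "DEFAULT_INITIALS",
]


class EstimationError(RuntimeError):
    pass


class UnderIdentifiedError(EstimationError):
    pass


REQUIRED_ARMS = {
    DoseArm.PO_PARENT: ("ka", "ka_dmo", "F_po_total", "F_d"),
    DoseArm.IV_PARENT: ("CL", "V1", "V2", "Q", "k_pm"),
    DoseArm.IV_METABOLITE: ("CL_dmo", "V1_dmo", "V2_dmo", "Q_dmo"),
}

# generic round-number starting values, deliberately not any group's truth
DEFAULT_INITIALS = PKParameters(
    ka=1.5, ka_dmo=1.5, V1=1.5, V2=3.0, Q=1.5, CL=2.0,
    V1_dmo=1.5, V2_dmo=2.0, Q_dmo=0.8, CL_dmo=0.4,
    k_pm=0.2, F_po_total=0.15, F_d=0.8,
)

_POSITIVE = ("ka", "ka_dmo", "V1", "V2", "Q", "CL",
             "V1_dmo", "V2_dmo", "Q_dmo", "CL_dmo")
_FRACTIONS = ("F_po_total", "F_d")
_PARAM_ORDER = _POSITIVE + ("fm",) + _FRACTIONS  # internal vector layout


@dataclass(frozen=True)
class FitSpec:
    """Fit configuration: initials, multistart and error handling.

    ``n_starts`` jittered starts (normal, ``jitter_sd`` on the transformed
    scale) are run from ``initials``; the best objective wins, ties broken
    by distance to the initial transformed vector.  BLQ records are excluded
    from the likelihood (``blq='exclude'``) or imputed at LLOQ/2
    (``blq='lloq_half'`` with ``lloq`` set).
    """

    initials: PKParameters = DEFAULT_INITIALS
    n_starts: int = 8
    jitter_sd: float = 0.3
    seed: int = 0
    blq: str = "exclude"
    lloq: float | None = None
    maxiter: int = 400
    doses: dict = field(default_factory=lambda: {
        DoseArm.PO_PARENT: DoseEvent(DoseArm.PO_PARENT, 4.0),
        DoseArm.IV_PARENT: DoseEvent(DoseArm.IV_PARENT, 0.5),
        DoseArm.IV_METABOLITE: DoseEvent(DoseArm.IV_METABOLITE, 0.5),
    })


@dataclass(frozen=True)
class FitResult:
    """Converged pooled-fit output for one group."""

    params: PKParameters
    objective: float
    converged: bool
    n_obs: int
    sigma: float                  # residual SD on the log scale
    residual_summary: dict
    seed: int
    n_starts: int

    @property
    def derived(self) -> dict:
        """Derived quantities, always recomputed from the estimates."""
        return derived_parameters(self.params)

    def value(self, name: str) -> float:
        if hasattr(self.params, name):
            return float(getattr(self.params, name))
        d = self.derived
        if name in d:
            return float(d[name])
        raise KeyError(name)


def _to_vector(p: PKParameters) -> np.ndarray:
    vals = []
    for name in _PARAM_ORDER:
        if name == "fm":
            fm = p.V1 * p.k_pm / p.CL
            vals.append(np.log(fm / (1 - fm)))
        elif name in _FRACTIONS:
            v = getattr(p, name)
            vals.append(np.log(v / (1 - v)))
        else:
            vals.append(np.log(getattr(p, name)))
    return np.array(vals)


def _from_vector(x: np.ndarray) -> PKParameters:
    # clip keeps every transformed point inside the valid parameter space so
    # the likelihood surface has no cliffs for gradient-based optimizers
    x = np.clip(x, -30.0, 30.0)
    d = {}
    for name, v in zip(_PARAM_ORDER, x):
        if name in _FRACTIONS or name == "fm":
            d[name] = float(1.0 / (1.0 + np.exp(-v)))
        else:
            d[name] = float(np.exp(v))
    fm = d.pop("fm")
    d["k_pm"] = fm * d["CL"] / d["V1"]
    return PKParameters(**d)


def _prepare(data: pd.DataFrame, spec: FitSpec) -> pd.DataFrame:
    df = data[(data["matrix"] == "plasma") & (data["time_h"] > 0)].copy()
    blq = df["blq_flag"].astype(bool)
    if spec.blq == "exclude":
        df = df[~blq]
    elif spec.blq == "lloq_half":
        if spec.lloq is None:
            raise EstimationError("blq='lloq_half' requires lloq")
        df.loc[blq, "conc"] = spec.lloq / 2.0
    else:
        raise EstimationError(f"unknown BLQ rule {spec.blq!r}")
    # structurally zero predictions cannot enter a lognormal likelihood
    df = df[~((df["arm_enum"] == DoseArm.IV_METABOLITE)
              & (df["compound"] == "parent"))]
    df = df[df["conc"] > 0]
    return df


def _resolve_arm(label: str) -> DoseArm:
    try:
        return DoseArm(label)
    except ValueError:
        pass
    lab = label.lower()
    if "dmo" in lab or "metab" in lab:
        return DoseArm.IV_METABOLITE
    if lab.startswith("iv"):
        return DoseArm.IV_PARENT
    if lab.startswith("po") or "oral" in lab:
        return DoseArm.PO_PARENT
    raise EstimationError(f"cannot map arm label {label!r} to a dosing arm")


def _build_blocks(data: pd.DataFrame, spec: FitSpec):
    """Validate arm coverage and assemble per-arm observation blocks."""
    df = data.copy()
    df["arm_enum"] = df["arm"].map(_resolve_arm)
    present = set(df["arm_enum"].unique())
    missing = [a for a in REQUIRED_ARMS if a not in present]
    if missing:
        confounded = sorted({p for a in missing for p in REQUIRED_ARMS[a]})
        raise UnderIdentifiedError(
            f"missing arm(s) {[a.value for a in missing]}: parameters "
            f"{confounded} are not identifiable from the remaining arms")
    df = _prepare(df, spec)
    if df.empty:
        raise EstimationError("no usable observations after filtering")
    arm_blocks = []
    for arm_enum, sub in df.groupby("arm_enum", sort=True):
        times = np.array(sorted(sub["time_h"].unique()))
        t_index = {t: j for j, t in enumerate(times)}
        idx = sub["time_h"].map(t_index).to_numpy()
        is_parent = (sub["compound"] == "parent").to_numpy()
        logc = np.log(sub["conc"].to_numpy(dtype=float))
        arm_blocks.append((spec.doses[arm_enum], times, idx, is_parent, logc))
    return arm_blocks, int(df.shape[0])


def pooled_objective(data: pd.DataFrame, params: PKParameters,
                     spec: FitSpec | None = None) -> float:
    """The pooled-fit objective n*log(SSR/n) at a given parameter set."""
    spec = spec or FitSpec()
    arm_blocks, n_obs = _build_blocks(data, spec)
    return _objective_from_blocks(arm_blocks, n_obs)(_to_vector(params))


def _objective_from_blocks(arm_blocks, n_obs):
    def objective(x):
        p = _from_vector(x)
        ssr = 0.0
        for dose, times, idx, is_parent, logc in arm_blocks:
            curves = solve(p, [dose], times)
            pred = np.where(is_parent, curves["parent"][idx],
                            curves["metabolite"][idx])
            if not np.all(np.isfinite(pred)):
                return 1e10
            r = logc - np.log(np.clip(pred, 1e-300, None))
            ssr += float(r @ r)
        if not np.isfinite(ssr) or ssr <= 0:
            return 1e10
        return n_obs * np.log(ssr / n_obs)

    return objective


def fit_group(data: pd.DataFrame, spec: FitSpec | None = None) -> FitResult:
    """Fit the joint model to one group's pooled three-arm plasma data.

    `data` is the long-format record table (one group); arm labels are
    mapped onto the three dosing arms.  Raises
    :class:`UnderIdentifiedError` when an arm is missing, naming the
    parameters the remaining data cannot separate.
    """
    spec = spec or FitSpec()
    arm_blocks, n_obs = _build_blocks(data, spec)
    objective = _objective_from_blocks(arm_blocks, n_obs)

    x0 = _to_vector(spec.initials)
    rng = np.random.default_rng(spec.seed)
    best = None
    for s in range(max(spec.n_starts, 1)):
        start = x0 if s == 0 else x0 + spec.jitter_sd * rng.standard_normal(x0.size)
        # quasi-Newton descent, simplex polish across any residual kinks,
        # then a final quasi-Newton tightening
        res = optimize.minimize(objective, start, method="L-BFGS-B",
                                options={"maxiter": spec.maxiter,
                                         "ftol": 1e-14, "gtol": 1e-12})
        res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                options={"maxiter": spec.maxiter * 10,
                                         "xatol": 1e-9, "fatol": 1e-11,
                                         "adaptive": True})
        res = optimize.minimize(objective, res.x, method="L-BFGS-B",
                                options={"maxiter": spec.maxiter,
                                         "ftol": 1e-15, "gtol": 1e-13})
        key = (round(res.fun, 6), float(np.linalg.norm(res.x - x0)))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    params = _from_vector(res.x)
    converged = bool(np.isfinite(res.fun) and res.fun < 1e9)
    if not converged:
        warnings.warn("pooled fit did not converge", stacklevel=2)

    sigma = float(np.sqrt(np.exp(res.fun / n_obs)))  # profiled residual SD
    resid = {}
    for dose, times, idx, is_parent, logc in arm_blocks:
        curves = solve(params, [dose], times)
        pred = np.where(is_parent, curves["parent"][idx],
                        curves["metabolite"][idx])
        r = logc - np.log(pred)
        resid[dose.arm.value] = {"n": int(r.size),
                                 "rmse_log": float(np.sqrt(np.mean(r ** 2))),
                                 "bias_log": float(np.mean(r))}
    return FitResult(params=params, objective=float(res.fun),
                     converged=converged, n_obs=n_obs, sigma=sigma,
                     residual_summary=resid, seed=spec.seed,
                     n_starts=max(spec.n_starts, 1))


def contrast_groups(fit_a: FitResult, fit_b: FitResult, name: str) -> dict:
    """Fold change and percent change of a parameter, a vs. b (LPS vs.
    control in the study's orientation)."""
    for fit in (fit_a, fit_b):
        if not fit.converged:
            raise EstimationError("cannot contrast a non-converged fit")
    a, b = fit_a.value(name), fit_b.value(name)
    if b == 0:
        raise EstimationError(f"reference value of {name} is zero")
    return {"parameter": name, "a": a, "b": b,
            "fold_change": a / b,
            "percent_change": 100.0 * (a - b) / b}


def welch_t_on_params(group_a, group_b, log: bool = False):
    """Welch two-sample t-test on per-animal parameter values.

    Returns ``(t, p)``.  Identical degenerate groups give (0, 1); otherwise
    zero variance in both groups is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EstimationError("need at least two values per group")
    if log:
        if np.any(a <= 0) or np.any(b <= 0):
            raise EstimationError("log transform requires positive values")
        a, b = np.log(a), np.log(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise EstimationError("degenerate variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
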