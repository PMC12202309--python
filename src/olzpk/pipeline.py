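"""Pipeline stage implementations used by `pipeline_run` and the CLI.

Each stage reads what it needs from the shared `context` (filled by earlier
stages) or from paths in the config, writes its table(s) into the run
directory, and leaves its products in the context for downstream stages.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import binding as _binding
from . import expression as _expression
from . import nca as _nca
from . import synthetic_data as _syn
from .estimation import FitSpec, contrast_groups, fit_group
from .io import read_concentrations, write_concentrations

# generator truths for the dialysis stage: study-level mean unbound
# fractions for olanzapine/DMO in plasma and brain (fractions, not %)
DEFAULT_FU_TRUTH = {
    ("parent", "plasma"): {"control": 0.416, "LPS": 0.401},
    ("parent", "brain"): {"control": 0.274, "LPS": 0.291},
    ("metabolite", "plasma"): {"control": 0.130, "LPS": 0.083},
    ("metabolite", "brain"): {"control": 0.087, "LPS": 0.088},
}

DEFAULT_EXPRESSION_FOLDS = {"Cyp1a2": 0.08, "Ugt1a1": 0.3, "Abcb1a": 0.5}


def _get_study(config, context):
    if "study" in context:
        return context["study"]
    if "data" in config:
        df = read_concentrations(config["data"])
        context["study"] = df
        return df
    raise ValueError("no simulated study in context and no 'data' in config")


def stage_simulate(config, out, seed, context, manifest):
    design = _syn.default_design()
    v = _syn.VariabilityModel(**config.get("variability", {}))
    medians = _syn.default_group_medians()
    df = _syn.simulate_study(design, medians, v, seed)
    write_concentrations(df, out / "study.csv")
    context["study"] = df
    context["design"] = design
    context["medians"] = medians


def stage_nca(config, out, seed, context, manifest):
    df = _get_study(config, context)
    n_boot = int(config.get("n_boot", 2000))
    t_last = config.get("t_last")
    rows = []
    for (group, arm, compound, matrix), sub in df.groupby(
            ["group", "arm", "compound", "matrix"], sort=True):
        clean = _nca.blq_rule(sub)
        if t_last is not None:
            clean = clean[clean["time_h"] <= float(t_last)]
        if clean.empty or clean["time_h"].nunique() < 2 \
                or (clean["conc"] <= 0).all():
            continue
        data = _nca.BatchDataset.from_frame(clean)
        res = _nca.batch_auc(data, n_boot=n_boot, seed=seed)
        rows.append({"group": group, "arm": arm, "compound": compound,
                     "matrix": matrix, "auc_h_ng_ml": res.auc,
                     "se": res.se, "ci_lower": res.ci_lower,
                     "ci_upper": res.ci_upper, "n_animals": res.n_animals,
                     "t_last_h": float(data.times[-1])})
    auc = pd.DataFrame(rows)
    auc.to_csv(out / "auc.csv", index=False)
    context["auc"] = auc

    ratios = []
    for (group, arm), sub in auc[auc["matrix"] == "plasma"].groupby(
            ["group", "arm"]):
        by = sub.set_index("compound")["auc_h_ng_ml"]
        if {"parent", "metabolite"} <= set(by.index):
            ratios.append({"group": group, "arm": arm,
                           "metabolic_ratio": by["metabolite"] / by["parent"]})
    pd.DataFrame(ratios).to_csv(out / "metabolic_ratios.csv", index=False)


def _matched_window_aucs(sub):
    """Brain and plasma AUC point estimates over their common time window.

    Brain is sampled only at terminal times, so an unmatched ratio of
    full-span AUCs would systematically understate the partition
    coefficient; both matrices are integrated over the overlap of their
    sampled spans.
    """
    out = {}
    spans = {}
    for matrix in ("brain", "plasma"):
        clean = _nca.blq_rule(sub[sub["matrix"] == matrix])
        if clean.empty or clean["time_h"].nunique() < 2:
            return None
        spans[matrix] = clean
    lo = max(spans[m]["time_h"].min() for m in spans)
    hi = min(spans[m]["time_h"].max() for m in spans)
    for matrix, clean in spans.items():
        clean = clean[(clean["time_h"] >= lo) & (clean["time_h"] <= hi)]
        if clean.empty or clean["time_h"].nunique() < 2 \
                or (clean["conc"] <= 0).all():
            return None
        res = _nca.batch_auc(_nca.BatchDataset.from_frame(clean), n_boot=0)
        out[matrix] = res.auc
    if out["plasma"] <= 0:
        return None
    return out


def stage_binding(config, out, seed, context, manifest):
    rng = np.random.default_rng(seed + 1)
    fu_truth = config.get("fu_truth", DEFAULT_FU_TRUTH)
    n_pools = int(config.get("n_dialysis_pools", 6))
    D = float(config.get("dilution_factor", _binding.DEFAULT_BRAIN_DILUTION))
    fu_rows = []
    for (compound, matrix), groups in fu_truth.items():
        kind = "plasma" if matrix == "plasma" else "brain_homogenate"
        for group, true_fu in groups.items():
            meas = _syn.simulate_dialysis(true_fu, kind, n_pools, rng,
                                          dilution_factor=D)
            fus = []
            for _, m in meas.iterrows():
                dm = _binding.DialysisMeasurement(
                    m["c_buffer"], m["c_matrix"], kind,
                    dilution_factor=m["dilution_factor"])
                if kind == "plasma":
                    fus.append(_binding.fu_plasma(dm))
                else:
                    fus.append(_binding.fu_brain(_binding.fu_diluted(dm), D))
            fu_rows.append({"compound": compound, "matrix": matrix,
                            "group": group, "fu_mean": float(np.mean(fus)),
                            "fu_min": float(np.min(fus)),
                            "fu_max": float(np.max(fus)), "n_pools": n_pools})
    fu = pd.DataFrame(fu_rows)
    fu.to_csv(out / "unbound_fractions.csv", index=False)
    context["fu"] = fu

    try:
        study = _get_study(config, context)
    except ValueError:
        return
    pen_rows = []
    fu_ix = fu.set_index(["compound", "matrix", "group"])["fu_mean"]
    for (group, arm, compound), sub in study.groupby(["group", "arm",
                                                      "compound"]):
        by = _matched_window_aucs(sub)
        if by is None:
            continue
        try:
            fu_b = fu_ix[(compound, "brain", group)]
            fu_p = fu_ix[(compound, "plasma", group)]
        except KeyError:
            continue
        res = _binding.brain_penetration(by["brain"], by["plasma"], fu_b, fu_p)
        pen_rows.append({"group": group, "arm": arm, "compound": compound,
                         "kp_brain": res.kp_brain,
                         "kp_uu_brain": res.kp_uu_brain,
                         "auc_brain": res.auc_brain,
                         "auc_plasma": res.auc_plasma,
                         "fu_brain": res.fu_brain, "fu_plasma": res.fu_plasma})
    pd.DataFrame(pen_rows).to_csv(out / "penetration.csv", index=False)


def stage_fit(config, out, seed, context, manifest):
    df = _get_study(config, context)
    spec = FitSpec(n_starts=int(config.get("n_starts", 4)), seed=seed)
    fits = {}
    for group, sub in df.groupby("group", sort=True):
        fit = fit_group(sub, spec)
        fits[group] = fit
        payload = {"group": group, "parameters": fit.params.to_dict(),
                   "derived": fit.derived, "objective": fit.objective,
                   "converged": fit.converged, "n_obs": fit.n_obs,
                   "sigma_log": fit.sigma,
                   "residuals": fit.residual_summary, "seed": fit.seed}
        with open(out / f"fit_{group}.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    context["fits"] = fits


def stage_contrast(config, out, seed, context, manifest):
    fits = context.get("fits")
    if fits is None:
        raise ValueError("contrast stage requires the fit stage")
    a = config.get("contrast_a", "LPS")
    b = config.get("contrast_b", "control")
    names = config.get("contrast_parameters",
                       ["CL", "CL_dmo", "F_po", "CL_parent_to_dmo"])
    rows = [contrast_groups(fits[a], fits[b], name) for name in names]
    pd.DataFrame(rows).to_csv(out / "contrasts.csv", index=False)


def stage_expression(config, out, seed, context, manifest):
    folds = config.get("expression_folds", DEFAULT_EXPRESSION_FOLDS)
    rng = np.random.default_rng(seed + 2)
    ct = _syn.simulate_ct_table(folds, rng=rng)
    ct.to_csv(out / "ct_records.csv", index=False)
    rel = _expression.ddct(ct, calibrator="control")
    rel.to_csv(out / "expression.csv", index=False)
    context["expression"] = rel
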