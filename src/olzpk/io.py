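"""Data contracts, run manifests, and the pipeline driver.

CSV is the single tabular interchange format, JSON carries configuration,
fit results and manifests.  Times are stored in hours as decimals
(3 min = 0.05 h).  Every run emits a :class:`RunManifest` recording input
hashes, the configuration snapshot, seeds and per-stage timing, so that a
rerun with the same manifest inputs reproduces stochastic outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = [
    "CONCENTRATION_COLUMNS",
    "read_concentrations",
    "write_concentrations",
    "RunManifest",
    "pipeline_run",
    "SchemaError",
]

CONCENTRATION_COLUMNS = ["animal_id", "group", "arm", "compound", "matrix",
                         "time_h", "conc", "unit", "blq_flag"]
KEY_COLUMNS = ["animal_id", "compound", "matrix", "time_h"]


class SchemaError(ValueError):
    pass


def read_concentrations(path) -> pd.DataFrame:
    """Read and validate a long-format concentration table.

    Rejects missing columns, negative times, negative concentrations,
    non-BLQ zero-information rows and duplicated
    (animal, compound, matrix, time) keys, reporting offending row numbers
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["blq_flag"] = df["blq_flag"].astype(bool)
    problems = []
    bad_time = df.index[df["time_h"] < 0]
    problems += [f"row {i + 1}: negative time_h" for i in bad_time]
    bad_conc = df.index[(df["conc"] < 0) & ~df["blq_flag"]]
    problems += [f"row {i + 1}: negative conc without blq_flag"
                 for i in bad_conc]
    bad_compound = df.index[~df["compound"].isin(["parent", "metabolite"])]
    problems += [f"row {i + 1}: unknown compound" for i in bad_compound]
    bad_matrix = df.index[~df["matrix"].isin(["plasma", "brain"])]
    problems += [f"row {i + 1}: unknown matrix" for i in bad_matrix]
    dup = df.index[df.duplicated(subset=KEY_COLUMNS, keep=False)
                   & df.duplicated(subset=KEY_COLUMNS, keep="first")]
    problems += [f"row {i + 1}: duplicate (animal, compound, matrix, time)"
                 for i in dup]
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems[:20]) +
                          (f" (+{len(problems) - 20} more)"
                           if len(problems) > 20 else ""))
    return df[CONCENTRATION_COLUMNS]


def write_concentrations(df: pd.DataFrame, path) -> None:
    df[CONCENTRATION_COLUMNS].to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted for every pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    status: str = "running"

    def record_input(self, path) -> None:
        self.input_hashes[str(path)] = _sha256(Path(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)


DEFAULT_STAGES = ("simulate", "nca", "binding", "fit", "contrast",
                  "expression")


def pipeline_run(config: dict, out_dir, seed: int) -> RunManifest:
    """Run the configured stage subset in canonical order.

    ``config['stages']`` names any subset of
    simulate -> nca -> binding -> fit -> contrast -> expression.  Stage
    outputs land in ``out_dir``; the manifest is written last (and marked
    failed, with partial outputs retained, if a stage raises).
    """
    from . import pipeline as _stages

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in DEFAULT_STAGES]
    if unknown:
        raise SchemaError(f"unknown stages: {unknown}")
    stages = [s for s in DEFAULT_STAGES if s in stages]
    manifest = RunManifest(config=config, seed=seed)
    context: dict = {}
    try:
        for name in stages:
            t0 = time.perf_counter()
            getattr(_stages, f"stage_{name}")(config, out, seed, context,
                                              manifest)
            manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        manifest.status = "ok"
    except Exception:
        manifest.status = "failed"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
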