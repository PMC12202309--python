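"""Non-compartmental AUC estimation for sparse and serial designs.

Destructive (batch) designs terminate animals at assigned times, so no
animal contributes a complete profile.  ``batch_auc`` implements a
Bailer-type estimator generalized to batch designs: the point estimate is
the trapezoid-weighted sum of per-time mean concentrations, the variance is
assembled from pooled within-batch covariances (a batch is a set of animals
sharing one sampling-time pattern), and the confidence interval is a
bootstrap-t interval built by resampling animals with replacement within
batches.

``serial_auc`` is the rich-design counterpart: a plain per-animal linear
trapezoid AUC for designs where each animal has a complete profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchDataset",
    "BatchAUCResult",
    "trapezoid_weights",
    "batch_auc",
    "auc_ratio",
    "serial_auc",
    "NCAError",
]


class NCAError(ValueError):
    pass


def trapezoid_weights(times) -> np.ndarray:
    """Linear trapezoid quadrature weights on a strictly increasing grid.

    w_0 = (t_1-t_0)/2, w_j = (t_{j+1}-t_{j-1})/2, w_J = (t_J-t_{J-1})/2;
    the weights sum to the span t_J - t_0.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise NCAError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly increasing")
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if t.size > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return w


@dataclass(frozen=True)
class Batch:
    """Animals sharing one sampling pattern: `conc[i, j]` is animal i at
    schedule index `time_idx[j]`."""

    animal_ids: tuple
    time_idx: np.ndarray
    conc: np.ndarray

    @property
    def n(self) -> int:
        return self.conc.shape[0]


@dataclass(frozen=True)
class BatchDataset:
    """A destructive-sampling dataset: a schedule plus disjoint batches."""

    times: np.ndarray
    batches: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise NCAError("schedule times must be strictly increasing")
        object.__setattr__(self, "times", t)
        seen = set()
        covered = np.zeros(t.size, dtype=int)
        for b in self.batches:
            dup = seen.intersection(b.animal_ids)
            if dup:
                raise NCAError(f"animals in more than one batch: {sorted(dup)}")
            seen.update(b.animal_ids)
            if b.conc.shape != (len(b.animal_ids), b.time_idx.size):
                raise NCAError("batch concentration matrix shape mismatch")
            covered[b.time_idx] += b.n
        if np.any(covered == 0):
            missing = t[covered == 0]
            raise NCAError(f"schedule times covered by no animal: {missing}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col: str = "time_h",
                   conc_col: str = "conc", animal_col: str = "animal_id"
                   ) -> "BatchDataset":
        """Build from a long table; animals are grouped into batches by their
        set of observed times."""
        times = np.array(sorted(df[time_col].unique()), dtype=float)
        t_index = {t: j for j, t in enumerate(times)}
        patterns: dict = {}
        for animal, sub in df.groupby(animal_col, sort=True):
            if sub[time_col].duplicated().any():
                raise NCAError(f"animal {animal!r} has duplicate times")
            sub = sub.sort_values(time_col)
            key = tuple(sub[time_col])
            patterns.setdefault(key, []).append(
                (animal, sub[conc_col].to_numpy(dtype=float)))
        batches = []
        for key, members in patterns.items():
            idx = np.array([t_index[t] for t in key], dtype=int)
            ids = tuple(m[0] for m in members)
            conc = np.vstack([m[1] for m in members])
            batches.append(Batch(ids, idx, conc))
        return cls(times, tuple(batches))


@dataclass(frozen=True)
class BatchAUCResult:
    """AUC_t point estimate with design-aware uncertainty."""

    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int | None
    n_animals: int
    times: np.ndarray = field(repr=False)

    def __post_init__(self):
        if (self.n_boot > 0 and np.isfinite(self.ci_lower)
                and not (self.ci_lower <= self.auc <= self.ci_upper)):
            raise NCAError("bootstrap interval does not bracket the estimate")


def _pooled_moments(times, batches):
    """Per-time pooled means, and pooled within-batch covariance pieces.

    Returns (mean_j, S, dof, N) where S[j, k] is the summed centered
    cross-product over batches covering both times, dof[j, k] the summed
    (n_b - 1), and N[j, k] the number of animals contributing to both.
    """
    J = times.size
    tot = np.zeros(J)
    cnt = np.zeros(J)
    S = np.zeros((J, J))
    dof = np.zeros((J, J))
    N = np.zeros((J, J))
    for b in batches:
        idx = b.time_idx
        tot[idx] += b.conc.sum(axis=0)
        cnt[idx] += b.n
        if b.n < 2:
            warnings.warn(
                f"batch {b.animal_ids} has a single animal and contributes "
                "no covariance; dropped from the variance", stacklevel=3)
            continue
        centered = b.conc - b.conc.mean(axis=0)
        ix = np.ix_(idx, idx)
        S[ix] += centered.T @ centered
        dof[ix] += b.n - 1
        N[ix] += b.n
    if np.any(cnt == 0):
        raise NCAError("schedule time with zero animals")
    return tot / cnt, S, dof, N


def _variance(w, S, dof, N):
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(dof > 0, S / np.where(dof > 0, dof, 1) / np.where(N > 0, N, 1), 0.0)
    return float(w @ cov @ w)


def batch_auc(data: BatchDataset, n_boot: int = 2000, seed: int | None = None,
              alpha: float = 0.05) -> BatchAUCResult:
    """Batch-design AUC_t with standard error and bootstrap-t interval.

    Point estimate: sum_j w_j * mean_j over per-time means of all animals
    sampled at t_j.  Variance: sum_jk w_j w_k cov_jk with cov_jk the pooled
    within-batch covariance at times (j, k) divided by the number of animals
    contributing to both (zero when no batch covers both).  The bootstrap
    resamples animals with replacement within batches, preserving each
    animal's time pattern, and studentizes each replicate with its own
    resampled standard error; set ``n_boot=0`` to skip the bootstrap.

    A seed is required whenever the bootstrap runs.
    """
    times, batches = data.times, data.batches
    w = trapezoid_weights(times)
    mean_j, S, dof, N = _pooled_moments(times, batches)
    auc = float(w @ mean_j)
    var = _variance(w, S, dof, N)
    se = float(np.sqrt(max(var, 0.0)))
    n_animals = sum(b.n for b in batches)

    if n_boot == 0:
        return BatchAUCResult(auc, se, np.nan, np.nan, 0, seed, n_animals, times)
    if seed is None:
        raise NCAError("a seed is required for the bootstrap")
    if not np.any(dof > 0):
        warnings.warn("no batch has two animals; standard error and "
                      "bootstrap interval are undefined", stacklevel=2)
        return BatchAUCResult(auc, se, np.nan, np.nan, n_boot, seed,
                              n_animals, times)

    lo, hi = _bootstrap_t(times, batches, w, auc, se, n_boot, seed, alpha)
    return BatchAUCResult(auc, se, lo, hi, n_boot, seed, n_animals, times)


def _bootstrap_t(times, batches, w, auc, se, n_boot, seed, alpha):
    rng = np.random.default_rng(seed)
    J = times.size
    cnt = np.zeros(J)
    for b in batches:
        cnt[b.time_idx] += b.n
    tot_r = np.zeros((n_boot, J))
    S_r = np.zeros((n_boot, J, J))
    dof = np.zeros((J, J))
    N = np.zeros((J, J))
    for b in batches:
        idx = rng.integers(0, b.n, size=(n_boot, b.n))
        X = b.conc[idx]                       # (B, n_b, m_b)
        tot_r[:, b.time_idx] += X.sum(axis=1)
        if b.n < 2:
            continue
        centered = X - X.mean(axis=1, keepdims=True)
        Sb = np.einsum("rij,rik->rjk", centered, centered)
        ix = np.ix_(b.time_idx, b.time_idx)
        S_r[(slice(None),) + ix] += Sb
        dof[ix] += b.n - 1
        N[ix] += b.n
    mean_r = tot_r / cnt
    auc_r = mean_r @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        cov_r = np.where(dof > 0, S_r / np.where(dof > 0, dof, 1)
                         / np.where(N > 0, N, 1), 0.0)
    var_r = np.einsum("j,rjk,k->r", w, cov_r, w)
    se_r = np.sqrt(np.clip(var_r, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_r = (auc_r - auc) / se_r
    t_r = t_r[np.isfinite(t_r)]
    if t_r.size == 0:
        raise NCAError("all bootstrap replicates degenerate (zero variance)")
    q_lo, q_hi = np.quantile(t_r, [alpha / 2.0, 1.0 - alpha / 2.0])
    return auc - se * q_hi, auc - se * q_lo


def auc_ratio(numerator, denominator) -> float:
    """Plain ratio of AUC point estimates (metabolic ratios, Kp,brain)."""
    num = numerator.auc if isinstance(numerator, BatchAUCResult) else float(numerator)
    den = denominator.auc if isinstance(denominator, BatchAUCResult) else float(denominator)
    if den <= 0:
        raise NCAError(f"denominator AUC must be > 0, got {den}")
    return num / den


def serial_auc(df: pd.DataFrame, time_col: str = "time_h", conc_col: str = "conc",
               animal_col: str = "animal_id") -> pd.DataFrame:
    """Per-animal linear trapezoid AUC_t for serial (complete-profile) data.

    Animals with fewer than two time points are skipped with a warning.
    Returns a frame with columns ``animal_id`` and ``auc``.
    """
    rows = []
    for animal, sub in df.groupby(animal_col, sort=True):
        sub = sub.sort_values(time_col)
        if len(sub) < 2:
            warnings.warn(f"animal {animal!r} has <2 points; skipped", stacklevel=2)
            continue
        auc = float(np.trapezoid(sub[conc_col].to_numpy(dtype=float),
                                 sub[time_col].to_numpy(dtype=float)))
        rows.append({"animal_id": animal, "auc": auc})
    return pd.DataFrame(rows, columns=["animal_id", "auc"])


def blq_rule(df: pd.DataFrame, rule: str = "zero_before_tmax",
             lloq: float | None = None, conc_col: str = "conc",
             blq_col: str = "blq_flag", time_col: str = "time_h") -> pd.DataFrame:
    """Apply a below-quantification handling rule before AUC estimation.

    ``zero_before_tmax`` (default): BLQ records before the time of the mean
    curve's maximum are set to 0 and retained; BLQ records after it are
    dropped.  ``lloq_half``: BLQ records set to LLOQ/2 (requires ``lloq``).
    ``drop``: all BLQ records removed.
    """
    df = df.copy()
    flag = df[blq_col].astype(bool)
    if rule == "drop":
        return df[~flag].reset_index(drop=True)
    if rule == "lloq_half":
        if lloq is None:
            raise NCAError("rule 'lloq_half' requires lloq")
        df.loc[flag, conc_col] = lloq / 2.0
        return df
    if rule != "zero_before_tmax":
        raise NCAError(f"unknown BLQ rule {rule!r}")
    obs = df[~flag]
    if obs.empty:
        df.loc[flag, conc_col] = 0.0
        return df
    tmax = obs.groupby(time_col)[conc_col].mean().idxmax()
    early = flag & (df[time_col] <= tmax)
    df.loc[early, conc_col] = 0.0
    return df[~flag | early].reset_index(drop=True)
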