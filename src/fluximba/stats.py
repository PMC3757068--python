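"""Statistics linking shadow prices to metabolite dynamics.

Covers the temporal-variation measure (coefficient of variation over a
post-perturbation window), the quadrant permutation test that asks whether
fewer metabolites than expected combine a strongly negative shadow price
with high temporal variation, the Matthews correlation coefficient for
sign-based classification, and rank/linear correlation reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

#: permutations used by default in both permutation tests
DEFAULT_N_PERM = 100_000


@dataclass
class TimeCourse:
    metabolite_id: str
    times: np.ndarray  # minutes since perturbation, ascending
    values: np.ndarray  # abundance, relative units

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError(
                f"{self.metabolite_id}: times and values have different lengths"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"{self.metabolite_id}: times must be strictly increasing"
            )


@dataclass
class VariationRecord:
    metabolite_id: str
    cv: float
    lam: float


@dataclass
class PermutationResult:
    m_s: float  # center (mean or median) of shadow prices
    m_t: float  # center of temporal variation
    p_original: int
    n_permutations: int
    p_value: Optional[float]
    seed: Optional[int]
    center: str
    degenerate: bool = False


def temporal_variation(
    tc: TimeCourse,
    window_minutes: float = 30.0,
    include_time_zero: bool = True,
) -> float:
    """Coefficient of variation of the time course within the window.

    CV = sample standard deviation (n-1 denominator) / mean over the points
    with time <= ``window_minutes``.  A labeled pre-perturbation baseline at
    time 0 is included by default.
    """
    mask = tc.times <= window_minutes
    if not include_time_zero:
        mask &= tc.times > 0
    values = tc.values[mask]
    if values.size < 2:
        raise ValidationError(
            f"{tc.metabolite_id}: need >=2 points within {window_minutes} min, "
            f"got {values.size}"
        )
    mean = values.mean()
    if mean == 0:
        return float("nan")  # undefined; excluded downstream
    return float(values.std(ddof=1) / mean)


def variation_table(
    timecourses: Sequence[TimeCourse],
    shadow_prices: Dict[str, float],
    window_minutes: float = 30.0,
) -> List[VariationRecord]:
    """Pair each metabolite's CV with its shadow price (drops undefined CVs)."""
    records = []
    for tc in timecourses:
        if tc.metabolite_id not in shadow_prices:
            continue
        cv = temporal_variation(tc, window_minutes)
        if np.isfinite(cv):
            records.append(
                VariationRecord(tc.metabolite_id, cv, shadow_prices[tc.metabolite_id])
            )
    return records


def read_timecourses(path) -> List[TimeCourse]:
    """Long-format TSV: metabolite_id, time_min, value."""
    table = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "time_min", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"time-course file missing columns {sorted(missing)}")
    out = []
    for met_id, group in table.groupby("metabolite_id", sort=False):
        group = group.sort_values("time_min")
        out.append(
            TimeCourse(
                str(met_id),
                group["time_min"].to_numpy(),
                group["value"].to_numpy(),
            )
        )
    return out


def write_timecourses(timecourses: Sequence[TimeCourse], path) -> None:
    rows = []
    for tc in timecourses:
        for t, v in zip(tc.times, tc.values):
            rows.append({"metabolite_id": tc.metabolite_id, "time_min": t, "value": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _center(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(values.mean())
    if how == "median":
        return float(np.median(values))
    raise ValueError(f"center must be 'mean' or 'median', got {how!r}")


def permutation_test(
    records: Sequence[VariationRecord],
    n_perm: int = DEFAULT_N_PERM,
    center: str = "mean",
    seed: Optional[int] = None,
    strict: bool = False,
    chunk: int = 10_000,
) -> PermutationResult:
    """Quadrant permutation test for the shadow-price/variation link.

    Counts the metabolites in the "incorrect" quadrant — shadow price more
    negative than the center m_S *and* temporal variation larger than the
    center m_T — then permutes the pairing between the two vectors
    ``n_perm`` times and reports the fraction of permutations doing at
    least as well (``p_i <= p_original``).  A small p-value means the
    observed pairing avoids the incorrect quadrant more than chance
    pairings do.

    The inclusive count is the default because the quadrant statistic is
    discrete: excluding ties (``strict=True``, ``p_i < p_original``) gives
    an anti-conservative test whose type-I error can exceed the nominal
    level substantially.  The strict variant is kept for comparison with
    analyses that used it.
    """
    lam = np.array([r.lam for r in records], dtype=float)
    cv = np.array([r.cv for r in records], dtype=float)
    if lam.size < 3:
        raise ValidationError(f"need >=3 records, got {lam.size}")
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(cv))):
        raise ValidationError("records must have finite shadow prices and CVs")
    m_s = _center(lam, center)
    m_t = _center(cv, center)
    if np.ptp(lam) == 0 and np.ptp(cv) == 0:
        return PermutationResult(
            m_s, m_t, 0, n_perm, None, seed, center, degenerate=True
        )
    bad_cv = cv > m_t
    p_original = int(np.sum((lam < m_s) & bad_cv))
    rng = np.random.default_rng(seed)
    below = (lam < m_s).astype(np.int8)
    count = 0
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        # permute the pairing by permuting the shadow-price labels
        perm = rng.permuted(np.tile(below, (size, 1)), axis=1)
        p_i = perm[:, bad_cv].sum(axis=1)
        count += int(np.sum(p_i < p_original if strict else p_i <= p_original))
        done += size
    return PermutationResult(
        m_s, m_t, p_original, n_perm, count / n_perm, seed, center
    )


def mcc(
    predicted: Sequence[int],
    observed: Sequence[int],
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
):
    """Matthews correlation coefficient with a label-permutation p-value.

    Labels are binary (0/1).  The p-value is the fraction of ``n_perm``
    random permutations of the observed labels whose MCC is at least as
    extreme (|MCC_perm| >= |MCC|, two-sided).  Returns (mcc, p_value);
    both are NaN when either label vector is single-class.
    """
    pred = np.asarray(predicted, dtype=np.int8)
    obs = np.asarray(observed, dtype=np.int8)
    if pred.shape != obs.shape:
        raise ValidationError("label vectors must have equal length")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(obs)) <= {0, 1}):
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(obs)) < 2 or len(np.unique(pred)) < 2:
        return float("nan"), float("nan")
    value = _mcc_value(pred, obs)
    rng = np.random.default_rng(seed)
    n = pred.size
    chunk = max(1, min(10_000, n_perm))
    count = 0
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(obs, (size, 1)), axis=1).astype(np.int64)
        tp = perms @ pred.astype(np.int64)
        ones_obs = int(obs.sum())
        ones_pred = int(pred.sum())
        fp = ones_pred - tp
        fn = ones_obs - tp
        tn = n - tp - fp - fn
        num = tp * tn - fp * fn
        den = np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn), dtype=float
        )
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        count += int(np.sum(np.abs(vals) >= abs(value) - 1e-12))
        done += size
    return float(value), count / n_perm


def _mcc_value(pred: np.ndarray, obs: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (obs == 1)))
    tn = int(np.sum((pred == 0) & (obs == 0)))
    fp = int(np.sum((pred == 1) & (obs == 0)))
    fn = int(np.sum((pred == 0) & (obs == 1)))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(den)


def associate(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Spearman (midrank ties) and Pearson correlations with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length vectors of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {
            "spearman_rho": float("nan"),
            "spearman_p": float("nan"),
            "pearson_r": float("nan"),
            "pearson_p": float("nan"),
        }
    rho, rho_p = sps.spearmanr(x, y)
    r, r_p = sps.pearsonr(x, y)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "pearson_r": float(r),
        "pearson_p": float(r_p),
    }
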