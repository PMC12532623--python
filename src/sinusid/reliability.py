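"""Observer-reliability metrics on repeated similarity measurements.

When the same examiner (or two examiners) re-collects the postmortem
images of a subset of cases and re-scores them, the agreement between the
two measurement sessions is quantified by the technical error of
measurement (TEM), its percentage of the grand mean (rTEM), and the
coefficient of reliability R — the proportion of between-subject variance
free of measurement error. Conventional acceptability thresholds:
rTEM < 1.5% within observer, < 2.0% between observers, R > 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: acceptability thresholds
RTEM_INTRA_MAX = 1.5
RTEM_INTER_MAX = 2.0
R_MIN = 0.75


class ReliabilityError(ValueError):
    pass


@dataclass(frozen=True)
class ReliabilityResult:
    tem: float
    rtem_percent: float
    r: float
    n: int

    def verdict(self, kind: str = "intra") -> dict:
        limit = RTEM_INTRA_MAX if kind == "intra" else RTEM_INTER_MAX
        return {
            "tem": self.tem,
            "rtem_percent": self.rtem_percent,
            "R": self.r,
            "n": self.n,
            "rtem_acceptable": bool(self.rtem_percent < limit),
            "r_acceptable": bool(self.r > R_MIN),
        }


def _as_pairs(data) -> np.ndarray:
    """Coerce repeated measures to an (n, 2) float array. Accepts an array
    or a DataFrame with columns (subject_id,) m1, m2."""
    if isinstance(data, pd.DataFrame):
        cols = [c for c in data.columns if c != "subject_id"]
        if len(cols) != 2:
            raise ReliabilityError(
                "repeated-measures table needs exactly two measurement columns "
                f"besides subject_id, got {cols}"
            )
        arr = data[cols].to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ReliabilityError(f"expected an (n>=2, 2) array of paired measurements, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ReliabilityError("repeated measures contain missing values")
    return arr


def tem(data) -> float:
    """Technical error of measurement for two sessions:
    TEM = sqrt( sum(d_i^2) / (2 n) ) with d_i = m1_i - m2_i."""
    arr = _as_pairs(data)
    d = arr[:, 0] - arr[:, 1]
    return float(np.sqrt((d * d).sum() / (2.0 * arr.shape[0])))


def rtem(data) -> float:
    """Relative TEM in percent: TEM / grand mean of all 2n measurements x 100."""
    arr = _as_pairs(data)
    grand = float(arr.mean())
    if grand <= 0:
        raise ReliabilityError(f"rTEM needs a positive grand mean, got {grand}")
    return tem(arr) / grand * 100.0


def coefficient_reliability(data, variance: str = "pooled") -> float:
    """Coefficient of reliability R = 1 - TEM^2 / s^2.

    With ``variance="pooled"`` (default) s^2 is the sample variance (n-1
    denominator) of all 2n pooled measurements; ``"subject_mean"`` uses
    the variance of the per-subject session means instead.
    """
    arr = _as_pairs(data)
    if variance == "pooled":
        s2 = float(arr.ravel().var(ddof=1))
    elif variance == "subject_mean":
        s2 = float(arr.mean(axis=1).var(ddof=1))
    else:
        raise ReliabilityError(f"unknown variance convention {variance!r}")
    if s2 <= 0:
        raise ReliabilityError("total sample variance must be positive for R")
    return 1.0 - tem(arr) ** 2 / s2


def reliability_report(data, variance: str = "pooled") -> ReliabilityResult:
    arr = _as_pairs(data)
    return ReliabilityResult(
        tem=tem(arr), rtem_percent=rtem(arr),
        r=coefficient_reliability(arr, variance), n=arr.shape[0],
    )
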