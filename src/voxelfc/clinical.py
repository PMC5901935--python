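"""Clinical self-report scale handling: range checks, severity bands, and
two-sample t statistics recomputed from per-group summary statistics."""

from __future__ import annotations

from typing import Tuple

import math

import pandas as pd

__all__ = [
    "SCALE_RANGES",
    "classify_psqi",
    "classify_isi",
    "classify_bdi",
    "summary_ttest",
    "classification_report",
]

SCALE_RANGES = {"PSQI": (0, 21), "ISI": (0, 28), "BDI": (0, 63), "MMSE": (0, 30)}


def _check_range(scale: str, score: int) -> None:
    lo, hi = SCALE_RANGES[scale]
    if not (isinstance(score, (int,)) or float(score).is_integer()):
        raise ValueError(f"{scale} score must be an integer, got {score!r}")
    if not lo <= score <= hi:
        raise ValueError(f"{scale} score {score} outside [{lo}, {hi}]")


def classify_psqi(score: int) -> str:
    """Sleep-quality band: scores strictly above 5 indicate a poor sleeper."""
    _check_range("PSQI", score)
    return "poor_sleeper" if score > 5 else "good_sleeper"


def classify_isi(score: int) -> str:
    """Insomnia severity band (0-7 / 8-14 / 15-21 / 22-28, inclusive)."""
    _check_range("ISI", score)
    if score <= 7:
        return "absence"
    if score <= 14:
        return "subthreshold"
    if score <= 21:
        return "moderate"
    return "severe"


def classify_bdi(score: int) -> str:
    """Depression band: minimal < 10 <= mild < 21 <= clinical."""
    _check_range("BDI", score)
    if score < 10:
        return "minimal"
    if score < 21:
        return "mild"
    return "clinical"


def summary_ttest(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> Tuple[float, int]:
    """Pooled-variance two-sample t statistic from summary statistics.

    Returns ``(t, df)`` with ``df = n1 + n2 - 2``. For equal group sizes
    this coincides with the unpooled statistic.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if pooled <= 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return t, df


def classification_report(covariates: pd.DataFrame) -> pd.DataFrame:
    """Severity bands for every subject in a cohort covariate table."""
    out = covariates[["subject_id", "group"]].copy()
    out["psqi_band"] = covariates["psqi"].map(classify_psqi)
    out["isi_band"] = covariates["isi"].map(classify_isi)
    out["bdi_band"] = covariates["bdi"].map(classify_bdi)
    return out
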