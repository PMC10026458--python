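"""Quality-assurance statistics for the nine-tube phantom.

ROI extraction (central 50 % of each tube's radius), per-tube means,
mapping-vs-reference bias tables with corner/central group summaries,
two-scan reproducibility with coefficients of variation, temperature
trends, and the qualification verdict (CoV <= 2.7 %).

Percent-difference denominators follow the conventions of the device's
benchmark tables: the spin-echo *reference* value for bias tables and the
*baseline* scan for reproducibility tables.  Sample standard deviations use
the n-1 denominator throughout; report rounding is half-away-from-zero and
never applied to stored values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fitting import ParameterMap
from .phantom import GroundTruthMaps
from .tables import CENTRAL_TUBES, CORNER_TUBES

__all__ = [
    "TubeROI",
    "locate_tube_rois",
    "tube_statistics",
    "bias_table",
    "coefficient_of_variation",
    "reproducibility_table",
    "temperature_trend",
    "qualify_phantom",
    "round_report",
    "QUALIFICATION_COV_PCT",
]

#: Acceptable CoV for a qualified phantom (%), boundary inclusive.
QUALIFICATION_COV_PCT = 2.7


def round_report(x, decimals: int = 0):
    """Half-away-from-zero rounding to the table's displayed precision."""
    x = np.asarray(x, dtype=float)
    scale = 10.0**decimals
    out = np.copysign(np.floor(np.abs(x) * scale + 0.5), x) / scale
    if decimals <= 0:
        return out.astype(int) if out.ndim else int(out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TubeROI:
    """Circular ROI strictly inside one tube."""

    tube_id: str
    center_px: tuple[float, float]
    radius_px: float
    mask: np.ndarray

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def locate_tube_rois(
    truth: GroundTruthMaps,
    shrink_fraction: float = 0.5,
    offsets_px: Mapping[str, tuple[float, float]] | None = None,
) -> list[TubeROI]:
    """Place a circular ROI at each tube's centroid, shrunk to 50 % radius.

    ``offsets_px`` applies optional manual re-centering per tube; an ROI
    escaping its tube mask after offsetting raises, naming the tube.
    """
    offsets_px = offsets_px or {}
    rois = []
    for tid in sorted(truth.tube_labels):
        tube_mask = truth.tube_mask(tid)
        if not tube_mask.any():
            continue
        ys, xs = np.nonzero(tube_mask)
        cy, cx = float(ys.mean()), float(xs.mean())
        dy, dx = offsets_px.get(tid, (0.0, 0.0))
        cy, cx = cy + dy, cx + dx
        tube_radius = np.sqrt(tube_mask.sum() / np.pi)
        radius = shrink_fraction * tube_radius
        yy, xx = np.indices(truth.shape)
        roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        if np.any(roi & ~tube_mask):
            raise ValueError(f"ROI for tube {tid} escapes its tube mask")
        rois.append(TubeROI(tube_id=tid, center_px=(cy, cx), radius_px=radius, mask=roi))
    return rois


def tube_statistics(pmap: ParameterMap, rois: Iterable[TubeROI]) -> pd.DataFrame:
    """Arithmetic mean and sample SD over converged ROI pixels, per tube."""
    records = []
    for roi in rois:
        sel = roi.mask & pmap.converged
        vals = pmap.values[sel]
        if vals.size == 0:
            import warnings

            warnings.warn(f"tube {roi.tube_id}: no converged pixels in ROI")
            records.append({"tube_id": roi.tube_id, "mean": np.nan, "sd": np.nan, "n": 0})
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        records.append(
            {"tube_id": roi.tube_id, "mean": float(vals.mean()), "sd": sd, "n": vals.size}
        )
    return pd.DataFrame.from_records(records).set_index("tube_id")


def _as_series(values) -> pd.Series:
    if isinstance(values, pd.Series):
        return values.astype(float)
    return pd.Series(values, dtype=float)


def _group_summary(diff: pd.Series, reference: pd.Series, tubes) -> dict:
    tubes = [t for t in tubes if t in diff.index]
    d = diff.loc[tubes].abs()
    r = reference.loc[tubes]
    return {
        "mean_abs_diff_ms": float(d.mean()),
        "mean_abs_diff_pct": float(100.0 * d.mean() / r.mean()),
        "n_tubes": len(tubes),
    }


def bias_table(mapped, reference) -> tuple[pd.DataFrame, dict]:
    """Mapping-minus-reference bias rows plus group summaries.

    Returns per-tube ``diff_ms`` (mapped - reference) and ``pct`` (of the
    reference), and summary means over all tubes and over the corner
    ({A,B,F,I}) and central ({C,D,E,G,H}) groups: mean |diff| in ms and
    100 * mean |diff| / mean reference.
    """
    mapped, reference = _as_series(mapped), _as_series(reference)
    if set(mapped.index) != set(reference.index):
        raise ValueError("mapped and reference tube ids differ")
    reference = reference.loc[mapped.index]
    diff = mapped - reference
    rows = pd.DataFrame(
        {
            "mapped_ms": mapped,
            "reference_ms": reference,
            "diff_ms": diff,
            "pct": 100.0 * diff / reference,
        }
    )
    summary = {
        "all": _group_summary(diff, reference, mapped.index),
        "corner": _group_summary(diff, reference, CORNER_TUBES),
        "central": _group_summary(diff, reference, CENTRAL_TUBES),
    }
    return rows, summary


def coefficient_of_variation(values) -> float:
    """CoV in %: 100 * sample SD (n-1) / mean.  Needs >= 2 values."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * np.std(vals, ddof=1) / mean)


def reproducibility_table(baseline, repeat) -> pd.DataFrame:
    """Two-scan reproducibility rows: |diff|, % of baseline, and pair CoV."""
    baseline, repeat = _as_series(baseline), _as_series(repeat)
    if set(baseline.index) != set(repeat.index):
        raise ValueError("baseline and repeat tube ids differ")
    repeat = repeat.loc[baseline.index]
    abs_diff = (repeat - baseline).abs()
    cov = pd.Series(
        {t: coefficient_of_variation([baseline[t], repeat[t]]) for t in baseline.index}
    )
    return pd.DataFrame(
        {
            "baseline_ms": baseline,
            "repeat_ms": repeat,
            "abs_diff_ms": abs_diff,
            "pct_diff": 100.0 * abs_diff / baseline,
            "cov_pct": cov,
        }
    )


def temperature_trend(series: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Least-squares T1/T2-vs-temperature slopes per tube.

    ``series`` maps tube id -> DataFrame with columns ``temperature_c``,
    ``t1_ms``, ``t2_ms`` (>= 3 temperatures).  Returns slopes (ms/°C) and
    their sign flags (T1 should rise, T2 should fall with temperature).
    """
    records = []
    for tid, df in series.items():
        if len(df) < 3:
            raise ValueError(f"tube {tid}: need >= 3 temperatures for a trend")
        temp = df["temperature_c"].to_numpy(float)
        s1 = np.polyfit(temp, df["t1_ms"].to_numpy(float), 1)[0]
        s2 = np.polyfit(temp, df["t2_ms"].to_numpy(float), 1)[0]
        records.append(
            {
                "tube_id": tid,
                "t1_slope_ms_per_c": s1,
                "t2_slope_ms_per_c": s2,
                "t1_increases": bool(s1 >= 0),
                "t2_decreases": bool(s2 <= 0),
            }
        )
    return pd.DataFrame.from_records(records).set_index("tube_id")


def qualify_phantom(
    cov_values: Mapping[str, float], threshold_pct: float = QUALIFICATION_COV_PCT
) -> tuple[pd.Series, bool]:
    """Pass/fail per tube (CoV <= threshold, boundary inclusive) and overall."""
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    verdicts = pd.Series({t: bool(c <= threshold_pct) for t, c in cov_values.items()})
    return verdicts, bool(verdicts.all())
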