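"""Volumetric steatosis statistics: LV%_TH and paired change measures.

LV%_TH is the percentage of liver-mask volume whose fat fraction lies above
a steatosis threshold TH (strictly, by default). Unlike a whole-liver mean
it is sensitive to how steatosis is distributed across the organ, which is
the point of the volumetric analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GeometryError, PDFFMap

__all__ = ["VolumetricResult", "lv_percent_above", "volumetric_result", "paired_changes"]

BASELINE = "baseline"
WEEK8 = "week8"


def lv_percent_above(pdff: PDFFMap, th: float, inclusive: bool = False) -> float:
    """LV%_TH: percent of masked voxels with fat fraction above ``th``.

    ``inclusive=True`` switches the comparison from strict ``>`` to ``>=``
    (sensitivity analysis; boundary voxels at exactly TH are not counted as
    steatotic by default).
    """
    if not 0.0 <= th <= 100.0:
        raise ValueError(f"threshold must lie in [0, 100], got {th}")
    vals = pdff.map.values[pdff.mask_bool]
    if vals.size == 0:
        raise GeometryError("liver mask is empty")
    above = (vals >= th) if inclusive else (vals > th)
    return 100.0 * float(above.sum()) / vals.size


@dataclass
class VolumetricResult:
    """Per subject-timepoint LV% at each declared threshold."""

    subject_id: str
    timepoint: str
    thresholds: tuple[float, ...]
    lv_percent: tuple[float, ...]
    liver_volume_ml: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.lv_percent)
        if lv.min() < 0 or lv.max() > 100:
            raise ValueError("LV% values must lie in [0, 100]")
        order = np.argsort(self.thresholds)
        if np.any(np.diff(lv[order]) > 1e-12):
            raise ValueError("LV% must be non-increasing in the threshold")


def volumetric_result(
    pdff: PDFFMap,
    thresholds: tuple[float, ...],
    subject_id: str = "",
    timepoint: str = "",
    inclusive: bool = False,
) -> VolumetricResult:
    lv = tuple(lv_percent_above(pdff, th, inclusive) for th in thresholds)
    return VolumetricResult(
        subject_id=subject_id,
        timepoint=timepoint,
        thresholds=tuple(float(t) for t in thresholds),
        lv_percent=lv,
        liver_volume_ml=pdff.liver_volume_ml,
    )


def paired_changes(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-subject change and percent change of one measure between timepoints.

    ``table`` is the long-format cohort table with columns ``subject_id``,
    ``arm``, ``timepoint`` (baseline / week8) and the measure column. Change
    is week8 - baseline; percent change is 100 * change / baseline, left NaN
    (and counted in ``df.attrs['n_undefined_percent']``) when the baseline
    is zero. Raises if any subject misses a timepoint.
    """
    if measure not in table.columns:
        raise KeyError(f"measure column {measure!r} not in table")
    wide = table.pivot_table(
        index=["subject_id", "arm"], columns="timepoint", values=measure, aggfunc="first"
    )
    for tp in (BASELINE, WEEK8):
        if tp not in wide.columns:
            raise ValueError(f"table has no {tp!r} rows for measure {measure!r}")
        missing = wide.index[wide[tp].isna()].get_level_values("subject_id").tolist()
        if missing:
            raise ValueError(f"subjects missing {tp} for {measure!r}: {missing}")
    out = wide.reset_index()[["subject_id", "arm"]]
    out["measure"] = measure
    out["baseline"] = wide[BASELINE].to_numpy()
    out["week8"] = wide[WEEK8].to_numpy()
    out["change"] = out["week8"] - out["baseline"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["change"].to_numpy() / out["baseline"].to_numpy()
    zero_base = out["baseline"].to_numpy() == 0
    pct = np.where(zero_base, np.nan, pct)
    out["percent_change"] = pct
    out.attrs["n_undefined_percent"] = int(zero_base.sum())
    return out
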