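"""Threshold calibration against negative controls and area-ratio statistics.

The assay's core statistic is the reporter ratio: eGFP-positive pixel area
divided by nuclei-positive pixel area within the analyzed region.  The
reporter threshold is not fixed but *calibrated to the negative control*:
tau is a high quantile (default 0.999) of the pooled reporter intensities of
PBS-treated control images, so that at most ~0.1% of control pixels count
as positive and control ratios sit at ~zero.  Nuclei area uses a per-image
Otsu threshold on the nuclei channel within the mask.

Positivity uses the strict comparison ``reporter > tau`` so that the
all-zero control case yields exactly zero positive pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .image_io import Micrograph, ResultRow
from .segmentation import SEGMENT_LABELS, RingPartition, SpheroidMask


class CalibrationError(ValueError):
    """No usable negative-control images for threshold calibration."""


@dataclass(frozen=True)
class ThresholdCalibration:
    """Reporter-intensity threshold calibrated on pooled control pixels."""

    tau: float
    control_quantile: float
    n_control_pixels: int
    control_image_ids: tuple = ()

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "control_quantile": self.control_quantile,
            "n_control_pixels": self.n_control_pixels,
            "control_image_ids": list(self.control_image_ids),
        }


@dataclass(frozen=True)
class SegmentQuant:
    """Per-segment eGFP area, nuclei area and their ratio.

    ``ratio`` is None (missing, never 0) when the nuclei area vanishes.
    """

    segment: str
    area_gfp_px: int
    area_nuclei_px: int

    @property
    def ratio(self) -> Optional[float]:
        if self.area_nuclei_px == 0:
            return None
        return self.area_gfp_px / self.area_nuclei_px


def calibrate_threshold(
    controls: Sequence[Micrograph],
    masks: Sequence[SpheroidMask],
    control_quantile: float = 0.999,
) -> ThresholdCalibration:
    """tau = the control_quantile quantile of pooled control reporter pixels.

    Pools the reporter intensities of all control images restricted to their
    analyzed masks (central plane for stacks) and takes the empirical
    quantile with the inverted-CDF (lower order statistic) convention.
    Pooling is by pixel, so duplicated identical controls leave tau
    unchanged.
    """
    if not 0 < control_quantile < 1:
        raise ValueError(f"control_quantile must be in (0,1), got {control_quantile}")
    ctrl = [(m, k) for m, k in zip(controls, masks) if m.is_control]
    if not ctrl:
        raise CalibrationError("no control images (is_control=True) supplied")
    pools: List[np.ndarray] = []
    ids = []
    for m, sm in ctrl:
        plane = m.plane(sm.plane_index)
        pools.append(plane.reporter[sm.mask].astype(float))
        ids.append(m.image_id)
        sat = float(np.mean(plane.reporter[sm.mask] >= 65535))
        if sat > 0.01:
            warnings.warn(
                f"control {m.image_id or '<unnamed>'}: {sat:.1%} saturated pixels",
                stacklevel=2,
            )
    pooled = np.concatenate(pools)
    if pooled.size == 0:
        raise CalibrationError("control masks contain no pixels")
    tau = float(np.quantile(pooled, control_quantile, method="inverted_cdf"))
    return ThresholdCalibration(
        tau=tau,
        control_quantile=control_quantile,
        n_control_pixels=int(pooled.size),
        control_image_ids=tuple(ids),
    )


def otsu_nuclei_rule(nuclei_plane: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Default nuclei-positivity rule: Otsu threshold within the mask."""
    vals = nuclei_plane[mask].astype(float)
    if vals.size == 0 or vals.max() == vals.min():
        return np.zeros(mask.shape, dtype=bool)
    tau = threshold_otsu(vals)
    return mask & (nuclei_plane > tau)


NucleiRule = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _positive_maps(
    micrograph: Micrograph,
    mask: SpheroidMask,
    calibration: ThresholdCalibration,
    nuclei_rule: NucleiRule,
):
    plane = micrograph.plane(mask.plane_index)
    gfp = mask.mask & (plane.reporter > calibration.tau)
    nuc = nuclei_rule(plane.nuclei, mask.mask)
    return gfp, nuc


def quantify_image(
    micrograph: Micrograph,
    mask: SpheroidMask,
    calibration: ThresholdCalibration,
    nuclei_rule: NucleiRule = otsu_nuclei_rule,
) -> SegmentQuant:
    """Whole-mask reporter ratio for one image (segment label 'whole')."""
    gfp, nuc = _positive_maps(micrograph, mask, calibration, nuclei_rule)
    return SegmentQuant("whole", int(gfp.sum()), int(nuc.sum()))


def quantify_segments(
    micrograph: Micrograph,
    mask: SpheroidMask,
    partition: RingPartition,
    calibration: ThresholdCalibration,
    nuclei_rule: NucleiRule = otsu_nuclei_rule,
) -> Dict[str, SegmentQuant]:
    """Reporter ratio per concentric segment plus the whole mask.

    Segment GFP (and nuclei) areas sum exactly to the whole-mask areas
    because the segments tile the mask.
    """
    gfp, nuc = _positive_maps(micrograph, mask, calibration, nuclei_rule)
    out: Dict[str, SegmentQuant] = {
        "whole": SegmentQuant("whole", int(gfp.sum()), int(nuc.sum()))
    }
    for name, lab in SEGMENT_LABELS.items():
        sel = partition.labels == lab
        out[name] = SegmentQuant(name, int(gfp[sel].sum()), int(nuc[sel].sum()))
    return out


def quants_to_rows(
    micrograph: Micrograph, quants: Dict[str, SegmentQuant] | Sequence[SegmentQuant]
) -> List[ResultRow]:
    if isinstance(quants, dict):
        quants = list(quants.values())
    return [
        ResultRow(
            image_id=micrograph.image_id,
            group=micrograph.group,
            dose_ng_per_ul=micrograph.dose_ng_per_ul,
            segment=q.segment,
            area_gfp_px=q.area_gfp_px,
            area_nuclei_px=q.area_nuclei_px,
            ratio=q.ratio,
        )
        for q in quants
    ]


def dose_response(rows: pd.DataFrame, segment: str = "whole") -> pd.DataFrame:
    """Mean ratio ± dispersion per (group, dose) for one segment.

    Returns a table with columns group, dose_ng_per_ul, mean, sd, sem, n,
    ordered by group then dose.  Missing ratios (NaN) are dropped from the
    statistics with the retained count in ``n``.
    """
    df = rows[rows["segment"] == segment].copy()
    if df.empty:
        raise ValueError(f"no rows with segment {segment!r}")

    def agg(g: pd.Series) -> pd.Series:
        vals = g.dropna().to_numpy(dtype=float)
        n = vals.size
        mean = vals.mean() if n else math.nan
        sd = float(np.std(vals, ddof=1)) if n > 1 else math.nan
        return pd.Series(
            {"mean": mean, "sd": sd, "sem": sd / math.sqrt(n) if n > 1 else math.nan,
             "n": n}
        )

    out = (
        df.groupby(["group", "dose_ng_per_ul"], sort=True)["ratio"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out.sort_values(["group", "dose_ng_per_ul"], kind="mergesort").reset_index(
        drop=True
    )


def segment_profile(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean ratio ± dispersion per (group, segment), outer→core order."""
    order = {"whole": 0, "outer": 1, "mid": 2, "inner": 3, "core": 4}
    df = rows[rows["segment"] != "whole"].copy()
    if df.empty:
        df = rows.copy()
    recs = []
    for (group, segment), g in df.groupby(["group", "segment"], sort=True):
        vals = g["ratio"].dropna().to_numpy(dtype=float)
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else math.nan
        recs.append(
            {"group": group, "segment": segment,
             "mean": vals.mean() if n else math.nan, "sd": sd,
             "sem": sd / math.sqrt(n) if n > 1 else math.nan, "n": n}
        )
    out = pd.DataFrame(recs)
    out["_rank"] = out["segment"].map(order)
    return (
        out.sort_values(["group", "_rank"], kind="mergesort")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
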