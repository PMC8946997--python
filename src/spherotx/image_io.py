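"""Image and table I/O with validated metadata.

A :class:`Micrograph` bundles the two acquisition channels of the assay —
a nuclear stain (DRAQ5-like, far red) and the eGFP reporter — with physical
pixel size and experimental annotations (group, dose, control flag).

TIFF page convention (fixed dialect, declared in the JSON sidecar):
channel-major within z, i.e. pages are ordered z0c0, z0c1, z1c0, z1c1, ...
with c0 = nuclei, c1 = reporter.  Arrays are (z, y, x) for stacks and (y, x)
for single planes.  Pixel (i, j) spans physical coordinates centred at
(i * pixel_size_um, j * pixel_size_um), 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

PAGE_ORDER = "z-major, channel-minor (z0c0, z0c1, z1c0, ...); c0=nuclei, c1=reporter"

SEGMENT_ORDER = ("whole", "outer", "mid", "inner", "core")
_SEGMENT_RANK = {name: i for i, name in enumerate(SEGMENT_ORDER)}

RESULT_COLUMNS = [
    "image_id",
    "group",
    "dose_ng_per_ul",
    "segment",
    "area_gfp_px",
    "area_nuclei_px",
    "ratio",
]


class FormatError(ValueError):
    """Raised when a file does not match the expected image layout."""


@dataclass
class Micrograph:
    """Two-channel fluorescence micrograph with acquisition metadata.

    ``nuclei`` and ``reporter`` are same-shaped non-negative intensity
    arrays, either (y, x) or (z, y, x).
    """

    nuclei: np.ndarray
    reporter: np.ndarray
    pixel_size_um: float
    z_step_um: Optional[float] = None
    group: str = ""
    dose_ng_per_ul: float = 0.0
    is_control: bool = False
    image_id: str = ""

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei)
        self.reporter = np.asarray(self.reporter)
        if self.nuclei.shape != self.reporter.shape:
            raise ValueError(
                f"channel shapes differ: nuclei {self.nuclei.shape} vs "
                f"reporter {self.reporter.shape}"
            )
        if self.nuclei.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D arrays, got ndim={self.nuclei.ndim}")
        for name, arr in (("nuclei", self.nuclei), ("reporter", self.reporter)):
            if not np.all(np.isfinite(arr.astype(float, copy=False))):
                raise ValueError(f"{name} channel contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} channel contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.is_3d:
            if self.z_step_um is not None and not self.z_step_um > 0:
                raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.dose_ng_per_ul < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose_ng_per_ul}")
        if self.is_control and self.dose_ng_per_ul != 0:
            raise ValueError("is_control=True requires dose_ng_per_ul == 0")

    @property
    def is_3d(self) -> bool:
        return self.nuclei.ndim == 3

    @property
    def n_planes(self) -> int:
        return self.nuclei.shape[0] if self.is_3d else 1

    def plane(self, index: int) -> "Micrograph":
        """Single optical plane as a 2D Micrograph (identity for 2D input)."""
        if not self.is_3d:
            if index != 0:
                raise IndexError("2D micrograph has only plane 0")
            return self
        return replace(
            self,
            nuclei=self.nuclei[index],
            reporter=self.reporter[index],
            z_step_um=None,
        )


def write_micrograph(micrograph: Micrograph, path: Union[str, Path]) -> Path:
    """Write a Micrograph as a multi-page 16-bit grayscale TIFF + JSON sidecar.

    Pages follow :data:`PAGE_ORDER`.  Intensities are stored as-is when the
    arrays are already uint16, otherwise cast (caller is responsible for
    scaling into range first).
    """
    path = Path(path)
    nuc = micrograph.nuclei
    rep = micrograph.reporter
    if nuc.ndim == 2:
        nuc = nuc[None]
        rep = rep[None]
    pages = np.empty((nuc.shape[0] * 2,) + nuc.shape[1:], dtype=np.uint16)
    pages[0::2] = nuc.astype(np.uint16, copy=False)
    pages[1::2] = rep.astype(np.uint16, copy=False)
    tifffile.imwrite(path, pages, photometric="minisblack")

    sidecar = {
        "page_order": PAGE_ORDER,
        "n_channels": 2,
        "n_planes": int(micrograph.n_planes),
        "pixel_size_um": micrograph.pixel_size_um,
        "z_step_um": micrograph.z_step_um,
        "group": micrograph.group,
        "dose_ng_per_ul": micrograph.dose_ng_per_ul,
        "is_control": micrograph.is_control,
        "image_id": micrograph.image_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_micrograph(
    path: Union[str, Path], metadata: Optional[dict] = None
) -> Micrograph:
    """Read a two-channel TIFF written in the package's page convention.

    ``metadata`` overrides or supplies the sidecar fields (``pixel_size_um``
    is required from one of the two).  A page count that is not an even
    multiple of two channels is a :class:`FormatError`.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a stack of grayscale pages")

    meta: dict = {}
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta.update(json.loads(sidecar_path.read_text()))
    if metadata:
        meta.update(metadata)

    n_channels = int(meta.get("n_channels", 2))
    if n_channels != 2:
        raise FormatError(
            f"{path}: pipeline expects 2 channels (nuclei, reporter), "
            f"metadata declares {n_channels}"
        )
    if pages.shape[0] % 2 != 0:
        raise FormatError(
            f"{path}: {pages.shape[0]} pages not divisible into 2 channels"
        )
    nuc = pages[0::2]
    rep = pages[1::2]
    if nuc.shape[0] == 1:
        nuc, rep = nuc[0], rep[0]

    if "pixel_size_um" not in meta:
        raise ValueError(f"{path}: pixel_size_um missing from sidecar and metadata")
    return Micrograph(
        nuclei=nuc,
        reporter=rep,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=meta.get("z_step_um"),
        group=str(meta.get("group", "")),
        dose_ng_per_ul=float(meta.get("dose_ng_per_ul", 0.0)),
        is_control=bool(meta.get("is_control", False)),
        image_id=str(meta.get("image_id", path.stem)),
    )


@dataclass(frozen=True)
class ResultRow:
    """One quantification record: one image, one segment (or 'whole')."""

    image_id: str
    group: str
    dose_ng_per_ul: float
    segment: str
    area_gfp_px: int
    area_nuclei_px: int
    ratio: Optional[float]

    def __post_init__(self) -> None:
        if self.segment not in _SEGMENT_RANK:
            raise ValueError(
                f"segment must be one of {SEGMENT_ORDER}, got {self.segment!r}"
            )
        if self.area_gfp_px < 0 or self.area_nuclei_px < 0:
            raise ValueError("areas must be >= 0")
        if self.area_nuclei_px > 0 and self.ratio is not None:
            expected = self.area_gfp_px / self.area_nuclei_px
            if abs(self.ratio - expected) > 1e-9 * max(1.0, expected):
                raise ValueError(
                    f"ratio {self.ratio} inconsistent with areas "
                    f"{self.area_gfp_px}/{self.area_nuclei_px}"
                )


def rows_to_frame(rows: Sequence[ResultRow]) -> pd.DataFrame:
    """Canonical result table: sorted by image_id then whole→outer→…→core."""
    if not rows:
        raise ValueError("empty result collection")
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "group": r.group,
                "dose_ng_per_ul": r.dose_ng_per_ul,
                "segment": r.segment,
                "area_gfp_px": r.area_gfp_px,
                "area_nuclei_px": r.area_nuclei_px,
                "ratio": np.nan if r.ratio is None else r.ratio,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )
    df["_rank"] = df["segment"].map(_SEGMENT_RANK)
    df = df.sort_values(["image_id", "_rank"], kind="mergesort").drop(columns="_rank")
    return df.reset_index(drop=True)


def write_results(rows: Sequence[ResultRow], path: Union[str, Path]) -> Path:
    """Write ResultRows as CSV with fixed header and deterministic order."""
    path = Path(path)
    df = rows_to_frame(rows)
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df


def write_ground_truth(cells: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Ground-truth cell table as CSV (cell_id, x_um, ..., is_positive)."""
    cols = [
        "cell_id", "x_um", "y_um", "z_um", "radius_um",
        "cell_type", "depth_um", "is_positive",
    ]
    cells.to_csv(path, index=False, columns=cols, float_format="%.17g")
    return Path(path)
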