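"""Shared fixtures: generated image batches and geometry oracles.

Batches are module-scoped and reused across tests so the (comparatively
expensive) 3D rendering happens once per condition.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

import spherotx as st
from spherotx.quantify import calibrate_threshold
from spherotx.segmentation import find_spheroid_mask, ring_width_from_group

MASK_SIGMA = 6.0  # pipeline-default mask smoothing used throughout the suite


class SpheroidBatch:
    """Treated + control spheroids with masks, wall width and calibration."""

    def __init__(self, cell_type, radius_um, n_treated, n_controls, seed0):
        kw = dict(cell_types=(cell_type,), spheroid_radius_um=radius_um)
        self.configs = [
            st.GeneratorConfig(seed=seed0 + i, **kw) for i in range(n_treated)
        ]
        self.treated = [st.generate_spheroid(c) for c in self.configs]
        self.controls = [
            st.generate_spheroid(
                st.GeneratorConfig(
                    seed=seed0 + 60 + i, is_control=True, dose_ng_per_ul=0.0, **kw
                )
            )
            for i in range(n_controls)
        ]
        self.masks = [find_spheroid_mask(m, sigma=MASK_SIGMA) for m, _ in self.treated]
        self.control_masks = [
            find_spheroid_mask(m, sigma=MASK_SIGMA) for m, _ in self.controls
        ]
        self.wall = ring_width_from_group(self.masks + self.control_masks)
        self.calibration = calibrate_threshold(
            [m for m, _ in self.controls], self.control_masks
        )


@pytest.fixture(scope="session")
def shallow_batch():
    """Shallow penetration: λ = 5 µm ≤ wall/2 — the peripheral regime."""
    ct = replace(st.KERATINOCYTE_LIKE, p_surface=0.5, penetration_length_um=5.0)
    return SpheroidBatch(ct, radius_um=80.0, n_treated=5, n_controls=2, seed0=100)


@pytest.fixture(scope="session")
def uniform_batch():
    """Depth-independent positivity: λ = ∞ — the pervasive regime."""
    ct = replace(st.KERATINOCYTE_LIKE, p_surface=0.5, penetration_length_um=math.inf)
    return SpheroidBatch(ct, radius_um=120.0, n_treated=5, n_controls=2, seed0=300)


@pytest.fixture(scope="session")
def default_spheroid():
    """One default keratinocyte-like spheroid with mask (λ = 10 µm)."""
    mg, gt = st.generate_spheroid(st.GeneratorConfig(seed=1))
    return mg, gt, find_spheroid_mask(mg, sigma=MASK_SIGMA)


def geometry_oracle_ratio(micrograph, gt, mask, tau, nuclei_tau):
    """Whole-image reporter ratio predicted from ground-truth geometry alone.

    Rasterizes, on the analyzed plane, the union of above-threshold blob
    cross-sections implied by the generator's intensity model: a Gaussian
    blob of peak I and width σ exceeds a threshold t out to radius
    σ·sqrt(2·ln(I/t)), shrinking with out-of-plane offset.  No rendering,
    no noise — an independent prediction of the measured area ratio.
    """
    px = micrograph.pixel_size_um
    zs = micrograph.z_step_um or px
    nz = micrograph.nuclei.shape[0] if micrograph.is_3d else 1
    extent = micrograph.nuclei.shape[-1] * px
    z_plane_um = mask.plane_index * zs - extent / 2.0

    shape = mask.mask.shape
    yy, xx = np.mgrid[: shape[0], : shape[1]]

    def union_area(cells, sigma_factor, peak, thresh):
        out = np.zeros(shape, bool)
        r2max_um = 2.0 * np.log(peak / thresh)  # in units of sigma^2
        if r2max_um <= 0:
            return 0
        for _, c in cells.iterrows():
            sig = sigma_factor * c.radius_um
            dz = c.z_um - z_plane_um
            rho2 = r2max_um * sig**2 - dz**2  # isotropic sigma
            if rho2 <= 0:
                continue
            r_px = math.sqrt(rho2) / px
            cy = (c.y_um + extent / 2.0) / px
            cx = (c.x_um + extent / 2.0) / px
            out |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        return int((out & mask.mask).sum())

    cells = gt.cells
    a_nuc = union_area(cells, 0.8, 8000.0, nuclei_tau)
    a_gfp = union_area(cells[cells.is_positive], 0.7, 600.0, max(tau, 1.0))
    return a_gfp / a_nuc if a_nuc else float("nan")
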