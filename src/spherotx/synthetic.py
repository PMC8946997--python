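"""Synthetic two-channel confocal data with known ground truth.

Emulates the statistical structure of the assay's micrographs — monolayer
fields of mixed cell types, compact or loose monoculture spheroids, and
triculture spheroids with a fibroblast core, keratinocyte shell and
melanoma surface patches — so that every downstream stage (mask detection,
ring partition, threshold calibration, area-ratio quantification,
inference) can be tested against a known answer.

Model
-----
* Cells are hard spheres placed by dart-throwing (random sequential
  addition) inside the spheroid ball or the monolayer field until a target
  packing fraction / cell count is reached.
* Each cell is transfection-positive with probability
  ``p_surface * exp(-depth / lambda)`` where ``depth`` is the distance from
  the spheroid surface and ``lambda`` the penetration length; a monolayer
  has no depth term but a dose-dependent multiplier on ``p_surface``.
* The nuclei channel renders a Gaussian blob per cell nucleus; the reporter
  channel a larger cytoplasm-scale blob per positive cell.  Both channels
  carry a constant background, Poisson shot noise and additive Gaussian
  read noise, and are emitted as 16-bit stacks.

Identical config + identical seed give bit-identical images and ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import Micrograph

MAX_PACKING = 0.74  # FCC bound; dart-throwing jams well below this


class PackingError(RuntimeError):
    """Raised when dart-throwing cannot reach the requested packing."""


def hill_dose_scale(k_half_ng_per_ul: float = 2.5) -> Callable[[float], float]:
    """Saturating dose→multiplier map d/(d + k); 0 at dose 0, →1 at high dose."""

    def scale(dose: float) -> float:
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        return dose / (dose + k_half_ng_per_ul)

    return scale


@dataclass(frozen=True)
class CellTypeParams:
    """Phenotype parameters for one cell population.

    ``packing_fraction`` is the target cell-volume (or 2D cell-area)
    fraction; "compact" phenotypes pack densely with smaller nuclei, the
    melanoma-like phenotype loosely with larger nuclei.  ``p_surface`` is
    the positivity probability at depth 0 and ``penetration_length_um`` the
    exponential decay length (``inf`` = depth-independent positivity).
    """

    name: str
    cell_radius_um: float
    packing_fraction: float
    p_surface: float
    penetration_length_um: float = math.inf

    def __post_init__(self) -> None:
        if not self.cell_radius_um > 0:
            raise ValueError(f"cell_radius_um must be > 0, got {self.cell_radius_um}")
        if not 0 < self.packing_fraction <= MAX_PACKING:
            raise ValueError(
                f"packing_fraction must be in (0, {MAX_PACKING}], "
                f"got {self.packing_fraction}"
            )
        if not 0 <= self.p_surface <= 1:
            raise ValueError(f"p_surface must be in [0, 1], got {self.p_surface}")
        if not self.penetration_length_um > 0:
            raise ValueError(
                f"penetration_length_um must be > 0 (inf allowed), "
                f"got {self.penetration_length_um}"
            )


# Phenotype presets (module defaults, not measured values): fibroblast-like
# and keratinocyte-like pack densely with small nuclei; melanoma-like has
# larger nuclei and a sparser arrangement with depth-pervasive positivity.
FIBROBLAST_LIKE = CellTypeParams("fibroblast", 5.0, 0.25, 0.05, 10.0)
KERATINOCYTE_LIKE = CellTypeParams("keratinocyte", 6.0, 0.25, 0.30, 10.0)
MELANOMA_LIKE = CellTypeParams("melanoma", 8.0, 0.15, 0.60, math.inf)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic acquisition.

    Modes: ``monolayer`` (single-plane field) or ``spheroid`` (3D stack);
    architectures: ``mono`` (first cell type only) or ``triculture``
    (fibroblast core / keratinocyte shell / melanoma surface patches, in
    ``cell_types`` order).
    """

    mode: str = "spheroid"
    architecture: str = "mono"
    cell_types: Tuple[CellTypeParams, ...] = (KERATINOCYTE_LIKE,)
    spheroid_radius_um: float = 80.0
    # triculture geometry
    core_radius_fraction: float = 0.55
    n_patches: int = 6
    patch_half_angle_deg: float = 25.0
    # monolayer geometry
    field_size_um: float = 400.0
    n_cells_monolayer: int = 450
    mixing_proportions: Optional[Tuple[float, ...]] = None
    # treatment
    dose_ng_per_ul: float = 10.0
    is_control: bool = False
    dose_scale: Optional[Callable[[float], float]] = None
    # imaging / intensity model
    pixel_size_um: float = 2.0
    z_step_um: Optional[float] = None  # None -> isotropic (= pixel size)
    nuclei_intensity_mean: float = 8000.0
    reporter_intensity_mean: float = 600.0
    background_mean: float = 100.0
    gaussian_noise_sd: float = 10.0
    shot_noise: bool = True
    depth_attenuation_length_um: Optional[float] = None  # optional, default off
    max_rejections: int = 100_000
    seed: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("monolayer", "spheroid"):
            raise ValueError(f"mode must be monolayer|spheroid, got {self.mode!r}")
        if self.architecture not in ("mono", "triculture"):
            raise ValueError(
                f"architecture must be mono|triculture, got {self.architecture!r}"
            )
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if self.architecture == "triculture" and self.mode == "spheroid":
            if len(self.cell_types) != 3:
                raise ValueError(
                    "triculture spheroid needs exactly 3 cell types "
                    "(core, shell, surface patches)"
                )
            if not 0 < self.core_radius_fraction <= 1:
                raise ValueError(
                    f"core_radius_fraction must be in (0, 1], "
                    f"got {self.core_radius_fraction}"
                )
            if self.n_patches < 0:
                raise ValueError("n_patches must be >= 0")
            if not 0 < self.patch_half_angle_deg <= 90:
                raise ValueError("patch_half_angle_deg must be in (0, 90]")
        for name, val in (
            ("spheroid_radius_um", self.spheroid_radius_um),
            ("field_size_um", self.field_size_um),
            ("pixel_size_um", self.pixel_size_um),
        ):
            if not val > 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if self.z_step_um is not None and not self.z_step_um > 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.dose_ng_per_ul < 0:
            raise ValueError("dose must be >= 0")
        if self.mixing_proportions is not None:
            if len(self.mixing_proportions) != len(self.cell_types):
                raise ValueError("mixing_proportions length must match cell_types")
            if any(p < 0 for p in self.mixing_proportions) or sum(
                self.mixing_proportions
            ) <= 0:
                raise ValueError("mixing_proportions must be >= 0 with positive sum")

    @property
    def effective_z_step_um(self) -> float:
        return self.z_step_um if self.z_step_um is not None else self.pixel_size_um

    def dose_multiplier(self) -> float:
        """Multiplier on p_surface from treatment dose (1 for spheroid default)."""
        if self.is_control:
            return 0.0
        if self.dose_scale is not None:
            return float(self.dose_scale(self.dose_ng_per_ul))
        if self.mode == "monolayer":
            return hill_dose_scale()(self.dose_ng_per_ul)
        return 1.0


@dataclass
class GroundTruth:
    """The generator's hidden truth: one record per placed cell.

    ``cells`` columns: cell_id, x_um, y_um, z_um, radius_um, cell_type,
    depth_um, is_positive.  Coordinates are relative to the spheroid centre
    (spheroid mode) or the field origin (monolayer mode).
    """

    cells: pd.DataFrame
    spheroid_radius_um: Optional[float]
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_positive(self) -> int:
        return int(self.cells["is_positive"].sum())

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_cells if self.n_cells else float("nan")

    def positive_fraction_by_type(self) -> Dict[str, float]:
        return self.cells.groupby("cell_type")["is_positive"].mean().to_dict()

    def ring_positive_fractions(
        self, wall_um: float, n_segments: int = 4
    ) -> Dict[str, float]:
        """Positive fraction of cells per depth band (outer→core geometry)."""
        names = ["outer", "mid", "inner", "core"][: n_segments - 1] + ["core"]
        edges = [i * wall_um for i in range(n_segments)] + [math.inf]
        out: Dict[str, float] = {}
        d = self.cells["depth_um"].to_numpy()
        pos = self.cells["is_positive"].to_numpy()
        for i in range(n_segments):
            sel = (d >= edges[i]) & (d < edges[i + 1])
            out[names[i] if i < n_segments - 1 else "core"] = (
                float(pos[sel].mean()) if sel.any() else float("nan")
            )
        return out


# ---------------------------------------------------------------------------
# hard-sphere placement


class _Grid:
    """Spatial hash for O(1) hard-sphere overlap queries."""

    def __init__(self, cell_size: float) -> None:
        self.h = cell_size
        self.buckets: Dict[Tuple[int, ...], List[Tuple[np.ndarray, float]]] = {}

    def _key(self, p: np.ndarray) -> Tuple[int, ...]:
        return tuple(int(math.floor(c / self.h)) for c in p)

    def fits(self, p: np.ndarray, r: float) -> bool:
        k = self._key(p)
        rng = range(-1, 2)
        dim = len(k)
        for off in np.ndindex(*(3,) * dim):
            kk = tuple(k[i] + off[i] - 1 for i in range(dim))
            for q, rq in self.buckets.get(kk, ()):
                d = p - q
                if float(d @ d) < (r + rq) ** 2:
                    return False
        return True

    def add(self, p: np.ndarray, r: float) -> None:
        self.buckets.setdefault(self._key(p), []).append((p, r))


def _dart_throw(
    rng: np.random.Generator,
    sampler: Callable[[np.random.Generator], np.ndarray],
    radius: float,
    n_target: int,
    grid: _Grid,
    max_rejections: int,
    context: str,
) -> List[np.ndarray]:
    placed: List[np.ndarray] = []
    for i in range(n_target):
        for _ in range(max_rejections):
            p = sampler(rng)
            if grid.fits(p, radius):
                grid.add(p, radius)
                placed.append(p)
                break
        else:
            raise PackingError(
                f"{context}: placed only {i}/{n_target} cells "
                f"({i / n_target:.1%} of target) after {max_rejections} "
                f"rejections; lower packing_fraction"
            )
    return placed


def _ball_sampler(r_max: float, r_min: float = 0.0):
    """Uniform sampler over a (hollow) ball r_min <= |x| <= r_max."""

    def sample(rng: np.random.Generator) -> np.ndarray:
        u = rng.random()
        rad = (r_min**3 + u * (r_max**3 - r_min**3)) ** (1.0 / 3.0)
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        return rad * v

    return sample


def _cap_sampler(r_max: float, r_min: float, axes: np.ndarray, half_angle: float):
    """Uniform sampler over spherical-cap patches around the given axes."""

    cos_a = math.cos(half_angle)

    def sample(rng: np.random.Generator) -> np.ndarray:
        axis = axes[rng.integers(len(axes))]
        u = rng.random()
        rad = (r_min**3 + u * (r_max**3 - r_min**3)) ** (1.0 / 3.0)
        # direction uniform on the cap around +z, then rotated onto axis
        cz = cos_a + rng.random() * (1.0 - cos_a)
        sz = math.sqrt(max(0.0, 1.0 - cz * cz))
        phi = rng.random() * 2.0 * math.pi
        d = np.array([sz * math.cos(phi), sz * math.sin(phi), cz])
        d = _rotate_z_to(axis) @ d
        return rad * d

    return sample


def _rotate_z_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the given unit axis."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.allclose(v, 0):
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _square_sampler(low: float, high: float):
    def sample(rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(low, high, size=2)

    return sample


# ---------------------------------------------------------------------------
# positivity and rendering


def _draw_positivity(
    rng: np.random.Generator,
    depth: np.ndarray,
    ct: CellTypeParams,
    dose_mult: float,
) -> np.ndarray:
    lam = ct.penetration_length_um
    decay = np.ones_like(depth) if math.isinf(lam) else np.exp(-depth / lam)
    p = np.clip(ct.p_surface * dose_mult * decay, 0.0, 1.0)
    return rng.random(depth.shape) < p


def _render_channel(
    shape: Tuple[int, ...],
    centers_px: np.ndarray,
    sigmas_px: np.ndarray,
    intensity_mean: float,
) -> np.ndarray:
    """Sum of Gaussian blobs with per-cell sigma (grouped by sigma class).

    ``sigmas_px`` has one per-axis sigma row per cell; blobs of equal sigma
    are rendered with a single separable Gaussian filter over an impulse
    image, scaled so each blob peaks at ``intensity_mean``.
    """
    img = np.zeros(shape, dtype=np.float64)
    if len(centers_px) == 0:
        return img
    keys = [tuple(np.round(s, 3)) for s in sigmas_px]
    for key in sorted(set(keys)):
        sel = [i for i, k in enumerate(keys) if k == key]
        impulses = np.zeros(shape, dtype=np.float64)
        idx = np.round(centers_px[sel]).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        amp = intensity_mean * float(np.prod([math.sqrt(2 * math.pi) * s for s in key]))
        np.add.at(impulses, tuple(idx.T), amp)
        img += ndimage.gaussian_filter(impulses, sigma=key, truncate=3.5)
    return img


def _apply_noise(
    signal: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    img = signal + config.background_mean
    if config.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if config.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, config.gaussian_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def _build_ground_truth(
    records: List[dict], spheroid_radius: Optional[float], seed: int
) -> GroundTruth:
    cols = ["cell_id", "x_um", "y_um", "z_um", "radius_um", "cell_type",
            "depth_um", "is_positive"]
    df = pd.DataFrame(records, columns=cols)
    return GroundTruth(cells=df, spheroid_radius_um=spheroid_radius, seed=seed)


def _spheroid_cells(
    config: GeneratorConfig, rng: np.random.Generator
) -> List[dict]:
    """Place all cells of a spheroid (mono or triculture), draw positivity."""
    R = config.spheroid_radius_um
    dose_mult = config.dose_multiplier()
    max_r = max(ct.cell_radius_um for ct in config.cell_types)
    grid = _Grid(2.0 * max_r)
    records: List[dict] = []

    def place(ct: CellTypeParams, sampler, n_target: int, context: str) -> None:
        centers = _dart_throw(
            rng, sampler, ct.cell_radius_um, n_target, grid,
            config.max_rejections, context,
        )
        if not centers:
            return
        c = np.array(centers)
        depth = R - np.linalg.norm(c, axis=1)
        pos = _draw_positivity(rng, depth, ct, dose_mult)
        for j in range(len(c)):
            records.append(
                dict(cell_id=len(records), x_um=c[j, 0], y_um=c[j, 1],
                     z_um=c[j, 2], radius_um=ct.cell_radius_um,
                     cell_type=ct.name, depth_um=float(depth[j]),
                     is_positive=bool(pos[j]))
            )

    if config.architecture == "mono":
        ct = config.cell_types[0]
        n = int(round(ct.packing_fraction * (R / ct.cell_radius_um) ** 3))
        place(ct, _ball_sampler(max(R - ct.cell_radius_um, 0.0)), n, "spheroid")
        return records

    core_ct, shell_ct, surf_ct = config.cell_types
    f = config.core_radius_fraction
    r_core = f * R

    # surface patches first (they constrain the outermost shell)
    if config.n_patches > 0 and f < 1.0:
        t = 2.0 * surf_ct.cell_radius_um
        alpha = math.radians(config.patch_half_angle_deg)
        omega = config.n_patches * (1.0 - math.cos(alpha)) / 2.0
        v_patch = min(omega, 1.0) * (R**3 - (R - t) ** 3)
        n_m = int(round(surf_ct.packing_fraction * v_patch / surf_ct.cell_radius_um**3))
        axes = rng.standard_normal((config.n_patches, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        place(
            surf_ct,
            _cap_sampler(R - surf_ct.cell_radius_um, max(R - t, 0.0), axes, alpha),
            n_m, "triculture surface patches",
        )

    # keratinocyte-like shell
    if f < 1.0:
        v_shell = R**3 - r_core**3
        n_k = int(round(shell_ct.packing_fraction * v_shell / shell_ct.cell_radius_um**3))
        place(
            shell_ct,
            _ball_sampler(max(R - shell_ct.cell_radius_um, 0.0), r_core),
            n_k, "triculture shell",
        )

    # fibroblast-like core
    r_core_avail = r_core - core_ct.cell_radius_um
    if r_core_avail > 0:
        n_f = int(round(core_ct.packing_fraction * (r_core / core_ct.cell_radius_um) ** 3))
        place(core_ct, _ball_sampler(r_core_avail), n_f, "triculture core")
    return records


def _render_spheroid(
    config: GeneratorConfig, gt: GroundTruth, rng: np.random.Generator
) -> Micrograph:
    R = config.spheroid_radius_um
    margin = 4.0 * max(ct.cell_radius_um for ct in config.cell_types)
    extent = 2.0 * (R + margin)
    px, zs = config.pixel_size_um, config.effective_z_step_um
    nz = int(math.ceil(extent / zs))
    nxy = int(math.ceil(extent / px))
    shape = (nz, nxy, nxy)

    cells = gt.cells
    # physical (x,y,z) -> array (z,y,x); volume centred on the spheroid
    centers = np.column_stack(
        [
            (cells["z_um"] + extent / 2) / zs,
            (cells["y_um"] + extent / 2) / px,
            (cells["x_um"] + extent / 2) / px,
        ]
    )
    radii = cells["radius_um"].to_numpy()
    nuc_sig = np.column_stack([0.8 * radii / zs, 0.8 * radii / px, 0.8 * radii / px])
    rep_sig = np.column_stack([0.8 * radii / zs, 0.8 * radii / px, 0.8 * radii / px])

    nuc = _render_channel(shape, centers, nuc_sig, config.nuclei_intensity_mean)
    pos = cells["is_positive"].to_numpy()
    rep = _render_channel(
        shape, centers[pos], rep_sig[pos], config.reporter_intensity_mean
    )
    if config.depth_attenuation_length_um is not None:
        # optional imaging attenuation with distance from the surface
        zz, yy, xx = np.meshgrid(
            (np.arange(nz) + 0.5) * zs - extent / 2,
            (np.arange(nxy) + 0.5) * px - extent / 2,
            (np.arange(nxy) + 0.5) * px - extent / 2,
            indexing="ij",
        )
        depth = np.clip(R - np.sqrt(xx**2 + yy**2 + zz**2), 0, None)
        att = np.exp(-depth / config.depth_attenuation_length_um)
        nuc *= att
        rep *= att
    return Micrograph(
        nuclei=_apply_noise(nuc, config, rng),
        reporter=_apply_noise(rep, config, rng),
        pixel_size_um=px,
        z_step_um=zs,
        group=config.group or config.cell_types[0].name,
        dose_ng_per_ul=0.0 if config.is_control else config.dose_ng_per_ul,
        is_control=config.is_control,
    )


def generate_spheroid(config: GeneratorConfig) -> Tuple[Micrograph, GroundTruth]:
    """Generate a 3D spheroid stack (monoculture architecture) + ground truth."""
    if config.mode != "spheroid":
        raise ValueError("config.mode must be 'spheroid'")
    if config.architecture != "mono":
        return generate_triculture(config)
    rng = np.random.default_rng(config.seed)
    records = _spheroid_cells(config, rng)
    gt = _build_ground_truth(records, config.spheroid_radius_um, config.seed)
    return _render_spheroid(config, gt, rng), gt


def generate_triculture(config: GeneratorConfig) -> Tuple[Micrograph, GroundTruth]:
    """Generate a triculture spheroid: fibroblast core, keratinocyte shell,
    melanoma surface patches (cell_types order: core, shell, patches)."""
    if config.mode != "spheroid" or config.architecture != "triculture":
        raise ValueError("config must have mode='spheroid', architecture='triculture'")
    rng = np.random.default_rng(config.seed)
    records = _spheroid_cells(config, rng)
    gt = _build_ground_truth(records, config.spheroid_radius_um, config.seed)
    return _render_spheroid(config, gt, rng), gt


def _monolayer_type_counts(config: GeneratorConfig) -> List[int]:
    """Deterministic per-type counts by largest-remainder apportionment."""
    props = config.mixing_proportions
    if props is None:
        props = tuple([1.0] + [0.0] * (len(config.cell_types) - 1))
    total = sum(props)
    quotas = [config.n_cells_monolayer * p / total for p in props]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = sorted(
        range(len(quotas)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in range(config.n_cells_monolayer - sum(counts)):
        counts[remainders[i % len(counts)]] += 1
    return counts


def generate_monolayer(config: GeneratorConfig) -> Tuple[Micrograph, GroundTruth]:
    """Generate a single-plane monolayer field + ground truth.

    Positivity probability is ``dose_scale(dose) * p_surface`` per type,
    with no depth term; dose 0 (PBS control) gives probability 0.
    """
    if config.mode != "monolayer":
        raise ValueError("config.mode must be 'monolayer'")
    rng = np.random.default_rng(config.seed)
    L = config.field_size_um
    dose_mult = config.dose_multiplier()
    counts = _monolayer_type_counts(config)
    max_r = max(ct.cell_radius_um for ct in config.cell_types)
    grid = _Grid(2.0 * max_r)
    records: List[dict] = []
    for ct, n in zip(config.cell_types, counts):
        if n == 0:
            continue
        centers = _dart_throw(
            rng,
            _square_sampler(ct.cell_radius_um, L - ct.cell_radius_um),
            ct.cell_radius_um, n, grid, config.max_rejections,
            f"monolayer {ct.name}",
        )
        c = np.array(centers)
        depth = np.zeros(len(c))
        pos = _draw_positivity(rng, depth, ct, dose_mult)
        for j in range(len(c)):
            records.append(
                dict(cell_id=len(records), x_um=c[j, 0], y_um=c[j, 1], z_um=0.0,
                     radius_um=ct.cell_radius_um, cell_type=ct.name,
                     depth_um=0.0, is_positive=bool(pos[j]))
            )
    gt = _build_ground_truth(records, None, config.seed)

    px = config.pixel_size_um
    n_px = int(math.ceil(L / px))
    shape = (n_px, n_px)
    cells = gt.cells
    centers_px = np.column_stack([cells["y_um"] / px, cells["x_um"] / px])
    radii = cells["radius_um"].to_numpy()
    nuc_sig = np.column_stack([0.8 * radii / px, 0.8 * radii / px])
    rep_sig = np.column_stack([0.7 * radii / px, 0.7 * radii / px])
    nuc = _render_channel(shape, centers_px, nuc_sig, config.nuclei_intensity_mean)
    pos_mask = cells["is_positive"].to_numpy()
    rep = _render_channel(
        shape, centers_px[pos_mask], rep_sig[pos_mask],
        config.reporter_intensity_mean,
    )
    mg = Micrograph(
        nuclei=_apply_noise(nuc, config, rng),
        reporter=_apply_noise(rep, config, rng),
        pixel_size_um=px,
        group=config.group or "monolayer",
        dose_ng_per_ul=0.0 if config.is_control else config.dose_ng_per_ul,
        is_control=config.is_control or config.dose_ng_per_ul == 0.0,
    )
    return mg, gt


def generate(config: GeneratorConfig) -> Tuple[Micrograph, GroundTruth]:
    """Dispatch on config.mode / architecture."""
    if config.mode == "monolayer":
        return generate_monolayer(config)
    if config.architecture == "triculture":
        return generate_triculture(config)
    return generate_spheroid(config)
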