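import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import spherotx as st
from spherotx.synthetic import (
    GeneratorConfig,
    PackingError,
    hill_dose_scale,
)

TRI_TYPES = (
    replace(st.FIBROBLAST_LIKE, p_surface=0.05, penetration_length_um=math.inf),
    replace(st.KERATINOCYTE_LIKE, p_surface=0.3, penetration_length_um=math.inf),
    replace(st.MELANOMA_LIKE, p_surface=0.6),
)


def small_spheroid_config(seed=0, **kw):
    kw.setdefault("spheroid_radius_um", 60.0)
    return GeneratorConfig(seed=seed, **kw)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(mode="slice"),
            dict(spheroid_radius_um=-5.0),
            dict(pixel_size_um=0.0),
            dict(dose_ng_per_ul=-1.0),
            dict(architecture="triculture"),  # needs 3 cell types
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(packing_fraction=0.0),
            dict(packing_fraction=0.8),
            dict(p_surface=1.5),
            dict(cell_radius_um=-1.0),
            dict(penetration_length_um=0.0),
        ],
    )
    def test_invalid_cell_type_rejected(self, kw):
        base = dict(name="x", cell_radius_um=6.0, packing_fraction=0.2, p_surface=0.5)
        base.update(kw)
        with pytest.raises(ValueError):
            st.CellTypeParams(**base)

    def test_triculture_geometry_validated(self):
        with pytest.raises(ValueError, match="core_radius_fraction"):
            GeneratorConfig(
                architecture="triculture", cell_types=TRI_TYPES,
                core_radius_fraction=1.5,
            )


class TestDeterminismAndPlacement:
    def test_identical_seed_bit_identical(self):
        a_img, a_gt = st.generate_spheroid(small_spheroid_config(seed=42))
        b_img, b_gt = st.generate_spheroid(small_spheroid_config(seed=42))
        np.testing.assert_array_equal(a_img.nuclei, b_img.nuclei)
        np.testing.assert_array_equal(a_img.reporter, b_img.reporter)
        pd.testing.assert_frame_equal(a_gt.cells, b_gt.cells)

    def test_different_seed_differs(self):
        a_img, _ = st.generate_spheroid(small_spheroid_config(seed=1))
        b_img, _ = st.generate_spheroid(small_spheroid_config(seed=2))
        assert not np.array_equal(a_img.nuclei, b_img.nuclei)

    def test_hard_sphere_no_overlap(self):
        _, gt = st.generate_spheroid(small_spheroid_config(seed=3))
        xyz = gt.cells[["x_um", "y_um", "z_um"]].to_numpy()
        r = gt.cells["radius_um"].to_numpy()
        pairs = cKDTree(xyz).query_pairs(2 * r.max(), output_type="ndarray")
        d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
        assert np.all(d >= r[pairs[:, 0]] + r[pairs[:, 1]] - 1e-9)

    def test_cells_inside_spheroid_with_valid_depth(self):
        _, gt = st.generate_spheroid(small_spheroid_config(seed=4))
        R = gt.spheroid_radius_um
        radial = np.linalg.norm(gt.cells[["x_um", "y_um", "z_um"]], axis=1)
        assert np.all(radial <= R - gt.cells.radius_um + 1e-9)
        assert np.all(gt.cells.depth_um >= 0)
        np.testing.assert_allclose(gt.cells.depth_um, R - radial)

    def test_unreachable_packing_errors_with_achieved_fraction(self):
        ct = replace(st.KERATINOCYTE_LIKE, packing_fraction=0.6)
        cfg = GeneratorConfig(
            cell_types=(ct,), spheroid_radius_um=40.0, max_rejections=500, seed=0
        )
        with pytest.raises(PackingError, match="%"):
            st.generate_spheroid(cfg)

    def test_output_is_16bit_stack(self):
        img, _ = st.generate_spheroid(small_spheroid_config(seed=5))
        assert img.nuclei.dtype == np.uint16 and img.is_3d
        assert img.nuclei.shape == img.reporter.shape


class TestPositivityModel:
    def test_zero_p_surface_gives_no_positives(self):
        ct = replace(st.KERATINOCYTE_LIKE, p_surface=0.0)
        _, gt = st.generate_spheroid(small_spheroid_config(seed=6, cell_types=(ct,)))
        assert gt.n_positive == 0

    def test_control_flag_silences_reporter(self):
        img, gt = st.generate_spheroid(
            small_spheroid_config(seed=7, is_control=True, dose_ng_per_ul=0.0)
        )
        assert gt.n_positive == 0
        assert img.is_control and img.dose_ng_per_ul == 0.0

    def test_uniform_positivity_matches_bernoulli_mean(self):
        """λ = ∞, p = 0.5: realized fraction within 3 binomial SDs of 0.5."""
        ct = replace(
            st.KERATINOCYTE_LIKE, p_surface=0.5, penetration_length_um=math.inf
        )
        _, gt = st.generate_spheroid(
            small_spheroid_config(seed=8, cell_types=(ct,), spheroid_radius_um=80.0)
        )
        sd = math.sqrt(0.25 / gt.n_cells)
        assert abs(gt.positive_fraction - 0.5) <= 3 * sd

    def test_deep_positivity_matches_monte_carlo_integral(self):
        """Positive fraction below one ring width matches the continuum
        integral of p_surface·exp(−d/λ) over the sphere's depth law."""
        lam, R, r, p_surf, cut = 12.0, 100.0, 5.0, 0.6, 25.0
        ct = replace(
            st.FIBROBLAST_LIKE, cell_radius_um=r, packing_fraction=0.25,
            p_surface=p_surf, penetration_length_um=lam,
        )
        tot = pos = 0
        for s in range(12):
            _, gt = st.generate_spheroid(
                GeneratorConfig(cell_types=(ct,), spheroid_radius_um=R, seed=400 + s)
            )
            deep = gt.cells[gt.cells.depth_um > cut]
            tot += len(deep)
            pos += int(deep.is_positive.sum())
        # oracle: direct Monte-Carlo integration over uniform centers in the
        # available ball (radius R - r), independent of the placement code
        rng = np.random.default_rng(99)
        rad = ((R - r) ** 3 * rng.random(1_000_000)) ** (1 / 3)
        d = R - rad
        expect = float(np.mean(p_surf * np.exp(-d[d > cut] / lam)))
        assert pos / tot == pytest.approx(expect, rel=0.10)

    @pytest.mark.parametrize("lam", [5.0, 15.0, 50.0])
    def test_depth_law_slope_recovery(self, lam):
        """log positive fraction vs depth recovers −1/λ within 15%."""
        ct = replace(
            st.FIBROBLAST_LIKE, cell_radius_um=5.0, packing_fraction=0.25,
            p_surface=0.8, penetration_length_um=lam,
        )
        cells = pd.concat(
            st.generate_spheroid(
                GeneratorConfig(cell_types=(ct,), spheroid_radius_um=110.0, seed=s)
            )[1].cells
            for s in (0, 1)
        )
        assert len(cells) >= 2000
        dmax = min(4 * lam, 100.0)
        bins = np.linspace(0, dmax, 11)
        mid, logf, wt = [], [], []
        for i in range(10):
            sel = (cells.depth_um >= bins[i]) & (cells.depth_um < bins[i + 1])
            n = int(sel.sum())
            if n < 50:
                continue
            p = cells.is_positive[sel].mean()
            if not 0 < p < 1:
                continue
            mid.append((bins[i] + bins[i + 1]) / 2)
            logf.append(math.log(p))
            wt.append(n * p / (1 - p))  # inverse variance of log(p̂)
        W, x, y = map(np.asarray, (wt, mid, logf))
        xm, ym = (W * x).sum() / W.sum(), (W * y).sum() / W.sum()
        slope = (W * (x - xm) * (y - ym)).sum() / (W * (x - xm) ** 2).sum()
        assert slope == pytest.approx(-1.0 / lam, rel=0.15)


class TestTriculture:
    def test_degenerate_core_is_all_fibroblast(self):
        _, gt = st.generate_triculture(
            GeneratorConfig(
                architecture="triculture", cell_types=TRI_TYPES,
                spheroid_radius_um=80.0, core_radius_fraction=1.0, n_patches=0,
                seed=3,
            )
        )
        assert set(gt.cells.cell_type) == {"fibroblast"}

    def test_spatial_arrangement(self):
        """Fibroblasts in the core ball, keratinocytes in the shell,
        melanoma confined near the surface."""
        cfg = GeneratorConfig(
            architecture="triculture", cell_types=TRI_TYPES,
            spheroid_radius_um=100.0, core_radius_fraction=0.55, seed=11,
        )
        _, gt = st.generate_triculture(cfg)
        c = gt.cells
        radial = np.linalg.norm(c[["x_um", "y_um", "z_um"]], axis=1)
        assert radial[c.cell_type == "fibroblast"].max() <= 55.0
        assert radial[c.cell_type == "keratinocyte"].min() >= 55.0 - 1e-9
        mel = c.cell_type == "melanoma"
        assert mel.sum() > 0
        assert c.depth_um[mel].max() <= 2 * 8.0 + 1e-9  # surface shell

    def test_counts_seed_invariant_coordinates_not(self):
        cfg = lambda s: GeneratorConfig(
            architecture="triculture", cell_types=TRI_TYPES,
            spheroid_radius_um=100.0, seed=s,
        )
        _, a = st.generate_triculture(cfg(500))
        _, b = st.generate_triculture(cfg(501))
        assert (
            a.cells.groupby("cell_type").size().to_dict()
            == b.cells.groupby("cell_type").size().to_dict()
        )
        assert not np.array_equal(a.cells.x_um.to_numpy(), b.cells.x_um.to_numpy())

    def test_per_type_positivity_recovery(self):
        """Realized per-type positive fractions recover the three p_surface
        parameters within 3 binomial SDs (pooled over seeds)."""
        agg = {}
        for s in range(8):
            _, gt = st.generate_triculture(
                GeneratorConfig(
                    architecture="triculture", cell_types=TRI_TYPES,
                    spheroid_radius_um=100.0, seed=500 + s,
                )
            )
            for t, g in gt.cells.groupby("cell_type"):
                a = agg.setdefault(t, [0, 0])
                a[0] += int(g.is_positive.sum())
                a[1] += len(g)
        targets = {"fibroblast": 0.05, "keratinocyte": 0.3, "melanoma": 0.6}
        for t, (pos, n) in agg.items():
            p = targets[t]
            sd = math.sqrt(p * (1 - p) / n)
            assert abs(pos / n - p) <= 3 * sd, t


class TestMonolayer:
    def test_pbs_control_has_zero_positivity(self):
        _, gt = st.generate_monolayer(
            GeneratorConfig(mode="monolayer", dose_ng_per_ul=0.0, seed=1)
        )
        assert gt.n_positive == 0

    def test_dose_scale_monotone_ground_truth(self):
        """Saturating dose map → realized positive fractions non-decreasing
        across the assay's 2D dose series (pooled over 3 seeds)."""
        doses = (0.3125, 0.625, 1.25, 2.5, 5.0, 10.0, 15.0)
        fracs = []
        for d in doses:
            tot = pos = 0
            for s in (700, 701, 702):
                _, gt = st.generate_monolayer(
                    GeneratorConfig(mode="monolayer", dose_ng_per_ul=d, seed=s)
                )
                tot += gt.n_cells
                pos += gt.n_positive
            fracs.append(pos / tot)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > 0.0

    def test_hill_dose_scale_properties(self):
        scale = hill_dose_scale(2.5)
        assert scale(0.0) == 0.0
        assert scale(2.5) == pytest.approx(0.5)
        assert scale(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_mixing_counts_exact_by_largest_remainder(self):
        cfg = GeneratorConfig(
            mode="monolayer", architecture="triculture",
            cell_types=(st.FIBROBLAST_LIKE, st.KERATINOCYTE_LIKE, st.MELANOMA_LIKE),
            mixing_proportions=(1.0, 1.0, 0.25), n_cells_monolayer=450, seed=9,
        )
        _, gt = st.generate_monolayer(cfg)
        counts = gt.cells.groupby("cell_type").size().to_dict()
        assert counts == {"fibroblast": 200, "keratinocyte": 200, "melanoma": 50}

    def test_monolayer_is_single_plane(self):
        img, gt = st.generate_monolayer(GeneratorConfig(mode="monolayer", seed=2))
        assert not img.is_3d
        assert np.all(gt.cells.z_um == 0.0) and np.all(gt.cells.depth_um == 0.0)


class TestGroundTruthSummaries:
    def test_ring_positive_fractions_partition_depths(self):
        ct = replace(st.KERATINOCYTE_LIKE, p_surface=0.5, penetration_length_um=10.0)
        _, gt = st.generate_spheroid(
            small_spheroid_config(seed=12, cell_types=(ct,), spheroid_radius_um=80.0)
        )
        rf = gt.ring_positive_fractions(wall_um=20.0)
        assert set(rf) == {"outer", "mid", "inner", "core"}
        assert all(0 <= v <= 1 for v in rf.values() if not math.isnan(v))
        # shallow decay: outer band strictly more positive than the core
        assert rf["outer"] > rf["core"]

    def test_totals_consistent(self):
        _, gt = st.generate_spheroid(small_spheroid_config(seed=13))
        assert gt.n_positive == int(gt.cells.is_positive.sum())
        assert gt.positive_fraction == pytest.approx(gt.n_positive / gt.n_cells)
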