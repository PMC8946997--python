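"""Reproducible end-to-end runs: generate → segment → calibrate → quantify → stats.

A :class:`RunConfig` names one of three experiment presets mirroring the
assay designs — a 2D dose–response series, monoculture spheroids of three
phenotypes, and triculture spheroids — or carries paths to existing images.
``run()`` executes every stage, writes all artifacts (images, masks,
partitions, result CSV, stats report, manifest) into a run directory, and
is value-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .image_io import (
    Micrograph,
    ResultRow,
    read_micrograph,
    rows_to_frame,
    write_ground_truth,
    write_micrograph,
    write_results,
)
from .quantify import (
    calibrate_threshold,
    dose_response,
    quantify_image,
    quantify_segments,
    quants_to_rows,
    segment_profile,
)
from .segmentation import (
    find_spheroid_mask,
    partition_rings,
    ring_width_from_group,
)
from .stats import (
    one_way_anova,
    significance_stars,
    t_test,
    tukey_hsd,
    two_way_anova,
)
from .synthetic import (
    FIBROBLAST_LIKE,
    KERATINOCYTE_LIKE,
    MELANOMA_LIKE,
    GeneratorConfig,
    generate,
)

EXPERIMENTS = ("monolayer_dose_response", "monoculture_spheroid", "triculture_spheroid")

# Reference doses of the assay: a 2D series from 0.3125 to 15 ng/uL
# (reference 1.25), and 10 ng/uL for 3D cultures.
DOSES_2D = (0.3125, 0.625, 1.25, 2.5, 5.0, 10.0, 15.0)
DOSE_3D = 10.0


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """One reproducible experiment run.

    Exactly one of (synthetic generation via the preset, ``input_paths``)
    provides the images.  ``n_replicates`` is the number of images per
    (group, dose) cell; ``n_controls`` the number of PBS control images per
    group.
    """

    experiment: str = "monoculture_spheroid"
    out_dir: str = "run"
    seed: int = 0
    n_replicates: int = 3
    n_controls: int = 2
    doses: Tuple[float, ...] = ()
    groups: Tuple[str, ...] = ()
    input_paths: Tuple[str, ...] = ()
    n_segments: int = 4
    smoothing_sigma: float = 6.0
    control_quantile: float = 0.999
    alpha: float = 0.05
    spheroid_radius_um: float = 80.0
    save_images: bool = True
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.input_paths and (self.doses or self.groups):
            raise ValueError(
                "provide either input_paths or generator settings, not both"
            )
        if self.n_replicates < 1 or self.n_controls < 0:
            raise ValueError("n_replicates >= 1 and n_controls >= 0 required")
        if not 0 < self.control_quantile < 1:
            raise ValueError("control_quantile must be in (0, 1)")


_PHENOTYPES = {
    "fibroblast": FIBROBLAST_LIKE,
    "keratinocyte": KERATINOCYTE_LIKE,
    "melanoma": MELANOMA_LIKE,
}


def _child_seed(seed: int, index: int) -> int:
    h = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _generator_configs(config: RunConfig) -> List[GeneratorConfig]:
    """Expand the experiment preset into one GeneratorConfig per image."""
    ov = dict(config.generator_overrides)
    out: List[GeneratorConfig] = []
    idx = 0

    def add(gc: GeneratorConfig) -> None:
        nonlocal idx
        out.append(replace(gc, seed=_child_seed(config.seed, idx), **ov))
        idx += 1

    if config.experiment == "monolayer_dose_response":
        groups = config.groups or ("monoculture", "triculture")
        doses = config.doses or DOSES_2D
        for group in groups:
            if group == "triculture":
                # seeding proportions fibroblast:keratinocyte:melanoma = 1:1:0.25
                types = (FIBROBLAST_LIKE, KERATINOCYTE_LIKE, MELANOMA_LIKE)
                mixing: Optional[Tuple[float, ...]] = (1.0, 1.0, 0.25)
            else:
                types, mixing = (KERATINOCYTE_LIKE,), None
            base = GeneratorConfig(
                mode="monolayer", architecture="mono", cell_types=types,
                mixing_proportions=mixing, group=group,
            )
            for _ in range(config.n_controls):
                add(replace(base, dose_ng_per_ul=0.0, is_control=True))
            for dose in doses:
                for _ in range(config.n_replicates):
                    add(replace(base, dose_ng_per_ul=dose))
    elif config.experiment == "monoculture_spheroid":
        groups = config.groups or ("fibroblast", "keratinocyte", "melanoma")
        doses = config.doses or (DOSE_3D,)
        for group in groups:
            ct = _PHENOTYPES[group]
            base = GeneratorConfig(
                mode="spheroid", architecture="mono", cell_types=(ct,),
                spheroid_radius_um=config.spheroid_radius_um, group=group,
            )
            for _ in range(config.n_controls):
                add(replace(base, dose_ng_per_ul=0.0, is_control=True))
            for dose in doses:
                for _ in range(config.n_replicates):
                    add(replace(base, dose_ng_per_ul=dose))
    else:  # triculture_spheroid
        doses = config.doses or (DOSE_3D,)
        base = GeneratorConfig(
            mode="spheroid", architecture="triculture",
            cell_types=(FIBROBLAST_LIKE, KERATINOCYTE_LIKE, MELANOMA_LIKE),
            spheroid_radius_um=config.spheroid_radius_um, group="triculture",
        )
        for _ in range(config.n_controls):
            add(replace(base, dose_ng_per_ul=0.0, is_control=True))
        for dose in doses:
            for _ in range(config.n_replicates):
                add(replace(base, dose_ng_per_ul=dose))
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["generator_overrides"] = {
        k: repr(v) if callable(v) else v for k, v in d["generator_overrides"].items()
    }
    return d


def _stats_plan(
    config: RunConfig, results: pd.DataFrame, log: List[str]
) -> dict:
    """The preset's inference: two-way ANOVA for the 2D dose series,
    one-way ANOVA + Tukey across segments for spheroids, t-test vs control."""
    report: dict = {"alpha": config.alpha}
    whole = results[(results["segment"] == "whole") & (results["dose_ng_per_ul"] > 0)]

    if config.experiment == "monolayer_dose_response":
        groups = sorted(whole["group"].unique())
        doses = sorted(whole["dose_ng_per_ul"].unique())
        if len(groups) >= 2 and len(doses) >= 2:
            records = [
                (r["group"], str(r["dose_ng_per_ul"]), r["ratio"])
                for _, r in whole.iterrows()
                if np.isfinite(r["ratio"])
            ]
            try:
                report["two_way_anova"] = two_way_anova(
                    records, alpha=config.alpha
                ).to_dict()
            except ValueError as exc:
                log.append(f"two-way ANOVA skipped: {exc}")
        by_group = {
            g: whole[whole["group"] == g]["ratio"].dropna().to_list() for g in groups
        }
        by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
        if len(by_group) >= 2:
            report["tukey_groups"] = tukey_hsd(by_group, alpha=config.alpha).to_dict()
    else:
        seg = results[
            (results["segment"] != "whole") & (results["dose_ng_per_ul"] > 0)
        ]
        for group, g in seg.groupby("group"):
            samples = {
                s: g[g["segment"] == s]["ratio"].dropna().to_list()
                for s in ("outer", "mid", "inner", "core")
            }
            samples = {s: v for s, v in samples.items() if len(v) >= 2}
            if len(samples) < 2:
                log.append(f"{group}: too few segment samples for ANOVA")
                continue
            key = f"segments_{group}"
            aov = one_way_anova(samples, alpha=config.alpha)
            report[key] = {"anova": aov.to_dict()}
            if aov.residual_ms > 0:
                report[key]["tukey"] = tukey_hsd(
                    samples, aov.residual_df, aov.residual_ms, alpha=config.alpha
                ).to_dict()

    # treated vs control whole-image ratios, per group
    ctrl = results[(results["segment"] == "whole") & (results["dose_ng_per_ul"] == 0)]
    for group in sorted(set(whole["group"]) & set(ctrl["group"])):
        a = whole[whole["group"] == group]["ratio"].dropna().to_list()
        b = ctrl[ctrl["group"] == group]["ratio"].dropna().to_list()
        if len(a) >= 2 and len(b) >= 2:
            tt = t_test(a, b)
            report[f"t_test_vs_control_{group}"] = {
                "t": tt.statistic, "df": tt.df, "p": tt.p,
                "stars": significance_stars(tt.p),
                "diagnostics": tt.diagnostics,
            }
    return report


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Artifacts: ``images/`` (TIFF + sidecars, if save_images), ``masks/`` and
    ``partitions/`` (label TIFFs), ``ground_truth/`` CSVs, ``results.csv``,
    ``dose_response.csv`` / ``segment_profile.csv``, ``calibration.json``,
    ``stats.json``, ``manifest.json``.  Re-running with the same config and
    seed reproduces all CSV outputs value-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = []
    manifest: dict = {
        "config": _config_dict(config),
        "seed": config.seed,
        "spherotx_version": __version__,
        "stages": {},
    }
    t0 = time.perf_counter()

    def stage_done(name: str) -> None:
        manifest["stages"][name] = {"elapsed_s": round(time.perf_counter() - t0, 3)}

    # -- generate / load -----------------------------------------------------
    micrographs: List[Micrograph] = []
    try:
        if config.input_paths:
            for p in config.input_paths:
                micrographs.append(read_micrograph(p))
            log.append(f"loaded {len(micrographs)} images")
        else:
            gcs = _generator_configs(config)
            (out / "ground_truth").mkdir(exist_ok=True)
            for i, gc in enumerate(gcs):
                mg, gt = generate(gc)
                mg = replace(mg, image_id=f"img{i:03d}")
                micrographs.append(mg)
                write_ground_truth(gt.cells, out / "ground_truth" / f"img{i:03d}.csv")
            log.append(f"generated {len(micrographs)} images")
            if config.save_images:
                (out / "images").mkdir(exist_ok=True)
                for mg in micrographs:
                    write_micrograph(mg, out / "images" / f"{mg.image_id}.tif")
    except Exception as exc:
        _write_manifest(out, manifest, log, failed="generate")
        raise StageError("generate", exc) from exc
    stage_done("generate")

    # -- segment -------------------------------------------------------------
    try:
        whole_field = config.experiment == "monolayer_dose_response"
        masks = [
            find_spheroid_mask(m, sigma=config.smoothing_sigma, whole_field=whole_field)
            for m in micrographs
        ]
        partitions: Dict[int, object] = {}
        if not whole_field:
            groups = sorted({m.group for m in micrographs})
            width_by_group = {}
            for g in groups:
                gmasks = [mk for m, mk in zip(micrographs, masks) if m.group == g]
                width_by_group[g] = ring_width_from_group(gmasks, config.n_segments)
            log.append(f"ring widths (px): {width_by_group}")
            manifest["ring_width_px"] = width_by_group
            import tifffile

            (out / "partitions").mkdir(exist_ok=True)
            for i, (m, mk) in enumerate(zip(micrographs, masks)):
                part = partition_rings(
                    mk, width_by_group[m.group], config.n_segments
                )
                partitions[i] = part
                if part.empty_segments:
                    log.append(f"{m.image_id}: empty segments {part.empty_segments}")
                tifffile.imwrite(
                    out / "partitions" / f"{m.image_id}_labels.tif",
                    part.labels.astype(np.uint8),
                )
    except Exception as exc:
        _write_manifest(out, manifest, log, failed="segment")
        raise StageError("segment", exc) from exc
    stage_done("segment")

    # -- calibrate + quantify ------------------------------------------------
    try:
        calib = calibrate_threshold(
            [m for m in micrographs if m.is_control],
            [mk for m, mk in zip(micrographs, masks) if m.is_control],
            control_quantile=config.control_quantile,
        )
        (out / "calibration.json").write_text(json.dumps(calib.to_dict(), indent=2))
        rows: List[ResultRow] = []
        for i, (m, mk) in enumerate(zip(micrographs, masks)):
            if i in partitions:
                quants = quantify_segments(m, mk, partitions[i], calib)
            else:
                quants = {"whole": quantify_image(m, mk, calib)}
            rows.extend(quants_to_rows(m, quants))
        write_results(rows, out / "results.csv")
        results = rows_to_frame(rows)
    except Exception as exc:
        _write_manifest(out, manifest, log, failed="quantify")
        raise StageError("quantify", exc) from exc
    stage_done("quantify")

    # -- summaries + stats ---------------------------------------------------
    try:
        dose_response(results, segment="whole").to_csv(
            out / "dose_response.csv", index=False, float_format="%.17g"
        )
        if partitions:
            segment_profile(results).to_csv(
                out / "segment_profile.csv", index=False, float_format="%.17g"
            )
        stats_report = _stats_plan(config, results, log)
        (out / "stats.json").write_text(json.dumps(stats_report, indent=2))
    except Exception as exc:
        _write_manifest(out, manifest, log, failed="stats")
        raise StageError("stats", exc) from exc
    stage_done("stats")

    _write_manifest(out, manifest, log)
    return out


def _write_manifest(
    out: Path, manifest: dict, log: List[str], failed: Optional[str] = None
) -> None:
    manifest = dict(manifest)
    manifest["log"] = list(log)
    if failed:
        manifest["failed_stage"] = failed
    canon = json.dumps(manifest["config"], sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(canon.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _fmt(x: float) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.4f}"


def make_report(run_dir) -> str:
    """Human-readable summary of a completed run; purely a function of the
    run directory, so regeneration is byte-identical."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    results_path = run_dir / "results.csv"
    if not manifest_path.exists() or not results_path.exists():
        raise FileNotFoundError(
            f"{run_dir}: missing manifest.json or results.csv (incomplete run)"
        )
    manifest = json.loads(manifest_path.read_text())
    results = pd.read_csv(results_path)
    stats_report = {}
    if (run_dir / "stats.json").exists():
        stats_report = json.loads((run_dir / "stats.json").read_text())

    lines: List[str] = []
    lines.append(f"spherotx run report — experiment: {manifest['config']['experiment']}")
    lines.append(f"seed: {manifest['seed']}   images: {results['image_id'].nunique()}")
    lines.append("")
    lines.append("Group means, whole-image reporter ratio (mean / sd / sem / n):")
    dr = dose_response(results, segment="whole")
    for _, r in dr.iterrows():
        lines.append(
            f"  {r['group']:<14} dose {r['dose_ng_per_ul']:>7.4f}: "
            f"{_fmt(r['mean'])} / {_fmt(r['sd'])} / {_fmt(r['sem'])} / {int(r['n'])}"
        )
    if (results["segment"] != "whole").any():
        lines.append("")
        lines.append("Segment profile (outer→core), reporter ratio:")
        sp = segment_profile(results)
        for _, r in sp.iterrows():
            lines.append(
                f"  {r['group']:<14} {r['segment']:<6}: "
                f"{_fmt(r['mean'])} / {_fmt(r['sd'])} / {_fmt(r['sem'])} / {int(r['n'])}"
            )
    if stats_report:
        lines.append("")
        lines.append("Inference:")
        for key, val in stats_report.items():
            if key == "alpha" or not isinstance(val, dict):
                continue
            if "terms" in val:
                for t in val["terms"]:
                    lines.append(
                        f"  {key} [{t['name']}]: F={_fmt(t['F'] or math.nan)} "
                        f"p={_fmt(t['p'] or math.nan)} {t['stars']}"
                    )
            if "anova" in val:
                t = val["anova"]["terms"][0]
                lines.append(
                    f"  {key} ANOVA: F={_fmt(t['F'] or math.nan)} "
                    f"p={_fmt(t['p'] or math.nan)} {t['stars']}"
                )
            if "tukey" in val:
                for p in val["tukey"]["pairs"]:
                    lines.append(
                        f"    {key} Tukey {p['pair']}: diff={_fmt(p['mean_diff'])} "
                        f"p_adj={_fmt(p['p_adj'])} {p['stars']}"
                    )
            if "pairs" in val:
                for p in val["pairs"]:
                    lines.append(
                        f"  {key} {p['pair']}: diff={_fmt(p['mean_diff'])} "
                        f"p_adj={_fmt(p['p_adj'])} {p['stars']}"
                    )
            if "t" in val:
                lines.append(
                    f"  {key}: t={_fmt(val['t'])} df={val['df']:.1f} "
                    f"p={_fmt(val['p'])} {val['stars']}"
                )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
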