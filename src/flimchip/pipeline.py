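"""End-to-end orchestration: simulate → fit → redox → segment → viability → stats.

The unit of work is a *sample*: one scene (density + condition) rendered
into two FLIM channel stacks and a viability image. Analysis of a
treated sample always pairs it with a control sample generated under the
same geometry and acquisition (sub-seeded from the same master seed), so
normalized redox effects can be computed the way the experiment defines
them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .flim import FitOptions, fit_image
from .redox import compute_redox_map, normalize_to_control
from .scene import (
    AcquisitionConfig,
    ChamberGeometry,
    IRFModel,
    SceneConfig,
    SceneGroundTruth,
    generate_scene,
    make_irf,
    render_flim_stack,
    render_viability_image,
)
from .segmentation import SegmentationOptions, aggregate_per_cell, segment
from .stats import run_stats
from .viability import (
    ViabilityOptions,
    classify_live_dead,
    necrotic_core_extent,
    region_viability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_fixture",
    "list_fixtures",
    "simulate_sample",
    "analyze_flim_sample",
    "analyze_viability",
    "run_all",
    "cmd_simulate",
]

IRF_FWHM_PS = 244.0  # measured instrument response width
IRF_T0_PS = 1000.0


@dataclass
class RunConfig:
    """Serializable description of one run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    irf_fwhm_ps: float = IRF_FWHM_PS
    irf_t0_ps: float = IRF_T0_PS
    fit: FitOptions = field(default_factory=FitOptions)
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    viability: ViabilityOptions = field(default_factory=ViabilityOptions)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "scene" in d:
            kwargs["scene"] = SceneConfig(**d["scene"])
        if "acquisition" in d:
            kwargs["acquisition"] = AcquisitionConfig(**d["acquisition"])
        if "fit" in d:
            fit = d["fit"].copy()
            for key in ("tau1_bounds_ps", "tau2_bounds_ps"):
                if key in fit:
                    fit[key] = tuple(fit[key])
            kwargs["fit"] = FitOptions(**fit)
        if "segmentation" in d:
            kwargs["segmentation"] = SegmentationOptions(**d["segmentation"])
        if "viability" in d:
            kwargs["viability"] = ViabilityOptions(**d["viability"])
        for key in ("irf_fwhm_ps", "irf_t0_ps", "seed"):
            if key in d:
                kwargs[key] = d[key]
        cfg = cls(**kwargs)
        cfg.scene.seed = cfg.seed if "seed" in d else cfg.scene.seed
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def irf(self) -> IRFModel:
        return make_irf(self.irf_fwhm_ps, self.irf_t0_ps, self.acquisition)


def list_fixtures() -> list[str]:
    base = resources.files("flimchip") / "fixtures"
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))


def load_fixture(name: str) -> RunConfig:
    """Load a packaged scene/run parameter file by name (e.g. ``lowdensity_ctl``)."""
    base = resources.files("flimchip") / "fixtures"
    path = base / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(f"no fixture {name!r}; available: {list_fixtures()}")
    import yaml

    return RunConfig.from_dict(yaml.safe_load(path.read_text()))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_sample(config: RunConfig, outdir: str | Path | None = None,
                    force: bool = False) -> dict:
    """Generate a scene and render all raw data; optionally write files.

    Returns a dict with the scene, stacks, viability image, and (when
    ``outdir`` is given) the written paths.
    """
    scene = generate_scene(config.scene)
    irf = config.irf()
    s_nadph, s_fad, s_via = _spawn_seeds(config.scene.seed, 3)
    nadph_stack, nadph_true = render_flim_stack(scene, "NADPH", irf, config.acquisition,
                                                seed=s_nadph)
    fad_stack, fad_true = render_flim_stack(scene, "FAD", irf, config.acquisition,
                                            seed=s_fad)
    via_img = render_viability_image(scene, seed=s_via)
    out = {
        "scene": scene,
        "irf": irf,
        "nadph_stack": nadph_stack,
        "fad_stack": fad_stack,
        "viability_image": via_img,
        "true_intensity": {"NADPH": nadph_true, "FAD": fad_true},
    }
    if outdir is not None:
        outdir = Path(outdir)
        paths = {
            "nadph": outdir / "nadph_stack.ome.tif",
            "fad": outdir / "fad_stack.ome.tif",
            "viability": outdir / "viability.tif",
            "sidecar": outdir / "sidecar.json",
        }
        existing = [p for p in paths.values() if p.exists()]
        if existing and not force:
            raise FileExistsError(
                f"refusing to overwrite {existing[0]} (pass force=True / --force)"
            )
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_flim_stack(paths["nadph"], nadph_stack, "NADPH")
        fio.write_flim_stack(paths["fad"], fad_stack, "FAD")
        fio.write_viability_image(paths["viability"], via_img)
        fio.write_sidecar(paths["sidecar"], scene, config.acquisition, irf)
        out["paths"] = {k: str(v) for k, v in paths.items()}
    return out


def analyze_flim_sample(
    nadph_stack: np.ndarray,
    fad_stack: np.ndarray,
    config: RunConfig,
    condition: str,
) -> tuple[pd.DataFrame, dict]:
    """Fit both channels, build metric maps, segment, and aggregate.

    Returns the per-cell table and the per-pixel maps used to build it.
    """
    irf = config.irf()
    nadph_maps = fit_image(nadph_stack, irf, config.fit)
    fad_maps = fit_image(fad_stack, irf, config.fit)
    redox = compute_redox_map(nadph_maps["intensity"], fad_maps["intensity"])
    labels = segment(nadph_maps["intensity"], config.segmentation)
    metric_maps = {
        "nadph_taum_ps": nadph_maps["tau_m_ps"],
        "fad_taum_ps": fad_maps["tau_m_ps"],
        "nadph_intensity": nadph_maps["intensity"],
        "fad_intensity": fad_maps["intensity"],
        "redox_ratio": redox.ratio,
    }
    table = aggregate_per_cell(metric_maps, labels.cytoplasm,
                               config.scene.geometry, condition)
    return table, {"nadph": nadph_maps, "fad": fad_maps, "redox": redox,
                   "labels": labels}


def analyze_viability(image: np.ndarray, config: RunConfig) -> dict:
    """Classify live/dead objects and quantify regions, profiles, core."""
    geometry = config.scene.geometry
    objects = classify_live_dead(image, config.viability)
    regions = dict(geometry.region_bands_mm())
    regions["overall"] = (0.0, geometry.width_mm)
    table = region_viability(objects, regions, geometry.pixel_size_um)
    core = necrotic_core_extent(objects, geometry)
    return {"objects": objects, "regions": table, "necrotic_core_fraction": core}


def _percent_decrease(normalized: pd.Series, cells: pd.DataFrame,
                      condition: str, position: str) -> float:
    sel = (cells["condition"] == condition) & (cells["position"] == position)
    if not sel.any():
        return float("nan")
    return float((1.0 - normalized[sel].mean()) * 100.0)


def run_all(config: RunConfig, outdir: str | Path | None = None,
            force: bool = False) -> dict:
    """Full pipeline on one condition, paired with its control.

    Simulates the configured sample plus a CTL sample (same geometry and
    density, control condition, independent sub-seed), runs FLIM fitting,
    segmentation and redox normalization on both, viability analysis on
    the configured sample, and the statistical cascade on the normalized
    redox ratio. Returns a summary dict (also written as
    ``summary.json`` when ``outdir`` is given).
    """
    condition = config.scene.condition
    seeds = _spawn_seeds(config.seed, 2)

    cond_cfg = config
    cond_cfg.scene.seed = seeds[0]
    sim = simulate_sample(cond_cfg, outdir=Path(outdir) / condition if outdir else None,
                          force=force)
    tables = []
    table_cond, _ = analyze_flim_sample(sim["nadph_stack"], sim["fad_stack"],
                                        cond_cfg, condition)
    tables.append(table_cond)

    if condition != "CTL":
        ctl_scene = SceneConfig(
            density_label=config.scene.density_label,
            condition="CTL",
            geometry=config.scene.geometry,
            seed=seeds[1],
            n_cells=config.scene.n_cells,
            cell_radius_px=config.scene.cell_radius_px,
            nucleus_radius_px=config.scene.nucleus_radius_px,
        )
        ctl_cfg = RunConfig(
            scene=ctl_scene, acquisition=config.acquisition,
            irf_fwhm_ps=config.irf_fwhm_ps, irf_t0_ps=config.irf_t0_ps,
            fit=config.fit, segmentation=config.segmentation,
            viability=config.viability, seed=seeds[1],
        )
        ctl_sim = simulate_sample(ctl_cfg,
                                  outdir=Path(outdir) / "CTL" if outdir else None,
                                  force=force)
        table_ctl, _ = analyze_flim_sample(ctl_sim["nadph_stack"],
                                           ctl_sim["fad_stack"], ctl_cfg, "CTL")
        tables.append(table_ctl)

    cells = pd.concat(tables, ignore_index=True)
    cells["redox_normalized"] = normalize_to_control(cells)

    via = analyze_viability(sim["viability_image"], config)

    summary: dict = {
        "condition": condition,
        "density_label": config.scene.density_label,
        "seed": config.seed,
        "n_cells": {
            cond: int((cells["condition"] == cond).sum())
            for cond in cells["condition"].unique()
        },
        "qc_min_cells": bool(table_cond.attrs.get("qc_min_cells", False)),
        "normalized_redox_mean": {
            pos: {
                cond: float(
                    cells.loc[
                        (cells.condition == cond) & (cells.position == pos),
                        "redox_normalized",
                    ].mean()
                )
                for cond in cells["condition"].unique()
            }
            for pos in ("proximal", "distal")
        },
        "viability": {
            row.region: (None if not row.valid else
                         {"live_percent": row.live_percent, "n": int(row.n)})
            for row in via["regions"].itertuples()
        },
        "necrotic_core_fraction": via["necrotic_core_fraction"],
        "ground_truth_live_fractions": sim["scene"].region_live_fractions(),
    }
    if condition != "CTL":
        summary["redox_percent_decrease"] = {
            pos: _percent_decrease(cells["redox_normalized"], cells, condition, pos)
            for pos in ("proximal", "distal")
        }
        report = run_stats(cells, "redox_normalized")
        summary["stats"] = {
            "omnibus": report.omnibus.to_dict(orient="records"),
            "pairwise": report.pairwise.to_dict(orient="records"),
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(outdir / "cells.csv", index=False)
        via["regions"].to_csv(outdir / "viability_regions.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    summary["cells"] = cells
    summary["viability_objects"] = via["objects"]
    return summary


def cmd_simulate(config: RunConfig, outdir: str | Path, force: bool = False) -> dict:
    """Simulation stage with file output (CLI backend)."""
    return simulate_sample(config, outdir=outdir, force=force)
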