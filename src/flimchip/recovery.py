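"""Recovery measurements: how well the pipeline reads back programmed truth.

Each function simulates scenes under the programmed study conditions and
runs the corresponding analysis stage(s) from scratch, returning the
measured quantity. These power the acceptance checks and are also useful
for benchmarking parameter changes. All randomness is derived from one
master seed via ``numpy.random.SeedSequence``; replicate averaging
mirrors the experimental practice of repeating each condition several
times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .flim import DecayHistogram, FitOptions, fit_decay, fit_image, estimate_fwhm, model_decay
from .pipeline import IRF_FWHM_PS, IRF_T0_PS, RunConfig, analyze_flim_sample, simulate_sample
from .redox import normalize_to_control
from .scene import (
    AcquisitionConfig,
    ChamberGeometry,
    SceneConfig,
    generate_scene,
    make_irf,
    render_viability_image,
)
from .viability import classify_live_dead, necrotic_core_extent, region_viability

__all__ = [
    "child_seeds",
    "mono_standard_lifetime_ns",
    "irf_fwhm_ps",
    "redox_percent_decrease",
    "viability_percent_live",
    "necrotic_core_percent",
    "segmented_cell_count",
]

STANDARD_TAU_PS = 2100.0  # fluorescent-microsphere daily standard
STANDARD_PHOTONS = 1e5


def child_seeds(master_seed: int, n: int) -> list[int]:
    """n independent 31-bit seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def mono_standard_lifetime_ns(
    master_seed: int,
    n_replicates: int = 7,
    acq: AcquisitionConfig | None = None,
) -> float:
    """Mean fitted lifetime (ns) of the simulated mono-exponential standard.

    Emulates the daily lifetime check: a 2.1 ns mono-exponential decay at
    ~1e5 photons, convolved with the 244 ps Gaussian IRF, Poisson noise,
    fit with the single-exponential model; repeated ``n_replicates``
    times and averaged.
    """
    acq = acq or AcquisitionConfig()
    irf = make_irf(IRF_FWHM_PS, IRF_T0_PS, acq)
    taus = []
    for seed in child_seeds(master_seed, n_replicates):
        rng = np.random.default_rng(seed)
        lam = model_decay(1.0, STANDARD_TAU_PS, STANDARD_TAU_PS, 0.01,
                          STANDARD_PHOTONS, irf, acq.time_grid_ps)
        hist = DecayHistogram(rng.poisson(lam), acq.bin_width_ps)
        res = fit_decay(hist, irf, FitOptions(model="mono"))
        taus.append(res.tau_m_ps)
    return float(np.mean(taus)) / 1000.0


def irf_fwhm_ps(acq: AcquisitionConfig | None = None) -> float:
    """Estimated FWHM (ps) of the sampled instrument-response model."""
    acq = acq or AcquisitionConfig()
    irf = make_irf(IRF_FWHM_PS, IRF_T0_PS, acq)
    return estimate_fwhm(irf.sampled, acq.bin_width_ps)


def redox_percent_decrease(
    master_seed: int,
    density: str = "high",
    condition: str = "2DG",
    geometry: ChamberGeometry | None = None,
    n_cells: int | None = None,
    acq: AcquisitionConfig | None = None,
) -> dict[str, float]:
    """Percent decrease of control-normalized redox ratio per position.

    Runs the full chain on a treated scene paired with a control scene:
    render both FLIM channels, fit every pixel, build redox maps, segment
    and aggregate per cytoplasm, normalize to the control at the same
    position, and report 100 x (1 - mean normalized ratio) for the
    proximal and distal strata.
    """
    seeds = child_seeds(master_seed, 2)
    tables = []
    for cond, seed in ((condition, seeds[0]), ("CTL", seeds[1])):
        cfg = RunConfig(
            scene=SceneConfig(
                density_label=density, condition=cond, seed=seed,
                geometry=geometry or ChamberGeometry(), n_cells=n_cells,
            ),
            acquisition=acq or AcquisitionConfig(),
            seed=seed,
        )
        sim = simulate_sample(cfg)
        table, _ = analyze_flim_sample(sim["nadph_stack"], sim["fad_stack"], cfg, cond)
        tables.append(table)
    cells = pd.concat(tables, ignore_index=True)
    cells["redox_normalized"] = normalize_to_control(cells)
    out = {}
    for pos in ("proximal", "distal"):
        sel = (cells["condition"] == condition) & (cells["position"] == pos)
        out[pos] = float((1.0 - cells.loc[sel, "redox_normalized"].mean()) * 100.0)
    return out


def viability_percent_live(
    master_seed: int,
    density: str,
    condition: str,
    region: str = "overall",
    n_replicates: int = 5,
) -> float:
    """Percent live objects in one region, averaged over replicate scenes."""
    vals = []
    for seed in child_seeds(master_seed, n_replicates):
        cfg = SceneConfig(density_label=density, condition=condition, seed=seed)
        scene = generate_scene(cfg)
        img = render_viability_image(scene, seed=seed + 1)
        objects = classify_live_dead(img)
        geom = cfg.geometry
        regions = dict(geom.region_bands_mm())
        regions["overall"] = (0.0, geom.width_mm)
        table = region_viability(objects, regions, geom.pixel_size_um)
        row = table.set_index("region").loc[region]
        if row["valid"]:
            vals.append(row["live_percent"])
    return float(np.mean(vals))


def necrotic_core_percent(
    master_seed: int,
    core_fraction: float = 0.8,
    n_replicates: int = 3,
) -> float:
    """Necrotic-core extent (% of chamber length) on extreme-density scenes."""
    vals = []
    for seed in child_seeds(master_seed, n_replicates):
        cfg = SceneConfig(
            density_label="extreme", condition="CTL", seed=seed,
            necrotic_core_fraction=core_fraction,
        )
        scene = generate_scene(cfg)
        img = render_viability_image(scene, seed=seed + 1)
        objects = classify_live_dead(img)
        vals.append(necrotic_core_extent(objects, cfg.geometry))
    return float(np.mean(vals)) * 100.0


def segmented_cell_count(master_seed: int) -> int:
    """Rows in the per-cell table of a default low-density sample."""
    seed = child_seeds(master_seed, 1)[0]
    cfg = RunConfig(
        scene=SceneConfig(density_label="low", condition="CTL", seed=seed),
        seed=seed,
    )
    sim = simulate_sample(cfg)
    table, _ = analyze_flim_sample(sim["nadph_stack"], sim["fad_stack"], cfg, "CTL")
    return int(len(table))
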