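"""Synthetic tumor-on-a-chip scenes with known ground truth.

A scene is a 2D scale model of the microdevice chamber: a collagen-filled
rectangle with the nutrient-supplying lumen at ``x = 0``. Cells are placed
across the chamber; the probability that a cell is alive decreases with
distance from the lumen following a logistic profile, so high seeding
densities develop a necrotic region at the distal wall. Each cell carries
true bi-exponential decay parameters for the NAD(P)H and FAD channels,
from which photon-count FLIM stacks are rendered (IRF convolution +
Poisson statistics), and a live/dead label from which a two-channel
calcein/propidium-iodide style viability image is rendered.

Treatment conditions (CTL, 2DG, etomoxir, oligomycin) act on the scene as
multiplicative effects: the redox effect scales the NAD(P)H photon budget
(the NAD(P)H/FAD intensity ratio moves by the programmed factor), the
lifetime effect scales NAD(P)H component lifetimes, and the viability
effect sets the live-fraction plateaus of the logistic profile. The FLIM
channels represent the metabolic-imaging time point, at which treated
cells have shifted their metabolism but not yet died, so decay effects
apply to every cell; the alive/dead flags represent the later staining
time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._kernels import exp_irf_conv

__all__ = [
    "ChamberGeometry",
    "ChannelDecay",
    "CellSpec",
    "SceneConfig",
    "SceneGroundTruth",
    "AcquisitionConfig",
    "IRFModel",
    "ConditionEffect",
    "CONDITION_EFFECTS",
    "DENSITY_TABLE",
    "PlacementError",
    "generate_scene",
    "make_irf",
    "render_flim_stack",
    "render_viability_image",
]

CHANNELS = ("NADPH", "FAD")
CONDITIONS = ("CTL", "2DG", "etomoxir", "oligomycin")
DENSITIES = ("low", "high", "extreme")

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


class PlacementError(RuntimeError):
    """Raised when the requested cell density cannot be placed."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Scale model of the chamber; the lumen sits at x = 0.

    ``distal_offset_mm`` marks where the distal analysis region begins
    (10 mm from the lumen in the physical device); ``proximal_fraction``
    is the fraction of the chamber length counted as proximal.
    """

    width_mm: float = 12.0
    height_mm: float = 5.0
    pixel_size_um: float = 62.5
    distal_offset_mm: float = 10.0
    proximal_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 < self.distal_offset_mm <= self.width_mm):
            raise ValueError("distal_offset_mm must lie in (0, width_mm]")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered frame."""
        nx = int(round(self.width_mm * 1000.0 / self.pixel_size_um))
        ny = int(round(self.height_mm * 1000.0 / self.pixel_size_um))
        return ny, nx

    def x_mm(self, col: np.ndarray | float) -> np.ndarray | float:
        """Axis coordinate (distance from the lumen) of a pixel column."""
        return (np.asarray(col, dtype=float) + 0.5) * self.pixel_size_um / 1000.0

    def position_label(self, x_mm: float) -> str:
        if x_mm <= self.proximal_fraction * self.width_mm:
            return "proximal"
        if x_mm >= self.distal_offset_mm:
            return "distal"
        return "other"

    def region_bands_mm(self) -> dict[str, tuple[float, float]]:
        return {
            "proximal": (0.0, self.proximal_fraction * self.width_mm),
            "distal": (self.distal_offset_mm, self.width_mm),
        }


@dataclass
class ChannelDecay:
    """True decay parameters of one autofluorescence channel of one cell.

    ``mean_intensity`` is a relative brightness (1.0 = nominal bright
    cytoplasm pixel); the acquisition photon budget converts it to
    expected photons per pixel at render time.
    """

    alpha1_frac: float
    tau1_ps: float
    tau2_ps: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1_frac <= 1.0):
            raise ValueError("alpha1_frac must lie in [0, 1]")
        if not (0 < self.tau1_ps < self.tau2_ps):
            raise ValueError("need 0 < tau1_ps < tau2_ps")
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be >= 0")

    @property
    def tau_m_ps(self) -> float:
        return self.alpha1_frac * self.tau1_ps + (1.0 - self.alpha1_frac) * self.tau2_ps


@dataclass
class CellSpec:
    center_xy: tuple[float, float]  # (x=col, y=row), pixels
    nucleus_radius_px: float
    cell_radius_px: float
    alive: bool
    channel_params: dict[str, ChannelDecay]
    viability_signal: tuple[float, float] = (1.0, 0.0)  # (green, red) amplitudes

    def __post_init__(self) -> None:
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ValueError("nucleus must be smaller than the cell")


@dataclass
class ConditionEffect:
    """Programmed multiplicative effects of one treatment at one density.

    Pairs are (proximal, distal); values between the strata are logistic
    interpolations along the chamber axis. ``live`` are live-fraction
    plateaus of the viability profile, not multipliers.
    """

    redox: tuple[float, float] = (1.0, 1.0)
    nadph_taum: tuple[float, float] = (1.0, 1.0)
    live: tuple[float, float] = (0.97, 0.97)
    live_midpoint_frac: float = 0.55
    live_steepness_frac: float = 0.08

    def __post_init__(self) -> None:
        self.redox = tuple(self.redox)
        self.nadph_taum = tuple(self.nadph_taum)
        self.live = tuple(self.live)


# Live-fraction plateaus follow the reported viability percentages per
# condition and seeding density; redox multipliers follow the reported
# normalized redox-ratio changes (40% decrease under 2DG at high density,
# position-dependent decreases for etomoxir/oligomycin, moderate shifts at
# low density). Where only a qualitative direction is reported the value
# is a fixed representative choice.
CONDITION_EFFECTS: dict[tuple[str, str], ConditionEffect] = {
    ("low", "CTL"): ConditionEffect(),
    ("low", "2DG"): ConditionEffect(redox=(0.85, 0.85), live=(0.75, 0.75)),
    ("low", "etomoxir"): ConditionEffect(redox=(0.88, 0.88)),
    ("low", "oligomycin"): ConditionEffect(),
    ("high", "CTL"): ConditionEffect(live=(0.87, 0.50)),
    ("high", "2DG"): ConditionEffect(
        redox=(0.60, 0.60), nadph_taum=(1.0, 1.12), live=(0.33, 0.30)
    ),
    ("high", "etomoxir"): ConditionEffect(redox=(0.85, 0.65), live=(0.87, 0.36)),
    ("high", "oligomycin"): ConditionEffect(redox=(0.90, 0.70), live=(0.66, 0.27)),
    ("extreme", "CTL"): ConditionEffect(
        live=(0.95, 0.0), live_midpoint_frac=0.18, live_steepness_frac=0.02
    ),
}

# density label -> (cell count in the default frame, cell radius px,
# nucleus radius px). Counts grow sublinearly with seeding density
# because the 2D frame saturates; the 3:15:30 seeding ratio is kept as
# metadata only.
DENSITY_TABLE: dict[str, tuple[int, float, float]] = {
    "low": (120, 4.5, 2.2),
    "high": (280, 3.2, 1.6),
    "extreme": (380, 3.0, 1.5),
}

# nominal decay parameters of cytoplasmic autofluorescence; FAD relative
# intensity sets the baseline optical redox ratio NAD(P)H/FAD = 1.5
BASE_DECAYS: dict[str, ChannelDecay] = {
    "NADPH": ChannelDecay(alpha1_frac=0.70, tau1_ps=400.0, tau2_ps=2500.0, mean_intensity=1.0),
    "FAD": ChannelDecay(alpha1_frac=0.60, tau1_ps=300.0, tau2_ps=2300.0, mean_intensity=1.0 / 1.5),
}

NUCLEUS_INTENSITY_FRAC = 0.35  # nuclei appear dim in cytoplasmic autofluorescence


@dataclass(frozen=True)
class AcquisitionConfig:
    """TCSPC acquisition grid and photon budget.

    The 12.5 ns window is one period of an 80 MHz excitation laser;
    256 channels is a common TCSPC histogram depth.
    """

    n_time_bins: int = 256
    window_ns: float = 12.5
    photons_per_bright_pixel: float = 150.0
    background_rate: float = 0.005  # dark counts per bin per pixel

    def __post_init__(self) -> None:
        if self.n_time_bins < 16:
            raise ValueError("need at least 16 time bins")
        if self.window_ns <= 0 or self.photons_per_bright_pixel <= 0:
            raise ValueError("window and photon budget must be positive")

    @property
    def bin_width_ps(self) -> float:
        return self.window_ns * 1000.0 / self.n_time_bins

    @property
    def time_grid_ps(self) -> np.ndarray:
        """Bin-center times in ps."""
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width_ps


@dataclass
class IRFModel:
    """Gaussian instrument response sampled on the acquisition grid."""

    fwhm_ps: float
    t0_ps: float
    bin_width_ps: float
    sampled: np.ndarray

    def __post_init__(self) -> None:
        self.sampled = np.asarray(self.sampled, dtype=float)
        if np.any(self.sampled < 0):
            raise ValueError("IRF samples must be non-negative")


def make_irf(fwhm_ps: float, t0_ps: float, acq: AcquisitionConfig) -> IRFModel:
    """Discretize a unit-area Gaussian IRF onto the acquisition grid.

    An ``fwhm_ps`` below one bin width cannot be represented and degrades
    to a single-bin impulse (with a warning).
    """
    if fwhm_ps <= 0:
        raise ValueError("fwhm_ps must be positive")
    t = acq.time_grid_ps
    if not (t[0] - acq.bin_width_ps <= t0_ps <= t[-1]):
        raise ValueError("IRF peak t0_ps must lie inside the acquisition window")
    if fwhm_ps < acq.bin_width_ps:
        warnings.warn(
            "IRF FWHM below one time bin; returning a delta-like IRF",
            RuntimeWarning,
            stacklevel=2,
        )
        sampled = np.zeros(acq.n_time_bins)
        sampled[int(np.argmin(np.abs(t - t0_ps)))] = 1.0
        return IRFModel(fwhm_ps, t0_ps, acq.bin_width_ps, sampled)
    sigma = fwhm_ps / FWHM_TO_SIGMA
    sampled = np.exp(-0.5 * ((t - t0_ps) / sigma) ** 2)
    sampled /= sampled.sum()
    return IRFModel(fwhm_ps, t0_ps, acq.bin_width_ps, sampled)


@dataclass
class SceneConfig:
    """Everything needed to regenerate a scene from a seed."""

    density_label: str = "low"
    condition: str = "CTL"
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    seed: int = 0
    n_cells: int | None = None  # override the density table
    cell_radius_px: float | None = None
    nucleus_radius_px: float | None = None
    necrotic_core_fraction: float | None = None  # overrides the live midpoint
    intensity_cv: float = 0.10  # per-cell lognormal brightness variation
    tau_jitter_cv: float = 0.03  # per-cell lifetime variation
    max_placement_attempts: int = 400  # per cell

    def __post_init__(self) -> None:
        if self.density_label not in DENSITIES:
            raise ValueError(f"unknown density_label {self.density_label!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if isinstance(self.geometry, dict):
            self.geometry = ChamberGeometry(**self.geometry)


@dataclass
class SceneGroundTruth:
    geometry: ChamberGeometry
    cells: list[CellSpec]
    condition: str
    density_label: str
    seed: int
    effect_multipliers: ConditionEffect

    def live_fraction(self, x0_mm: float | None = None, x1_mm: float | None = None) -> float:
        """Ground-truth live fraction of cells whose center lies in [x0, x1)."""
        x0 = -np.inf if x0_mm is None else x0_mm
        x1 = np.inf if x1_mm is None else x1_mm
        flags = [
            c.alive
            for c in self.cells
            if x0 <= self.geometry.x_mm(c.center_xy[0]) < x1
        ]
        if not flags:
            return float("nan")
        return float(np.mean(flags))

    def region_live_fractions(self) -> dict[str, float]:
        out = {"overall": self.live_fraction()}
        for name, (a, b) in self.geometry.region_bands_mm().items():
            out[name] = self.live_fraction(a, b)
        return out

    def to_dict(self) -> dict:
        # canonical JSON-safe form: tuples as lists, undefined fractions None
        effects = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(self.effect_multipliers).items()
        }
        fractions = {
            k: (None if np.isnan(v) else v)
            for k, v in self.region_live_fractions().items()
        }
        return {
            "geometry": asdict(self.geometry),
            "condition": self.condition,
            "density_label": self.density_label,
            "seed": self.seed,
            "effect_multipliers": effects,
            "region_live_fractions": fractions,
            "cells": [
                {
                    "center_xy": list(c.center_xy),
                    "nucleus_radius_px": c.nucleus_radius_px,
                    "cell_radius_px": c.cell_radius_px,
                    "alive": bool(c.alive),
                    "viability_signal": list(c.viability_signal),
                    "channel_params": {
                        ch: asdict(p) for ch, p in c.channel_params.items()
                    },
                }
                for c in self.cells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneGroundTruth":
        cells = [
            CellSpec(
                center_xy=tuple(c["center_xy"]),
                nucleus_radius_px=c["nucleus_radius_px"],
                cell_radius_px=c["cell_radius_px"],
                alive=c["alive"],
                viability_signal=tuple(c["viability_signal"]),
                channel_params={
                    ch: ChannelDecay(**p) for ch, p in c["channel_params"].items()
                },
            )
            for c in d["cells"]
        ]
        return cls(
            geometry=ChamberGeometry(**d["geometry"]),
            cells=cells,
            condition=d["condition"],
            density_label=d["density_label"],
            seed=d["seed"],
            effect_multipliers=ConditionEffect(**d["effect_multipliers"]),
        )


def _logistic_blend(x_mm: np.ndarray | float, prox: float, dist: float,
                    geometry: ChamberGeometry, midpoint_frac: float,
                    steepness_frac: float):
    """Monotone interpolation from the proximal to the distal plateau."""
    mid = midpoint_frac * geometry.width_mm
    steep = max(steepness_frac * geometry.width_mm, 1e-9)
    w = 1.0 / (1.0 + np.exp((np.asarray(x_mm, dtype=float) - mid) / steep))
    return dist + (prox - dist) * w


def live_probability(x_mm, effect: ConditionEffect, geometry: ChamberGeometry):
    """Probability that a cell at axis position ``x_mm`` is alive."""
    return _logistic_blend(
        x_mm, effect.live[0], effect.live[1], geometry,
        effect.live_midpoint_frac, effect.live_steepness_frac,
    )


def generate_scene(config: SceneConfig) -> SceneGroundTruth:
    """Place cells and assign ground-truth parameters.

    Cell centers are drawn by rejection sampling so that no two nuclei
    overlap (cell bodies may overlap, as in dense tissue). Each cell's
    alive flag is Bernoulli with the logistic axis profile of its
    condition; decay parameters start from the channel baselines, receive
    the condition's position-interpolated redox / lifetime multipliers,
    and per-cell lognormal brightness plus lifetime jitter.
    """
    geometry = config.geometry
    effect = CONDITION_EFFECTS[(config.density_label, config.condition)]
    if config.necrotic_core_fraction is not None:
        if not (0.0 <= config.necrotic_core_fraction <= 1.0):
            raise ValueError("necrotic_core_fraction must lie in [0, 1]")
        effect = ConditionEffect(
            redox=effect.redox,
            nadph_taum=effect.nadph_taum,
            live=(effect.live[0], 0.0),
            live_midpoint_frac=1.0 - config.necrotic_core_fraction,
            live_steepness_frac=0.02,
        )

    n_default, r_cell_default, r_nuc_default = DENSITY_TABLE[config.density_label]
    n_cells = config.n_cells if config.n_cells is not None else n_default
    r_cell = config.cell_radius_px if config.cell_radius_px is not None else r_cell_default
    r_nuc = config.nucleus_radius_px if config.nucleus_radius_px is not None else r_nuc_default

    ny, nx = geometry.shape
    rng = np.random.default_rng(config.seed)

    margin = r_cell + 1.0
    if nx <= 2 * margin or ny <= 2 * margin:
        raise PlacementError("frame too small for the requested cell radius")

    centers: list[tuple[float, float]] = []
    min_sep = 2.0 * r_nuc + 0.5
    for _ in range(n_cells):
        for _attempt in range(config.max_placement_attempts):
            x = rng.uniform(margin, nx - margin)
            y = rng.uniform(margin, ny - margin)
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place {n_cells} cells at density "
                f"{config.density_label!r} after "
                f"{config.max_placement_attempts} attempts per cell"
            )

    cells: list[CellSpec] = []
    for (x, y) in centers:
        x_mm = float(geometry.x_mm(x))
        p_alive = float(live_probability(x_mm, effect, geometry))
        alive = bool(rng.random() < p_alive)

        redox_mult = float(
            _logistic_blend(x_mm, effect.redox[0], effect.redox[1], geometry, 0.5, 0.08)
        )
        taum_mult = float(
            _logistic_blend(
                x_mm, effect.nadph_taum[0], effect.nadph_taum[1], geometry, 0.5, 0.08
            )
        )

        params: dict[str, ChannelDecay] = {}
        # lognormal with mean exactly 1 at the configured CV
        ln_sigma2 = np.log(1.0 + config.intensity_cv**2)
        brightness = float(rng.lognormal(-0.5 * ln_sigma2, np.sqrt(ln_sigma2)))
        for ch in CHANNELS:
            base = BASE_DECAYS[ch]
            jit1 = float(rng.normal(1.0, config.tau_jitter_cv))
            jit2 = float(rng.normal(1.0, config.tau_jitter_cv))
            tau_scale = taum_mult if ch == "NADPH" else 1.0
            intensity = base.mean_intensity * brightness
            if ch == "NADPH":
                intensity *= redox_mult
            params[ch] = ChannelDecay(
                alpha1_frac=base.alpha1_frac,
                tau1_ps=base.tau1_ps * tau_scale * max(jit1, 0.8),
                tau2_ps=base.tau2_ps * tau_scale * max(jit2, 0.8),
                mean_intensity=intensity,
            )
        viability = (1.0, 0.0) if alive else (0.0, 1.0)
        cells.append(
            CellSpec(
                center_xy=(x, y),
                nucleus_radius_px=r_nuc,
                cell_radius_px=r_cell,
                alive=alive,
                channel_params=params,
                viability_signal=viability,
            )
        )
    return SceneGroundTruth(
        geometry=geometry,
        cells=cells,
        condition=config.condition,
        density_label=config.density_label,
        seed=config.seed,
        effect_multipliers=effect,
    )


def _ownership_maps(scene: SceneGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel owning cell index (-1 = background) and distance to its center.

    Where cell discs overlap, the pixel belongs to the cell whose center
    is nearest in radius-normalized distance.
    """
    ny, nx = scene.geometry.shape
    owner = np.full((ny, nx), -1, dtype=np.int32)
    best = np.full((ny, nx), np.inf, dtype=float)
    dist = np.zeros((ny, nx), dtype=float)
    for i, cell in enumerate(scene.cells):
        cx, cy = cell.center_xy
        r = cell.cell_radius_px
        x0, x1 = max(int(cx - r - 1), 0), min(int(cx + r + 2), nx)
        y0, y1 = max(int(cy - r - 1), 0), min(int(cy + r + 2), ny)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        norm = d / r
        inside = norm <= 1.0
        closer = inside & (norm < best[y0:y1, x0:x1])
        sub = owner[y0:y1, x0:x1]
        sub[closer] = i
        best[y0:y1, x0:x1][closer] = norm[closer]
        dist[y0:y1, x0:x1][closer] = d[closer]
    return owner, dist


def _nucleus_mask(scene: SceneGroundTruth) -> np.ndarray:
    """Pixels inside any cell's nucleus (nuclei never overlap by placement)."""
    ny, nx = scene.geometry.shape
    mask = np.zeros((ny, nx), dtype=bool)
    for cell in scene.cells:
        cx, cy = cell.center_xy
        r = cell.nucleus_radius_px
        x0, x1 = max(int(cx - r - 1), 0), min(int(cx + r + 2), nx)
        y0, y1 = max(int(cy - r - 1), 0), min(int(cy + r + 2), ny)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= np.hypot(xx - cx, yy - cy) <= r
    return mask


def decay_shape(params: ChannelDecay, irf: IRFModel, acq: AcquisitionConfig) -> np.ndarray:
    """Expected unit-sum arrival-time distribution of one cell's photons."""
    conv = params.alpha1_frac * exp_irf_conv(
        params.tau1_ps, irf.sampled, acq.bin_width_ps
    ) + (1.0 - params.alpha1_frac) * exp_irf_conv(
        params.tau2_ps, irf.sampled, acq.bin_width_ps
    )
    return conv / conv.sum()


def render_flim_stack(
    scene: SceneGroundTruth,
    channel: str,
    irf: IRFModel,
    acq: AcquisitionConfig,
    seed: int | None = None,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one channel of the scene into a TCSPC photon-count stack.

    Returns ``(stack, true_intensity)`` where ``stack`` has shape
    ``(n_time_bins, rows, cols)`` and ``true_intensity`` is the expected
    photons per pixel (signal + background). With ``noise=True`` counts
    are Poisson; otherwise the noiseless expectation is returned.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    ny, nx = scene.geometry.shape
    owner, _dist = _ownership_maps(scene)
    # nuclei dim every covering cell's signal: without this, overlapping
    # neighbors' cytoplasm would fill in dense-scene nuclei
    in_nucleus = _nucleus_mask(scene)
    lam = np.full((acq.n_time_bins, ny, nx), acq.background_rate, dtype=np.float64)

    budget = np.zeros((ny, nx), dtype=float)
    for i, cell in enumerate(scene.cells):
        mask = owner == i
        if not mask.any():
            continue
        params = cell.channel_params[channel]
        shape = decay_shape(params, irf, acq)
        px_budget = params.mean_intensity * acq.photons_per_bright_pixel
        b = np.where(in_nucleus[mask], px_budget * NUCLEUS_INTENSITY_FRAC, px_budget)
        budget[mask] = b
        lam[:, mask] += shape[:, None] * b[None, :]

    true_intensity = budget + acq.background_rate * acq.n_time_bins
    if not noise:
        return lam, true_intensity
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    stack = rng.poisson(lam).astype(np.uint16)
    return stack, true_intensity


def render_viability_image(
    scene: SceneGroundTruth,
    seed: int | None = None,
    noise: bool = True,
    blob_radius_frac: float = 0.55,
    amplitude: float = 600.0,
    background: float = 10.0,
    read_noise_sd: float = 5.0,
    blur_sigma: float = 1.0,
) -> np.ndarray:
    """Render the two-channel live/dead staining image.

    Channel 0 is green (calcein, live cells), channel 1 is red
    (propidium iodide, dead cells). Cells are bright discs somewhat
    smaller than the cell body (stain concentrates around the nucleus),
    blurred, over a flat background with Gaussian read noise.
    """
    from scipy.ndimage import gaussian_filter

    ny, nx = scene.geometry.shape
    img = np.zeros((2, ny, nx), dtype=np.float64)
    rng = np.random.default_rng(scene.seed + 1 if seed is None else seed)
    for cell in scene.cells:
        cx, cy = cell.center_xy
        r = max(cell.cell_radius_px * blob_radius_frac, 1.2)
        x0, x1 = max(int(cx - r - 1), 0), min(int(cx + r + 2), nx)
        y0, y1 = max(int(cy - r - 1), 0), min(int(cy + r + 2), ny)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (np.hypot(xx - cx, yy - cy) <= r).astype(float)
        jitter = float(rng.normal(1.0, 0.10))
        green, red = cell.viability_signal
        img[0, y0:y1, x0:x1] += disc * amplitude * green * max(jitter, 0.2)
        img[1, y0:y1, x0:x1] += disc * amplitude * red * max(jitter, 0.2)
    for c in range(2):
        img[c] = gaussian_filter(img[c], blur_sigma)
    img += background
    if noise:
        img += rng.normal(0.0, read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None).astype(np.float32)
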