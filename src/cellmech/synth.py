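"""Seeded generators for every input modality, with ground truth attached.

The generators emulate the study conditions of a two-cell-line comparison:

* AFM fast force volume maps — 3 um vertical ramp at 183 um/s with a 0.1 N/m
  cantilever and nN-scale trigger forces; cells are spherical caps on a
  tilted substrate, each pixel carrying power-law-rheology parameters drawn
  around cell-level means. Presets encode a soft/tall/high-alpha cancer-like
  phenotype ("mcf7-like") and a stiff/flat/low-alpha normal epithelial
  phenotype ("mcf10a-like").
* FLIM decays — Poisson photon-limited monoexponential histograms, 256 bins
  over the 12.5 ns window of an 80 MHz excitation train, ~5000 photons per
  region of interest, optionally contaminated by a short-lifetime component.
* ToF-SIMS peak tables — two-class lognormal ion intensities with
  configurable class fold changes over a panel of lipid fragment peaks.
* Fiber images — superpositions of oriented sinusoidal stripes with
  controllable orientation dispersion.

A single top-level seed is split through ``numpy.random.SeedSequence`` so
each modality draws from an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flim import DecayHistogram
from .maps import ForceVolumeMap
from .mechanics import (
    BECSpec,
    ForceCurve,
    IndentationTrajectory,
    PLRParameters,
    TipGeometry,
    apparent_modulus_linear_ramp,
    ting_force,
)
from .sims import PeakTable

__all__ = [
    "CellMechPreset",
    "MCF7_LIKE",
    "MCF10A_LIKE",
    "MapConfig",
    "SceneTruth",
    "FlimConfig",
    "SimsConfig",
    "FiberConfig",
    "DEFAULT_PEAK_PANEL",
    "gen_force_volume",
    "make_force_curve",
    "gen_flim_dataset",
    "gen_peak_tables",
    "gen_fiber_image",
    "modality_rng",
]

_MODALITIES = ("afm", "flim", "sims", "fibers")


def modality_rng(seed: int, modality: str) -> np.random.Generator:
    """Independent generator for one modality derived from the top seed."""
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    children = np.random.SeedSequence(seed).spawn(len(_MODALITIES))
    return np.random.default_rng(children[_MODALITIES.index(modality)])


# ---------------------------------------------------------------------------
# AFM force-volume scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellMechPreset:
    """Cell-level distributions of mechanical parameters and shape.

    Means follow the measured phenotypes of the two cell lines: the
    cancer-like preset is tall, soft and relaxes strongly (high alpha), the
    normal-like preset is flat, stiff and solid-like.
    """

    name: str
    e0_mean: float
    e0_sd: float
    alpha_mean: float
    alpha_sd: float
    eta_mean: float
    eta_sd: float
    height_mean: float
    height_sd: float
    radius_mean: float = 9e-6
    radius_sd: float = 1.5e-6


MCF7_LIKE = CellMechPreset(
    name="mcf7-like", e0_mean=600.0, e0_sd=200.0,
    alpha_mean=0.28, alpha_sd=0.06, eta_mean=1.0, eta_sd=0.25,
    height_mean=7.8e-6, height_sd=2.3e-6, radius_mean=8e-6, radius_sd=1e-6,
)

MCF10A_LIKE = CellMechPreset(
    name="mcf10a-like", e0_mean=5000.0, e0_sd=1500.0,
    alpha_mean=0.14, alpha_sd=0.03, eta_mean=2.0, eta_sd=0.4,
    height_mean=2.4e-6, height_sd=0.5e-6, radius_mean=11e-6, radius_sd=1.5e-6,
)


@dataclass
class MapConfig:
    """Acquisition geometry and scene layout of one force-volume map."""

    shape: tuple[int, int] = (48, 48)
    extent: tuple[float, float] = (60e-6, 60e-6)
    n_cells: int = 3
    preset: CellMechPreset = MCF7_LIKE
    tilt: tuple[float, float] = (5e-3, 2e-3)   # dz/dx, dz/dy (m per m)
    speed: float = 183e-6
    ramp_size: float = 3e-6
    trigger_force: float = 0.75e-9             # within the 0.5-1 nN range
    force_noise: float = 25e-12
    height_noise: float = 5e-9
    param_pixel_cv: float = 0.10
    generate_curves: bool = False
    curve_samples: int = 96                    # per approach segment
    max_placement_tries: int = 2000

    def __post_init__(self) -> None:
        r, c = self.shape
        if r < 2 or c < 2:
            raise ValueError("map must be at least 2 x 2")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not 0.5e-9 - 1e-15 <= self.trigger_force <= 1e-9 + 1e-15:
            # the acquisition protocol uses triggers between 0.5 and 1 nN
            if self.trigger_force <= 0:
                raise ValueError("trigger force must be positive")


@dataclass
class SceneTruth:
    """Ground truth of a generated force-volume scene."""

    cells: pd.DataFrame            # per-cell: centre, radius, height, params
    height: np.ndarray             # true local thickness h (m)
    e0: np.ndarray
    alpha: np.ndarray
    eta: np.ndarray
    e_hertz: np.ndarray            # rate-dependent apparent modulus (Pa)
    plane: tuple[float, float]
    seed: int


def _spherical_cap(rr: np.ndarray, cc: np.ndarray, centre: tuple[float, float],
                   base_radius: float, height: float,
                   pixel: tuple[float, float]) -> np.ndarray:
    """Height field of a spherical cap (m) on the pixel grid."""
    y = (rr - centre[0]) * pixel[0]
    x = (cc - centre[1]) * pixel[1]
    rho2 = x**2 + y**2
    sphere_r = (base_radius**2 + height**2) / (2.0 * height)
    inside = rho2 < base_radius**2
    h = np.zeros_like(rho2)
    h[inside] = np.sqrt(sphere_r**2 - rho2[inside]) - (sphere_r - height)
    return np.clip(h, 0.0, None)


def make_force_curve(params: PLRParameters, geom: TipGeometry,
                     thickness: float = np.inf,
                     bec: BECSpec | None = None,
                     speed: float = 183e-6, trigger_force: float = 0.75e-9,
                     max_depth: float = 1.5e-6, n_approach: int = 96,
                     pre_contact: int = 32, contact_z: float = 0.5e-6,
                     noise: float = 0.0,
                     rng: np.random.Generator | None = None) -> ForceCurve:
    """Synthesize one Ting-model force curve with a triangular ramp.

    The indentation depth is chosen so the Hertz-equivalent force reaches the
    trigger (clipped to ``max_depth``); the piezo coordinate superposes the
    cantilever deflection so that reconstructing indentation as
    ``z - z_c - F/k`` recovers the generating trajectory exactly.
    """
    if bec is None:
        bec = BECSpec(thickness=thickness)
    e_guess = apparent_modulus_linear_ramp(params, 1e-6 / speed)
    nu = geom.poisson_ratio
    pref = 4.0 / 3.0 * e_guess / (1.0 - nu**2) * np.sqrt(geom.radius)
    depth = float(np.clip((trigger_force / pref) ** (2.0 / 3.0),
                          0.2e-6, max_depth))
    tm = depth / speed
    t_app = np.linspace(0.0, tm, n_approach)
    t = np.concatenate([t_app, t_app[1:] + tm])
    d = np.where(t <= tm, speed * t, np.clip(speed * (2 * tm - t), 0.0, None))
    traj = IndentationTrajectory(time=t, indentation=d, t_approach=tm)
    f = ting_force(traj, params, geom, bec)

    dt = t_app[1] - t_app[0]
    t_pre = np.arange(-pre_contact, 0) * dt
    time = np.concatenate([t_pre, t]) - t_pre[0]
    z = np.concatenate([contact_z + speed * t_pre,
                        contact_z + d + f / geom.spring_constant])
    force = np.concatenate([np.zeros(pre_contact), f])
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        force = force + rng.normal(0.0, noise, force.size)
    return ForceCurve(time=time, z=z, force=force, speed=speed,
                      trigger_force=trigger_force, ramp_size=3e-6)


def gen_force_volume(config: MapConfig, seed: int,
                     geom: TipGeometry | None = None
                     ) -> tuple[ForceVolumeMap, SceneTruth]:
    """Generate a force-volume map of spherical-cap cells on a tilted substrate.

    Returns the map (contact heights always; per-pixel curves when
    ``config.generate_curves``) together with the scene truth: per-pixel
    thickness and PLR parameters, the rate-dependent apparent modulus, and
    the per-cell table. Identical seeds give bit-identical scenes.
    """
    rng = modality_rng(seed, "afm")
    geom = geom or TipGeometry()
    rows, cols = config.shape
    pixel = (config.extent[0] / rows, config.extent[1] / cols)
    preset = config.preset

    # non-overlapping cell placement (rejection sampling)
    cells = []
    tries = 0
    while len(cells) < config.n_cells:
        if tries > config.max_placement_tries:
            raise ValueError(
                f"could not place {config.n_cells} non-overlapping cells "
                f"of radius ~{preset.radius_mean * 1e6:.0f} um on a "
                f"{config.extent[0] * 1e6:.0f} um map: packing limit exceeded")
        tries += 1
        radius = max(rng.normal(preset.radius_mean, preset.radius_sd), 2e-6)
        if (radius / pixel[0] >= rows - radius / pixel[0]
                or radius / pixel[1] >= cols - radius / pixel[1]):
            continue    # cell would not fit on the map at all
        centre = (rng.uniform(radius / pixel[0], rows - radius / pixel[0]),
                  rng.uniform(radius / pixel[1], cols - radius / pixel[1]))
        if any(np.hypot((centre[0] - c["row"]) * pixel[0],
                        (centre[1] - c["col"]) * pixel[1])
               < radius + c["radius"] + 1e-6 for c in cells):
            continue
        height = max(rng.normal(preset.height_mean, preset.height_sd), 0.4e-6)
        cells.append({
            "cell": len(cells) + 1, "row": centre[0], "col": centre[1],
            "radius": radius, "height": height,
            "e0": max(rng.normal(preset.e0_mean, preset.e0_sd), 50.0),
            "alpha": float(np.clip(rng.normal(preset.alpha_mean,
                                              preset.alpha_sd), 0.01, 0.9)),
            "eta": max(rng.normal(preset.eta_mean, preset.eta_sd), 0.05),
        })

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    height = np.zeros(config.shape)
    e0 = np.full(config.shape, np.nan)
    alpha = np.full(config.shape, np.nan)
    eta = np.full(config.shape, np.nan)
    cv = config.param_pixel_cv
    for c in cells:
        cap = _spherical_cap(rr, cc, (c["row"], c["col"]), c["radius"],
                             c["height"], pixel)
        m = cap > height     # taller surface wins (cells never overlap anyway)
        height[m] = cap[m]
        npix = int(m.sum())
        e0[m] = np.clip(c["e0"] * (1 + cv * rng.standard_normal(npix)), 20.0, None)
        alpha[m] = np.clip(c["alpha"] * (1 + cv * rng.standard_normal(npix)),
                           0.005, 0.95)
        eta[m] = np.clip(c["eta"] * (1 + cv * rng.standard_normal(npix)),
                         0.01, None)

    ramp_time = 1e-6 / config.speed    # nominal 1 um indentation time
    e_hertz = np.full(config.shape, np.nan)
    on_cell = height > 0
    for idx in zip(*np.nonzero(on_cell)):
        e_hertz[idx] = apparent_modulus_linear_ramp(
            PLRParameters(e0[idx], alpha[idx], eta[idx]), ramp_time)

    plane = (config.tilt[0] * pixel[0], config.tilt[1] * pixel[1])
    contact = (height + plane[0] * rr + plane[1] * cc
               + rng.normal(0.0, config.height_noise, config.shape))

    curves = None
    if config.generate_curves:
        curves = {}
        for idx in zip(*np.nonzero(on_cell)):
            params = PLRParameters(e0[idx], alpha[idx], eta[idx])
            curves[idx] = make_force_curve(
                params, geom, thickness=height[idx],
                speed=config.speed, trigger_force=config.trigger_force,
                n_approach=config.curve_samples,
                contact_z=float(contact[idx]),
                noise=config.force_noise, rng=rng)

    fv = ForceVolumeMap(shape=config.shape, extent=config.extent,
                        curves=curves, contact_height=contact)
    truth = SceneTruth(cells=pd.DataFrame(cells), height=height,
                       e0=e0, alpha=alpha, eta=eta, e_hertz=e_hertz,
                       plane=plane, seed=seed)
    return fv, truth


# ---------------------------------------------------------------------------
# FLIM decays
# ---------------------------------------------------------------------------

@dataclass
class FlimConfig:
    """ROI decay simulation: lifetimes, photon budget, contamination."""

    n_rois: int = 60
    tau_mean: float = 2.49       # ns
    tau_sd: float = 0.23
    photons: int = 5000
    n_bins: int = 256
    window: float = 12.5         # ns (80 MHz repetition)
    start_bin: int = 8           # instrument delay before the decay peak
    contamination_fraction: float = 0.0
    contaminant_tau: float = 0.5

    def __post_init__(self) -> None:
        if self.photons < 100:
            raise ValueError("photon budget must be at least 100")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination fraction must lie in [0, 1)")


def gen_flim_dataset(config: FlimConfig, seed: int
                     ) -> tuple[dict[str, DecayHistogram], pd.DataFrame]:
    """Poisson-sampled (optionally contaminated) monoexponential ROI decays.

    Each ROI draws a true lifetime from N(tau_mean, tau_sd); the expected
    histogram is the exponential decay over the TCSPC window starting at
    ``start_bin``, scaled to the photon budget, then Poisson-sampled.
    Returns the decays and a truth table (ROI, true lifetime, photons).
    """
    rng = modality_rng(seed, "flim")
    bin_w = config.window / config.n_bins
    t = (np.arange(config.n_bins) + 0.5) * bin_w
    t0 = config.start_bin * bin_w
    decays: dict[str, DecayHistogram] = {}
    rows = []
    for i in range(config.n_rois):
        tau = max(rng.normal(config.tau_mean, config.tau_sd), 0.2)
        shape = np.where(t >= t0, np.exp(-(t - t0) / tau), 0.0)
        if config.contamination_fraction > 0:
            short = np.where(t >= t0,
                             np.exp(-(t - t0) / config.contaminant_tau), 0.0)
            shape = ((1 - config.contamination_fraction) * shape / shape.sum()
                     + config.contamination_fraction * short / short.sum())
        expected = shape / shape.sum() * config.photons
        counts = rng.poisson(expected)
        roi = f"roi{i:03d}"
        decays[roi] = DecayHistogram(counts=counts, bin_width=bin_w)
        rows.append({"roi": roi, "tau_true": tau,
                     "photons": int(counts.sum())})
    return decays, pd.DataFrame(rows).set_index("roi")


# ---------------------------------------------------------------------------
# ToF-SIMS peak tables
# ---------------------------------------------------------------------------

#: (m/z, assignment, group, base normalized intensity, cancer/normal fold).
#: Saturated fatty-acid fragments share one fold so that the ratio-based
#: saturation truths are exactly the configured MUFA/SFA and PUFA/SFA values.
DEFAULT_PEAK_PANEL: tuple[tuple[float, str, str, float, float], ...] = (
    (224.1, "PC", "phospholipid", 4.0e-3, 1 / 2.0),
    (264.2, "SM", "phospholipid", 2.0e-3, 2.2),
    (259.1, "PI", "phospholipid", 3.0e-3, 1 / 7.1),
    (369.3, "cholesterol", "sterol", 6.0e-3, 1.0),
    (180.06, "Tyr", "amino-acid", 2.0e-3, 1.7),
    (227.2, "C14:0", "SFA", 1.0e-2, 1.5),
    (255.2, "C16:0", "SFA", 2.0e-2, 1.5),
    (283.3, "C18:0", "SFA", 1.5e-2, 1.5),
    (253.2, "C16:1", "MUFA", 8.0e-3, 1.5 * 1.8),
    (281.2, "C18:1", "MUFA", 1.8e-2, 1.5 * 1.8),
    (279.2, "C18:2", "PUFA", 9.0e-3, 1.5 / 6.0),
    (303.2, "C20:4", "PUFA", 6.0e-3, 1.5 / 6.0),
    (96.96, "phosphate", "other", 2.5e-2, 1.0),
    (78.96, "PO3", "other", 3.0e-2, 1.0),
    (59.0, "frag59", "other", 1.2e-2, 1.0),
    (71.0, "frag71", "other", 9.0e-3, 1.0),
    (87.0, "frag87", "other", 7.0e-3, 1.0),
    (101.0, "frag101", "other", 5.0e-3, 1.0),
    (115.0, "frag115", "other", 4.0e-3, 1.0),
    (129.0, "frag129", "other", 3.0e-3, 1.0),
)


@dataclass
class SimsConfig:
    """Two-class lognormal peak-table simulation."""

    n_per_class: tuple[int, int] = (20, 21)
    sigma_log: float = 0.3
    tic_mean: float = 1e6
    panel: tuple = DEFAULT_PEAK_PANEL
    class_names: tuple[str, str] = ("cancer", "normal")
    fold_overrides: dict = field(default_factory=dict)
    polarity: str = "negative"

    def folds(self) -> dict[str, float]:
        f = {name: fold for _, name, _, _, fold in self.panel}
        f.update(self.fold_overrides)
        if any(v <= 0 for v in f.values()):
            raise ValueError("fold changes must be positive")
        return f


def gen_peak_tables(config: SimsConfig, seed: int
                    ) -> tuple[PeakTable, np.ndarray, dict]:
    """Two-class lognormal ToF-SIMS peak table with known fold changes.

    Raw intensities are ``base * fold^(class) * TIC_s * lognormal(sigma)``;
    the per-spectrum TIC is stored so that TIC normalization recovers the
    configured normalized scale. Returns ``(table, labels, truth)`` where
    truth holds the per-peak fold changes (first class / second class) and
    the saturation-ratio truths.
    """
    rng = modality_rng(seed, "sims")
    folds = config.folds()
    n1, n2 = config.n_per_class
    labels = np.array([config.class_names[0]] * n1 + [config.class_names[1]] * n2)
    tic = config.tic_mean * rng.lognormal(0.0, 0.2, n1 + n2)
    cols, names, groups = [], {}, {}
    data = np.zeros((n1 + n2, len(config.panel)))
    for j, (mz, name, group, base, _) in enumerate(config.panel):
        fold = folds[name]
        scale = np.where(labels == config.class_names[0], base * fold, base)
        # divide by exp(sigma^2/2) so the *mean* matches the configured scale
        data[:, j] = (scale * tic
                      * rng.lognormal(-0.5 * config.sigma_log**2,
                                      config.sigma_log, n1 + n2))
        cols.append(mz)
        names[mz] = name
        groups.setdefault(group, []).append(mz)
    spectra = [f"s{i:02d}" for i in range(n1 + n2)]
    table = PeakTable(
        intensities=pd.DataFrame(data, index=spectra, columns=cols),
        tic=pd.Series(tic, index=spectra), names=names,
        polarity=config.polarity,
    )
    sfa_fold = folds["C14:0"]
    truth = {
        "folds": {mz: folds[names[mz]] for mz in cols},
        "fold_by_name": dict(folds),
        "groups": groups,
        "MUFA/SFA": folds["C18:1"] / sfa_fold,
        "PUFA/SFA": folds["C18:2"] / sfa_fold,
    }
    return table, labels, truth


# ---------------------------------------------------------------------------
# fiber images
# ---------------------------------------------------------------------------

@dataclass
class FiberConfig:
    """Oriented-stripe image simulation with orientation dispersion."""

    shape: tuple[int, int] = (192, 192)
    n_stripes: int = 48
    mean_angle: float = 0.0       # radians
    dispersion: float = 0.0       # angular SD (radians), kappa >= 0
    wavelength: float = 8.0       # stripe period, px
    noise: float = 0.02

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def gen_fiber_image(config: FiberConfig, seed: int
                    ) -> tuple[np.ndarray, dict]:
    """Sum of sinusoidal stripe fields with dispersed orientations.

    Each stripe field is a full-frame sinusoid whose normal is drawn around
    ``mean_angle`` with SD ``dispersion``; Gaussian pixel noise is added.
    Returns the image and the truth (angles, dispersion).
    """
    rng = modality_rng(seed, "fibers")
    yy, xx = np.meshgrid(np.arange(config.shape[0]),
                         np.arange(config.shape[1]), indexing="ij")
    angles = rng.normal(config.mean_angle, config.dispersion, config.n_stripes)
    phases = rng.uniform(0.0, 2.0 * np.pi, config.n_stripes)
    k = 2.0 * np.pi / config.wavelength
    img = np.zeros(config.shape)
    for th, ph in zip(angles, phases):
        img += np.cos(k * (xx * np.cos(th) + yy * np.sin(th)) + ph)
    img /= np.sqrt(config.n_stripes)
    if config.noise > 0:
        img = img + rng.normal(0.0, config.noise, config.shape)
    truth = {"angles": angles, "dispersion": config.dispersion,
             "mean_angle": config.mean_angle}
    return img, truth
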