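"""Force-volume map processing: topography, cell segmentation, summaries.

A fast force volume (FFV) map is a grid of force-distance curves. The
contact-point position of each curve gives the local surface height; after a
global tilt correction the substrate sits at zero and everything above a
background threshold (default 200 nm) is treated as cell material. Cells are
connected components of the foreground; per-cell statistics are computed
over a *central mask* — the pixels above half of that cell's maximum height,
which avoids the thin actin-rich periphery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .mechanics import ForceCurve, TipGeometry, detect_contact_point

__all__ = [
    "ForceVolumeMap",
    "TopographyMap",
    "NoBackgroundError",
    "build_topography",
    "segment_and_mask",
    "cell_summary",
]

#: default background threshold: local height below this is substrate (m)
BACKGROUND_HEIGHT = 200e-9
#: central mask: pixels above this fraction of the cell's maximum height
CENTRAL_FRACTION = 0.5


class NoBackgroundError(RuntimeError):
    """Raised when no substrate pixels can be identified for the tilt plane."""


@dataclass
class ForceVolumeMap:
    """Grid of per-pixel force curves and/or pre-extracted contact heights.

    Either ``curves`` (mapping ``(row, col) -> ForceCurve``) or
    ``contact_height`` (2-D array of contact-point z, in metres) must be
    provided; missing pixels are flagged in ``missing``.
    """

    shape: tuple[int, int]
    extent: tuple[float, float]  # physical size (m), rows x cols
    curves: dict[tuple[int, int], ForceCurve] | None = None
    contact_height: np.ndarray | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        r, c = self.shape
        if r < 2 or c < 2:
            raise ValueError("map must be at least 2 x 2")
        if self.curves is None and self.contact_height is None:
            raise ValueError("need per-pixel curves or contact heights")
        if self.contact_height is not None:
            self.contact_height = np.asarray(self.contact_height, dtype=float)
            if self.contact_height.shape != self.shape:
                raise ValueError("contact_height shape mismatch")
        if self.missing is None:
            self.missing = np.zeros(self.shape, dtype=bool)

    @property
    def pixel_size(self) -> tuple[float, float]:
        return (self.extent[0] / self.shape[0], self.extent[1] / self.shape[1])


@dataclass
class TopographyMap:
    """Tilt-corrected per-pixel heights with substrate at zero."""

    height: np.ndarray          # m
    valid: np.ndarray           # bool: pixel had a detectable contact
    plane: tuple[float, float, float] = (0.0, 0.0, 0.0)  # subtracted a*r+b*c+d

    @property
    def background(self) -> np.ndarray:
        return self.valid & (self.height < BACKGROUND_HEIGHT)


def _fit_plane(rows: np.ndarray, cols: np.ndarray, h: np.ndarray) -> np.ndarray:
    a = np.column_stack([rows, cols, np.ones_like(rows, dtype=float)])
    coef, *_ = np.linalg.lstsq(a, h, rcond=None)
    return coef


def build_topography(fv: ForceVolumeMap, geom: TipGeometry | None = None,
                     refine_passes: int = 2,
                     plane_band: float = 100e-9) -> TopographyMap:
    """Extract surface height per pixel and remove the global tilt plane.

    The raw height is the contact-point z of each curve. Substrate pixels are
    identified iteratively: an initial low-quantile set seeds a least-squares
    plane; pixels within ``plane_band`` (default 100 nm) of the plane are
    re-selected and the plane refit (``refine_passes`` times). The plane is
    subtracted so the substrate sits at height 0.
    """
    rows, cols = fv.shape
    if fv.contact_height is not None:
        h = fv.contact_height.copy()
        valid = ~fv.missing
    else:
        h = np.full(fv.shape, np.nan)
        geom = geom or TipGeometry()
        for (r, c), curve in fv.curves.items():
            try:
                _, zc = detect_contact_point(curve, geom)
                h[r, c] = zc
            except Exception:
                pass
        valid = np.isfinite(h)
    if valid.sum() < 0.1 * h.size:
        raise NoBackgroundError("fewer than 10% of pixels have a contact point")

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    hv = h[valid]
    # seed: the lowest 40% of heights are candidate substrate
    seed = hv <= np.quantile(hv, 0.4)
    sel_r, sel_c, sel_h = rr[valid][seed], cc[valid][seed], hv[seed]
    if sel_h.size < 3:
        raise NoBackgroundError("no background plane: too few substrate pixels")
    coef = _fit_plane(sel_r, sel_c, sel_h)
    for _ in range(refine_passes):
        plane_all = coef[0] * rr[valid] + coef[1] * cc[valid] + coef[2]
        near = np.abs(hv - plane_all) < plane_band
        if near.sum() < 3:
            raise NoBackgroundError("no background plane: refinement emptied the set")
        coef = _fit_plane(rr[valid][near], cc[valid][near], hv[near])

    corrected = h - (coef[0] * rr + coef[1] * cc + coef[2])
    corrected[~valid] = np.nan
    return TopographyMap(height=corrected, valid=valid,
                         plane=(float(coef[0]), float(coef[1]), float(coef[2])))


def segment_and_mask(topo: TopographyMap,
                     background_height: float = BACKGROUND_HEIGHT,
                     central_fraction: float = CENTRAL_FRACTION,
                     connectivity: int = 4,
                     quantile_mode: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Label cells and derive per-cell central masks.

    Pixels below ``background_height`` are substrate. Remaining pixels are
    grouped into cells by 4-connectivity (8 if ``connectivity=8``). The
    central mask of a cell holds the pixels above ``central_fraction`` of the
    cell's maximum height; with ``quantile_mode=True`` it instead keeps the
    top ``central_fraction`` of the cell's pixels by height (count quantile).

    Returns ``(labels, central)`` where ``labels`` is 0 for background and
    ``central`` a boolean map of the union of central masks.
    """
    h = topo.height
    fg = topo.valid & (h >= background_height)
    structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if connectivity == 4
                 else np.ones((3, 3), dtype=int))
    labels, n = ndimage.label(fg, structure=structure)
    central = np.zeros_like(fg)
    for lab in range(1, n + 1):
        m = labels == lab
        if quantile_mode:
            thr = np.nanquantile(h[m], 1.0 - central_fraction)
            central |= m & (h >= thr)
        else:
            thr = central_fraction * np.nanmax(h[m])
            central |= m & (h > thr)
    return labels, central


def cell_summary(labels: np.ndarray, central: np.ndarray,
                 topo: TopographyMap,
                 param_maps: dict[str, np.ndarray] | None = None,
                 fit_valid: np.ndarray | None = None) -> pd.DataFrame:
    """Arithmetic per-cell means over each cell's central mask.

    ``param_maps`` are per-pixel parameter images congruent with the
    topography grid (e.g. ``E_hertz``, ``E0``, ``alpha``, ``eta``). Pixels
    with failed fits (``fit_valid`` False or non-finite values) are excluded
    from the means and counted. Cells whose central mask is empty are skipped
    with a warning.
    """
    param_maps = param_maps or {}
    for name, m in param_maps.items():
        if m.shape != labels.shape:
            raise ValueError(f"parameter map {name!r} shape mismatch")
    if fit_valid is None:
        fit_valid = np.ones(labels.shape, dtype=bool)
    records = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        cmask = (labels == lab) & central
        if not cmask.any():
            warnings.warn(f"cell {lab}: empty central mask, skipped")
            continue
        rec = {
            "cell_id": int(lab),
            "n_pixels": int(cmask.sum()),
            "mean_height": float(np.nanmean(topo.height[cmask])),
        }
        use = cmask & fit_valid
        rec["n_excluded"] = int(cmask.sum() - use.sum())
        for name, m in param_maps.items():
            vals = m[use]
            vals = vals[np.isfinite(vals)]
            rec[f"mean_{name}"] = float(np.mean(vals)) if vals.size else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)
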