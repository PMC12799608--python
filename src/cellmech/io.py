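"""File I/O for the open exchange formats the pipeline consumes and produces.

* Force curves: HDF5 with datasets ``/curves/<id>/{t,z,F}`` (float64, SI) and
  attributes ``{k, R, v, trigger_force}``; single-curve TSV with ``# k=...``
  header lines and columns ``t_s  z_m  F_N``.
* TCSPC decays: HDF5 ``/decays/<roi>/counts`` with attrs ``{bin_ns}``; CSV
  alternative with columns ``bin_index, counts``.
* Peak tables: CSV with an ``mz`` column, optional ``name`` column and one
  intensity column per spectrum; polarity in a ``# polarity=`` header
  comment. Class labels: CSV ``spectrum_id,class``.
* Maps: 32-bit single-channel TIFF plus a JSON sidecar with pixel size and
  units; ROI/label images as integer TIFF.

Proprietary vendor formats are out of scope by design.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .flim import DecayHistogram
from .mechanics import ForceCurve, TipGeometry
from .sims import PeakTable

__all__ = [
    "save_curves_h5", "load_curves_h5", "save_curve_tsv", "load_curve_tsv",
    "save_decays_h5", "load_decays_h5", "save_decay_csv", "load_decay_csv",
    "save_peak_table", "load_peak_table", "save_labels", "load_labels",
    "save_map_tiff", "load_map_tiff", "load_label_tiff",
]


# -- force curves -----------------------------------------------------------

def save_curves_h5(path, curves: dict[str, ForceCurve],
                   geom: TipGeometry | None = None) -> None:
    geom = geom or TipGeometry()
    with h5py.File(path, "w") as f:
        root = f.create_group("curves")
        root.attrs["k"] = geom.spring_constant
        root.attrs["R"] = geom.radius
        for cid, c in curves.items():
            g = root.create_group(str(cid))
            g.create_dataset("t", data=c.time)
            g.create_dataset("z", data=c.z)
            g.create_dataset("F", data=c.force)
            g.attrs["v"] = c.speed
            g.attrs["trigger_force"] = c.trigger_force
            g.attrs["ramp_size"] = c.ramp_size


def load_curves_h5(path) -> tuple[dict[str, ForceCurve], TipGeometry]:
    curves = {}
    with h5py.File(path, "r") as f:
        root = f["curves"]
        geom = TipGeometry(radius=float(root.attrs.get("R", 70e-9)),
                           spring_constant=float(root.attrs.get("k", 0.1)))
        for cid, g in root.items():
            curves[cid] = ForceCurve(
                time=g["t"][:], z=g["z"][:], force=g["F"][:],
                speed=float(g.attrs.get("v", 183e-6)),
                trigger_force=float(g.attrs.get("trigger_force", 1e-9)),
                ramp_size=float(g.attrs.get("ramp_size", 3e-6)),
            )
    return curves, geom


def save_curve_tsv(path, curve: ForceCurve, geom: TipGeometry | None = None) -> None:
    geom = geom or TipGeometry()
    header = (f"# k={geom.spring_constant}\n# R={geom.radius}\n"
              f"# v={curve.speed}\n# trigger_force={curve.trigger_force}\n"
              f"# ramp_size={curve.ramp_size}\n"
              "t_s\tz_m\tF_N\n")
    with open(path, "w") as fh:
        fh.write(header)
        for row in zip(curve.time, curve.z, curve.force):
            fh.write("\t".join(f"{v:.9e}" for v in row) + "\n")


def load_curve_tsv(path) -> tuple[ForceCurve, TipGeometry]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("=")
            meta[key.strip()] = float(val)
        elif ln.strip() and not ln.startswith("t_s"):
            body.append([float(x) for x in ln.split()])
    arr = np.asarray(body)
    geom = TipGeometry(radius=meta.get("R", 70e-9),
                       spring_constant=meta.get("k", 0.1))
    curve = ForceCurve(time=arr[:, 0], z=arr[:, 1], force=arr[:, 2],
                       speed=meta.get("v", 183e-6),
                       trigger_force=meta.get("trigger_force", 1e-9),
                       ramp_size=meta.get("ramp_size", 3e-6))
    return curve, geom


# -- TCSPC decays -----------------------------------------------------------

def save_decays_h5(path, decays: dict[str, DecayHistogram]) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("decays")
        for roi, d in decays.items():
            g = root.create_group(str(roi))
            g.create_dataset("counts", data=np.asarray(d.counts, dtype=np.int64))
            g.attrs["bin_ns"] = d.bin_width


def load_decays_h5(path) -> dict[str, DecayHistogram]:
    out = {}
    with h5py.File(path, "r") as f:
        for roi, g in f["decays"].items():
            out[roi] = DecayHistogram(counts=g["counts"][:],
                                      bin_width=float(g.attrs["bin_ns"]))
    return out


def save_decay_csv(path, decay: DecayHistogram) -> None:
    df = pd.DataFrame({"bin_index": np.arange(decay.counts.size),
                       "counts": decay.counts})
    with open(path, "w") as fh:
        fh.write(f"# bin_ns={decay.bin_width}\n")
        df.to_csv(fh, index=False)


def load_decay_csv(path) -> DecayHistogram:
    with open(path) as fh:
        first = fh.readline()
        bin_ns = float(first.partition("=")[2]) if first.startswith("#") else None
    df = pd.read_csv(path, comment="#")
    if bin_ns is None:
        raise ValueError("decay CSV is missing the '# bin_ns=' header")
    return DecayHistogram(counts=df["counts"].to_numpy(), bin_width=bin_ns)


# -- peak tables ------------------------------------------------------------

def save_peak_table(path, table: PeakTable) -> None:
    df = table.intensities.T     # rows: peaks; columns: spectra
    out = pd.DataFrame({"mz": df.index})
    if table.names:
        out["name"] = [table.names.get(mz, "") for mz in df.index]
    for col in df.columns:
        out[col] = df[col].to_numpy()
    with open(path, "w") as fh:
        fh.write(f"# polarity={table.polarity}\n")
        if table.tic is not None:
            fh.write("# tic=" + ",".join(f"{v:.6g}" for v in table.tic) + "\n")
        out.to_csv(fh, index=False)


def load_peak_table(path) -> PeakTable:
    polarity, tic_vals = "negative", None
    with open(path) as fh:
        for ln in fh:
            if not ln.startswith("#"):
                break
            key, _, val = ln[1:].partition("=")
            if key.strip() == "polarity":
                polarity = val.strip()
            elif key.strip() == "tic":
                tic_vals = [float(x) for x in val.split(",")]
    df = pd.read_csv(path, comment="#")
    names = {}
    if "name" in df.columns:
        names = {mz: nm for mz, nm in zip(df["mz"], df["name"]) if nm}
        df = df.drop(columns=["name"])
    intens = df.set_index("mz").T
    intens.columns = list(intens.columns)
    tic = (pd.Series(tic_vals, index=intens.index)
           if tic_vals is not None else None)
    return PeakTable(intensities=intens, tic=tic, names=names,
                     polarity=polarity)


def save_labels(path, labels, spectra=None) -> None:
    idx = spectra if spectra is not None else range(len(labels))
    pd.DataFrame({"spectrum_id": list(idx), "class": list(labels)}
                 ).to_csv(path, index=False)


def load_labels(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["class"].to_numpy(), index=df["spectrum_id"])


# -- maps and ROI images ----------------------------------------------------

def save_map_tiff(path, data: np.ndarray, units: str,
                  pixel_size: tuple[float, float] | None = None,
                  masks: dict | None = None) -> None:
    """Write a 32-bit single-channel TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))
    sidecar = {"units": units}
    if pixel_size is not None:
        sidecar["pixel_size_m"] = list(pixel_size)
    if masks:
        sidecar["masks"] = {
            name: _rle_encode(np.asarray(m, dtype=bool))
            for name, m in masks.items()
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_map_tiff(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = {}
    if path.with_suffix(".json").exists():
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if "masks" in sidecar:
            sidecar["masks"] = {
                name: _rle_decode(spec) for name, spec in sidecar["masks"].items()
            }
    return data, sidecar


def load_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)


def _rle_encode(mask: np.ndarray) -> dict:
    flat = mask.ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds).tolist()
    return {"shape": list(mask.shape), "first": bool(flat[0]), "runs": runs}


def _rle_decode(spec: dict) -> np.ndarray:
    vals = []
    val = spec["first"]
    for run in spec["runs"]:
        vals.append(np.full(run, val, dtype=bool))
        val = not val
    return np.concatenate(vals).reshape(spec["shape"])
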