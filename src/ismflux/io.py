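"""Reading and writing of MDF sets, count tensors and localization tables.

MDF sets and count tensors go to HDF5 (h5py); MDF sets can additionally be
exported as multi-page TIFF (orbit-major, element-minor page order) with a
JSON sidecar carrying the geometry. Localizations go to CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .estimator import LocalizationResult
from .geometry import DetectorGeometry, GridSpec, OrbitGeometry
from .mdf import MDFSet
from .simulate import CountTensor

__all__ = [
    "save_mdf", "load_mdf", "export_mdf_tiff", "save_tensor", "load_tensor",
    "localizations_to_csv", "read_localizations",
]


def _meta_dict(mdf: MDFSet) -> dict:
    return {
        "grid": {"pixel_size": mdf.grid.pixel_size,
                 "n_pixels": mdf.grid.n_pixels},
        "detector": {
            "n_rows": mdf.detector.n_rows, "n_cols": mdf.detector.n_cols,
            "pitch": mdf.detector.pitch,
            "element_size": mdf.detector.element_size,
            "excluded_elements": sorted(mdf.detector.excluded_elements)},
        "orbit": {"L": mdf.orbit.L, "alpha0": mdf.orbit.alpha0,
                  "direction": mdf.orbit.direction,
                  "n_positions": mdf.orbit.n_positions,
                  "period": mdf.orbit.period},
        "provenance": mdf.provenance,
    }


def _mdf_from_meta(base: np.ndarray, meta: dict) -> MDFSet:
    det = dict(meta["detector"])
    det["excluded_elements"] = frozenset(det.get("excluded_elements", []))
    return MDFSet(
        base=base, grid=GridSpec(**meta["grid"]),
        detector=DetectorGeometry(**det), orbit=OrbitGeometry(**meta["orbit"]),
        provenance=meta.get("provenance", "simulated"))


def save_mdf(path, mdf: MDFSet) -> None:
    """Write an MDF set (base stack + geometry metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("mdf")
        g.create_dataset("base", data=mdf.base.astype(np.float32),
                         compression="gzip")
        g.attrs["meta"] = json.dumps(_meta_dict(mdf))


def load_mdf(path) -> MDFSet:
    with h5py.File(path, "r") as f:
        g = f["mdf"]
        base = g["base"][...].astype(float)
        meta = json.loads(g.attrs["meta"])
    return _mdf_from_meta(base, meta)


def export_mdf_tiff(path, mdf: MDFSet) -> None:
    """Materialize the full shifted stack as multi-page TIFF + JSON sidecar.

    Page order is orbit-major, element-minor: page k = (i * N_d + j).
    """
    pages = mdf.values.reshape(-1, mdf.grid.n_pixels, mdf.grid.n_pixels)
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps(_meta_dict(mdf), indent=2))


def save_tensor(path, tensor: CountTensor) -> None:
    """Write a photon-count tensor (counts[N_t, N_c, N_d] + orbit) to HDF5."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=tensor.counts,
                             compression="gzip")
        d.attrs["t0"] = tensor.t0
        if tensor.seed is not None:
            d.attrs["seed"] = tensor.seed
        d.attrs["orbit"] = json.dumps({
            "L": tensor.orbit.L, "alpha0": tensor.orbit.alpha0,
            "direction": tensor.orbit.direction,
            "n_positions": tensor.orbit.n_positions,
            "period": tensor.orbit.period})


def load_tensor(path) -> CountTensor:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        counts = d[...]
        orbit = OrbitGeometry(**json.loads(d.attrs["orbit"]))
        t0 = float(d.attrs.get("t0", 0.0))
        seed = int(d.attrs["seed"]) if "seed" in d.attrs else None
    return CountTensor(counts=counts, orbit=orbit, t0=t0, seed=seed)


def localizations_to_csv(path, results, event_ids=None,
                         segments=None) -> pd.DataFrame:
    """Write LocalizationResults as a CSV table; returns the DataFrame."""
    rows = []
    for k, res in enumerate(results):
        if res is None:
            continue
        flags = ";".join(fl for fl, on in
                         [("on_border", res.on_border),
                          ("degenerate", res.degenerate)] if on)
        rows.append({
            "event_id": event_ids[k] if event_ids is not None else k,
            "segment": segments[k] if segments is not None else 0,
            "x_nm": res.x, "y_nm": res.y, "n_photons": res.n_photons,
            "loglik": res.log_likelihood, "flags": flags})
    df = pd.DataFrame(rows, columns=["event_id", "segment", "x_nm", "y_nm",
                                     "n_photons", "loglik", "flags"])
    df.to_csv(path, index=False)
    return df


def read_localizations(path) -> pd.DataFrame:
    return pd.read_csv(path)
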