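"""Plain-text containers for curves, maps, decays and lipid tables.

Formats are deliberately simple and open:

* force curve: tab-separated ``t_s  z_nm  force_nN`` (one file per curve);
* force-volume map: one directory per map with ``metadata.json`` (probe,
  ramp/units, seed, grid shape) and one curve file per pixel,
  ``curve_<i>_<j>.tsv``;
* TCSPC decay: tab-separated ``t_ns  counts`` plus a JSON metadata sidecar;
* lipid table: CSV with columns ``line,replicate,component,raw_intensity,
  total_ion_count`` (raw) or ``line,component,ion_yield`` (normalized).

Readers validate the structural invariants (monotone time, non-negative
counts, exactly one approach/retract transition) so that every generated
dataset round-trips through its reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .afm_mechanics import ForceCurve, ForceVolumeMap, ProbeGeometry
from .flim_viscosity import DecayHistogram

_CURVE_HEADER = "t_s\tz_nm\tforce_nN"


def write_force_curve(path: str | Path, curve: ForceCurve) -> Path:
    path = Path(path)
    arr = np.column_stack(
        [curve.t_s, np.asarray(curve.z_um) * 1e3, curve.force_nN]
    )
    meta = {k: v for k, v in curve.meta.items() if not isinstance(v, np.ndarray)}
    header = _CURVE_HEADER + f"\n# n_approach={curve.n_approach}\n# meta={json.dumps(meta, default=str)}"
    np.savetxt(path, arr, fmt="%.9g", delimiter="\t", header=header)
    return path


def read_force_curve(path: str | Path, probe: ProbeGeometry) -> ForceCurve:
    path = Path(path)
    n_approach, meta = None, {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("# ").strip()
            if body.startswith("n_approach="):
                n_approach = int(body.split("=", 1)[1])
            elif body.startswith("meta="):
                meta = json.loads(body.split("=", 1)[1])
    if n_approach is None:
        raise ValueError(f"{path}: missing n_approach header")
    arr = np.loadtxt(path)
    curve = ForceCurve(
        t_s=arr[:, 0],
        z_um=arr[:, 1] * 1e-3,
        force_nN=arr[:, 2],
        probe=probe,
        n_approach=n_approach,
        meta=meta,
    )
    curve.validate()
    return curve


def write_map(directory: str | Path, fv_map: ForceVolumeMap) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ny, nx = fv_map.shape
    meta = {
        "shape": [ny, nx],
        "pixel_size_um": fv_map.pixel_size_um,
        "probe": asdict(fv_map.probe),
        "units": {"t": "s", "z": "nm", "force": "nN"},
        "seed": fv_map.meta.get("seed"),
        "tilt_nm_per_um": list(fv_map.meta.get("tilt_nm_per_um", (0.0, 0.0))),
        "map_size_um": fv_map.meta.get("map_size_um"),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    for i in range(ny):
        for j in range(nx):
            write_force_curve(directory / f"curve_{i:03d}_{j:03d}.tsv", fv_map.curves[i][j])
    return directory


def read_map(directory: str | Path) -> ForceVolumeMap:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    probe = ProbeGeometry(**meta["probe"])
    ny, nx = meta["shape"]
    curves = [
        [read_force_curve(directory / f"curve_{i:03d}_{j:03d}.tsv", probe) for j in range(nx)]
        for i in range(ny)
    ]
    return ForceVolumeMap(
        curves=curves, pixel_size_um=meta["pixel_size_um"], probe=probe, meta=meta
    )


def write_decay(path: str | Path, decay: DecayHistogram) -> Path:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([decay.t_ns, decay.counts]),
        fmt="%.9g",
        delimiter="\t",
        header="t_ns\tcounts",
    )
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(
        json.dumps({"bin_width_ns": decay.bin_width_ns, **{
            k: v for k, v in decay.meta.items() if not isinstance(v, np.ndarray)
        }}, default=str)
    )
    return path


def read_decay(path: str | Path) -> DecayHistogram:
    path = Path(path)
    arr = np.loadtxt(path)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    bw = meta.pop("bin_width_ns", None)
    if bw is None:
        bw = float(np.median(np.diff(arr[:, 0])))
    decay = DecayHistogram(t_ns=arr[:, 0], counts=arr[:, 1], bin_width_ns=float(bw), meta=meta)
    decay.validate()
    return decay


def write_lipid_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_lipid_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    raw_cols = {"line", "component", "raw_intensity", "total_ion_count"}
    norm_cols = {"line", "component", "ion_yield"}
    if not (raw_cols.issubset(table.columns) or norm_cols.issubset(table.columns)):
        raise ValueError(
            "lipid table must provide either raw intensities with total ion "
            "counts or normalized ion yields"
        )
    return table
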