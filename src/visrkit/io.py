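"""File formats: RF fixtures, array+JSON containers, cohort tables.

The on-disk RF fixture is deliberately simple and language-neutral: a raw
little-endian float32 array (fast-time × slow-time × lateral, C order)
next to a JSON sidecar holding sampling, timing, geometry, and — for
synthetic data — the ground-truth block.  Intermediate arrays
(displacement fields, parametric maps) travel as ``.npz`` containers with
a single embedded JSON attribute blob.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import RFEnsemble, SequenceTiming
from .tracking import DisplacementField
from .visr import VisRMaps

__all__ = [
    "save_rf",
    "load_rf",
    "save_displacement_field",
    "load_displacement_field",
    "save_maps",
    "load_maps",
    "load_participants",
    "DENSE_RATINGS",
]

DENSE_RATINGS = {"C", "D"}


def save_rf(rf: RFEnsemble, path: str | Path) -> Path:
    """Write an RF ensemble as ``<path>.f32`` + ``<path>.json``."""
    path = Path(path)
    data = np.ascontiguousarray(rf.samples, dtype="<f4")
    data.tofile(path.with_suffix(".f32"))
    sidecar = {
        "shape": list(rf.samples.shape),
        "dtype": "<f4",
        "order": "C",
        "axes": ["fast_time", "slow_time", "lateral"],
        "fs_mhz": rf.fs_mhz,
        "c_m_s": rf.c_m_s,
        "axial_start_mm": rf.axial_start_mm,
        "line_positions_mm": rf.line_positions_mm.tolist(),
        "compression_mm": rf.compression_mm,
        "angle_deg": rf.angle_deg,
        "seed": rf.seed,
        "timing": dataclasses.asdict(rf.timing),
        "ground_truth": rf.ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".f32")


def load_rf(path: str | Path) -> RFEnsemble:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    samples = np.fromfile(path.with_suffix(".f32"), dtype="<f4").reshape(meta["shape"])
    return RFEnsemble(
        samples=samples,
        fs_mhz=meta["fs_mhz"],
        c_m_s=meta["c_m_s"],
        timing=SequenceTiming(**meta["timing"]),
        axial_start_mm=meta["axial_start_mm"],
        line_positions_mm=np.asarray(meta["line_positions_mm"]),
        compression_mm=meta["compression_mm"],
        angle_deg=meta["angle_deg"],
        seed=meta["seed"],
        ground_truth=meta.get("ground_truth"),
    )


def _save_container(path: Path, arrays: dict[str, np.ndarray], attrs: dict) -> None:
    np.savez_compressed(path, attrs_json=np.frombuffer(json.dumps(attrs).encode(), dtype=np.uint8),
                        **arrays)


def _load_container(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files if k != "attrs_json"}
        attrs = json.loads(bytes(z["attrs_json"]).decode())
    return arrays, attrs


def save_displacement_field(field: DisplacementField, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    _save_container(
        path,
        {
            "disp": field.disp,
            "corr": field.corr,
            "valid": field.valid,
            "axial_positions_mm": field.axial_positions_mm,
            "lateral_positions_mm": field.lateral_positions_mm,
            "times_ms": field.times_ms,
        },
        {"n_reference": field.n_reference},
    )
    return path


def load_displacement_field(path: str | Path) -> DisplacementField:
    arrays, attrs = _load_container(Path(path))
    return DisplacementField(n_reference=attrs["n_reference"], **arrays)


def save_maps(maps: VisRMaps, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    _save_container(
        path,
        {
            "pd": maps.pd,
            "re": maps.re,
            "rv": maps.rv,
            "fit_error": maps.fit_error,
            "valid": maps.valid,
            "axial_positions_mm": maps.axial_positions_mm,
            "lateral_positions_mm": maps.lateral_positions_mm,
        },
        {"focal_depth_mm": maps.focal_depth_mm},
    )
    return path


def load_maps(path: str | Path) -> VisRMaps:
    arrays, attrs = _load_container(Path(path))
    return VisRMaps(focal_depth_mm=attrs["focal_depth_mm"], **arrays)


def maps_to_tidy(maps: VisRMaps) -> pd.DataFrame:
    """Per-pixel tidy export (depth, lateral, PD, RE, RV, fit error)."""
    ax, lat = np.meshgrid(maps.axial_positions_mm, maps.lateral_positions_mm, indexing="ij")
    return pd.DataFrame(
        {
            "depth_mm": ax.ravel(),
            "lateral_mm": lat.ravel(),
            "pd_um": maps.pd.ravel(),
            "re": maps.re.ravel(),
            "rv": maps.rv.ravel(),
            "fit_error_um": maps.fit_error.ravel(),
            "valid": maps.valid.ravel(),
        }
    )


def load_participants(path: str | Path | None = None) -> pd.DataFrame:
    """Demographics of the 20-subject clinical cohort the synthetic study emulates.

    Columns: patient, birads_density (BI-RADS A–D), age, history columns,
    plus a derived boolean ``dense`` (C/D ratings count as dense in
    clinical practice).
    """
    if path is None:
        src = resources.files("visrkit.data").joinpath("participants.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df["dense"] = df["birads_density"].astype(str).str.strip().isin(DENSE_RATINGS)
    return df
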