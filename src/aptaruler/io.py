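"""Plain-text I/O for every artifact the pipeline exchanges.

Conventions: CSV for tabular data with explicit unit-suffixed column
names, a JSON sidecar (same path + ``.json``) for provenance (seed,
spec hash, parameters), TIFF/PNG for images, YAML for parameter
configs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .energy import EnergyProfile
from .qcm import QCMTrace
from .scattering import Spectrum
from .singleparticle import DarkFieldImage, Detection
from .tether import ParticleSpec, PositionEnsemble
from .dynamics import Trajectory

__all__ = [
    "write_ensemble",
    "read_ensemble",
    "write_profile",
    "read_profile",
    "write_trajectory",
    "write_spectrum",
    "read_spectrum",
    "write_detections",
    "read_qcm_trace",
    "write_qcm_trace",
    "load_config",
]


def _write_sidecar(path: Path, payload: dict[str, Any]) -> None:
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_ensemble(path: str | Path, ensemble: PositionEnsemble, **extra: Any) -> None:
    path = Path(path)
    pd.DataFrame({"z_nm": ensemble.z_values}).to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "seed": ensemble.seed,
            "n_chains": ensemble.n_chains,
            "spec_hash": ensemble.spec_hash,
            **extra,
        },
    )


def read_ensemble(path: str | Path) -> PositionEnsemble:
    path = Path(path)
    z = pd.read_csv(path)["z_nm"].to_numpy()
    meta = json.loads(Path(str(path) + ".json").read_text())
    return PositionEnsemble(
        z_values=z,
        n_chains=meta.get("n_chains", z.size),
        seed=meta.get("seed", -1),
        spec_hash=meta.get("spec_hash", ""),
    )


def write_profile(path: str | Path, profile: EnergyProfile) -> None:
    pd.DataFrame(
        {
            "z_nm": profile.z_bins,
            "energy_kT": profile.energy,
            "force_kT_per_nm": profile.force,
        }
    ).to_csv(path, index=False)


def read_profile(path: str | Path, temperature: float = 298.0) -> EnergyProfile:
    df = pd.read_csv(path)
    return EnergyProfile(
        z_bins=df["z_nm"].to_numpy(),
        energy=df["energy_kT"].to_numpy(),
        force=df["force_kT_per_nm"].to_numpy(),
        temperature=temperature,
    )


def write_trajectory(path: str | Path, traj: Trajectory, stride: int = 1) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": traj.times[::stride], "z_nm": traj.z[::stride]}).to_csv(
        path, index=False
    )
    _write_sidecar(
        path,
        {
            "dt_s": traj.dt,
            "seed": traj.seed,
            "diffusion_coefficient_m2_s": traj.diffusion_coefficient,
            "stride": stride,
        },
    )


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def write_detections(path: str | Path, detections: list[Detection]) -> None:
    pd.DataFrame(
        [
            {
                "x_px": d.x,
                "y_px": d.y,
                "rg": d.rg,
                "mean_red": d.mean_red,
                "mean_green": d.mean_green,
            }
            for d in detections
        ],
        columns=["x_px", "y_px", "rg", "mean_red", "mean_green"],
    ).to_csv(path, index=False)


def read_image(path: str | Path, pixel_size: float) -> DarkFieldImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    arr = np.asarray(px)
    bit_depth = 16 if arr.dtype == np.uint16 else 8 if arr.dtype == np.uint8 else None
    return DarkFieldImage(arr.astype(float), pixel_size=pixel_size, bit_depth=bit_depth)


def write_image(path: str | Path, image: DarkFieldImage) -> None:
    path = Path(path)
    arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_qcm_trace(path: str | Path, trace: QCMTrace) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": trace.times,
            "delta_f_hz": trace.delta_f,
            "overtone": trace.overtone,
        }
    ).to_csv(path, index=False)
    _write_sidecar(path, {"annotations": {k: list(v) for k, v in trace.annotations.items()}})


def read_qcm_trace(path: str | Path, annotations_path: str | Path | None = None) -> QCMTrace:
    path = Path(path)
    df = pd.read_csv(path)
    ann_file = Path(annotations_path) if annotations_path else Path(str(path) + ".json")
    annotations: dict[str, tuple[float, float]] = {}
    if ann_file.exists():
        raw = (
            yaml.safe_load(ann_file.read_text())
            if ann_file.suffix in (".yaml", ".yml")
            else json.loads(ann_file.read_text())
        )
        annotations = {k: tuple(v) for k, v in raw.get("annotations", raw).items()}
    overtone = int(df["overtone"].iloc[0]) if "overtone" in df else 3
    return QCMTrace(
        times=df["time_s"].to_numpy(),
        delta_f=df["delta_f_hz"].to_numpy(),
        overtone=overtone,
        annotations=annotations,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON) parameter config into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
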