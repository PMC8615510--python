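"""Shared I/O: images, validated tables, run configs and manifests.

Images are exchanged as 8/16-bit RGB TIFF or PNG (converted to float in
[0, 1] on read), masks as single-channel label PNGs, truth as `.truth.json`
sidecars, tables as CSV with a header row.  Every CLI run records its
resolved configuration and a manifest of input checksums and produced
files so deterministic stages can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "write_label_mask",
    "read_label_mask",
    "read_viability_csv",
    "write_viability_csv",
    "read_dose_csv",
    "write_truth_json",
    "RunConfig",
    "RunManifest",
    "sha256_file",
]


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF/PNG image to float [0, 1]; returns (array, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise ValueError(f"unreadable or unsupported image file: {path}") from exc
    meta = {"path": str(path), "dtype": str(arr.dtype), "shape": arr.shape}
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
        meta["bit_depth"] = 8
    elif arr.dtype == np.uint16:
        out = arr.astype(float) / 65535.0
        meta["bit_depth"] = 16
    else:
        out = arr.astype(float)
        meta["bit_depth"] = None
    return out, meta


def write_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a float [0, 1] image as 8- or 16-bit TIFF/PNG."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        arr = np.round(img * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_label_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def read_label_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr.astype(np.uint8)


def read_viability_csv(path):
    """Read a `time_days, value, replicate, culture` CSV into time series.

    Returns a dict culture -> ViabilityTimeSeries.
    """
    from .growth import ViabilityTimeSeries

    df = pd.read_csv(path)
    required = {"time_days", "value", "culture"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability CSV missing columns: {sorted(missing)}")
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0].tolist()
        raise ValueError(f"negative viability values at rows {bad}")
    out = {}
    for culture, grp in df.groupby("culture"):
        times = np.sort(grp["time_days"].unique())
        values = [grp.loc[grp["time_days"] == t, "value"].to_numpy() for t in times]
        out[str(culture)] = ViabilityTimeSeries(times, values, culture=str(culture))
    return out


def write_viability_csv(path, series_map: dict) -> None:
    rows = []
    for culture, series in series_map.items():
        for t, reps in zip(series.times_days, series.values):
            for i, v in enumerate(reps):
                rows.append(
                    {"time_days": t, "value": v, "replicate": i, "culture": culture}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_csv(path, mode: str = "effect"):
    """Read a dose-response CSV into DoseResponseTable objects.

    ``mode='effect'`` expects `dose_ug_ml, E, sigma_E[, n, culture,
    formulation]`; ``mode='absorbance'`` expects `dose_ug_ml,
    absorbance_mean, absorbance_sd[, n, ...]` and converts through the
    control row (dose 0).  Returns dict (culture, formulation) -> table.
    """
    from .doseresponse import DoseResponseTable, dead_fraction

    df = pd.read_csv(path)
    if "dose_ug_ml" not in df.columns:
        raise ValueError("dose-response CSV missing column 'dose_ug_ml'")
    if (df["dose_ug_ml"] < 0).any():
        bad = df.index[df["dose_ug_ml"] < 0].tolist()
        raise ValueError(f"negative doses at rows {bad}")
    for col, default in (("culture", "2D"), ("formulation", "free")):
        if col not in df.columns:
            df[col] = default
    out = {}
    for (culture, formulation), grp in df.groupby(["culture", "formulation"]):
        grp = grp.sort_values("dose_ug_ml")
        if mode == "effect":
            need = {"E", "sigma_E"}
            if need - set(grp.columns):
                raise ValueError("effect mode needs columns E, sigma_E")
            doses = grp["dose_ug_ml"].to_numpy(float)
            e = grp["E"].to_numpy(float)
            se = grp["sigma_E"].to_numpy(float)
        elif mode == "absorbance":
            need = {"absorbance_mean", "absorbance_sd"}
            if need - set(grp.columns):
                raise ValueError("absorbance mode needs absorbance_mean, absorbance_sd")
            ctrl = grp[grp["dose_ug_ml"] == 0]
            if ctrl.empty:
                raise ValueError("absorbance mode requires a zero-dose control row")
            a0 = float(ctrl["absorbance_mean"].iloc[0])
            doses = grp["dose_ug_ml"].to_numpy(float)
            pairs = [
                dead_fraction(a, a0, sd)
                for a, sd in zip(grp["absorbance_mean"], grp["absorbance_sd"])
            ]
            e = np.array([p[0] for p in pairs])
            se = np.array([p[1] for p in pairs])
        else:
            raise ValueError("mode must be 'effect' or 'absorbance'")
        n = grp["n"].to_numpy() if "n" in grp.columns else None
        out[(str(culture), str(formulation))] = DoseResponseTable(
            doses, e, se, n=n, culture=str(culture), formulation=str(formulation)
        )
    return out


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_truth_json(path, truth) -> None:
    """Write a SyntheticTruth sidecar (`<basename>.truth.json` convention)."""
    with open(path, "w") as fh:
        json.dump(truth, fh, cls=_TruthEncoder, indent=1)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    pixel_size_um: float = 1.0
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_checksums: dict[str, str]
    outputs: dict[str, str]
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def finalize_run(config: RunConfig, out_dir: Path, started: float) -> RunManifest:
    """Write config.json + manifest.json next to a stage's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    input_sums = {
        name: sha256_file(p) for name, p in config.inputs.items() if Path(p).exists()
    }
    outputs = {}
    for p in sorted(out_dir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        outputs[p.name] = sha256_file(p)
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config.config_hash(),
        input_checksums=input_sums,
        outputs=outputs,
        started=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(started)),
        finished=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
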