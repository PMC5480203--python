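"""File formats, run configuration, and provenance.

Images and label maps travel as NIfTI-1 (one slice, time along the fourth
dimension, TR in ``pixdim[4]``); curves and tables as CSV; metrics, pulse
designs and provenance as JSON; run configs as YAML or JSON (JSON is a YAML
subset, both parse through the same loader).  Config keys embed their units
(``venc_cm_s``, ``t1_blood_s``) to prevent unit drift.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, FormatError, InvalidInputError
from .phantom import (
    AcquisitionProtocol,
    BolusKinetics,
    DynamicSeries,
    FlowWaveform,
    PhantomConfig,
    PhantomGeometry,
    RelaxationModel,
)
from .physics import ExcitationSettings, GradientLimits

from . import __version__ as _pkg_version


# ---------------------------------------------------------------------------
# NIfTI image series
# ---------------------------------------------------------------------------


def write_series(path, series: DynamicSeries) -> None:
    """Write a dynamic series as a 4D NIfTI-1 file (x, y, 1 slice, time)."""
    data = series.data  # (t, row, col)
    arr = np.ascontiguousarray(data.transpose(2, 1, 0)[:, :, np.newaxis, :])
    img = nib.Nifti1Image(arr, affine=np.diag([series.pixel_mm, series.pixel_mm, 1.0, 1.0]))
    tr = series.tr_s if np.isfinite(series.tr_s) else 1.0
    img.header.set_zooms((series.pixel_mm, series.pixel_mm, 1.0, tr))
    img.header.set_xyzt_units("mm", "sec")
    img.header["descrip"] = f"vsperf {series.meta.get('mode', '')}".encode()[:79]
    nib.save(img, str(path))


def read_series(path) -> DynamicSeries:
    """Read a 4D (or 2D+time) NIfTI-1 series written by :func:`write_series`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: got a 3D volume without a time axis; expected 2D+time or 3D+time")
    if arr.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {arr.ndim}D")
    if arr.shape[2] != 1:
        raise FormatError(f"{path}: expected a single slice, got {arr.shape[2]}")
    zooms = img.header.get_zooms()
    pixel_mm = float(zooms[0])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    data = arr[:, :, 0, :].transpose(2, 1, 0).astype(float)
    times = np.arange(data.shape[0]) * tr
    return DynamicSeries(data, times, pixel_mm, meta={"source": str(path), "tr_s": tr})


def write_labels(path, labels: np.ndarray, pixel_mm: float) -> None:
    """Write a label map as a single-slice integer NIfTI-1 file."""
    arr = np.ascontiguousarray(
        np.asarray(labels, dtype=np.int16).transpose(1, 0)[:, :, np.newaxis])
    img = nib.Nifti1Image(arr, affine=np.diag([pixel_mm, pixel_mm, 1.0, 1.0]))
    img.header.set_zooms((pixel_mm, pixel_mm, 1.0))
    nib.save(img, str(path))


def read_labels(path, strict: bool = False) -> np.ndarray:
    """Read a label map; non-integer voxel values warn (or raise if strict)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be a single 2D slice")
    if not np.allclose(arr, np.round(arr)):
        msg = f"{path}: label map has non-integer values"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg + "; rounding", stacklevel=2)
    return np.round(arr).astype(np.int16).transpose(1, 0)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _build_dataclass(cls, d: dict, where: str):
    """Instantiate a config dataclass from a dict, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**kwargs)
    except (InvalidInputError, TypeError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


_PROTOCOL_EXTRA_KEYS = {"mode", "flip_deg", "venc_cm_s", "limits"}
_TOP_KEYS = {"seed", "geometry", "flow", "kinetics", "relaxation", "protocol",
             "analysis", "output_dir"}
_ANALYSIS_KEYS = {"baseline_frames", "pre_bolus_frames", "plane_correct"}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration: phantom + mode selection + analysis options."""

    phantom: PhantomConfig
    mode: str = "both"  # both | conventional | velocity_selective
    seed: int = 0
    analysis: dict = dataclasses.field(default_factory=dict)
    output_dir: str | None = None
    raw: dict = dataclasses.field(default_factory=dict)

    def modes(self) -> list[str]:
        if self.mode == "both":
            return ["conventional", "velocity_selective"]
        return [self.mode]


def config_from_dict(d: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed config mapping (strict keys)."""
    if not isinstance(d, dict):
        raise ConfigError("top level of the config must be a mapping")
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    seed = int(d.get("seed", 0))
    geometry = _build_dataclass(PhantomGeometry, d.get("geometry", {}), "geometry")
    flow = _build_dataclass(FlowWaveform, d.get("flow", {}), "flow")
    kinetics = _build_dataclass(BolusKinetics, d.get("kinetics", {}), "kinetics")
    relaxation = _build_dataclass(RelaxationModel, d.get("relaxation", {}), "relaxation")

    prot_d = dict(d.get("protocol", {}))
    if not isinstance(prot_d, dict):
        raise ConfigError("protocol: expected a mapping")
    mode = prot_d.pop("mode", "both")
    if mode not in ("both", "conventional", "velocity_selective"):
        raise ConfigError(f"protocol.mode: unknown mode {mode!r}")
    flip = prot_d.pop("flip_deg", None)
    venc = prot_d.pop("venc_cm_s", None)
    limits_d = prot_d.pop("limits", {})
    limits = _build_dataclass(GradientLimits, limits_d, "protocol.limits")

    allowed = {f.name for f in dataclasses.fields(AcquisitionProtocol)} - {
        "excitation", "limits"}
    unknown = set(prot_d) - allowed
    if unknown:
        raise ConfigError(f"protocol: unknown keys {sorted(unknown)}")

    if mode == "conventional":
        exc = ExcitationSettings.conventional(flip if flip is not None else 60.0)
    else:
        # for 'both' store the velocity-selective settings; with_mode() swaps
        exc = ExcitationSettings.velocity_selective(
            flip if flip is not None else 30.0,
            venc if venc is not None else abs(flow.lv_at_trigger.mean_cm_s))
    coil = prot_d.get("coil_plane")
    if coil is not None:
        prot_d["coil_plane"] = tuple(coil)
    try:
        protocol = AcquisitionProtocol(excitation=exc, limits=limits, seed=seed, **prot_d)
    except InvalidInputError as exc_:
        raise ConfigError(f"protocol: {exc_}") from exc_

    analysis = d.get("analysis", {})
    if not isinstance(analysis, dict):
        raise ConfigError("analysis: expected a mapping")
    unknown = set(analysis) - _ANALYSIS_KEYS
    if unknown:
        raise ConfigError(f"analysis: unknown keys {sorted(unknown)}")

    phantom = PhantomConfig(geometry=geometry, flow=flow, kinetics=kinetics,
                            relaxation=relaxation, protocol=protocol)
    return RunConfig(phantom=phantom, mode=mode, seed=seed, analysis=dict(analysis),
                     output_dir=d.get("output_dir"), raw=d)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read config file {path}: {exc}") from exc
    try:
        d = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    return config_from_dict(d or {})


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_record(config_dict: dict, seed: int, files=()) -> dict:
    """Provenance: tool version, config hash, seed, timestamp, file digests."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return {
        "tool": "vsperf",
        "version": _pkg_version,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": int(seed),
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "files": {str(Path(p).name): _sha256_file(Path(p)) for p in files},
    }


def write_provenance(path, config_dict: dict, seed: int, files=()) -> dict:
    rec = provenance_record(config_dict, seed, files)
    Path(path).write_text(json.dumps(rec, indent=2) + "\n")
    return rec
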