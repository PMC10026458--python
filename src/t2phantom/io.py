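"""NIfTI-1 + JSON-sidecar persistence for image stacks and parameter maps.

A stack is one 3-D NIfTI volume (frames along the third axis) with a JSON
sidecar carrying everything needed to re-run the producing step: protocol,
frame parameters, seed, noise SD, units.  Complex stacks are stored as a
4-D volume with real/imaginary along the fourth axis.  Round trips are
lossless (bit-identical frames and metadata).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, FormatError
from .fitting import ParameterMap
from .simulate import ImageStack, protocol_from_dict, protocol_to_dict

__all__ = [
    "write_stack",
    "read_stack",
    "write_parameter_map",
    "read_parameter_map",
    "load_run_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(pixel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_size_mm
    return aff


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as NIfTI + sidecar; returns the image path."""
    path = Path(path)
    pixel = float(stack.meta.get("pixel_size_mm", 1.0))
    if stack.is_complex:
        data = np.stack(
            [stack.frames.real, stack.frames.imag], axis=-1
        ).transpose(2, 1, 0, 3)
    else:
        data = np.asarray(stack.frames, dtype=np.float64).transpose(2, 1, 0)
    img = nib.Nifti1Image(data, _affine(pixel))
    nib.save(img, str(path))
    sidecar = {
        "protocol": protocol_to_dict(stack.protocol),
        "frame_parameter": list(map(float, stack.frame_parameter)),
        "parameter_name": stack.parameter_name,
        "noise_sd": stack.noise_sd,
        "seed": stack.seed,
        "complex": bool(stack.is_complex),
        "meta": {k: v for k, v in stack.meta.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`; validates the sidecar."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    data = np.asarray(nib.load(str(path)).dataobj)
    if sidecar.get("complex"):
        data = data[..., 0] + 1j * data[..., 1]
    frames = data.transpose(2, 1, 0)
    params = sidecar["frame_parameter"]
    if len(params) != frames.shape[0]:
        raise FormatError(
            f"sidecar lists {len(params)} frame parameters but volume has "
            f"{frames.shape[0]} frames"
        )
    return ImageStack(
        frames=frames,
        frame_parameter=np.asarray(params, dtype=float),
        parameter_name=sidecar["parameter_name"],
        protocol=protocol_from_dict(sidecar["protocol"]),
        noise_sd=sidecar.get("noise_sd", 0.0),
        seed=sidecar.get("seed"),
        meta=sidecar.get("meta", {}),
    )


def write_parameter_map(pmap: ParameterMap, path, *, pixel_size_mm: float = 1.0) -> Path:
    path = Path(path)
    layers = [pmap.values, pmap.rss, pmap.converged.astype(float)]
    names = ["values", "rss", "converged"]
    for k in sorted(pmap.aux):
        layers.append(pmap.aux[k])
        names.append(f"aux:{k}")
    data = np.stack(layers, axis=0).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, _affine(pixel_size_mm)), str(path))
    sidecar = {
        "parameter_name": pmap.parameter_name,
        "units": pmap.units,
        "layers": names,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_parameter_map(path) -> ParameterMap:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    data = np.asarray(nib.load(str(path)).dataobj).transpose(2, 1, 0)
    names = sidecar["layers"]
    if len(names) != data.shape[0]:
        raise FormatError("layer list does not match volume")
    layer = dict(zip(names, data))
    aux = {k.split(":", 1)[1]: v for k, v in layer.items() if k.startswith("aux:")}
    return ParameterMap(
        values=layer["values"],
        rss=layer["rss"],
        converged=layer["converged"] > 0.5,
        parameter_name=sidecar["parameter_name"],
        units=sidecar.get("units", "ms"),
        aux=aux,
    )


_CONFIG_KEYS = {
    "layout",
    "field_strength_t",
    "sequence",
    "protocol",
    "noise_sd",
    "seed",
    "temperature_c",
    "output_dir",
    "report_decimals",
    "pixel_size_mm",
}


def load_run_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys.

    A ``seed`` is mandatory whenever ``noise_sd`` is non-zero — every
    stochastic step must be reproducible.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if cfg.get("noise_sd", 0) and "seed" not in cfg:
        raise ConfigError("a seed is mandatory for any stochastic step")
    return cfg
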