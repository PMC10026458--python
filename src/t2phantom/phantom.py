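"""Virtual nine-tube phantom: geometry, ground-truth maps, field conditions.

The physical device is a ~1 L square-cross-section bottle (10 x 10 cm)
holding a 3x3 array of 24 mm inner-diameter gel tubes embedded in an outer
gel matrix.  Long-T1/T2 tubes sit away from the corners, which places tubes
A, B, F, I in the corners and C, D, E, G, H on edges/centre — the grouping
used by the QA statistics.

This module rasterizes that geometry onto a pixel grid, attaches per-tube
T1/T2 truth (taken from the embedded calibration table by default), applies
a phenomenological linear temperature model, and builds B0/B1 field
conditions for the field-mapping simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import LayoutError, TruthError
from .recipe import RelaxationPair
from .tables import CENTRAL_TUBES, CORNER_TUBES, TUBE_IDS, calibration_table

__all__ = [
    "PhantomLayout",
    "GroundTruthMaps",
    "FieldCondition",
    "default_layout",
    "rasterize_layout",
    "apply_temperature",
    "default_temperature_coeffs",
    "uniform_condition",
    "radial_b1_droop_condition",
    "OUTER_LABEL",
    "REFERENCE_TEMPERATURE_C",
]

OUTER_LABEL = 10
REFERENCE_TEMPERATURE_C = 22.0

# 3x3 grid placement: corners get the short/stable tubes per the device design.
_GRID_ORDER = {
    (0, 0): "A", (0, 1): "C", (0, 2): "B",
    (1, 0): "D", (1, 1): "E", (1, 2): "G",
    (2, 0): "F", (2, 1): "H", (2, 2): "I",
}
assert set(v for k, v in _GRID_ORDER.items() if k[0] % 2 == 0 and k[1] % 2 == 0) == set(
    CORNER_TUBES
)
assert set(v for k, v in _GRID_ORDER.items() if not (k[0] % 2 == 0 and k[1] % 2 == 0)) == set(
    CENTRAL_TUBES
)


@dataclass(frozen=True)
class PhantomLayout:
    """Tube placement and per-compartment relaxation truth.

    ``tube_centers`` maps tube id -> (y, x) centre in mm, origin at the
    body's top-left corner.  ``truth`` maps tube id -> RelaxationPair (ms)
    at the layout's field strength; ``outer_fill_truth`` covers the
    inter-tube gel.
    """

    tube_centers: dict[str, tuple[float, float]]
    truth: dict[str, RelaxationPair]
    outer_fill_truth: RelaxationPair
    tube_inner_diameter_mm: float = 24.0
    body_mm: tuple[float, float] = (100.0, 100.0)
    field_strength_t: float = 1.5

    def validate(self) -> None:
        ids = list(self.tube_centers)
        r = self.tube_inner_diameter_mm / 2.0
        for tid, (cy, cx) in self.tube_centers.items():
            if tid not in self.truth:
                raise LayoutError(f"tube {tid} has no truth values")
            if not (r <= cy <= self.body_mm[0] - r and r <= cx <= self.body_mm[1] - r):
                raise LayoutError(f"tube {tid} extends outside the body")
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = np.hypot(
                    self.tube_centers[a][0] - self.tube_centers[b][0],
                    self.tube_centers[a][1] - self.tube_centers[b][1],
                )
                if d < self.tube_inner_diameter_mm:
                    raise LayoutError(f"tubes {a} and {b} overlap (centres {d:.1f} mm apart)")


@dataclass
class GroundTruthMaps:
    """Rasterized compartment labels and per-pixel T1/T2 truth (ms).

    Labels: 0 = background (outside the body), 1–9 = tubes A–I in order,
    10 = outer matrix fill.  Truth maps are NaN in the background.
    """

    label_map: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    pixel_size_mm: float
    tube_labels: dict[str, int] = field(default_factory=dict)
    field_strength_t: float = 1.5
    temperature_c: float = REFERENCE_TEMPERATURE_C

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def tube_mask(self, tube_id: str) -> np.ndarray:
        return self.label_map == self.tube_labels[tube_id]

    def foreground(self) -> np.ndarray:
        return self.label_map > 0

    def validate(self) -> None:
        fg = self.foreground()
        for name, m in (("t1", self.t1_map), ("t2", self.t2_map)):
            vals = m[fg]
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise TruthError(f"{name} truth must be positive and finite inside compartments")


@dataclass
class FieldCondition:
    """Spatial B0 off-resonance (Hz) and relative flip-angle scale maps."""

    b0_offset_hz: np.ndarray
    b1_relative: np.ndarray
    field_strength_t: float = 1.5
    temperature_c: float = REFERENCE_TEMPERATURE_C

    def validate(self, shape: tuple[int, int]) -> None:
        if self.b0_offset_hz.shape != shape or self.b1_relative.shape != shape:
            raise LayoutError("field-condition maps must match the truth-map shape")
        if np.any(self.b1_relative <= 0):
            raise LayoutError("b1_relative must be positive everywhere")


def default_layout(field_strength_t: float = 1.5) -> PhantomLayout:
    """The production 3x3 layout with truth from the calibration table.

    Tube centres sit on a 30 mm pitch grid (20/50/80 mm) inside the
    100 x 100 mm body, leaving 6 mm gel between adjacent 24 mm tubes.
    """
    label = {1.5: ("t1_1p5T_ms", "t2_1p5T_ms"), 3.0: ("t1_3T_ms", "t2_3T_ms")}
    if field_strength_t not in label:
        raise ValueError("default truth available at 1.5 and 3.0 T only")
    t1_col, t2_col = label[field_strength_t]
    cal = calibration_table()
    centers = {
        tid: (20.0 + 30.0 * r, 20.0 + 30.0 * c) for (r, c), tid in _GRID_ORDER.items()
    }
    truth = {
        tid: RelaxationPair(float(cal.loc[tid, t1_col]), float(cal.loc[tid, t2_col]))
        for tid in TUBE_IDS
    }
    # The outer fill was characterised on the benchtop relaxometer only;
    # reuse those values at both clinical fields (it is not a QA target).
    outer = RelaxationPair(
        float(cal.loc["outer", "t1_1p4T_ms"]), float(cal.loc["outer", "t2_1p4T_ms"])
    )
    return PhantomLayout(
        tube_centers=centers,
        truth=truth,
        outer_fill_truth=outer,
        field_strength_t=field_strength_t,
    )


def layout_from_config(path) -> PhantomLayout:
    """Load a layout preset from a YAML file (keys: tubes, diameter_mm, body_mm,
    truth map per tube, outer_fill)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {"tubes", "diameter_mm", "body_mm", "outer_fill", "field_strength_t"}
    unknown = set(cfg) - known
    if unknown:
        raise LayoutError(f"unknown layout keys: {sorted(unknown)}")
    centers, truth = {}, {}
    for tid, row in cfg["tubes"].items():
        centers[tid] = (float(row["center_mm"][0]), float(row["center_mm"][1]))
        truth[tid] = RelaxationPair(float(row["t1_ms"]), float(row["t2_ms"]))
    outer = RelaxationPair(
        float(cfg["outer_fill"]["t1_ms"]), float(cfg["outer_fill"]["t2_ms"])
    )
    return PhantomLayout(
        tube_centers=centers,
        truth=truth,
        outer_fill_truth=outer,
        tube_inner_diameter_mm=float(cfg.get("diameter_mm", 24.0)),
        body_mm=tuple(cfg.get("body_mm", (100.0, 100.0))),
        field_strength_t=float(cfg.get("field_strength_t", 1.5)),
    )


def rasterize_layout(
    layout: PhantomLayout, pixel_size_mm: float = 1.0, *, margin_mm: float = 0.0
) -> GroundTruthMaps:
    """Rasterize a layout by pixel-centre point sampling.

    A pixel belongs to a tube iff its centre lies strictly inside the tube
    disk; remaining pixels inside the body are outer fill, and pixels in
    the optional margin outside the body are background (label 0).
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    layout.validate()
    ny = int(round((layout.body_mm[0] + 2 * margin_mm) / pixel_size_mm))
    nx = int(round((layout.body_mm[1] + 2 * margin_mm) / pixel_size_mm))
    y = (np.arange(ny) + 0.5) * pixel_size_mm - margin_mm
    x = (np.arange(nx) + 0.5) * pixel_size_mm - margin_mm
    yy, xx = np.meshgrid(y, x, indexing="ij")

    inside_body = (
        (yy >= 0) & (yy <= layout.body_mm[0]) & (xx >= 0) & (xx <= layout.body_mm[1])
    )
    labels = np.where(inside_body, OUTER_LABEL, 0).astype(np.int16)
    t1 = np.full((ny, nx), np.nan)
    t2 = np.full((ny, nx), np.nan)
    t1[inside_body] = layout.outer_fill_truth.t1_ms
    t2[inside_body] = layout.outer_fill_truth.t2_ms

    tube_labels: dict[str, int] = {}
    r2 = (layout.tube_inner_diameter_mm / 2.0) ** 2
    for i, tid in enumerate(sorted(layout.tube_centers), start=1):
        cy, cx = layout.tube_centers[tid]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 < r2
        labels[disk] = i
        t1[disk] = layout.truth[tid].t1_ms
        t2[disk] = layout.truth[tid].t2_ms
        tube_labels[tid] = i

    maps = GroundTruthMaps(
        label_map=labels,
        t1_map=t1,
        t2_map=t2,
        pixel_size_mm=pixel_size_mm,
        tube_labels=tube_labels,
        field_strength_t=layout.field_strength_t,
    )
    maps.validate()
    return maps


def default_temperature_coeffs(truth: GroundTruthMaps) -> dict[int, tuple[float, float]]:
    """Per-compartment linear temperature slopes (ms/°C) for (T1, T2).

    T1 lengthens and T2 shortens with temperature, and tubes with longer
    relaxation times drift more; the defaults make the slopes proportional
    to the compartment's reference value: +0.8 %/°C for T1, −0.4 %/°C for
    T2 — magnitudes typical of NiCl2/agarose gels near room temperature.
    """
    coeffs = {}
    for lab in np.unique(truth.label_map):
        if lab == 0:
            continue
        m = truth.label_map == lab
        t1_ref = float(np.nanmedian(truth.t1_map[m]))
        t2_ref = float(np.nanmedian(truth.t2_map[m]))
        coeffs[int(lab)] = (0.008 * t1_ref, -0.004 * t2_ref)
    return coeffs


def apply_temperature(
    truth: GroundTruthMaps,
    temperature_c: float,
    coeffs: dict[int, tuple[float, float]] | None = None,
) -> GroundTruthMaps:
    """Shift truth maps to a new temperature with per-compartment linear slopes.

    ``T(temp) = T_ref + slope * (temp - 22 °C)``, clamped to stay positive.
    Slopes must satisfy dT1/dT >= 0 and dT2/dT <= 0.
    """
    if coeffs is None:
        coeffs = default_temperature_coeffs(truth)
    t1 = truth.t1_map.copy()
    t2 = truth.t2_map.copy()
    dt = temperature_c - REFERENCE_TEMPERATURE_C
    for lab, (s1, s2) in coeffs.items():
        if s1 < 0 or s2 > 0:
            raise ValueError(f"compartment {lab}: need dT1/dT >= 0 and dT2/dT <= 0")
        m = truth.label_map == lab
        t1[m] = truth.t1_map[m] + s1 * dt
        t2[m] = truth.t2_map[m] + s2 * dt
    fg = truth.foreground()
    if np.any(t1[fg] <= 0) or np.any(t2[fg] <= 0):
        raise TruthError(
            f"temperature {temperature_c} °C drives a relaxation time non-positive"
        )
    out = replace(truth, t1_map=t1, t2_map=t2, temperature_c=temperature_c)
    out.validate()
    return out


def uniform_condition(
    shape: tuple[int, int],
    field_strength_t: float = 1.5,
    *,
    b0_offset_hz: float = 0.0,
    b1_relative: float = 1.0,
) -> FieldCondition:
    """Spatially uniform B0/B1 condition (the well-shimmed design goal)."""
    return FieldCondition(
        b0_offset_hz=np.full(shape, float(b0_offset_hz)),
        b1_relative=np.full(shape, float(b1_relative)),
        field_strength_t=field_strength_t,
    )


def radial_b1_droop_condition(
    shape: tuple[int, int],
    field_strength_t: float = 3.0,
    *,
    center_scale: float = 0.66,
    edge_drop: float = 0.07,
    b0_offset_hz: float = 0.0,
) -> FieldCondition:
    """Smooth radial B1 droop preset.

    Mimics the stronger relative-flip-angle variation seen at 3 T (centre
    scale ~0.59–0.66 across tubes): ``b1 = center_scale - edge_drop * rho^2``
    with rho the normalized radius from the image centre.
    """
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2) / (ny / 2)
    x = (np.arange(nx) - (nx - 1) / 2) / (nx / 2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    rho2 = yy**2 + xx**2
    b1 = center_scale - edge_drop * rho2 / rho2.max()
    return FieldCondition(
        b0_offset_hz=np.full(shape, float(b0_offset_hz)),
        b1_relative=b1,
        field_strength_t=field_strength_t,
    )
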