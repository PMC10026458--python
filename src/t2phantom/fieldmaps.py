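"""B0 off-resonance and B1 flip-angle field maps.

B0 is mapped from two gradient-echo acquisitions at distinct echo times:
the pixel-wise phase difference is 2*pi*df*dTE, so df follows from the
complex ratio of the frames — unambiguously for |df| < 1/(2 dTE); larger
offsets alias by 1/dTE.  No spatial unwrapping is applied (a well-shimmed
phantom sits far below the aliasing limit).

B1 is mapped by the double-angle method: with long TR, signals at nominal
flip angles alpha and 2*alpha obey S2/S1 = 2 cos(actual alpha), hence
actual_alpha = arccos(S2/(2 S1)) and the relative flip-angle scale is
actual/nominal.

Off-resonance in ppm is df / (gamma * B0) with gamma = 42.576 MHz/T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError
from .simulate import ImageStack

__all__ = [
    "GAMMA_MHZ_PER_T",
    "FieldMapResult",
    "EMProperties",
    "compute_b0_map",
    "frequency_to_ppm",
    "report_ppm",
    "compute_b1_dam",
    "displacement_current_ratio",
    "aliasing_limit_hz",
]

#: Proton gyromagnetic ratio, MHz per tesla.
GAMMA_MHZ_PER_T = 42.576


@dataclass
class FieldMapResult:
    """Per-pixel field-map values; NaN where undefined, ``valid`` flags why."""

    delta_f_hz: np.ndarray | None = None
    ppm: np.ndarray | None = None
    relative_fa: np.ndarray | None = None
    actual_fa_deg: np.ndarray | None = None
    valid: np.ndarray | None = None
    field_strength_t: float | None = None


@dataclass(frozen=True)
class EMProperties:
    """Electromagnetic properties of the fill at the Larmor frequency."""

    omega_rad_per_s: float
    permittivity_f_per_m: float
    conductivity_s_per_m: float

    def __post_init__(self) -> None:
        if min(self.omega_rad_per_s, self.permittivity_f_per_m) <= 0:
            raise ValueError("omega and permittivity must be positive")
        if self.conductivity_s_per_m < 0:
            raise ValueError("conductivity must be non-negative")


def aliasing_limit_hz(delta_te_ms: float) -> float:
    """Largest unambiguous |off-resonance| for a given echo spacing."""
    return 1000.0 / (2.0 * abs(delta_te_ms))


def compute_b0_map(
    stack: ImageStack, *, magnitude_threshold: float | None = None
) -> FieldMapResult:
    """Phase-difference B0 map from a two-echo complex stack.

    df = angle(frame2 * conj(frame1)) / (2 pi dTE).  Pixels whose magnitude
    falls below ``magnitude_threshold`` (default: 5 % of the peak) are
    flagged undefined.
    """
    if not stack.is_complex or stack.frames.shape[0] != 2:
        raise ProtocolError("B0 mapping needs exactly two complex frames")
    te1, te2 = stack.frame_parameter
    if te1 == te2:
        raise ProtocolError("echo times must be distinct")
    f1, f2 = stack.frames
    mag = np.minimum(np.abs(f1), np.abs(f2))
    if magnitude_threshold is None:
        magnitude_threshold = 0.05 * mag.max()
    valid = mag > magnitude_threshold
    dte_s = (te2 - te1) / 1000.0
    delta_f = np.angle(f2 * np.conj(f1)) / (2.0 * np.pi * dte_s)
    delta_f = np.where(valid, delta_f, np.nan)
    b0 = stack.meta.get("field_strength_t")
    ppm = frequency_to_ppm(delta_f, b0) if b0 else None
    return FieldMapResult(delta_f_hz=delta_f, ppm=ppm, valid=valid, field_strength_t=b0)


def frequency_to_ppm(delta_f_hz, field_strength_t: float):
    """Convert an off-resonance in Hz to parts per million of the Larmor
    frequency: ppm = df / (42.576 MHz/T * B0)."""
    if field_strength_t <= 0:
        raise ValueError("field strength must be positive")
    return np.asarray(delta_f_hz, dtype=float) / (GAMMA_MHZ_PER_T * field_strength_t)


def report_ppm(ppm_value: float) -> float:
    """Round a ppm value to one significant figure for reporting.

    Stored maps are never rounded; this matches the display precision used
    in phantom uniformity summaries (e.g. 0.00783 -> 0.008).
    """
    if ppm_value == 0 or not np.isfinite(ppm_value):
        return float(ppm_value)
    exp = int(np.floor(np.log10(abs(ppm_value))))
    scale = 10.0 ** (-exp)
    return float(np.copysign(np.floor(abs(ppm_value) * scale + 0.5), ppm_value) / scale)


def compute_b1_dam(stack: ImageStack) -> FieldMapResult:
    """Double-angle-method flip-angle map from frames at (alpha, 2 alpha).

    actual_alpha = arccos(S(2a) / (2 S(a))); pixels whose ratio leaves the
    (0, 1] arccos domain (e.g. S2 > 2 S1 from noise, or zero signal) are
    flagged invalid rather than raising.
    """
    if stack.frames.shape[0] != 2:
        raise ProtocolError("double-angle method needs exactly two frames")
    a1, a2 = stack.frame_parameter
    if not np.isclose(a2, 2 * a1):
        raise ProtocolError("nominal angles must be (alpha, 2*alpha)")
    s1, s2 = np.abs(stack.frames[0]), np.abs(stack.frames[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s2 / (2.0 * s1)
    valid = np.isfinite(ratio) & (ratio > 0.0) & (ratio <= 1.0)
    actual = np.degrees(np.arccos(np.where(valid, ratio, 0.5)))
    actual = np.where(valid, actual, np.nan)
    return FieldMapResult(
        relative_fa=actual / a1,
        actual_fa_deg=actual,
        valid=valid,
        field_strength_t=stack.meta.get("field_strength_t"),
    )


def displacement_current_ratio(props: EMProperties) -> float:
    """Q = omega * permittivity / conductivity.

    The ratio of displacement to conduction current in the RF field; B1
    uniformity improves as Q drops, which is why the outer fill's
    permittivity is lowered by packing it with HDPE beads.
    """
    if props.conductivity_s_per_m == 0:
        raise ZeroDivisionError("conductivity must be non-zero")
    return props.omega_rad_per_s * props.permittivity_f_per_m / props.conductivity_s_per_m
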