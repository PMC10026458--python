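"""Simulators for the acquisitions used to qualify the phantom.

Reference sequences (inversion-recovery gradient echo, single-echo spin
echo) have exact closed-form signal models and are evaluated directly.
The mapping sequences (MOLLI T1 mapping, T2-prepared bSSFP T2 mapping) are
simulated as event chains on the Bloch equations: instantaneous RF
rotations alternating in sign, exact on-resonance free-precession
relaxation between pulses, ideal T2 preparations and inversions.  Because
every pixel in a compartment shares (T1, T2), the Bloch chain runs once
per compartment and is painted onto the label map.

Noise is Rician on magnitude frames (complex Gaussian per channel followed
by magnitude reconstruction) and additive complex Gaussian on complex
field-mapping frames; a seed fully determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ProtocolError, TruthError
from .phantom import FieldCondition, GroundTruthMaps, uniform_condition

__all__ = [
    "AcquisitionProtocol",
    "ImageStack",
    "ir_gre_protocol",
    "spin_echo_protocol",
    "molli_protocol",
    "t2prep_bssfp_protocol",
    "dual_echo_protocol",
    "double_angle_protocol",
    "simulate_inversion_recovery",
    "simulate_spin_echo",
    "simulate_molli",
    "simulate_t2prep_bssfp",
    "simulate_dual_echo_gre",
    "simulate_double_angle",
    "add_noise",
]

SEQUENCES = ("IR_GRE", "SE", "MOLLI", "T2PREP_BSSFP", "DUAL_ECHO_GRE", "DOUBLE_ANGLE")

#: Inversion times (ms) of the reference IR-GRE protocol.
REFERENCE_TI_MS = (20, 50, 100, 200, 400, 600, 800, 1000, 1300, 1700, 2100)
#: Echo times (ms) of the reference single-echo spin-echo protocol.
REFERENCE_TE_MS = (10, 20, 30, 40, 50, 60, 80, 100, 125, 150)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence parameters; unused fields stay at their defaults."""

    sequence: str
    ti_list_ms: tuple[float, ...] = ()
    te_list_ms: tuple[float, ...] = ()
    teprep_list_ms: tuple[float, ...] = ()
    flip_angle_deg: float = 90.0
    tr_ms: float = 10000.0
    rr_ms: float = 900.0
    readout_pulses: int = 65
    readout_tr_ms: float = 2.8
    ramp_pulses: int = 10
    recovery_beats: int = 3
    ti_min_ms: float = 100.0
    ti_increment_ms: float = 80.0
    echo_times_fieldmap_ms: tuple[float, float] = (4.0, 6.5)
    nominal_angles_deg: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ProtocolError(f"unknown sequence {self.sequence!r}")
        for name in ("ti_list_ms", "te_list_ms", "teprep_list_ms"):
            vals = getattr(self, name)
            if list(vals) != sorted(vals):
                raise ProtocolError(f"{name} must be sorted ascending")
        if self.rr_ms <= 0:
            raise ProtocolError("rr_ms must be positive")


def ir_gre_protocol(
    ti_list_ms=REFERENCE_TI_MS, tr_ms: float = 10000.0
) -> AcquisitionProtocol:
    """Reference inversion-recovery gradient echo (long TR, FA 90°)."""
    return AcquisitionProtocol(sequence="IR_GRE", ti_list_ms=tuple(ti_list_ms), tr_ms=tr_ms)


def spin_echo_protocol(
    te_list_ms=REFERENCE_TE_MS, tr_ms: float = 10000.0
) -> AcquisitionProtocol:
    """Reference single-echo spin echo (one TE per repetition, long TR)."""
    return AcquisitionProtocol(sequence="SE", te_list_ms=tuple(te_list_ms), tr_ms=tr_ms)


def molli_protocol(field_strength_t: float = 1.5) -> AcquisitionProtocol:
    """5s(3s)3s MOLLI at RR 900 ms (FA 35° at 1.5 T, 20° at 3 T).

    The readout is a 32-pulse bSSFP train (2.8 ms TR, 10-pulse linear
    ramp-up) so that the first k-space centre is reachable at TI 100 ms;
    the second inversion's TIs are offset by 80 ms.
    """
    fa = 35.0 if field_strength_t < 2.0 else 20.0
    return AcquisitionProtocol(
        sequence="MOLLI", flip_angle_deg=fa, rr_ms=900.0, readout_pulses=32
    )


def t2prep_bssfp_protocol(
    teprep_list_ms=(0.0, 25.0, 55.0), flip_angle_deg: float = 70.0
) -> AcquisitionProtocol:
    """T2-prepared bSSFP mapping (FA 70°, 65-pulse readout, 3 recovery beats)."""
    return AcquisitionProtocol(
        sequence="T2PREP_BSSFP",
        teprep_list_ms=tuple(teprep_list_ms),
        flip_angle_deg=flip_angle_deg,
    )


def dual_echo_protocol(echo_times_ms=(4.0, 6.5)) -> AcquisitionProtocol:
    """Dual-echo gradient echo for phase-difference B0 mapping."""
    return AcquisitionProtocol(
        sequence="DUAL_ECHO_GRE", echo_times_fieldmap_ms=tuple(echo_times_ms)
    )


def double_angle_protocol(alpha_deg: float = 60.0) -> AcquisitionProtocol:
    """Double-angle B1 mapping at (alpha, 2*alpha) with long TR."""
    return AcquisitionProtocol(
        sequence="DOUBLE_ANGLE", nominal_angles_deg=(alpha_deg, 2 * alpha_deg), tr_ms=8000.0
    )


@dataclass
class ImageStack:
    """A stack of 2-D frames varying along one acquisition parameter.

    ``frames`` has shape (n_frames, ny, nx); magnitude stacks are real and
    non-negative, field-mapping stacks are complex.  ``frame_parameter``
    gives the varying quantity per frame (TI, TE, TEprep in ms, or nominal
    flip angle in degrees).
    """

    frames: np.ndarray
    frame_parameter: np.ndarray
    parameter_name: str
    protocol: AcquisitionProtocol
    noise_sd: float = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_parameter = np.asarray(self.frame_parameter, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if len(self.frame_parameter) != self.frames.shape[0]:
            raise ValueError("frame_parameter length must equal frame count")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.frames)


def _check_truth(truth: GroundTruthMaps) -> None:
    try:
        truth.validate()
    except Exception as exc:  # re-raise with the simulator's vocabulary
        raise TruthError(str(exc)) from exc


def _finish(frames, params, name, protocol, truth, noise_sd, seed) -> ImageStack:
    stack = ImageStack(
        frames=np.asarray(frames),
        frame_parameter=np.asarray(params, dtype=float),
        parameter_name=name,
        protocol=protocol,
        noise_sd=0.0,
        seed=seed,
        meta={"pixel_size_mm": truth.pixel_size_mm, "field_strength_t": truth.field_strength_t},
    )
    if noise_sd > 0:
        stack = add_noise(stack, noise_sd, seed)
    return stack


def simulate_inversion_recovery(
    truth: GroundTruthMaps,
    protocol: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageStack:
    """Closed-form IR-GRE magnitude frames.

    S(TI) = |M0 (1 - 2 exp(-TI/T1) + exp(-TR/T1))| inside the body, 0 outside.
    """
    protocol = protocol or ir_gre_protocol()
    if protocol.sequence != "IR_GRE" or not protocol.ti_list_ms:
        raise ProtocolError("need an IR_GRE protocol with a non-empty TI list")
    _check_truth(truth)
    fg = truth.foreground()
    t1 = truth.t1_map
    frames = []
    with np.errstate(invalid="ignore"):
        for ti in protocol.ti_list_ms:
            s = np.abs(1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-protocol.tr_ms / t1))
            frames.append(np.where(fg, s, 0.0))
    return _finish(frames, protocol.ti_list_ms, "TI_ms", protocol, truth, noise_sd, seed)


def simulate_spin_echo(
    truth: GroundTruthMaps,
    protocol: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageStack:
    """Closed-form single-echo SE frames: S(TE) = M0 (1 - e^(-TR/T1)) e^(-TE/T2)."""
    protocol = protocol or spin_echo_protocol()
    if protocol.sequence != "SE" or not protocol.te_list_ms:
        raise ProtocolError("need an SE protocol with a non-empty TE list")
    _check_truth(truth)
    fg = truth.foreground()
    t1, t2 = truth.t1_map, truth.t2_map
    frames = []
    with np.errstate(invalid="ignore"):
        sat = 1.0 - np.exp(-protocol.tr_ms / t1)
        for te in protocol.te_list_ms:
            frames.append(np.where(fg, sat * np.exp(-te / t2), 0.0))
    return _finish(frames, protocol.te_list_ms, "TE_ms", protocol, truth, noise_sd, seed)


# ---------------------------------------------------------------------------
# Bloch event chain (scalar, per compartment, on-resonance)
# ---------------------------------------------------------------------------


def _relax(m: np.ndarray, dt_ms: float, t1: float, t2: float) -> None:
    """Exact free-precession relaxation over dt (on-resonance)."""
    if dt_ms < 0:
        raise ProtocolError(f"negative event gap ({dt_ms:.1f} ms): timeline infeasible")
    e1 = np.exp(-dt_ms / t1)
    m[0] *= np.exp(-dt_ms / t2)
    m[1] *= np.exp(-dt_ms / t2)
    m[2] = 1.0 + (m[2] - 1.0) * e1


def _rot_x(m: np.ndarray, angle_rad: float) -> None:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    my, mz = m[1], m[2]
    m[1] = c * my - s * mz
    m[2] = s * my + c * mz


def _bssfp_train(
    m: np.ndarray,
    t1: float,
    t2: float,
    fa_rad: float,
    n_pulses: int,
    tr_ms: float,
    n_ramp: int,
) -> float:
    """Run a ramped, sign-alternating bSSFP train; return the k-centre signal.

    Pulses are instantaneous rotations about x with alternating sign; each
    is followed by exact relaxation over one TR.  The echo forms TR/2 after
    the pulse, so the recorded signal is |Mxy| after the centre pulse of
    the main train decayed by exp(-TR/(2 T2)).  Phase-encode ordering is
    linear with the k-space centre at the middle pulse.
    """
    sign = 1.0
    for k in range(n_ramp):
        _rot_x(m, sign * fa_rad * (k + 1) / (n_ramp + 1))
        _relax(m, tr_ms, t1, t2)
        sign = -sign
    center = n_pulses // 2
    signal = np.nan
    for k in range(n_pulses):
        _rot_x(m, sign * fa_rad)
        if k == center:
            signal = float(np.hypot(m[0], m[1])) * np.exp(-tr_ms / (2.0 * t2))
        _relax(m, tr_ms, t1, t2)
        sign = -sign
    return signal


def _train_center_offset_ms(protocol: AcquisitionProtocol) -> float:
    """Time from the start of the ramp to the k-space-centre echo (ms)."""
    return (
        protocol.ramp_pulses + protocol.readout_pulses // 2
    ) * protocol.readout_tr_ms + protocol.readout_tr_ms / 2.0


def _compartments(truth: GroundTruthMaps):
    for lab in np.unique(truth.label_map):
        if lab == 0:
            continue
        m = truth.label_map == lab
        yield lab, m, float(truth.t1_map[m][0]), float(truth.t2_map[m][0])


def _molli_compartment(t1, t2, protocol):
    """Simulate one compartment through the 5s(3s)3s MOLLI scheme.

    Returns (effective TI list, signal list), TI measured from the
    preceding inversion to the k-space centre of each image.
    """
    fa = np.radians(protocol.flip_angle_deg)
    rr = protocol.rr_ms
    offset = _train_center_offset_ms(protocol)
    trains = [
        (0.0, protocol.ti_min_ms, 5),
        (8 * rr, protocol.ti_min_ms + protocol.ti_increment_ms, 3),
    ]
    m = np.array([0.0, 0.0, 1.0])
    now = 0.0
    tis, sigs = [], []
    for inv_time, ti0, n_images in trains:
        _relax(m, inv_time - now, t1, t2)
        m[0] = m[1] = 0.0  # inversion crusher
        m[2] = -m[2]  # adiabatic inversion, efficiency 1.0
        now = inv_time
        for k in range(n_images):
            ti = ti0 + k * rr
            start = inv_time + ti - offset
            _relax(m, start - now, t1, t2)
            s = _bssfp_train(
                m, t1, t2, fa, protocol.readout_pulses, protocol.readout_tr_ms,
                protocol.ramp_pulses,
            )
            now = start + (protocol.ramp_pulses + protocol.readout_pulses) * protocol.readout_tr_ms
            tis.append(ti)
            sigs.append(s)
    order = np.argsort(tis, kind="stable")
    return np.asarray(tis)[order], np.asarray(sigs)[order]


def simulate_molli(
    truth: GroundTruthMaps,
    protocol: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageStack:
    """Bloch-event MOLLI simulation (5 beats + 3 rest + 3 beats at fixed RR).

    Frames are magnitude images ordered by effective inversion time (time
    from the owning inversion to the image's k-space centre), which is
    also the stack's ``frame_parameter``.
    """
    protocol = protocol or molli_protocol(truth.field_strength_t)
    if protocol.sequence != "MOLLI":
        raise ProtocolError("need a MOLLI protocol")
    _check_truth(truth)
    tis = None
    frames = None
    for lab, mask, t1, t2 in _compartments(truth):
        c_tis, c_sigs = _molli_compartment(t1, t2, protocol)
        if frames is None:
            tis = c_tis
            frames = np.zeros((len(c_tis),) + truth.shape)
        frames[:, mask] = c_sigs[:, None]
    return _finish(frames, tis, "TI_ms", protocol, truth, noise_sd, seed)


def _t2prep_compartment(t1, t2, protocol):
    m = np.array([0.0, 0.0, 1.0])
    sigs = []
    for teprep in protocol.teprep_list_ms:
        # ideal T2 preparation: tip-down, TE_prep of pure T2 decay, tip-up;
        # residual transverse magnetization spoiled
        m[2] = m[2] * np.exp(-teprep / t2)
        m[0] = m[1] = 0.0
        s = _bssfp_train(
            m, t1, t2, np.radians(protocol.flip_angle_deg),
            protocol.readout_pulses, protocol.readout_tr_ms, protocol.ramp_pulses,
        )
        sigs.append(s)
        m[0] = m[1] = 0.0
        _relax(m, protocol.recovery_beats * protocol.rr_ms, t1, t2)
    return np.asarray(sigs)


def simulate_t2prep_bssfp(
    truth: GroundTruthMaps,
    protocol: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageStack:
    """Bloch-event T2-prepared bSSFP simulation, frames ordered by TEprep.

    Each preparation scales Mz by exp(-TEprep/T2); a ramped bSSFP train
    reads out with the k-space centre at the middle pulse, followed by
    ``recovery_beats`` heartbeats of free relaxation.  T1 recovery between
    the preparation and the k-space centre is the physical source of the
    sequence's positive, short-T1-enhanced T2 bias.
    """
    protocol = protocol or t2prep_bssfp_protocol()
    if protocol.sequence != "T2PREP_BSSFP" or not protocol.teprep_list_ms:
        raise ProtocolError("need a T2PREP_BSSFP protocol with a TEprep list")
    if len(protocol.teprep_list_ms) < 2:
        import warnings

        warnings.warn("fewer than 2 TEprep values: T2 fitting will be infeasible")
    _check_truth(truth)
    frames = np.zeros((len(protocol.teprep_list_ms),) + truth.shape)
    for lab, mask, t1, t2 in _compartments(truth):
        frames[:, mask] = _t2prep_compartment(t1, t2, protocol)[:, None]
    return _finish(
        frames, protocol.teprep_list_ms, "TEprep_ms", protocol, truth, noise_sd, seed
    )


def simulate_dual_echo_gre(
    truth: GroundTruthMaps,
    condition: FieldCondition | None = None,
    protocol: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    phase_offset_rad: float = 0.0,
) -> ImageStack:
    """Complex dual-echo frames for phase-difference B0 mapping.

    Phase at echo time TE is 2*pi*df*TE + phi0 per pixel; magnitude uses a
    spin-echo-like weighting so the compartments remain visible.
    """
    protocol = protocol or dual_echo_protocol()
    te1, te2 = protocol.echo_times_fieldmap_ms
    if te1 == te2:
        raise ProtocolError("field-map echo times must be distinct")
    _check_truth(truth)
    condition = condition or uniform_condition(truth.shape, truth.field_strength_t)
    condition.validate(truth.shape)
    fg = truth.foreground()
    frames = []
    with np.errstate(invalid="ignore"):
        sat = 1.0 - np.exp(-protocol.tr_ms / truth.t1_map)
        for te in (te1, te2):
            mag = np.where(fg, sat * np.exp(-te / truth.t2_map), 0.0)
            phase = 2.0 * np.pi * condition.b0_offset_hz * (te / 1000.0) + phase_offset_rad
            frames.append(mag * np.exp(1j * phase))
    return _finish(frames, (te1, te2), "TE_ms", protocol, truth, noise_sd, seed)


def simulate_double_angle(
    truth: GroundTruthMaps,
    condition: FieldCondition | None = None,
    protocol: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageStack:
    """Two long-TR frames at nominal angles (alpha, 2*alpha).

    Signals are proportional to sin(b1_relative * angle); long TR removes
    T1 weighting so the double-angle ratio depends on B1 alone.
    """
    protocol = protocol or double_angle_protocol()
    a1, a2 = protocol.nominal_angles_deg
    if not np.isclose(a2, 2 * a1):
        raise ProtocolError("double-angle method needs nominal angles (alpha, 2*alpha)")
    _check_truth(truth)
    condition = condition or uniform_condition(truth.shape, truth.field_strength_t)
    condition.validate(truth.shape)
    fg = truth.foreground()
    frames = [
        np.where(fg, np.abs(np.sin(np.radians(a) * condition.b1_relative)), 0.0)
        for a in (a1, a2)
    ]
    return _finish(frames, (a1, a2), "nominal_angle_deg", protocol, truth, noise_sd, seed)


def add_noise(stack: ImageStack, noise_sd: float, seed: int | None) -> ImageStack:
    """Add measurement noise; identity when noise_sd == 0.

    Magnitude frames receive Rician noise (independent complex Gaussian of
    SD ``noise_sd`` per channel, then magnitude); complex frames receive
    additive complex Gaussian noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return stack
    rng = np.random.default_rng(seed)
    shape = stack.frames.shape
    if stack.is_complex:
        noisy = stack.frames + noise_sd * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
    else:
        noisy = np.hypot(
            stack.frames + noise_sd * rng.standard_normal(shape),
            noise_sd * rng.standard_normal(shape),
        )
    return replace(stack, frames=noisy, noise_sd=noise_sd, seed=seed)


def protocol_to_dict(protocol: AcquisitionProtocol) -> dict:
    d = {
        "sequence": protocol.sequence,
        "ti_list_ms": list(protocol.ti_list_ms),
        "te_list_ms": list(protocol.te_list_ms),
        "teprep_list_ms": list(protocol.teprep_list_ms),
        "flip_angle_deg": protocol.flip_angle_deg,
        "tr_ms": protocol.tr_ms,
        "rr_ms": protocol.rr_ms,
        "readout_pulses": protocol.readout_pulses,
        "readout_tr_ms": protocol.readout_tr_ms,
        "ramp_pulses": protocol.ramp_pulses,
        "recovery_beats": protocol.recovery_beats,
        "ti_min_ms": protocol.ti_min_ms,
        "ti_increment_ms": protocol.ti_increment_ms,
        "echo_times_fieldmap_ms": list(protocol.echo_times_fieldmap_ms),
        "nominal_angles_deg": list(protocol.nominal_angles_deg),
    }
    return d


def protocol_from_dict(d: dict) -> AcquisitionProtocol:
    d = dict(d)
    for key in ("ti_list_ms", "te_list_ms", "teprep_list_ms"):
        d[key] = tuple(d.get(key, ()))
    for key in ("echo_times_fieldmap_ms", "nominal_angles_deg"):
        if key in d:
            d[key] = tuple(d[key])
    return AcquisitionProtocol(**d)


def protocol_json(protocol: AcquisitionProtocol) -> str:
    return json.dumps(protocol_to_dict(protocol), sort_keys=True)
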