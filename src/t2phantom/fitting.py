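"""Pixel-wise relaxometry fitting.

All models here are single exponentials in disguise:

* T2 decay:            S(t) = A exp(-t/T2)                (SE, T2-prep bSSFP)
* inversion recovery:  S(t) = |A - B exp(-t/T1)|          (IR-GRE magnitude)
* MOLLI:               S(t) = |A - B exp(-t/T1*)|, then the Look-Locker
                       correction T1 = T1* (B/A - 1)

They are fitted by variable projection: for a fixed rate the linear
coefficients (A, or A and B) have a closed-form least-squares solution, so
the fit reduces to a 1-D search over the rate.  That search is a global
log-spaced grid followed by per-pixel zoom stages and a final parabolic
refinement — deterministic, vectorized over pixels, and free of
initialization failures.  Magnitude IR data additionally needs polarity
restoration: every candidate flip index k (frames 1..k negated) is fitted
and the lowest-RSS candidate wins, ties broken toward the smaller index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ImageStack

__all__ = [
    "ParameterMap",
    "fit_t2_monoexponential",
    "fit_t1_inversion_recovery",
    "fit_molli_t1",
    "reconstruct_map",
]

#: Rate search bounds in 1/ms: T between 0.5 ms and 20 s.
_RATE_BOUNDS_T1 = (1.0 / 20000.0, 1.0 / 0.5)
_RATE_BOUNDS_T2 = (1.0 / 5000.0, 1.0 / 0.5)


@dataclass
class ParameterMap:
    """A fitted parameter image plus per-pixel diagnostics.

    ``values`` is NaN outside the fitted mask and where the fit failed;
    ``aux`` holds nuisance parameters (A, B, apparent T1*, flip index).
    """

    values: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    parameter_name: str
    units: str = "ms"
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    fitted_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# variable-projection engine
# ---------------------------------------------------------------------------


def _profiled_rss(t: np.ndarray, Y: np.ndarray, rates: np.ndarray, intercept: bool):
    """RSS of the best linear fit at each candidate rate.

    ``rates`` is (G,) for a grid shared by all pixels or (G, npx) for
    per-pixel grids.  Returns rss with shape (G, npx).
    """
    yy = np.einsum("pt,pt->p", Y, Y)
    if rates.ndim == 1:
        E = np.exp(-rates[:, None] * t[None, :])  # (G, nt)
        Sey = E @ Y.T  # (G, npx)
        See = np.einsum("gt,gt->g", E, E)[:, None]
        if not intercept:
            return yy[None, :] - Sey**2 / See
        Se = E.sum(axis=1)[:, None]
        Sy = Y.sum(axis=1)[None, :]
        nt = float(len(t))
    else:
        E = np.exp(-rates[:, :, None] * t[None, None, :])  # (G, npx, nt)
        Sey = np.einsum("gpt,pt->gp", E, Y)
        See = np.einsum("gpt,gpt->gp", E, E)
        if not intercept:
            return yy[None, :] - Sey**2 / See
        Se = E.sum(axis=2)
        Sy = Y.sum(axis=1)[None, :]
        nt = float(len(t))
    det = nt * See - Se**2
    a0 = (See * Sy - Se * Sey) / det
    a1 = (nt * Sey - Se * Sy) / det
    return yy[None, :] - (a0 * Sy + a1 * Sey)


def _linear_coefs(t, Y, rate, intercept):
    """Closed-form linear coefficients at the final per-pixel rate."""
    e = np.exp(-rate[:, None] * t[None, :])  # (npx, nt)
    Sey = np.einsum("pt,pt->p", e, Y)
    See = np.einsum("pt,pt->p", e, e)
    if not intercept:
        amp = Sey / See
        resid = Y - amp[:, None] * e
        return np.zeros_like(amp), amp, np.einsum("pt,pt->p", resid, resid)
    Se = e.sum(axis=1)
    Sy = Y.sum(axis=1)
    nt = float(len(t))
    det = nt * See - Se**2
    a0 = (See * Sy - Se * Sey) / det
    a1 = (nt * Sey - Se * Sy) / det
    resid = Y - a0[:, None] - a1[:, None] * e
    return a0, a1, np.einsum("pt,pt->p", resid, resid)


def _search_rate(
    t: np.ndarray,
    Y: np.ndarray,
    intercept: bool,
    rate_bounds: tuple[float, float],
    n_coarse: int = 96,
    n_zoom: int = 4,
    zoom_grid: int = 17,
):
    """Profiled 1-D rate search; returns (rate, a0, a1, rss) per pixel."""
    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])
    grid = np.linspace(lo, hi, n_coarse)
    rss = _profiled_rss(t, Y, np.exp(grid), intercept)
    idx = np.argmin(rss, axis=0)
    log_r = grid[idx]
    step = grid[1] - grid[0]
    for _ in range(n_zoom):
        offs = np.linspace(-step, step, zoom_grid)
        local = log_r[None, :] + offs[:, None]
        np.clip(local, lo, hi, out=local)
        rss = _profiled_rss(t, Y, np.exp(local), intercept)
        k = np.argmin(rss, axis=0)
        px = np.arange(Y.shape[0])
        # parabolic refinement on the uniform local grid
        kc = np.clip(k, 1, zoom_grid - 2)
        r0, r1, r2 = rss[kc - 1, px], rss[kc, px], rss[kc + 1, px]
        denom = r0 - 2 * r1 + r2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(denom > 0, 0.5 * (r0 - r2) / denom, 0.0)
        h = offs[1] - offs[0]
        log_r = local[k, px] + np.clip(delta, -1.0, 1.0) * h * (k == kc)
        np.clip(log_r, lo, hi, out=log_r)
        step = h
    rate = np.exp(log_r)
    a0, a1, rss_final = _linear_coefs(t, Y, rate, intercept)
    return rate, a0, a1, rss_final


def _ir_fit(t: np.ndarray, Y: np.ndarray, magnitude: bool = True):
    """Three-parameter |A - B exp(-t/T1)| fit with polarity restoration.

    Returns per-pixel (t1, A, B, rss, flip_index).  For signed input data
    set ``magnitude=False`` (only flip index 0 is tried).
    """
    npx, nt = Y.shape
    candidates = range(nt + 1) if magnitude else [0]
    lo, hi = np.log(_RATE_BOUNDS_T1[0]), np.log(_RATE_BOUNDS_T1[1])
    grid = np.exp(np.linspace(lo, hi, 96))
    best_rss = np.full(npx, np.inf)
    best_k = np.zeros(npx, dtype=int)
    for k in candidates:
        Ys = Y.copy()
        Ys[:, :k] *= -1.0
        rss_k = _profiled_rss(t, Ys, grid, intercept=True).min(axis=0)
        better = rss_k < best_rss  # strict: ties stay with the smaller k
        best_rss[better] = rss_k[better]
        best_k[better] = k

    t1 = np.empty(npx)
    A = np.empty(npx)
    B = np.empty(npx)
    rss = np.empty(npx)
    for k in np.unique(best_k):
        sel = best_k == k
        Ys = Y[sel].copy()
        Ys[:, :k] *= -1.0
        rate, a0, a1, r = _search_rate(t, Ys, True, _RATE_BOUNDS_T1)
        t1[sel] = 1.0 / rate
        A[sel] = a0
        B[sel] = -a1
        rss[sel] = r
    return t1, A, B, rss, best_k


def _extract(stack: ImageStack, mask: np.ndarray | None):
    frames = np.asarray(stack.frames, dtype=float)
    nf, ny, nx = frames.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    t = stack.frame_parameter
    order = np.argsort(t, kind="stable")
    Y = frames.reshape(nf, -1).T[mask.ravel()][:, order]
    return t[order], Y, mask


def _assemble(shape, mask, valid, values, rss, aux, name) -> ParameterMap:
    def paint(v, where=None):
        out = np.full(shape, np.nan, dtype=float)
        flat = np.full(mask.sum(), np.nan, dtype=float)
        if where is None:
            flat[:] = v
        else:
            flat[where] = v[where]
        out[mask] = flat
        return out

    vmap = paint(values, valid)  # NaN where the fit failed
    rmap = paint(rss)
    conv = np.zeros(shape, dtype=bool)
    conv[mask] = valid
    # diagnostics stay available even for unconverged pixels
    aux_maps = {k: paint(v) for k, v in aux.items()}
    return ParameterMap(
        values=vmap, rss=rmap, converged=conv, parameter_name=name,
        aux=aux_maps, fitted_mask=mask,
    )


def _interior(rate, bounds):
    return (rate > bounds[0] * 1.05) & (rate < bounds[1] * 0.95)


def fit_t2_monoexponential(
    stack: ImageStack, mask: np.ndarray | None = None, *, with_offset: bool = False
) -> ParameterMap:
    """Fit S = A exp(-t/T2) per pixel (t = TE or TEprep).

    ``with_offset=True`` adds a constant: S = A exp(-t/T2) + C.  Pixels
    whose signal is non-positive at every frame are marked unconverged,
    never raised.
    """
    if len(stack.frame_parameter) < (3 if with_offset else 2):
        raise ValueError("need at least 2 frames (3 with offset) to fit T2")
    t, Y, mask = _extract(stack, mask)
    fitable = np.any(Y > 0, axis=1)
    rate = np.full(Y.shape[0], np.nan)
    a0 = np.zeros(Y.shape[0])
    amp = np.full(Y.shape[0], np.nan)
    rss = np.full(Y.shape[0], np.nan)
    if fitable.any():
        r, c0, c1, rs = _search_rate(t, Y[fitable], with_offset, _RATE_BOUNDS_T2)
        rate[fitable] = r
        if with_offset:
            a0[fitable], amp[fitable] = c0, c1
        else:
            amp[fitable] = c1
        rss[fitable] = rs
    valid = fitable & np.isfinite(rate) & _interior(np.nan_to_num(rate), _RATE_BOUNDS_T2)
    t2 = 1.0 / rate
    aux = {"amplitude": amp}
    if with_offset:
        aux["offset"] = a0
    return _assemble(stack.frames.shape[1:], mask, valid, t2, rss, aux, "T2")


def fit_t1_inversion_recovery(
    stack: ImageStack, mask: np.ndarray | None = None, *, magnitude: bool = True
) -> ParameterMap:
    """Three-parameter IR fit with polarity restoration (magnitude data)."""
    if len(stack.frame_parameter) < 4:
        raise ValueError("need at least 4 inversion times for the 3-parameter fit")
    t, Y, mask = _extract(stack, mask)
    t1, A, B, rss, flip = _ir_fit(t, Y, magnitude=magnitude)
    rate = 1.0 / t1
    valid = np.isfinite(t1) & (B > 0) & _interior(rate, _RATE_BOUNDS_T1)
    aux = {"A": A, "B": B, "flip_index": flip.astype(float)}
    return _assemble(stack.frames.shape[1:], mask, valid, t1, rss, aux, "T1")


def fit_molli_t1(stack: ImageStack, mask: np.ndarray | None = None) -> ParameterMap:
    """MOLLI T1: 3-parameter apparent fit plus Look-Locker correction.

    T1 = T1* (B/A - 1).  Pixels with B/A <= 1 (correction undefined) are
    flagged unconverged; the apparent T1* is retained in ``aux``.
    """
    t, Y, mask = _extract(stack, mask)
    t1_star, A, B, rss, flip = _ir_fit(t, Y, magnitude=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = B / A
        t1 = t1_star * (ratio - 1.0)
    correctable = np.isfinite(ratio) & (ratio > 1.0)
    valid = (
        correctable & np.isfinite(t1_star) & _interior(1.0 / t1_star, _RATE_BOUNDS_T1)
    )
    t1 = np.where(correctable, t1, np.nan)
    aux = {"A": A, "B": B, "t1_star": t1_star, "flip_index": flip.astype(float)}
    return _assemble(stack.frames.shape[1:], mask, valid, t1, rss, aux, "T1")


_METHODS = {
    "t2_monoexp": ("SE", "T2PREP_BSSFP"),
    "ir_t1": ("IR_GRE",),
    "molli_t1": ("MOLLI",),
}


def reconstruct_map(
    stack: ImageStack,
    method: str,
    *,
    mask: np.ndarray | None = None,
    truth=None,
    signal_threshold: float | None = None,
    **kwargs,
) -> ParameterMap:
    """Dispatch the matching fitter with background exclusion.

    Background pixels are excluded via an explicit ``mask``, the label map
    of ``truth`` (label > 0), or a mean-signal threshold; excluded pixels
    are flagged, not fitted.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    allowed = _METHODS[method]
    if stack.protocol.sequence not in allowed:
        raise ValueError(
            f"method {method!r} expects sequence in {allowed}, "
            f"got {stack.protocol.sequence}"
        )
    if mask is None:
        if truth is not None:
            mask = truth.label_map > 0
        elif signal_threshold is not None:
            mask = np.abs(stack.frames).mean(axis=0) > signal_threshold
    if method == "t2_monoexp":
        return fit_t2_monoexponential(stack, mask, **kwargs)
    if method == "ir_t1":
        return fit_t1_inversion_recovery(stack, mask, **kwargs)
    return fit_molli_t1(stack, mask, **kwargs)
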