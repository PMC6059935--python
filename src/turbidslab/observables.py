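"""Observables from time-gated frame stacks and time-resolved traces.

A :class:`FrameStack` is the emulated (or measured) gated-camera output: a
sequence of 2-D transmitted-intensity maps at increasing delays.  The key
observable is the mean square width, the variance of the transverse
exit-position distribution, which grows as 4Dt in the diffusive regime and
is exactly independent of any amplitude factor applied to the frames (in
particular of absorption).  A :class:`TimeTrace` is the emulated
photomultiplier channel; the instrument response is the temporal
cross-correlation of two squared-hyperbolic-secant pulses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


# --------------------------------------------------------------------------
# time traces

@dataclass
class TimeTrace:
    """A binned time-resolved intensity trace (t in ps)."""

    t: np.ndarray
    counts: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.t) != len(self.counts):
            raise ValueError("t and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.sigma is None:
            self.sigma = np.sqrt(np.maximum(self.counts, 1.0))
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def save(self, path) -> None:
        header = "t_ps counts sigma"
        np.savetxt(path, np.column_stack([self.t, self.counts, self.sigma]),
                   header=header)

    @classmethod
    def load(cls, path) -> "TimeTrace":
        arr = np.loadtxt(path)
        return cls(t=arr[:, 0], counts=arr[:, 1],
                   sigma=arr[:, 2] if arr.shape[1] > 2 else None)


# --------------------------------------------------------------------------
# instrument response

_SECH2_FWHM = 2.0 * np.arccosh(np.sqrt(2.0))   # FWHM of sech^2(t/tau) in tau
#: FWHM ratio of the sech^2 autocorrelation to the pulse itself
SECH2_AUTOCORR_RATIO = 1.5427


@dataclass(frozen=True)
class IRF:
    """Gated-detection instrument response: cross-correlation of two sech^2 pulses.

    Widths are the FWHM of the individual intensity pulses, in fs.
    """

    fwhm_probe: float
    fwhm_gate: float

    def __post_init__(self):
        if self.fwhm_probe <= 0 or self.fwhm_gate <= 0:
            raise ValueError("pulse widths must be positive")

    @classmethod
    def from_response_fwhm(cls, fwhm_fs: float) -> "IRF":
        """Equal probe/gate pulses whose cross-correlation has the given FWHM."""
        return cls(fwhm_fs / SECH2_AUTOCORR_RATIO, fwhm_fs / SECH2_AUTOCORR_RATIO)

    @property
    def response_fwhm_ps(self) -> float:
        """FWHM (ps) of the cross-correlation, measured on the computed curve."""
        t, y = self._curve()
        return _fwhm(t, y)

    def _curve(self, dt_fs: float = 1.0):
        """Cross-correlation sampled on a <= 1 fs grid, unit area; t in ps."""
        span = 6.0 * (self.fwhm_probe + self.fwhm_gate)
        half = int(np.ceil(span / dt_fs))
        tg = np.arange(-half, half + 1) * dt_fs      # exactly symmetric grid
        tau_p = self.fwhm_probe / _SECH2_FWHM
        tau_g = self.fwhm_gate / _SECH2_FWHM
        p = 1.0 / np.cosh(tg / tau_p) ** 2
        g = 1.0 / np.cosh(tg / tau_g) ** 2
        cc = np.convolve(p, g, mode="same")
        cc /= np.trapezoid(cc, tg)
        return tg * 1e-3, cc * 1e3     # ps, 1/ps


def _fwhm(t, y) -> float:
    y = np.asarray(y)
    half = y.max() / 2.0
    above = np.where(y >= half)[0]
    i0, i1 = above[0], above[-1]

    def cross(ia, ib):
        return t[ia] + (half - y[ia]) * (t[ib] - t[ia]) / (y[ib] - y[ia])

    left = cross(i0 - 1, i0) if i0 > 0 else t[i0]
    right = cross(i1 + 1, i1) if i1 < len(y) - 1 else t[i1]
    return right - left


def irf_crosscorrelation(irf: IRF, t) -> np.ndarray:
    """The IRF evaluated at times t (ps), normalized to unit area."""
    tg, cc = irf._curve()
    return np.interp(np.asarray(t, dtype=float), tg, cc, left=0.0, right=0.0)


def convolve_trace(trace: TimeTrace, irf: IRF, strict: bool = False) -> TimeTrace:
    """Convolve a trace with the IRF on its own grid, preserving total area.

    The trace binning should be at most FWHM/5 for a faithful kernel; a
    coarser binning raises in ``strict`` mode and warns otherwise.
    """
    dt = trace.dt
    fwhm_ps = irf.response_fwhm_ps
    if dt > fwhm_ps / 5.0:
        msg = (f"trace binning {dt} ps is coarse against the "
               f"{fwhm_ps:.4f} ps instrument response")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    half = max(int(np.ceil(4.0 * fwhm_ps / dt)), 1)
    tk = np.arange(-half, half + 1) * dt
    kernel = irf_crosscorrelation(irf, tk)
    s = kernel.sum()
    kernel = kernel / s if s > 0 else kernel
    out = np.convolve(trace.counts, kernel, mode="same")
    return TimeTrace(t=trace.t.copy(), counts=out,
                     sigma=np.sqrt(np.maximum(out, 1.0)))


# --------------------------------------------------------------------------
# frame stacks

@dataclass
class FrameStack:
    """Time-ordered 2-D intensity maps on a common spatial grid.

    ``meta`` carries the acquisition descriptor: pixel pitch (um), frame
    times (ps), averaging count, noise model tag, and optionally the
    declared optical-resolution blur ``blur_sigma`` (sigma_x, sigma_y in um)
    that the analysis may subtract from measured widths.
    """

    frames: np.ndarray             # (n_frames, ny, nx)
    x_centers: np.ndarray
    y_centers: np.ndarray
    frame_times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.x_centers = np.asarray(self.x_centers, dtype=float)
        self.y_centers = np.asarray(self.y_centers, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        n, ny, nx = self.frames.shape
        if len(self.frame_times) != n:
            raise ValueError("frame_times must match the number of frames")
        if len(self.y_centers) != ny or len(self.x_centers) != nx:
            raise ValueError("grid coordinates must match the frame shape")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    def save(self, path) -> None:
        """Write a multi-page TIFF plus a `.meta.json` sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = {
            "pixel_pitch_um": float(self.x_centers[1] - self.x_centers[0]),
            "x0_um": float(self.x_centers[0]),
            "y0_um": float(self.y_centers[0]),
            "frame_times_ps": self.frame_times.tolist(),
            **self.meta,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "FrameStack":
        path = Path(path)
        frames = tifffile.imread(path).astype(float)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text())
        pitch = meta.pop("pixel_pitch_um")
        x0 = meta.pop("x0_um")
        y0 = meta.pop("y0_um")
        times = np.array(meta.pop("frame_times_ps"))
        _, ny, nx = frames.shape
        return cls(frames=frames, x_centers=x0 + pitch * np.arange(nx),
                   y_centers=y0 + pitch * np.arange(ny),
                   frame_times=times, meta=meta)


def subtract_background(frame: np.ndarray, border: int = 2):
    """Median-of-border background subtraction with negative clipping.

    Returns (clean frame, clipped-weight fraction).  The border ring is the
    outermost ``border`` pixels on all four sides.
    """
    ring = np.concatenate([
        frame[:border].ravel(), frame[-border:].ravel(),
        frame[border:-border, :border].ravel(),
        frame[border:-border, -border:].ravel()])
    bg = np.median(ring)
    out = frame - bg
    neg = -out[out < 0].sum()
    out = np.clip(out, 0.0, None)
    total = out.sum()
    return out, float(neg / total) if total > 0 else 0.0


def mean_square_width(frame: np.ndarray, x_centers: np.ndarray,
                      y_centers: np.ndarray, per_axis: bool = False) -> float:
    """Variance of the transverse exit vector: Var(x) + Var(y) (um^2).

    Moments are taken about the intensity centroid, so the result is
    invariant under global intensity scaling and spatial translation.  With
    ``per_axis`` the single-axis variance Var(x) is returned instead
    (differing by a factor ~2 in slope interpretation for isotropic
    profiles); the default is the full 2-D variance consistent with the
    diffusive law w^2 = 4Dt.
    """
    frame = np.asarray(frame, dtype=float)
    total = frame.sum()
    if total <= 0:
        raise ValueError("frame has no intensity; mean square width undefined")
    px = frame.sum(axis=0) / total
    py = frame.sum(axis=1) / total
    mx = px @ x_centers
    my = py @ y_centers
    var_x = px @ (x_centers - mx) ** 2
    var_y = py @ (y_centers - my) ** 2
    if per_axis:
        return float(var_x)
    return float(var_x + var_y)


def _msw_sigma_propagation(frame, x, y, sigma_pix):
    """Delta-method standard error of w^2 from per-pixel uncertainties."""
    total = frame.sum()
    X, Y = np.meshgrid(x, y)
    mx = (frame * X).sum() / total
    my = (frame * Y).sum() / total
    w2 = ((frame * ((X - mx) ** 2 + (Y - my) ** 2)).sum() / total)
    grad = (((X - mx) ** 2 + (Y - my) ** 2) - w2) / total
    return float(np.sqrt(((grad * sigma_pix) ** 2).sum()))


def msw_series(stack: FrameStack, subtract_bg: bool = True,
               n_bootstrap: int = 50, seed: int = 0,
               correct_blur: bool = True):
    """Mean square width per frame, with uncertainties.

    Background is removed per frame (median of the outer 2-pixel ring,
    negatives clipped).  For a declared Poisson noise model the w^2
    uncertainty is bootstrapped over noise realizations; otherwise it comes
    from pixel-level error propagation.  If the sidecar declares an optical
    blur, its variance sigma_x^2 + sigma_y^2 is subtracted (Gaussian
    convolution adds exactly that much to w^2).  Frames with no signal are
    excluded and reported.

    Frames whose profile is wider than a third of the field half-extent
    (a window under 6 profile standard deviations, where truncation bias
    exceeds ~1%) are likewise excluded and reported.

    Returns (t, w2, sigma_w2, excluded) with ``excluded`` a list of
    (frame time, reason) pairs.
    """
    rng = np.random.default_rng(seed)
    noise = stack.meta.get("noise", "")
    avg = stack.meta.get("averaging", 1)
    mns = stack.meta.get("mc_noise_scale")
    blur = stack.meta.get("blur_sigma")
    blur_var = (blur[0] ** 2 + blur[1] ** 2) if (blur and correct_blur) else 0.0
    half_x = 0.5 * (stack.x_centers[-1] - stack.x_centers[0])
    half_y = 0.5 * (stack.y_centers[-1] - stack.y_centers[0])
    ts, w2s, sig, excluded = [], [], [], []
    for i, (t, raw) in enumerate(zip(stack.frame_times, stack.frames)):
        # effective averaging: camera Poisson variance c/avg plus the
        # generator's Monte Carlo sampling variance c * mc_noise_scale
        avg_eff = 1.0 / (1.0 / avg + (mns[i] if mns else 0.0))
        frame, _clip = subtract_background(raw) if subtract_bg else (raw, 0.0)
        if frame.sum() <= 0:
            excluded.append((float(t), "no signal"))
            continue
        w2 = mean_square_width(frame, stack.x_centers, stack.y_centers)
        # enforce the finite-field window check: the grid must span at
        # least ~6 profile standard deviations per axis, otherwise the
        # truncation bias on the variance exceeds the percent level
        sx = np.sqrt(mean_square_width(frame, stack.x_centers,
                                       stack.y_centers, per_axis=True))
        sy = np.sqrt(max(w2 - sx * sx, 0.0))
        if half_x < 3.0 * sx or half_y < 3.0 * sy:
            excluded.append((float(t), "field narrower than 6 profile sigma"))
            continue
        if noise == "poisson":
            boots = []
            for _ in range(n_bootstrap):
                resampled = rng.poisson(
                    np.maximum(frame, 0.0) * avg_eff) / avg_eff
                if resampled.sum() > 0:
                    boots.append(mean_square_width(
                        resampled, stack.x_centers, stack.y_centers))
            s = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.inf
        else:
            s = _msw_sigma_propagation(
                frame, stack.x_centers, stack.y_centers,
                np.sqrt(np.maximum(frame, 1.0) / avg_eff))
        ts.append(t)
        w2s.append(w2 - blur_var)
        sig.append(s)
    return (np.array(ts), np.array(w2s), np.array(sig), excluded)


def integrate_frames(stack: FrameStack, subtract_bg: bool = True) -> TimeTrace:
    """Total intensity per frame vs frame time (the emulated PMT channel)."""
    totals = []
    for raw in stack.frames:
        frame, _ = subtract_background(raw) if subtract_bg else (raw, 0.0)
        totals.append(frame.sum())
    return TimeTrace(t=stack.frame_times.copy(), counts=np.array(totals))


def radial_profile(frame: np.ndarray, x_centers: np.ndarray,
                   y_centers: np.ndarray, center: tuple | None = None,
                   return_npix: bool = False):
    """Azimuthally averaged intensity profile I(r) about the beam axis.

    For an isotropic transverse distribution this estimates the same curve
    as a row cross-cut but with far lower variance.  Radial bins have the
    pixel pitch; returns (r_centers, mean intensity per pixel).
    """
    frame = np.asarray(frame, dtype=float)
    cx, cy = (0.0, 0.0) if center is None else center
    X, Y = np.meshgrid(x_centers - cx, y_centers - cy)
    r = np.hypot(X, Y).ravel()
    pitch = abs(x_centers[1] - x_centers[0])
    nb = int(r.max() / pitch) + 1
    idx = np.minimum((r / pitch).astype(int), nb - 1)
    sums = np.bincount(idx, weights=frame.ravel(), minlength=nb)
    cnts = np.bincount(idx, minlength=nb)
    prof = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    if return_npix:
        return (np.arange(nb) + 0.5) * pitch, prof, cnts
    return (np.arange(nb) + 0.5) * pitch, prof


def cross_cut(frame: np.ndarray, x_centers: np.ndarray,
              y_centers: np.ndarray, row: int | None = None,
              n_rows: int = 3):
    """1-D intensity profile along x at a given row (default: centroid row).

    ``n_rows`` adjacent rows centred on the selection are averaged to
    reduce noise.
    """
    frame = np.asarray(frame, dtype=float)
    ny = frame.shape[0]
    if row is None:
        total = frame.sum()
        if total <= 0:
            raise ValueError("frame has no intensity")
        my = (frame.sum(axis=1) @ y_centers) / total
        row = int(np.argmin(np.abs(y_centers - my)))
    if not 0 <= row < ny:
        raise IndexError(f"row {row} outside 0..{ny - 1}")
    half = max(n_rows // 2, 0)
    lo, hi = max(row - half, 0), min(row + half + 1, ny)
    return x_centers, frame[lo:hi].mean(axis=0)
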