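"""Fitting procedures: DA fits, tail/slope estimators, Monte Carlo inversions.

The Monte Carlo inversions evaluate a chi-square objective on a parameter
grid with common random numbers (identical per-packet RNG streams at every
grid node), which makes the stochastic objective quasi-smooth so that local
quadratic interpolation and simplex refinement are meaningful.  Time traces
are compared after area normalization over the fit window (the experiment
has no absolute intensity scale); mean-square-width series are compared
absolutely, since w^2 is scale free by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import minimize

from .da import BoundaryModel, DAParams, da_transmittance
from .mc import BinningSpec, SimulationResult, run_simulation
from .observables import IRF, TimeTrace, convolve_trace, radial_profile
from .slab import LayeredSlab, energy_velocity, symmetric_five_layer


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and diagnostics."""

    params: dict
    uncertainties: dict
    objective: float
    dof: int
    window: tuple
    diagnostics: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.params[name]


@dataclass
class MCObjectiveSpec:
    """Datasets and policy for a Monte Carlo inversion objective."""

    trace: TimeTrace | None = None
    msw: tuple | None = None            # (t, w2, sigma)
    crosscuts: list | None = None       # [(t, x, profile, sigma), ...]
    weights: dict = field(default_factory=dict)
    normalization: str = "area"         # 'area' | 'peak'
    mc_seed: int = 12345
    n_packets: int = 200_000
    binning: BinningSpec | None = None
    irf: IRF | None = None

    def __post_init__(self):
        if self.trace is None and self.msw is None and self.crosscuts is None:
            raise ValueError("objective needs at least one dataset")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("dataset weights must be positive")


# --------------------------------------------------------------------------
# closed-form-model fits

def _trace_window(trace: TimeTrace, min_tail_counts: float = 10.0):
    """Default DA fit window: 50%-of-peak rising edge to last bin >= 10 counts."""
    c = trace.counts
    ipk = int(np.argmax(c))
    rising = np.where(c[: ipk + 1] >= 0.5 * c[ipk])[0]
    i0 = int(rising[0]) if len(rising) else 0
    above = np.where(c >= min_tail_counts)[0]
    i1 = int(above[-1]) + 1 if len(above) else len(c)
    return i0, i1


def fit_da(trace: TimeTrace, L: float, n: float, irf: IRF | None = None,
           n_out: float = 1.0, float_time_origin: bool = False) -> FitResult:
    """Diffusion-approximation fit of a time trace with D and mu_a free.

    Minimizes the Poisson-weighted chi-square between the (optionally
    IRF-convolved) slab transmittance and the data over the window from the
    50%-of-peak rising edge to the last bin with >= 10 counts.  The sample
    thickness and refractive index are held fixed.  Also reports the
    implied l_t = 3D/v and l_a = 1/mu_a.
    """
    i0, i1 = _trace_window(trace)
    if i1 - i0 < 50:
        raise ValueError("need at least 50 bins above the noise floor")
    t_all = trace.t
    data = trace.counts[i0:i1]
    sigma = np.sqrt(np.maximum(data, 1.0))
    v = energy_velocity(n)

    pars = lmfit.Parameters()
    lt0 = L / 8.0
    pars.add("D", value=lt0 * v / 3.0, min=1e-3)
    pars.add("mu_a", value=1e-6, min=0.0, max=1e-2)
    pars.add("amp", value=1.0, min=0.0)
    pars.add("t0", value=0.0, vary=float_time_origin, min=-0.2, max=0.2)

    def model_counts(p):
        D, mu_a, amp, t0 = (p["D"].value, p["mu_a"].value,
                            p["amp"].value, p["t0"].value)
        params = DAParams(D=D, mu_a=mu_a, L=L, n_in=n, n_out=n_out)
        boundary = BoundaryModel.for_slab(params.l_t, L, n, n_out)
        tm = t_all - t0
        y = np.zeros_like(tm)
        pos = tm > 1e-4
        y[pos] = da_transmittance(params, boundary, tm[pos], n_images=40)
        m = TimeTrace(t=t_all, counts=np.maximum(y, 0.0))
        if irf is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = convolve_trace(m, irf)
        return amp * m.counts

    # scale-free initial amplitude
    y0 = model_counts(pars)[i0:i1]
    if y0.sum() > 0:
        pars["amp"].value = float(data.sum() / y0.sum())

    def residual(p):
        return (model_counts(p)[i0:i1] - data) / sigma

    out = lmfit.minimize(residual, pars, method="leastsq")
    if not out.success:
        raise RuntimeError(f"DA fit did not converge: {out.message}")
    D = out.params["D"].value
    mu_a = out.params["mu_a"].value
    err = {k: (out.params[k].stderr or np.nan) for k in ("D", "mu_a")}
    mu_a_pinned = mu_a < max(err["mu_a"] if np.isfinite(err["mu_a"]) else 0.0,
                             1e-12)
    return FitResult(
        params={"D": D, "mu_a": mu_a, "l_t": 3.0 * D / v,
                "l_a": (1.0 / mu_a if mu_a > 0 else np.inf),
                "amp": out.params["amp"].value,
                "t0": out.params["t0"].value},
        uncertainties={"D": err["D"], "mu_a": err["mu_a"],
                       "l_t": 3.0 * (err["D"] or np.nan) / v},
        objective=float(out.chisqr), dof=int(out.nfree),
        window=(float(t_all[i0]), float(t_all[i1 - 1])),
        diagnostics={"n_evaluations": out.nfev, "mu_a_pinned": bool(mu_a_pinned),
                     "success": out.success})


def fit_tail_decay(trace: TimeTrace, start: float | None = None,
                   min_tail_counts: float = 10.0,
                   min_decades: float = 2.0) -> FitResult:
    """Exponential decay time from a weighted log-linear fit of the tail.

    The window runs from twice the peak time (default) to the last bin with
    at least ``min_tail_counts``; it must hold >= 20 bins spanning at least
    ``min_decades`` decades of intensity.
    """
    t, c = trace.t, trace.counts
    ipk = int(np.argmax(c))
    t_start = 2.0 * t[ipk] if start is None else start
    above = np.where(c >= min_tail_counts)[0]
    t_end = t[above[-1]] if len(above) else t[-1]
    m = (t >= t_start) & (t <= t_end) & (c > 0)
    if m.sum() < 20:
        raise ValueError(f"tail window has only {m.sum()} usable bins")
    # the measurable decay range: window maximum down to the count floor
    decades = np.log10(c[m].max() / min_tail_counts)
    if decades < min_decades:
        raise ValueError(
            f"tail spans only {decades:.2f} decades (need {min_decades})")
    # weighted linear fit of log counts; Var(log c) ~ 1/c for Poisson data
    w = c[m]
    coef, cov = np.polyfit(t[m], np.log(c[m]), 1, w=np.sqrt(w), cov=True)
    slope = coef[0]
    if slope >= 0:
        raise ValueError("tail is not decaying")
    tau = -1.0 / slope
    tau_err = tau * tau * np.sqrt(cov[0, 0])
    return FitResult(params={"tau": tau}, uncertainties={"tau": tau_err},
                     objective=float(np.sum(w * (np.log(c[m])
                                                 - np.polyval(coef, t[m])) ** 2)),
                     dof=int(m.sum() - 2),
                     window=(float(t_start), float(t_end)),
                     diagnostics={"decades": float(decades),
                                  "n_bins": int(m.sum())})


def fit_msw_slope(t, w2, sigma=None) -> FitResult:
    """Weighted least-squares line through w^2(t); D = slope / 4.

    The intercept is reported as a diagnostic: a nonzero value absorbs
    source-depth and early-time transients and does not bias the slope.
    """
    t = np.asarray(t, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    sigma = np.ones_like(w2) if sigma is None else np.asarray(sigma, float)
    sigma = np.where(sigma > 0, sigma, np.inf)
    A = np.column_stack([t, np.ones_like(t)])
    Aw = A / sigma[:, None]
    bw = w2 / sigma
    coef, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
    cov = np.linalg.inv(Aw.T @ Aw)
    slope, intercept = coef
    if slope <= 0:
        raise ValueError("non-positive mean-square-width slope")
    resid = (A @ coef - w2) / sigma
    return FitResult(
        params={"D": slope / 4.0, "slope": slope, "intercept": intercept},
        uncertainties={"D": np.sqrt(cov[0, 0]) / 4.0,
                       "slope": np.sqrt(cov[0, 0]),
                       "intercept": np.sqrt(cov[1, 1])},
        objective=float(resid @ resid), dof=int(len(t) - 2),
        window=(float(t[0]), float(t[-1])),
        diagnostics={})


# --------------------------------------------------------------------------
# Monte Carlo observables and objectives

def _peak_time(result: SimulationResult, smooth_bins: int = 11) -> float:
    """Transmittance-peak time from a boxcar-smoothed histogram.

    The raw argmax of a noisy histogram jitters by several bins between
    seeds, which would move every window anchored at the peak; smoothing
    over ~0.5 ps stabilizes it.
    """
    k = np.ones(smooth_bins) / smooth_bins
    sm = np.convolve(result.T_hist, k, mode="same")
    return float(result.t_centers[int(np.argmax(sm))])


def mc_tail_decay(result: SimulationResult, start_factor: float = 2.0,
                  rebin: int = 4) -> FitResult:
    """Tail decay time of a simulated T(t) histogram.

    The per-bin transmitted weight is converted back to packet counts (so
    the log-linear fit is weighted by the actual statistics) and rebinned
    by ``rebin`` to consolidate the sparse tail; rebinning does not bias an
    exponential slope.
    """
    counts = result.T_hist * result.n_packets
    t = result.t_centers
    if rebin > 1:
        n = (len(counts) // rebin) * rebin
        counts = counts[:n].reshape(-1, rebin).sum(axis=1)
        t = t[:n].reshape(-1, rebin).mean(axis=1)
    trace = TimeTrace(t=t, counts=counts)
    return fit_tail_decay(trace, start=start_factor * _peak_time(result))


def mc_msw_slope(result: SimulationResult, t_start: float | None = None,
                 t_end: float | None = 14.0,
                 min_weight_rel: float = 1e-4) -> FitResult:
    """w^2(t) slope of a simulation over the linear diffusive window.

    Defaults follow :func:`msw_fit_window`: from twice the transmittance
    peak time (where the diffusive decay is established) to the last
    camera frame delay.
    """
    t_start = 2.0 * _peak_time(result) if t_start is None else t_start
    tmsw, w2, sig = result.msw_series(
        min_weight=min_weight_rel * result.T_hist.max())
    m = tmsw >= t_start
    if t_end is not None:
        m &= tmsw <= t_end
    return fit_msw_slope(tmsw[m], w2[m], sig[m])


def _area_normalized_trace_chi2(data: TimeTrace, model_t, model_y,
                                normalization: str = "area",
                                model_var=None):
    """Chi-square between a measured trace and a model curve, scale removed.

    ``model_var`` (same grid/units as ``model_y``) carries the Monte Carlo
    noise floor of a simulated model curve; it is scaled along with the
    model and added in quadrature to the data sigma, otherwise the
    objective fits the model's own noise realization.
    """
    y = np.interp(data.t, model_t, model_y, left=0.0, right=0.0)
    i0, i1 = _trace_window(data)
    d = data.counts[i0:i1]
    s = np.maximum(data.sigma[i0:i1], 1.0)
    ym = y[i0:i1]
    if normalization == "peak":
        scale = d.max() / max(ym.max(), 1e-300)
    else:
        scale = d.sum() / max(ym.sum(), 1e-300)
    var = s * s
    if model_var is not None:
        vm = np.interp(data.t, model_t, model_var, left=0.0, right=0.0)
        var = var + scale * scale * vm[i0:i1]
    r = (scale * ym - d) / np.sqrt(var)
    return float(r @ r), int(i1 - i0)


def _msw_chi2(msw_data, result: SimulationResult):
    t_d, w2_d, s_d = msw_data
    t_m, w2_m, s_m = result.msw_series(min_weight=1e-9)
    w2_i = np.interp(t_d, t_m, w2_m)
    s_i = np.interp(t_d, t_m, s_m)
    s_tot = np.sqrt(np.asarray(s_d) ** 2 + s_i ** 2)
    r = (w2_i - np.asarray(w2_d)) / np.where(s_tot > 0, s_tot, np.inf)
    return float(r @ r), len(t_d)


def _crosscut_chi2(cuts, result: SimulationResult, gate: float = 0.2,
                   blur_sigma: float = 0.0):
    """Joint chi-square over cross-cut profiles, each area-normalized.

    The model profile is the azimuthal average of the gated (x, y)
    histogram mapped onto the cut axis (transverse transport is isotropic
    in-plane), which suppresses the Monte Carlo noise of a single row;
    ``blur_sigma`` (um) applies the declared optical resolution to the
    model so data and model are compared on equal footing.  The model's
    own Monte Carlo noise floor is added in quadrature to the data sigma.
    """
    from scipy.ndimage import gaussian_filter

    ft = 0.5 * (result.frame_t_edges[:-1] + result.frame_t_edges[1:])
    xc = 0.5 * (result.xy_edges[:-1] + result.xy_edges[1:])
    pitch = float(xc[1] - xc[0])
    dft = float(np.diff(result.frame_t_edges).min())
    total, npts = 0.0, 0
    for (t_cut, x_d, prof_d, sig_d) in cuts:
        m = np.abs(ft - t_cut) <= max(gate / 2.0, 0.51 * dft)
        frame = result.xyt_hist[m].mean(axis=0)
        if frame.sum() <= 0:
            total += 1e6   # no model signal at this gate: heavy penalty
            continue
        if blur_sigma > 0:
            frame = gaussian_filter(frame, sigma=blur_sigma / pitch)
        r, prof_m, npix = radial_profile(frame, xc, xc, return_npix=True)
        prof_mi = np.interp(np.abs(x_d), r, prof_m)
        dx = np.median(np.diff(x_d))
        a_m = prof_mi.sum() * dx
        a_d = np.asarray(prof_d).sum() * dx
        if a_m <= 0 or a_d <= 0:
            total += 1e6
            continue
        pm = prof_mi / a_m
        pd = np.asarray(prof_d) / a_d
        sd = np.asarray(sig_d) / a_d
        # model MC noise floor: per-packet weights are ~the mean exit
        # weight, so Var(I_r) ~ I_r * w_mean / (N * n_pix(r)); propagate
        # through the area normalization and add in quadrature
        npix_i = np.maximum(np.interp(np.abs(x_d), r, npix), 1.0)
        var_m = np.maximum(pm, 1e-12 / a_m) / (
            result.n_packets * npix_i * a_m)
        s_tot = np.sqrt(sd * sd + var_m)
        res = (pm - pd) / np.where(s_tot > 0, s_tot, np.inf)
        total += float(res @ res)
        npts += len(x_d)
    return total, npts


def _joint_objective(spec: MCObjectiveSpec, result: SimulationResult,
                     irf: IRF | None):
    """Per-dataset reduced chi-squares, weighted and summed."""
    chi2 = 0.0
    parts = {}
    if spec.trace is not None:
        model = TimeTrace(t=result.t_centers,
                          counts=np.maximum(result.T_hist, 0.0) + 1e-300)
        if irf is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = convolve_trace(model, irf)
        # per-bin MC variance of the simulated curve (packet weights ~1);
        # the IRF convolution only narrows it, so this is conservative
        model_var = result.T_hist / result.n_packets
        c2, npt = _area_normalized_trace_chi2(
            spec.trace, model.t, model.counts, spec.normalization,
            model_var=model_var)
        parts["trace"] = c2 / max(npt, 1)
        chi2 += spec.weights.get("trace", 1.0) * parts["trace"]
    if spec.msw is not None:
        c2, npt = _msw_chi2(spec.msw, result)
        parts["msw"] = c2 / max(npt, 1)
        chi2 += spec.weights.get("msw", 1.0) * parts["msw"]
    if spec.crosscuts is not None:
        c2, npt = _crosscut_chi2(spec.crosscuts, result)
        parts["crosscuts"] = c2 / max(npt, 1)
        chi2 += spec.weights.get("crosscuts", 1.0) * parts["crosscuts"]
    return chi2, parts


def _paraboloid_vertex(xs, ys, z):
    """Vertex of a weighted 2-D quadratic fitted to a chi-square surface.

    Using every grid node (down-weighted away from the minimum) averages
    the Monte Carlo noise of the individual node evaluations, which makes
    the vertex far more stable than argmin-and-neighbours interpolation.
    Returns (x*, y*, sigma_x, sigma_y) with the Delta-chi2=1 half widths
    from the fitted curvature; falls back to the best node if the surface
    is not convex.
    """
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    k = np.unravel_index(np.argmin(z), z.shape)
    # normalized coordinates for conditioning
    sx = (xs[-1] - xs[0]) or 1.0
    sy = (ys[-1] - ys[0]) or 1.0
    u = (X - xs[k[0]]).ravel() / sx
    v = (Y - ys[k[1]]).ravel() / sy
    dz = (z - z[k]).ravel()
    # temperature: lower-quartile excess, so the fit concentrates on the
    # valley floor rather than the steep walls
    T = max(float(np.partition(dz, len(dz) // 4)[len(dz) // 4]), 10.0)
    w = np.exp(-dz / T)
    A = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
    coef, *_ = np.linalg.lstsq(A * w[:, None], dz * w, rcond=None)
    c0, c1, c2, c11, c12, c22 = coef
    H = np.array([[2 * c11, c12], [c12, 2 * c22]])
    if np.any(np.linalg.eigvalsh(H) <= 0):
        return xs[k[0]], ys[k[1]], np.nan, np.nan
    uv = np.linalg.solve(H, -np.array([c1, c2]))
    # keep the vertex inside the sampled box
    uv = np.clip(uv, [(xs[0] - xs[k[0]]) / sx, (ys[0] - ys[k[1]]) / sy],
                 [(xs[-1] - xs[k[0]]) / sx, (ys[-1] - ys[k[1]]) / sy])
    cov = 2.0 * np.linalg.inv(H)
    return (xs[k[0]] + uv[0] * sx, ys[k[1]] + uv[1] * sy,
            np.sqrt(abs(cov[0, 0])) * sx, np.sqrt(abs(cov[1, 1])) * sy)


def _quadratic_min(xs, ys):
    """Vertex and Delta-chi2=1 half-width of a parabola through 3+ points."""
    c = np.polyfit(xs, ys, 2)
    if c[0] <= 0:
        return xs[int(np.argmin(ys))], np.nan
    xmin = -c[1] / (2.0 * c[0])
    half_width = 1.0 / np.sqrt(c[0])
    return xmin, half_width


# --------------------------------------------------------------------------
# Monte Carlo inversions

def mc_fit_homogeneous(spec: MCObjectiveSpec, L: float, n: float,
                       lt_bracket: tuple = (10.0, 60.0),
                       n_grid: int = 15, n_front: float = 1.0,
                       n_back: float = 1.0) -> FitResult:
    """Single-parameter (l_t) Monte Carlo inversion of trace + width data.

    A log-spaced l_t grid is simulated with common random numbers; the
    joint objective (area-normalized trace + absolute mean square width) is
    interpolated by a local quadratic around the best node.  Requires both
    datasets so the two constraints act simultaneously.
    """
    if spec.trace is None or spec.msw is None:
        raise ValueError("homogeneous inversion needs trace and msw datasets")
    grid = np.geomspace(lt_bracket[0], lt_bracket[1], n_grid)
    chis = []
    for lt in grid:
        slab = LayeredSlab.homogeneous(L, l_s=lt, n=n,
                                       n_front=n_front, n_back=n_back)
        res = run_simulation(slab, spec.n_packets, spec.mc_seed,
                             spec.binning or BinningSpec(record_frames=False))
        chi2, _ = _joint_objective(spec, res, spec.irf)
        chis.append(chi2)
    chis = np.array(chis)
    k = int(np.argmin(chis))
    if k in (0, n_grid - 1):
        raise RuntimeError(
            f"objective minimum at bracket edge (l_t={grid[k]:.3g}); "
            "widen lt_bracket")
    sl = slice(max(k - 2, 0), min(k + 3, n_grid))
    lt_hat, half = _quadratic_min(grid[sl], chis[sl])
    return FitResult(params={"l_t": float(lt_hat)},
                     uncertainties={"l_t": float(half)},
                     objective=float(chis[k]), dof=0,
                     window=(float(grid[0]), float(grid[-1])),
                     diagnostics={"grid": grid.tolist(),
                                  "chi2": chis.tolist(),
                                  "seed": spec.mc_seed,
                                  "n_evaluations": n_grid})


def _layered_slab(lts, thicknesses, n):
    return symmetric_five_layer(thicknesses, lts, n=n)


def mc_fit_layered(spec: MCObjectiveSpec, thicknesses: tuple, n: float,
                   brackets: tuple = ((5.0, 20.0), (10.0, 40.0), (1.5, 8.0)),
                   n_coarse: int = 3, simplex_evals: int = 60) -> FitResult:
    """Three-parameter inversion of the symmetric 5-layer stack.

    ``thicknesses``/parameters are (outer, interstitial, core) layer values;
    the stack is mirrored about the core.  A coarse brute-force grid is
    refined by Nelder-Mead on the common-random-number objective, started
    from the best corners of the grid (ties broken by the smallest outer
    l_t).  Flat directions of the quadratic model are flagged.
    """
    if spec.trace is None or spec.msw is None:
        raise ValueError("layered inversion needs trace and msw datasets")
    cache: dict = {}

    def objective(lts):
        key = tuple(np.round(lts, 4))
        if key in cache:
            return cache[key]
        if any(v <= 0 for v in lts):
            return 1e9
        slab = _layered_slab(lts, thicknesses, n)
        res = run_simulation(slab, spec.n_packets, spec.mc_seed,
                             spec.binning or BinningSpec(record_frames=False))
        chi2, _ = _joint_objective(spec, res, spec.irf)
        cache[key] = chi2
        return chi2

    axes = [np.geomspace(b[0], b[1], n_coarse) for b in brackets]
    nodes = [(o, i, c) for o in axes[0] for i in axes[1] for c in axes[2]]
    vals = [objective(np.array(p)) for p in nodes]
    order = np.argsort(vals, kind="stable")
    starts = [np.array(nodes[j]) for j in order[:4]]
    best = None
    for s in starts:
        out = minimize(objective, s, method="Nelder-Mead",
                       options={"maxfev": simplex_evals, "xatol": 0.05,
                                "fatol": 1e-3})
        if best is None or out.fun < best.fun or (
                np.isclose(out.fun, best.fun) and out.x[0] < best.x[0]):
            best = out
    lts = best.x
    # Delta-chi2 = 1 intervals from axis-wise quadratic probes
    unc = {}
    flat = []
    names = ("l_t_outer", "l_t_inter", "l_t_core")
    for i, name in enumerate(names):
        step = 0.1 * lts[i]
        xs = np.array([lts[i] - step, lts[i], lts[i] + step])
        ys = [objective(np.array([*lts[:i], xv, *lts[i + 1:]])) for xv in xs]
        _, half = _quadratic_min(xs, np.array(ys))
        unc[name] = float(half)
        if not np.isfinite(half) or half > lts[i]:
            flat.append(name)
    return FitResult(
        params=dict(zip(names, map(float, lts))),
        uncertainties=unc, objective=float(best.fun), dof=0,
        window=tuple(brackets),
        diagnostics={"flat_directions": flat, "seed": spec.mc_seed,
                     "n_evaluations": len(cache)})


def mc_fit_thin_membrane(crosscuts: list, L: float, n: float,
                         g_grid=None, ls_grid=None,
                         n_packets: int = 200_000, seed: int = 2024,
                         binning: BinningSpec | None = None,
                         blur_sigma: float = 0.0,
                         refine_factor: int = 8,
                         degeneracy_threshold: float = 9.0) -> FitResult:
    """Two-parameter (g, l_s) inversion of thin-membrane cross-cuts.

    ``crosscuts`` is a list of (t, x, profile, sigma) tuples spanning at
    least 3 ps.  Stage one evaluates the joint area-normalized chi-square
    on a coarse (g, l_s) grid with common random numbers to locate the
    low-chi-square valley (which tracks l_t = l_s/(1-g)); stage two
    re-grids locally in (g, l_t) coordinates at ``refine_factor`` times
    the packet count, where the along-valley discrimination is limited by
    the model's own Monte Carlo noise.  In the thin regime the profiles
    break the similarity degeneracy, so the refined objective curves along
    the constant-l_t direction and both parameters are identifiable; if
    the input is optically thick that direction is flat (within
    ``degeneracy_threshold`` in chi-square) and a degeneracy error advises
    trace-based fitting instead.
    """
    if len(crosscuts) < 3:
        raise ValueError("need at least 3 cross-cut times")
    times = sorted(c[0] for c in crosscuts)
    if times[-1] - times[0] < 3.0:
        raise ValueError("cross-cut times must span at least 3 ps")
    g_grid = np.linspace(0.0, 0.9, 7) if g_grid is None else np.asarray(g_grid)
    ls_grid = (np.geomspace(60.0, 400.0, 7) if ls_grid is None
               else np.asarray(ls_grid))
    binning = binning or BinningSpec(t_max=20.0, t_bin=0.05, xy_half=3000.0,
                                     xy_bin=20.0, frame_t_max=6.0,
                                     frame_t_bin=0.1)

    def objective(g, ls, npk):
        slab = LayeredSlab.homogeneous(L, l_s=float(ls), g=float(g), n=n)
        res = run_simulation(slab, npk, seed, binning)
        return _crosscut_chi2(crosscuts, res, blur_sigma=blur_sigma)[0]

    chi2 = np.empty((len(g_grid), len(ls_grid)))
    for i, g in enumerate(g_grid):
        for j, ls in enumerate(ls_grid):
            chi2[i, j] = objective(g, ls, n_packets)
    k = np.unravel_index(np.argmin(chi2), chi2.shape)
    g0, lt0 = g_grid[k[0]], ls_grid[k[1]] / (1.0 - g_grid[k[0]])

    # refined stage in (g, l_t) coordinates around the coarse minimum; the
    # g window spans two coarse steps on each side because the coarse
    # minimum can sit well away from the truth along the shallow
    # constant-l_t valley.  If the refined minimum lands on a window edge
    # the window is re-centred there and re-evaluated (the coarse stage is
    # noisy enough to mis-locate the valley by more than the window span).
    n_fine = n_packets * refine_factor
    dg = np.diff(g_grid).mean()
    cache: dict = {}

    def fine_objective(g, ls):
        key = (round(float(g), 6), round(float(ls), 4))
        if key not in cache:
            cache[key] = objective(g, ls, n_fine)
        return cache[key]

    g_c, lt_c = g0, lt0
    for _ in range(4):
        g_fine = np.unique(np.clip(
            g_c + dg * np.array([-2.0, -1.5, -1.0, -0.5, 0.0,
                                 0.5, 1.0, 1.5, 2.0]), 0.0, 0.95))
        lt_fine = lt_c * np.array([0.85, 0.925, 1.0, 1.075, 1.15])
        chi_f = np.empty((len(g_fine), len(lt_fine)))
        for i, g in enumerate(g_fine):
            for j, lt in enumerate(lt_fine):
                chi_f[i, j] = fine_objective(g, lt * (1.0 - g))
        kf = np.unravel_index(np.argmin(chi_f), chi_f.shape)
        on_g_edge = (kf[0] == 0 and g_fine[0] > 0.0) or \
                    (kf[0] == len(g_fine) - 1 and g_fine[-1] < 0.95)
        on_lt_edge = kf[1] in (0, len(lt_fine) - 1)
        if not on_g_edge and not on_lt_edge:
            break
        g_c, lt_c = float(g_fine[kf[0]]), float(lt_fine[kf[1]])

    # similarity-degeneracy check: curvature along constant l_t
    iso = chi_f[:, kf[1]]
    iso_span = float(iso.max() - iso.min())
    if iso_span < degeneracy_threshold:
        raise RuntimeError(
            "objective is flat along the constant-l_t direction "
            f"(chi-square span {iso_span:.1f}): the similarity degeneracy "
            "holds; fit the time trace for l_t instead")

    g_fit, lt_fit, g_err, lt_err = _paraboloid_vertex(g_fine, lt_fine, chi_f)
    g_fit = float(np.clip(g_fit, 0.0, 0.999))
    ls_fit = float(lt_fit * (1.0 - g_fit))
    ls_err = float(np.hypot((1.0 - g_fit) * (lt_err if np.isfinite(lt_err)
                                             else 0.0),
                            lt_fit * (g_err if np.isfinite(g_err) else 0.0)))
    return FitResult(
        params={"g": g_fit, "l_s": ls_fit, "l_t": float(lt_fit)},
        uncertainties={"g": float(g_err), "l_s": ls_err},
        objective=float(chi_f[kf]), dof=0,
        window=(times[0], times[-1]),
        diagnostics={"g_grid": g_grid.tolist(), "ls_grid": ls_grid.tolist(),
                     "chi2_coarse": chi2.tolist(),
                     "g_fine": g_fine.tolist(), "lt_fine": lt_fine.tolist(),
                     "chi2_fine": chi_f.tolist(), "seed": seed,
                     "iso_lt_span": iso_span,
                     "n_evaluations": chi2.size + chi_f.size})


# --------------------------------------------------------------------------
# homogeneous-equivalent scans (layered-sample inconsistency analysis)

def lt_matching_decay_time(target_tau: float, L: float, n: float,
                           lt_bracket: tuple, n_scan: int = 7,
                           n_packets: int = 300_000, seed: int = 7,
                           binning: BinningSpec | None = None) -> float:
    """Homogeneous l_t whose MC tail decay time equals ``target_tau``.

    Scans l_t over the bracket, fits each decay time, and inverts the
    monotonic tau(l_t) relation by interpolation.
    """
    grid = np.geomspace(lt_bracket[0], lt_bracket[1], n_scan)
    taus = []
    # slow-decaying candidates need a longer histogram for >=2 tail decades
    binning = binning or BinningSpec(t_max=80.0, record_frames=False)
    for lt in grid:
        res = run_simulation(LayeredSlab.homogeneous(L, l_s=lt, n=n),
                             n_packets, seed, binning)
        # coarse rebinning consolidates the scan statistics; an
        # exponential slope is insensitive to bin width << tau
        taus.append(mc_tail_decay(res, rebin=8).params["tau"])
    taus = np.array(taus)
    order = np.argsort(taus)
    if not (taus.min() <= target_tau <= taus.max()):
        raise RuntimeError("target decay time outside the scanned bracket")
    return float(np.interp(target_tau, taus[order], grid[order]))


#: last gated-camera frame delay (ps): width data exists only up to here
LAST_FRAME_DELAY = 14.0


def msw_fit_window(result: SimulationResult,
                   t_end: float = LAST_FRAME_DELAY) -> tuple:
    """Slope-fit window for a dataset: [2 x transmittance-peak time, t_end].

    The window opens where the diffusive decay is established (the same
    convention as the tail fit) and closes at the last camera delay.  When
    matching a homogeneous model to a measured sample the *sample's*
    window is applied to both, so the compared slopes are window
    consistent.
    """
    return (2.0 * _peak_time(result), t_end)


def lt_matching_msw_slope(target_slope: float, L: float, n: float,
                          lt_bracket: tuple, n_scan: int = 7,
                          n_packets: int = 300_000, seed: int = 7,
                          binning: BinningSpec | None = None,
                          t_window: tuple = (2.0, LAST_FRAME_DELAY)) -> float:
    """Homogeneous l_t whose MC mean-square-width slope equals ``target_slope``.

    The default ``t_window`` is the full camera range (2-14 ps): matching
    compares the measured width evolution, so the target slope must be
    extracted over the same absolute window (w^2(t) is not perfectly
    linear and fitted slopes are window dependent).
    """
    grid = np.geomspace(lt_bracket[0], lt_bracket[1], n_scan)
    slopes = []
    binning = binning or BinningSpec(record_frames=False)
    for lt in grid:
        res = run_simulation(LayeredSlab.homogeneous(L, l_s=lt, n=n),
                             n_packets, seed, binning)
        slopes.append(mc_msw_slope(res, t_start=t_window[0],
                                   t_end=t_window[1]).params["slope"])
    slopes = np.array(slopes)
    order = np.argsort(slopes)
    if not (slopes.min() <= target_slope <= slopes.max()):
        raise RuntimeError("target slope outside the scanned bracket")
    return float(np.interp(target_slope, slopes[order], grid[order]))
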