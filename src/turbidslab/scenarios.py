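"""Scenario presets and instrument emulation for end-to-end synthetic studies.

Three preset scenarios mirror the experimental cases this package is built
to analyze:

``homogeneous_203um``
    A 203-um TiO2-in-polymer slab, n=1.52.  The default ("mc") optical
    variant is the isotropic l_t = 25.5 um, mu_a = 0 model that reproduces
    both the measured decay time and width slope; the "da" variant carries
    the diffusion-fit parameters l_t = 24.1 um, l_a = 12.0 mm whose implied
    ~8% absorption is the artifact under study.

``layered_190um``
    A 190-um slab that is secretly a symmetric 5-layer stack
    (22/60/26/60/22 um with l_t = 11.0/21.5/3.5/21.5/11.0 um, n=1.52):
    large-scale layering that mimics anisotropic transport and defeats any
    single-l_t description.

``membrane_85um``
    An 85-um almost-transparent membrane (dried citrus skin), n=1.31,
    g=0.7, l_s=150 um: in-plane l_t = 500 um, far below one transport mean
    free path of optical thickness, where the similarity relation breaks
    down and (g, l_s) become separately measurable.

The emulation chain turns a Monte Carlo result into detector-like data:
IRF convolution (cross-correlation of two sech^2 pulses, 174 fs response),
Poisson counting noise over an ~8-decade dynamic range for the PMT channel,
and gated frames with anisotropic optical-resolution blur and averaging
over disorder realizations for the camera channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .mc import BinningSpec, SimulationResult, run_simulation
from .observables import (IRF, FrameStack, TimeTrace, convolve_trace,
                          cross_cut, msw_series)
from .slab import LayeredSlab, symmetric_five_layer

PRESET_NAMES = ("homogeneous_203um", "layered_190um", "membrane_85um")

#: isotropic post-Fourier-filter resolution, line pairs per mm at 0.5 contrast
DEFAULT_RESOLUTION_LP_MM = 11.3
#: pre-filter anisotropic resolution (x, y)
ANISO_RESOLUTION_LP_MM = (22.6, 11.3)


def blur_sigma_from_resolution(lp_per_mm: float) -> float:
    """Gaussian blur sigma (um) for a resolution quoted in lp/mm at 0.5 contrast.

    The blur FWHM is taken as half the finest resolvable line-pair period,
    1/(2 * lp_per_mm) mm.
    """
    fwhm_um = 1000.0 / (2.0 * lp_per_mm)
    return fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NoiseModel:
    """Poisson counting noise with a finite dynamic range."""

    kind: str = "poisson"
    peak_counts: float = 1e5
    dynamic_range_decades: float = 8.0
    dark_floor: float = 0.0

    def __post_init__(self):
        if self.kind != "poisson":
            raise ValueError("only Poisson counting noise is modelled")
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        if self.dynamic_range_decades > 8.0:
            raise ValueError("dynamic range cannot exceed 8 decades")


@dataclass(frozen=True)
class Scenario:
    """A sample plus the acquisition settings used to emulate its datasets."""

    name: str
    slab: LayeredSlab
    binning: BinningSpec
    frame_times: tuple
    irf: IRF
    trace_noise: NoiseModel = NoiseModel(peak_counts=1e5)
    frame_peak_counts: float = 1e3
    averaging: int = 100
    resolution_lp_mm: float = DEFAULT_RESOLUTION_LP_MM
    #: 'global': one intensity scale for the whole stack; 'per_frame': each
    #: frame exposed to its own peak (adjustable integration time per delay,
    #: usual for weak late gates — w^2 and cross-cut shapes are scale free)
    frame_scaling: str = "global"

    @property
    def blur_sigma(self) -> tuple:
        s = blur_sigma_from_resolution(self.resolution_lp_mm)
        return (s, s)


def make_scenario(name: str, variant: str = "mc") -> Scenario:
    """Build a named preset scenario (or load a YAML config by path).

    For ``homogeneous_203um`` the ``variant`` selects the optical model:
    "mc" (default) the non-absorbing l_t=25.5 um Monte Carlo solution, "da"
    the absorbing diffusion-fit parameters (l_t=24.1 um, l_a=12.0 mm).
    """
    irf = IRF.from_response_fwhm(174.0)
    if name == "homogeneous_203um":
        if variant == "mc":
            slab = LayeredSlab.homogeneous(203.0, l_s=25.5, n=1.52)
        elif variant == "da":
            slab = LayeredSlab.homogeneous(203.0, l_s=24.1, mu_a=1.0 / 12000.0,
                                           n=1.52)
        else:
            raise ValueError(f"unknown variant {variant!r} (use 'mc' or 'da')")
        return Scenario(name=name, slab=slab, binning=BinningSpec(),
                        frame_times=tuple(np.arange(2.0, 14.1, 1.0)), irf=irf)
    if name == "layered_190um":
        slab = symmetric_five_layer((22.0, 60.0, 26.0), (11.0, 21.5, 3.5),
                                    n=1.52)
        return Scenario(name=name, slab=slab, binning=BinningSpec(),
                        frame_times=tuple(np.arange(2.0, 14.1, 1.0)), irf=irf)
    if name == "membrane_85um":
        slab = LayeredSlab.homogeneous(85.0, l_s=150.0, g=0.7, n=1.31)
        binning = BinningSpec(t_max=20.0, t_bin=0.05, xy_half=3000.0,
                              xy_bin=20.0, frame_t_max=6.0, frame_t_bin=0.1)
        return Scenario(name=name, slab=slab, binning=binning,
                        frame_times=(1.0, 2.0, 3.0, 4.0, 5.0), irf=irf,
                        frame_peak_counts=1e3, averaging=100,
                        frame_scaling="per_frame")
    path = Path(name)
    if path.exists():
        return scenario_from_yaml(path)
    raise ValueError(
        f"unknown scenario {name!r}; presets are {', '.join(PRESET_NAMES)}")


def scenario_to_yaml(scn: Scenario, path) -> None:
    d = {
        "name": scn.name,
        "slab": scn.slab.to_dict(),
        "binning": {k: getattr(scn.binning, k) for k in
                    ("t_max", "t_bin", "xy_half", "xy_bin",
                     "frame_t_max", "frame_t_bin", "record_frames")},
        "frame_times": list(scn.frame_times),
        "irf": {"fwhm_probe": scn.irf.fwhm_probe,
                "fwhm_gate": scn.irf.fwhm_gate},
        "trace_noise": {"peak_counts": scn.trace_noise.peak_counts,
                        "dynamic_range_decades":
                            scn.trace_noise.dynamic_range_decades,
                        "dark_floor": scn.trace_noise.dark_floor},
        "frame_peak_counts": scn.frame_peak_counts,
        "averaging": scn.averaging,
        "resolution_lp_mm": scn.resolution_lp_mm,
        "frame_scaling": scn.frame_scaling,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def scenario_from_yaml(path) -> Scenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return Scenario(
        name=d["name"], slab=LayeredSlab.from_dict(d["slab"]),
        binning=BinningSpec(**d["binning"]),
        frame_times=tuple(d["frame_times"]),
        irf=IRF(**d["irf"]), trace_noise=NoiseModel(**d["trace_noise"]),
        frame_peak_counts=d["frame_peak_counts"], averaging=d["averaging"],
        resolution_lp_mm=d["resolution_lp_mm"],
        frame_scaling=d.get("frame_scaling", "global"))


def synthesize_pmt_trace(result: SimulationResult, irf: IRF,
                         noise: NoiseModel, seed: int) -> TimeTrace:
    """Emulate the photon-counting channel from a simulated T(t).

    The transmittance histogram is convolved with the instrument response,
    scaled so its maximum expectation equals ``peak_counts``, Poisson
    sampled, offset by the dark floor, and truncated below the dynamic
    range floor.  Deterministic per seed.
    """
    dt = float(np.diff(result.t_edges).min())
    if dt > irf.response_fwhm_ps:
        raise ValueError("time binning is coarser than the instrument response")
    model = TimeTrace(t=result.t_centers, counts=result.T_hist.copy())
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = convolve_trace(model, irf)
    peak = model.counts.max()
    if peak <= 0:
        raise ValueError("simulation has no transmitted signal")
    expected = model.counts * (noise.peak_counts / peak)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected + noise.dark_floor).astype(float)
    floor = noise.peak_counts * 10.0 ** (-noise.dynamic_range_decades)
    counts[expected + noise.dark_floor < floor] = 0.0
    return TimeTrace(t=model.t, counts=counts)


def synthesize_frame_stack(result: SimulationResult, scenario: Scenario,
                           seed: int, noiseless: bool = False,
                           blur: bool = True) -> FrameStack:
    """Emulate the gated camera from a simulated (x, y, t) histogram.

    Each frame averages the histogram over a gate window equal to the IRF
    cross-correlation FWHM centred on the frame time, is blurred with the
    optical-resolution Gaussian, scaled so the brightest pixel of the stack
    expects ``frame_peak_counts``, and Poisson sampled averaged over the
    scenario's number of disorder realizations.  Deterministic per seed.
    """
    ft_edges = result.frame_t_edges
    ft_centers = 0.5 * (ft_edges[:-1] + ft_edges[1:])
    if len(ft_centers) == 0:
        raise ValueError("simulation was run without frame recording")
    gate = scenario.irf.response_fwhm_ps
    frames = []
    for t in scenario.frame_times:
        if not ft_edges[0] <= t <= ft_edges[-1]:
            raise ValueError(f"frame time {t} ps outside the simulated range "
                             f"[{ft_edges[0]}, {ft_edges[-1]}] ps")
        m = np.abs(ft_centers - t) <= max(gate / 2.0,
                                          0.51 * np.diff(ft_edges).min())
        frames.append(result.xyt_hist[m].mean(axis=0))
    frames = np.array(frames)
    xc = 0.5 * (result.xy_edges[:-1] + result.xy_edges[1:])
    pitch = float(xc[1] - xc[0])
    meta = {"frame_times": list(scenario.frame_times),
            "averaging": scenario.averaging, "noise": "poisson",
            "gate_fwhm_ps": gate}
    if blur:
        sx, sy = scenario.blur_sigma
        frames = np.array([gaussian_filter(f, sigma=(sy / pitch, sx / pitch))
                           for f in frames])
        meta["blur_sigma"] = [sx, sy]
    if not noiseless:
        if scenario.frame_scaling == "per_frame":
            peaks = frames.max(axis=(1, 2))
            if np.any(peaks <= 0):
                raise ValueError("a gated frame has no transmitted signal")
            scales = scenario.frame_peak_counts / peaks
        else:
            peak = frames.max()
            if peak <= 0:
                raise ValueError("no transmitted signal in the gated frames")
            scales = np.full(len(frames), scenario.frame_peak_counts / peak)
        expected = frames * scales[:, None, None]
        rng = np.random.default_rng(seed)
        avg = scenario.averaging
        frames = rng.poisson(expected * avg).astype(float) / avg
        meta["frame_scaling"] = scenario.frame_scaling
        # counts inherit the generator's Monte Carlo sampling noise:
        # Var_MC(counts) = counts * scale / n_packets per pixel
        meta["mc_noise_scale"] = (scales / result.n_packets).tolist()
    else:
        meta["noise"] = "none"
    return FrameStack(frames=frames, x_centers=xc, y_centers=xc,
                      frame_times=np.array(scenario.frame_times), meta=meta)


def synthesize_crosscuts(stack: FrameStack, method: str = "radial",
                         n_rows: int = 3) -> list:
    """Per-frame transverse profiles as (t, x, profile, sigma) tuples.

    ``method='radial'`` (default) takes the azimuthal average about the
    beam axis: for the isotropically disordered samples the ensemble-
    averaged profile is rotationally symmetric, so this is the cross-cut
    of a frame averaged over many disorder realizations, with the noise
    reduced by the pixels per radial bin.  ``method='row'`` cuts the
    centroid row averaged over ``n_rows`` rows, as one would on a single
    anisotropic frame.  Sigma combines the camera counting noise with the
    generator's Monte Carlo sampling noise declared in the sidecar.
    """
    from .observables import radial_profile

    cuts = []
    avg = stack.meta.get("averaging", 1)
    mns = stack.meta.get("mc_noise_scale")
    for i, (t, frame) in enumerate(zip(stack.frame_times, stack.frames)):
        if method == "radial":
            x, prof, npix = radial_profile(frame, stack.x_centers,
                                           stack.y_centers, return_npix=True)
            n_avg = np.maximum(npix, 1)
        elif method == "row":
            x, prof = cross_cut(frame, stack.x_centers, stack.y_centers,
                                n_rows=n_rows)
            n_avg = n_rows
        else:
            raise ValueError(f"unknown method {method!r}")
        var = np.maximum(prof, 1e-3) / avg
        if mns is not None:
            var = var + np.maximum(prof, 1e-3) * mns[i]
        sigma = np.sqrt(var / n_avg)
        cuts.append((float(t), x, prof, sigma))
    return cuts


def run_case_study(name: str, out_dir, seed: int = 1,
                   n_packets: int = 500_000, make_figures: bool = True) -> dict:
    """Simulate a preset scenario, synthesize its datasets, and invert them.

    Writes the synthetic data (TIFF stack + sidecar, trace text file), a
    machine-readable ``report.json`` with every fitted value, and summary
    figures.  Returns the report dict.
    """
    from . import fits  # deferred: fits imports observables/mc as well

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scn = make_scenario(name)
    report: dict = {"scenario": name, "seed": seed, "n_packets": n_packets}

    res = run_simulation(scn.slab, n_packets, seed, scn.binning)
    trace = synthesize_pmt_trace(res, scn.irf, scn.trace_noise, seed + 1)
    stack = synthesize_frame_stack(res, scn, seed + 2)
    trace.save(out / "trace.txt")
    stack.save(out / "frames.tiff")

    if name == "homogeneous_203um":
        da = fits.fit_da(trace, L=scn.slab.L, n=1.52, irf=scn.irf)
        tail = fits.fit_tail_decay(trace)
        t_m, w2_m, s_m, _ = msw_series(stack)
        msw = fits.fit_msw_slope(t_m, w2_m, s_m)
        v = 299.792458 / 1.52
        lt_msw = 3.0 * msw.params["D"] / v
        spec = fits.MCObjectiveSpec(trace=trace, msw=(t_m, w2_m, s_m),
                                    mc_seed=seed + 10,
                                    n_packets=max(n_packets // 2, 100_000),
                                    irf=scn.irf)
        inv = fits.mc_fit_homogeneous(spec, L=scn.slab.L, n=1.52,
                                      lt_bracket=(15.0, 45.0), n_grid=9)
        da_slab = LayeredSlab.homogeneous(203.0, l_s=da.params["l_t"],
                                          mu_a=da.params["mu_a"], n=1.52)
        da_mc = run_simulation(da_slab, max(n_packets // 2, 100_000), seed + 3,
                               BinningSpec(record_frames=False))
        report.update({
            "da_fit": {"l_t_um": da.params["l_t"],
                       "l_a_um": da.params["l_a"],
                       "mu_a_per_um": da.params["mu_a"]},
            "da_implied_absorbed_fraction": da_mc.absorbed_weight,
            "tail_tau_ps": tail.params["tau"],
            "tail_tau_err_ps": tail.uncertainties["tau"],
            "msw_lt_um": lt_msw,
            "msw_lt_excess_pct": 100.0 * (lt_msw / 25.5 - 1.0),
            "mc_inversion_lt_um": inv.params["l_t"],
        })
    elif name == "layered_190um":
        tail = fits.mc_tail_decay(res)
        slope = fits.mc_msw_slope(res, t_start=2.0, t_end=14.0)
        n_scan_packets = max(n_packets // 3, 100_000)
        lt_tau = fits.lt_matching_decay_time(
            tail.params["tau"], L=scn.slab.L, n=1.52, lt_bracket=(10.0, 22.0),
            n_packets=n_scan_packets, seed=seed + 5)
        lt_w2 = fits.lt_matching_msw_slope(
            slope.params["slope"], L=scn.slab.L, n=1.52,
            lt_bracket=(10.0, 22.0), n_packets=n_scan_packets, seed=seed + 5)
        t_m, w2_m, s_m, _ = msw_series(stack)
        spec = fits.MCObjectiveSpec(trace=trace, msw=(t_m, w2_m, s_m),
                                    mc_seed=seed + 10,
                                    n_packets=max(n_packets // 10, 30_000),
                                    irf=scn.irf)
        layered = fits.mc_fit_layered(spec, thicknesses=(22.0, 60.0, 26.0),
                                      n=1.52)
        report.update({
            "layered_tail_tau_ps": tail.params["tau"],
            "lt_matching_decay_um": lt_tau,
            "lt_matching_msw_slope_um": lt_w2,
            "homogeneous_inconsistency_pct":
                100.0 * abs(lt_w2 - lt_tau) / lt_tau,
            "layered_fit": layered.params,
        })
    elif name == "membrane_85um":
        cuts = synthesize_crosscuts(stack)
        fit = fits.mc_fit_thin_membrane(
            cuts, L=scn.slab.L, n=1.31,
            n_packets=max(n_packets // 5, 50_000), seed=seed + 10)
        report.update({
            "recovered_g": fit.params["g"],
            "recovered_ls_um": fit.params["l_s"],
            "recovered_lt_um": fit.params["l_t"],
            "g_rel_err_pct": 100.0 * abs(fit.params["g"] / 0.7 - 1.0),
            "ls_rel_err_pct": 100.0 * abs(fit.params["l_s"] / 150.0 - 1.0),
        })
    else:
        raise ValueError(f"no case study defined for {name!r}")

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    if make_figures:
        _case_figures(name, out, res, trace, stack)
    return report


def _case_figures(name, out, res, trace, stack):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    ax = axes[0]
    ax.semilogy(trace.t, np.maximum(trace.counts, 0.5), ".", ms=2)
    ax.set_xlabel("t (ps)")
    ax.set_ylabel("counts")
    ax.set_title("time-resolved transmittance")
    ax = axes[1]
    t_m, w2_m, s_m, _ = msw_series(stack)
    ax.errorbar(t_m, w2_m, yerr=s_m, fmt="o", ms=3)
    ax.set_xlabel("t (ps)")
    ax.set_ylabel(r"$w^2$ ($\mu m^2$)")
    ax.set_title("mean square width")
    ax = axes[2]
    mid = len(stack.frames) // 2
    ax.imshow(stack.frames[mid], origin="lower",
              extent=[stack.x_centers[0], stack.x_centers[-1],
                      stack.y_centers[0], stack.y_centers[-1]])
    ax.set_title(f"frame at {stack.frame_times[mid]:.1f} ps")
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=110)
    plt.close(fig)
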