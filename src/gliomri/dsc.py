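"""Dynamic susceptibility contrast (DSC) perfusion quantification.

A gadolinium bolus transiently shortens T2*, so the first-pass signal drop
encodes tissue haemodynamics. Per voxel the pipeline:

1. converts signal to concentration, C(t) = -ln(S(t)/S_base) / TE, with
   S_base the pre-injection baseline mean (Delta-R2* taken linear in
   concentration with unit proportionality, i.e. arbitrary units — without
   an arterial input function no absolute calibration is possible);
2. fits the standard gamma-variate bolus model
   C(t) = K (t - t0)^alpha exp(-(t - t0)/beta) for t > t0;
3. summarizes: CBV = integral of C = K beta^(alpha+1) Gamma(alpha+1),
   MTT = first moment of C about t0 = beta (alpha + 1), and
   CBF = CBV / MTT by the central-volume relation;
4. normalizes each map to a healthy reference region, giving the relative
   (dimensionless) values that are reported.

MTT is defined relative to the arrival time t0 (a pure shape property of
the bolus passage), and the fit is restricted to the first pass: frames up
to 150% of the time at which the curve returns to 20% of its peak, which
excludes recirculation.

``fit_gamma_variate`` is the reference single-curve fitter (scipy
nonlinear least squares seeded by a log-linearized pre-fit). Whole-map
quantification uses ``perfusion_maps``, which runs the same model with
numpy-vectorized solves across all voxels: a golden-section search on the
arrival time wrapped around a linear log-domain solve, followed by a
batched Gauss-Newton polish in concentration space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gamma as gamma_fn

from .volumes import ImageVolume, ParametricMap, ROIMask

__all__ = [
    "DSCAcquisition",
    "GammaVariateFit",
    "PerfusionResult",
    "gamma_variate",
    "signal_to_concentration",
    "baseline_frames",
    "fit_gamma_variate",
    "perfusion_summaries",
    "perfusion_summaries_from_curve",
    "perfusion_maps",
    "normalize_to_reference",
]


@dataclass
class DSCAcquisition:
    """Bolus-tracking acquisition timing (defaults: TR 250 ms, TE 7.1 ms,
    150 repetitions, injection 10 s after the acquisition start)."""

    tr_s: float = 0.25
    te_s: float = 0.0071
    n_repetitions: int = 150
    injection_time_s: float = 10.0
    flip_angle_deg: float = 30.0   # metadata only

    def __post_init__(self) -> None:
        if self.te_s <= 0:
            raise ValueError("TE must be positive")
        if self.tr_s <= 0 or self.n_repetitions < 2:
            raise ValueError("need a positive TR and at least two repetitions")
        if self.duration_s < self.injection_time_s:
            raise ValueError(
                f"acquisition ({self.duration_s:.1f} s) ends before the "
                f"injection at {self.injection_time_s:.1f} s"
            )

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_repetitions

    @property
    def times(self) -> np.ndarray:
        """Frame times in s (frame i at i*TR)."""
        return np.arange(self.n_repetitions) * self.tr_s


@dataclass
class GammaVariateFit:
    """One voxel's first-pass bolus fit."""

    K: float
    alpha: float
    beta: float          # s
    t0: float            # s
    residual_norm: float = 0.0
    converged: bool = True


def gamma_variate(t: np.ndarray, K: float, alpha: float, beta: float,
                  t0: float) -> np.ndarray:
    """K (t - t0)^alpha exp(-(t - t0)/beta) for t > t0, else 0."""
    t = np.asarray(t, dtype=float)
    x = t - t0
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = K * x[pos] ** alpha * np.exp(-x[pos] / beta)
    return out


def baseline_frames(acq: DSCAcquisition, guard_frames: int = 1) -> slice:
    """Frames entirely before the injection, minus a guard frame."""
    stop = int(np.floor(acq.injection_time_s / acq.tr_s)) - guard_frames
    if stop < 1:
        raise ValueError("no baseline frames before the injection")
    return slice(0, stop)


def signal_to_concentration(series: np.ndarray, acq: DSCAcquisition,
                            baseline: slice | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Convert signal time courses to concentration (a.u.).

    ``series`` has time on the last axis. Returns ``(conc, ok)`` where
    ``ok`` flags frames with S > 0 (the log is undefined elsewhere; those
    frames get concentration 0 and ok = False).
    """
    series = np.asarray(series, dtype=float)
    if baseline is None:
        baseline = baseline_frames(acq)
    if baseline.stop is not None and baseline.stop > acq.injection_time_s / acq.tr_s:
        raise ValueError("baseline frames must precede the injection")
    base = series[..., baseline]
    if base.shape[-1] == 0:
        raise ValueError("empty baseline window")
    s_base = base.mean(axis=-1, keepdims=True)
    if np.any(s_base <= 0):
        raise ValueError("baseline mean must be positive")
    ok = series > 0
    conc = np.zeros_like(series)
    np.log(np.divide(series, s_base, out=np.ones_like(series), where=ok),
           out=conc, where=ok)
    conc /= -acq.te_s
    conc[~ok] = 0.0
    return conc, ok


def _first_pass_cutoff(conc: np.ndarray, times: np.ndarray,
                       factor: float = 1.5) -> float:
    """End of the fit window: ``factor`` times the return-to-20%-of-peak time."""
    ipk = int(np.argmax(conc))
    peak = conc[ipk]
    after = np.where(conc[ipk:] < 0.2 * peak)[0]
    t_ret = times[ipk + after[0]] if after.size else times[-1]
    return min(float(factor * t_ret), float(times[-1]))


def fit_gamma_variate(curve: np.ndarray, times: np.ndarray,
                      recirculation_factor: float = 1.5,
                      max_nfev: int = 200) -> GammaVariateFit:
    """Fit the gamma-variate model to one concentration time course.

    Nonlinear least squares (scipy) initialized from the peak position and
    a log-linearized pre-fit; the fit window excludes recirculation. A
    flat, non-positive or non-converged curve returns a flagged result
    (``converged=False``) rather than raising.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    peak = curve.max(initial=0.0)
    flagged = GammaVariateFit(K=0.0, alpha=1.0, beta=1.0, t0=0.0,
                              residual_norm=float(np.linalg.norm(curve)),
                              converged=False)
    if peak <= 0 or not np.isfinite(peak):
        return flagged
    noise_floor = max(1e-12, 0.05 * peak)
    above = np.where(curve > noise_floor)[0]
    if above.size < 5:
        return flagged

    cutoff = _first_pass_cutoff(curve, times, recirculation_factor)
    window = (times <= cutoff)
    ipk = int(np.argmax(curve))
    t_peak = times[ipk]
    # arrival guess: last frame below the floor before the upslope
    i_first = above[0]
    t0_init = times[i_first - 1] if i_first > 0 else times[0] - (times[1] - times[0])

    # log-linearized pre-fit on the upslope/peak frames for (ln K, alpha, 1/beta)
    use = window & (curve > noise_floor) & (times > t0_init)
    x = times[use] - t0_init
    y = np.log(curve[use])
    basis = np.column_stack([np.ones_like(x), np.log(x), -x])
    try:
        p, *_ = np.linalg.lstsq(basis, y, rcond=None)
        k0 = float(np.exp(np.clip(p[0], -500, 500)))
        a0 = float(np.clip(p[1], 0.05, 50.0))
        b0 = float(np.clip(1.0 / p[2], 1e-3, times[-1])) if p[2] > 0 else \
            max(t_peak - t0_init, times[1] - times[0])
    except np.linalg.LinAlgError:
        a0, b0 = 2.0, max(t_peak - t0_init, times[1] - times[0]) / 2.0
        k0 = peak / max(gamma_variate(np.array([t_peak]), 1.0, a0, b0,
                                      t0_init)[0], 1e-12)

    fit_t = times[window]
    fit_c = curve[window]

    def resid(theta: np.ndarray) -> np.ndarray:
        k, a, b, t0 = theta
        return gamma_variate(fit_t, k, a, b, t0) - fit_c

    lo = [0.0, 1e-3, 1e-4, times[0] - (times[1] - times[0])]
    hi = [np.inf, 100.0, float(times[-1]), t_peak]
    x0 = np.clip([k0, a0, b0, t0_init], lo, hi)
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), max_nfev=max_nfev)
    k, a, b, t0 = sol.x
    return GammaVariateFit(K=float(k), alpha=float(a), beta=float(b),
                           t0=float(t0),
                           residual_norm=float(np.linalg.norm(sol.fun)),
                           converged=bool(sol.success))


def perfusion_summaries(fit: GammaVariateFit) -> tuple[float, float, float]:
    """(CBV, CBF, MTT) from a gamma-variate fit, by the closed forms.

    CBV = K beta^(alpha+1) Gamma(alpha+1); MTT = beta (alpha+1);
    CBF = CBV / MTT (central-volume relation). A flagged fit returns NaNs.
    """
    if not fit.converged:
        return (float("nan"),) * 3
    cbv = fit.K * fit.beta ** (fit.alpha + 1.0) * gamma_fn(fit.alpha + 1.0)
    mtt = fit.beta * (fit.alpha + 1.0)
    cbf = cbv / mtt if mtt > 0 else float("nan")
    return float(cbv), float(cbf), float(mtt)


def perfusion_summaries_from_curve(curve: np.ndarray, times: np.ndarray,
                                   t0: float) -> tuple[float, float, float]:
    """(CBV, CBF, MTT) by trapezoid quadrature of a concentration curve.

    MTT is the first moment of C about the arrival time t0.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    cbv = float(np.trapezoid(curve, times))
    if cbv <= 0:
        return float("nan"), float("nan"), float("nan")
    mtt = float(np.trapezoid((times - t0) * curve, times) / cbv)
    cbf = cbv / mtt if mtt > 0 else float("nan")
    return cbv, cbf, mtt


@dataclass
class PerfusionResult:
    """CBV/CBF/MTT maps (a.u.) plus, after normalization, relative maps."""

    cbv: ParametricMap
    cbf: ParametricMap
    mtt: ParametricMap
    rel_cbv: ParametricMap | None = None
    rel_cbf: ParametricMap | None = None
    rel_mtt: ParametricMap | None = None

    def normalize(self, reference: ROIMask) -> "PerfusionResult":
        """Fill the relative maps by dividing by the reference-ROI mean."""
        self.rel_cbv = normalize_to_reference(self.cbv, reference)
        self.rel_cbf = normalize_to_reference(self.cbf, reference)
        self.rel_mtt = normalize_to_reference(self.mtt, reference)
        return self


# ---------------------------------------------------------------------------
# batched whole-map fitting


def _batched_loglinear(conc: np.ndarray, times: np.ndarray,
                       noise_frac: float = 0.05,
                       recirculation_factor: float = 1.5,
                       n_golden: int = 40):
    """Vectorized log-domain gamma-variate fit across voxels.

    For a fixed arrival time the model is linear in (ln K, alpha, 1/beta)
    in log space, so each candidate t0 costs one batched 3x3 normal-
    equation solve; t0 itself is refined per voxel by golden-section
    search between the last pre-bolus frame and the first fitted frame.
    Returns (K, alpha, beta, t0, ok, window) arrays.
    """
    V, T = conc.shape
    dt = times[1] - times[0]
    peak = conc.max(axis=1)
    ipk = conc.argmax(axis=1)
    ok = peak > 0

    floor = np.maximum(1e-12, noise_frac * peak)[:, None]
    above = conc > floor

    # first-pass window: up to recirculation_factor * return-to-20%-peak time
    after_peak = np.arange(T)[None, :] >= ipk[:, None]
    below20 = after_peak & (conc < 0.2 * peak[:, None])
    t_ret = np.where(below20.any(axis=1),
                     times[np.where(below20, np.arange(T)[None, :], T - 1)
                           .min(axis=1).clip(0, T - 1)],
                     times[-1])
    cutoff = np.minimum(recirculation_factor * t_ret, times[-1])
    window = times[None, :] <= cutoff[:, None]

    use_base = above & window
    ok &= use_base.sum(axis=1) >= 5

    # t0 bracket: [frame before first used frame, first used frame)
    i_first = np.where(ok, np.where(use_base, np.arange(T)[None, :], T).min(axis=1),
                       0).clip(0, T - 1)
    t_hi = times[i_first] - 1e-9 * dt
    t_lo = np.where(i_first > 0, times[np.maximum(i_first - 1, 0)], times[0] - dt)

    logc = np.where(use_base, np.log(np.where(use_base, conc, 1.0)), 0.0)

    def sse_and_params(t0: np.ndarray):
        x = times[None, :] - t0[:, None]
        w = use_base & (x > 0)
        xs = np.where(w, x, 1.0)
        phi = np.stack([np.ones((V, T)), np.log(xs), -xs], axis=2)  # (V,T,3)
        wf = w.astype(float)[:, :, None]
        G = np.einsum("vti,vtj->vij", phi * wf, phi)
        rhs = np.einsum("vti,vt->vi", phi * wf, logc)
        G += 1e-12 * np.eye(3)[None]
        try:
            p = np.linalg.solve(G, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            p = np.einsum("vij,vj->vi", np.linalg.pinv(G), rhs)
        pred = np.einsum("vti,vi->vt", phi, p)
        sse = (((pred - logc) ** 2) * wf[:, :, 0]).sum(axis=1)
        return sse, p

    # golden-section on t0, all voxels in parallel
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = t_lo.copy(), t_hi.copy()
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, _ = sse_and_params(c1)
    f2, _ = sse_and_params(c2)
    for _ in range(n_golden):
        take1 = f1 < f2
        c1_old, c2_old, f1_old, f2_old = c1, c2, f1, f2
        b = np.where(take1, c2_old, b)
        a = np.where(take1, a, c1_old)
        width = b - a
        t_new = np.where(take1, b - invphi * width, a + invphi * width)
        f_new, _ = sse_and_params(t_new)
        c1 = np.where(take1, t_new, c2_old)
        f1 = np.where(take1, f_new, f2_old)
        c2 = np.where(take1, c1_old, t_new)
        f2 = np.where(take1, f1_old, f_new)
    t0 = np.where(f1 < f2, c1, c2)
    _, p = sse_and_params(t0)

    K = np.exp(np.clip(p[:, 0], -500, 500))
    alpha = p[:, 1]
    with np.errstate(divide="ignore"):
        beta = np.where(p[:, 2] > 0, 1.0 / np.where(p[:, 2] > 0, p[:, 2], 1.0),
                        np.nan)
    ok &= np.isfinite(beta) & (alpha > 0) & (beta > 0)
    return K, alpha, beta, t0, ok, window


def _batched_polish(conc, times, K, alpha, beta, t0, ok, window,
                    n_iter: int = 25):
    """Batched Gauss-Newton refinement of (K, alpha, beta) in concentration
    space with Levenberg damping; the arrival time stays at the profile-
    search estimate."""
    th = np.stack([np.log(np.maximum(K, 1e-300)),
                   np.log(np.maximum(alpha, 1e-12)),
                   np.log(np.maximum(beta, 1e-12))], axis=1)
    lam = np.full(len(K), 1e-3)

    x = times[None, :] - t0[:, None]
    w = (x > 0) & window
    xs = np.where(w, x, 1.0)

    def model_sse(theta):
        k = np.exp(theta[:, 0])[:, None]
        a = np.exp(theta[:, 1])[:, None]
        b = np.exp(theta[:, 2])[:, None]
        m = np.where(w, k * xs ** a * np.exp(-xs / b), 0.0)
        r = np.where(w, conc - m, 0.0)
        return m, r, (r**2).sum(axis=1)

    m, r, sse = model_sse(th)
    for _ in range(n_iter):
        a = np.exp(th[:, 1])[:, None]
        b = np.exp(th[:, 2])[:, None]
        J = np.stack([m, m * a * np.log(xs), m * xs / b], axis=2)  # (V,T,3)
        J = np.where(w[:, :, None], J, 0.0)
        G = np.einsum("vti,vtj->vij", J, J)
        g = np.einsum("vti,vt->vi", J, r)
        step_ok = ok & (sse > 0)
        dg = np.maximum(np.einsum("vii->vi", G), 1e-12)
        Gd = G + lam[:, None, None] * dg[:, :, None] * np.eye(3)[None]
        try:
            delta = np.linalg.solve(Gd, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("vij,vj->vi", np.linalg.pinv(Gd), g)
        trial = th + np.where(step_ok[:, None], delta, 0.0)
        m2, r2, sse2 = model_sse(trial)
        better = step_ok & (sse2 < sse)
        th = np.where(better[:, None], trial, th)
        m = np.where(better[:, None], m2, m)
        r = np.where(better[:, None], r2, r)
        sse = np.where(better, sse2, sse)
        lam = np.where(better, lam * 0.3, lam * 2.5)
        if not better.any():
            break
    return np.exp(th[:, 0]), np.exp(th[:, 1]), np.exp(th[:, 2]), np.sqrt(sse)


def perfusion_maps(series: ImageVolume, acq: DSCAcquisition,
                   mask: ROIMask, polish: bool = True,
                   recirculation_factor: float = 1.5) -> PerfusionResult:
    """Quantify a 4D DSC series into CBV, CBF and MTT maps over a mask.

    Signal is converted to concentration against the pre-injection
    baseline, the gamma-variate model is fitted per voxel (vectorized
    across the mask), and the closed-form summaries are mapped. Voxels
    whose curve is flat, non-positive or un-fittable are flagged invalid.
    """
    data = series.data
    if data.ndim != 4:
        raise ValueError("DSC series must be 4D")
    if data.shape[3] != acq.n_repetitions:
        raise ValueError(
            f"series has {data.shape[3]} frames but acquisition lists "
            f"{acq.n_repetitions} repetitions"
        )
    if mask.data.shape != data.shape[:3]:
        raise ValueError("mask shape does not match series grid")
    if not mask.data.any():
        raise ValueError("mask selects no voxels")

    times = acq.times
    vox = mask.data
    sig = data[vox]                               # (V, T)
    conc, _ = signal_to_concentration(sig, acq)

    K, alpha, beta, t0, ok, window = _batched_loglinear(
        conc, times, recirculation_factor=recirculation_factor)
    if polish and ok.any():
        K2, a2, b2, _ = _batched_polish(conc, times, K, alpha, beta, t0, ok,
                                        window)
        K = np.where(ok, K2, K)
        alpha = np.where(ok, a2, alpha)
        beta = np.where(ok, b2, beta)

    with np.errstate(invalid="ignore", over="ignore"):
        cbv_v = K * beta ** (alpha + 1.0) * gamma_fn(alpha + 1.0)
        mtt_v = beta * (alpha + 1.0)
        cbf_v = np.where(mtt_v > 0, cbv_v / np.where(mtt_v > 0, mtt_v, 1.0),
                         np.nan)
    ok &= np.isfinite(cbv_v) & np.isfinite(mtt_v)
    cbf_ok = ok & np.isfinite(cbf_v) & (mtt_v > 0)

    shape = data.shape[:3]

    def as_map(vals: np.ndarray, quantity: str, valid_v: np.ndarray) -> ParametricMap:
        out = np.zeros(shape)
        val = np.zeros(shape, bool)
        out[vox] = np.where(valid_v, vals, 0.0)
        val[vox] = valid_v
        return ParametricMap(data=out, voxel_size=series.voxel_size,
                             unit="a.u.", quantity=quantity, valid=val)

    return PerfusionResult(
        cbv=as_map(cbv_v, "CBV", ok),
        cbf=as_map(cbf_v, "CBF", cbf_ok),
        mtt=as_map(mtt_v, "MTT", ok),
    )


def normalize_to_reference(pmap: ParametricMap, reference: ROIMask) -> ParametricMap:
    """Divide a map by its reference-ROI mean (over valid voxels).

    The result is dimensionless ("relative (a.u.)"); it is invariant to
    any global scaling of the input map.
    """
    if reference.data.shape != pmap.data.shape:
        raise ValueError("reference ROI shape does not match map")
    sel = reference.data & pmap.valid
    if not sel.any():
        raise ValueError("reference ROI contains no valid voxels")
    ref_mean = float(pmap.data[sel].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference-ROI mean must be positive, got {ref_mean}")
    out = pmap.with_data(pmap.data / ref_mean,
                         quantity=f"rel{pmap.quantity}", unit="relative (a.u.)")
    out.data[~out.valid] = 0.0
    return out
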