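"""Semi-quantitative first-pass perfusion analysis.

Implements the measurement pipeline for dynamic myocardial perfusion series:
coil-sensitivity plane correction, per-sector and LV blood-pool curve
extraction with baseline offset subtraction, gamma-variate (hyperpolarized)
or 4th-order polynomial (gadolinium-type contrast) curve fitting, the
semi-quantitative measures AUC / peak contrast-to-noise ratio (pCNR) /
upslope, SNR by the difference-of-two-noise-frames method, CNR as peak minus
baseline SNR, cross-sector coefficients of variance, and paired two-sided
Wilcoxon signed-rank comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats
from scipy.special import gamma as gamma_fn

from .errors import FitError, InvalidInputError
from .phantom import (
    DynamicSeries,
    LABEL_LV,
    LABEL_SECTOR_BASE,
    N_SECTORS,
    sector_label,
)

# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SectorCurves:
    """Baseline-corrected signal-time curves: 6 myocardial sectors + LV pool."""

    times_s: np.ndarray
    sectors: np.ndarray  # shape (n_frames, 6)
    lv: np.ndarray
    baseline_corrected: bool = True

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.sectors = np.asarray(self.sectors, dtype=float)
        self.lv = np.asarray(self.lv, dtype=float)
        n = self.times_s.size
        if self.sectors.shape != (n, N_SECTORS) or self.lv.shape != (n,):
            raise InvalidInputError("curve lengths do not match the time axis")
        if n >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise InvalidInputError("times must be strictly increasing")


@dataclass
class GammaVariateFit:
    """Result of a gamma-variate fit ``a t^b exp(-t/c)`` on a first-pass window."""

    a: float
    b: float
    c: float
    t0_s: float  # time origin (bolus arrival) the fit is expressed against
    residual: float
    converged: bool

    @property
    def peak_time_s(self) -> float:
        """Peak of the fitted curve, ``t0 + b*c``."""
        return self.t0_s + self.b * self.c

    @property
    def peak_value(self) -> float:
        return self.a * (self.b * self.c) ** self.b * math.exp(-self.b)

    def __call__(self, t):
        u = np.asarray(t, dtype=float) - self.t0_s
        out = np.zeros_like(u)
        pos = u > 0
        out[pos] = self.a * u[pos] ** self.b * np.exp(-u[pos] / self.c)
        return out if out.ndim else float(out)


@dataclass
class PolynomialFit:
    """Least-squares polynomial fit over a first-pass window."""

    coefficients: np.ndarray  # ascending powers
    t0_s: float
    residual: float
    degree: int = 4

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(
            np.asarray(t, dtype=float) - self.t0_s, self.coefficients)


@dataclass
class PerfusionMetrics:
    """Per-sector semi-quantitative measures and their cross-sector CoV."""

    auc: np.ndarray
    pcnr: np.ndarray
    upslope: np.ndarray
    snr: np.ndarray
    cnr: np.ndarray
    cov: dict = field(default_factory=dict)
    noise_sd: float = float("nan")
    modality: str = "hyperpolarized"
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "modality": self.modality,
            "noise_sd": self.noise_sd,
            "per_sector": {
                "auc_signal_s": list(map(float, self.auc)),
                "pcnr": list(map(float, self.pcnr)),
                "upslope_signal_per_s": list(map(float, self.upslope)),
                "snr": list(map(float, self.snr)),
                "cnr": list(map(float, self.cnr)),
            },
            "cov": {k: float(v) for k, v in self.cov.items()},
            "diagnostics": self.diagnostics,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PerfusionMetrics":
        ps = d["per_sector"]
        return cls(
            auc=np.asarray(ps["auc_signal_s"], dtype=float),
            pcnr=np.asarray(ps["pcnr"], dtype=float),
            upslope=np.asarray(ps["upslope_signal_per_s"], dtype=float),
            snr=np.asarray(ps["snr"], dtype=float),
            cnr=np.asarray(ps["cnr"], dtype=float),
            cov={k: float(v) for k, v in d.get("cov", {}).items()},
            noise_sd=float(d.get("noise_sd", float("nan"))),
            modality=d.get("modality", "hyperpolarized"),
            diagnostics=d.get("diagnostics", {}),
        )


@dataclass
class PairedComparison:
    """Paired two-sided Wilcoxon signed-rank comparison of one metric."""

    p_value: float
    significant: bool
    n: int
    statistic: float = float("nan")


# ---------------------------------------------------------------------------
# Corrections and curve extraction
# ---------------------------------------------------------------------------


def plane_fit_correction(series: DynamicSeries, myocardial_mask: np.ndarray,
                         reference_frame: int) -> DynamicSeries:
    """Divide out a linear coil-sensitivity plane.

    Least-squares plane ``z = c0 + c1 x + c2 y`` over masked pixels at the
    reference frame; the whole series is divided by the plane normalized to
    unit mean over the mask.  Raises for degenerate (collinear / too small)
    masks and vanishing myocardial signal.
    """
    mask = np.asarray(myocardial_mask, dtype=bool)
    if mask.sum() < 3:
        raise InvalidInputError("plane fit needs at least 3 masked pixels")
    frame = series.data[reference_frame]
    rows, cols = np.nonzero(mask)
    a = np.column_stack([np.ones(rows.size), cols.astype(float), rows.astype(float)])
    zvals = frame[mask]
    if not np.any(zvals != 0):
        raise InvalidInputError("reference frame has no myocardial signal")
    if np.linalg.matrix_rank(a) < 3:
        raise FitError("masked pixels are collinear; plane fit is degenerate")
    coef, *_ = np.linalg.lstsq(a, zvals, rcond=None)
    rr, cc = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
    plane = coef[0] + coef[1] * cc + coef[2] * rr
    plane_mean = plane[mask].mean()
    if plane_mean == 0:
        raise FitError("fitted plane has zero mean over the mask")
    plane_norm = plane / plane_mean
    # guard against sign flips / near-zero plane values far from the mask
    plane_norm = np.where(np.abs(plane_norm) < 1e-6, 1.0, plane_norm)
    corrected = series.data / plane_norm[None, :, :]
    return DynamicSeries(corrected, series.frame_times_s.copy(), series.pixel_mm,
                         dict(series.meta, plane_corrected=True))


def myocardium_mask(labels: np.ndarray) -> np.ndarray:
    return np.asarray(labels) >= LABEL_SECTOR_BASE


def extract_curves(series: DynamicSeries, labels: np.ndarray,
                   modality: str = "hyperpolarized", baseline_frames: int = 10,
                   pre_bolus_frames: int = 5) -> SectorCurves:
    """Mean-over-mask sector and LV curves with baseline offset subtraction.

    Hyperpolarized series subtract the mean over the last ``baseline_frames``
    frames (magnitude noise floor after the bolus has decayed); contrast
    series subtract the mean over the first ``pre_bolus_frames`` frames.
    """
    if modality not in ("hyperpolarized", "contrast"):
        raise InvalidInputError("modality must be 'hyperpolarized' or 'contrast'")
    n = series.n_frames
    window = baseline_frames if modality == "hyperpolarized" else pre_bolus_frames
    if n <= window:
        raise InvalidInputError(
            f"series has {n} frames, fewer than the {window}-frame baseline window")
    labels = np.asarray(labels)
    if labels.shape != series.data.shape[1:]:
        raise InvalidInputError("label map shape does not match the series")

    def mean_curve(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            raise InvalidInputError("empty mask in label map")
        return series.data[:, mask].mean(axis=1)

    lv = mean_curve(labels == LABEL_LV)
    sectors = np.column_stack(
        [mean_curve(labels == sector_label(s)) for s in range(1, N_SECTORS + 1)])
    if modality == "hyperpolarized":
        base_slice = slice(n - baseline_frames, n)
    else:
        base_slice = slice(0, pre_bolus_frames)
    lv = lv - lv[base_slice].mean()
    sectors = sectors - sectors[base_slice].mean(axis=0, keepdims=True)
    return SectorCurves(series.frame_times_s.copy(), sectors, lv)


def first_pass_window(times: np.ndarray, lv_curve: np.ndarray,
                      baseline_sd: float | None = None,
                      baseline_frames: int = 10) -> tuple[int, int]:
    """First-pass frame window (start, stop) from the LV bolus curve.

    Starts at the first frame where the LV curve exceeds 5x the baseline
    noise sd (estimated from the trailing ``baseline_frames`` frames when not
    given); ends when the LV curve has fallen below 10 % of its peak after
    the peak (inclusive stop index for ``slice(start, stop)``).
    """
    times = np.asarray(times, dtype=float)
    lv = np.asarray(lv_curve, dtype=float)
    if baseline_sd is None:
        baseline_sd = float(np.std(lv[-baseline_frames:], ddof=1))
    thresh = 5.0 * baseline_sd
    above = np.nonzero(lv > max(thresh, 0.0))[0]
    start = int(above[0]) if above.size else 0
    peak = int(np.argmax(lv))
    stop = lv.size
    for i in range(peak, lv.size):
        if lv[i] < 0.1 * lv[peak]:
            stop = i + 1
            break
    stop = max(stop, start + 6)
    return start, min(stop, lv.size)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Initialize (a, b, c) from log s = log a + b log t - t/c on positive samples."""
    pos = (y > 0) & (t > 0)
    t, y = t[pos], y[pos]
    if t.size < 3:
        raise FitError("not enough positive samples for log-linear initialization")
    design = np.column_stack([np.ones(t.size), np.log(t), -t])
    coef, *_ = np.linalg.lstsq(design, np.log(y), rcond=None)
    a = math.exp(min(coef[0], 700.0))
    b = coef[1]
    c = 1.0 / coef[2] if coef[2] > 0 else float(t[np.argmax(y)])
    return a, min(max(b, 1e-3), 10.0), max(c, 1e-3)


def fit_gamma_variate(times: np.ndarray, curve: np.ndarray,
                      window: tuple[int, int] | None = None,
                      t0_s: float | None = None) -> GammaVariateFit:
    """Nonlinear least-squares gamma-variate fit on a first-pass window.

    ``times`` are absolute frame times; the model is evaluated against
    ``t - t0`` with ``t0`` the bolus arrival (default: time of the window
    start minus half a frame).  Non-convergence and degenerate inputs are
    reported through the ``converged`` flag, not exceptions.
    """
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if window is None:
        i0, i1 = 0, times.size
    else:
        i0, i1 = window
    t_w, y_w = times[i0:i1], curve[i0:i1]
    if t_w.size < 6:
        raise InvalidInputError("need at least 6 points in the fitting window")
    if not np.any(y_w > 0):
        return GammaVariateFit(float("nan"), float("nan"), float("nan"),
                               0.0, float("inf"), converged=False)
    if t0_s is None:
        dt = times[1] - times[0] if times.size > 1 else 0.0
        t0_s = float(t_w[0] - 0.5 * dt) if i0 > 0 else float(times[0] - 0.5 * dt)
        t0_s = min(t0_s, float(t_w[y_w > 0][0]) - 1e-6)
    u = t_w - t0_s
    keep = u > 0
    u, y = u[keep], y_w[keep]
    if u.size < 6:
        return GammaVariateFit(float("nan"), float("nan"), float("nan"),
                               t0_s, float("inf"), converged=False)
    try:
        p0 = _loglinear_init(u, y)
    except FitError:
        return GammaVariateFit(float("nan"), float("nan"), float("nan"),
                               t0_s, float("inf"), converged=False)

    def resid(p):
        a, b, c = p
        return a * u**b * np.exp(-u / c) - y

    try:
        sol = optimize.least_squares(
            resid, p0, bounds=([0.0, 0.0, 1e-6], [np.inf, 10.0, np.inf]),
            xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=500)
    except Exception:
        return GammaVariateFit(float("nan"), float("nan"), float("nan"),
                               t0_s, float("inf"), converged=False)
    a, b, c = sol.x
    residual = float(np.sqrt(2.0 * sol.cost))
    ok = bool(sol.success and a > 0 and b > 0 and c > 0)
    return GammaVariateFit(float(a), float(b), float(c), float(t0_s),
                           residual, converged=ok)


def fit_polynomial4(times: np.ndarray, curve: np.ndarray,
                    window: tuple[int, int] | None = None,
                    degree: int = 4) -> PolynomialFit:
    """Least-squares degree-4 polynomial over the first-pass window."""
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    i0, i1 = (0, times.size) if window is None else window
    t_w, y_w = times[i0:i1], curve[i0:i1]
    if t_w.size < degree + 1:
        raise InvalidInputError(f"need at least {degree + 1} points for degree {degree}")
    t0 = float(t_w[0])
    u = t_w - t0
    design = np.vander(u, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise FitError("rank-deficient design (repeated time samples?)")
    coef, res, *_ = np.linalg.lstsq(design, y_w, rcond=None)
    residual = float(np.sqrt(res[0])) if res.size else float(
        np.linalg.norm(design @ coef - y_w))
    return PolynomialFit(coef, t0, residual, degree)


# ---------------------------------------------------------------------------
# Semi-quantitative measures
# ---------------------------------------------------------------------------


def gamma_variate_area(fit: GammaVariateFit) -> float:
    """Closed-form full-pass area ``a c^(b+1) Gamma(b+1)``."""
    return fit.a * fit.c ** (fit.b + 1) * float(gamma_fn(fit.b + 1))


def semi_quant_metrics(fit, times: np.ndarray, noise_sd: float,
                       window: tuple[int, int] | None = None) -> dict:
    """AUC, pCNR and upslope of a fitted first-pass curve.

    AUC integrates the fitted curve over the window (closed form for a
    gamma-variate when the window covers the full pass); pCNR is the fitted
    peak over the noise sd; upslope is the maximum derivative between bolus
    arrival and the peak.  An invalid (non-converged) fit yields NaNs.
    """
    times = np.asarray(times, dtype=float)
    i0, i1 = (0, times.size) if window is None else window
    t_lo, t_hi = float(times[i0]), float(times[i1 - 1])
    if isinstance(fit, GammaVariateFit):
        if not fit.converged:
            return {"auc": float("nan"), "pcnr": float("nan"), "upslope": float("nan")}
        full_pass = t_hi >= fit.peak_time_s + 3.0 * fit.c
        if full_pass:
            auc = gamma_variate_area(fit)
        else:
            grid = np.linspace(max(t_lo, fit.t0_s), t_hi, 2048)
            auc = float(np.trapezoid(fit(grid), grid))
        peak_t, peak_v = fit.peak_time_s, fit.peak_value
        rise = np.linspace(fit.t0_s + 1e-9, peak_t, 2048)
        upslope = float(np.max(np.gradient(fit(rise), rise)))
    elif isinstance(fit, PolynomialFit):
        grid = np.linspace(t_lo, t_hi, 2048)
        vals = fit(grid)
        auc = float(np.trapezoid(vals, grid))
        ip = int(np.argmax(vals))
        peak_v = float(vals[ip])
        rise = grid[: max(ip, 2)]
        upslope = float(np.max(np.gradient(fit(rise), rise)))
    else:
        raise InvalidInputError(f"unsupported fit type {type(fit).__name__}")
    pcnr = peak_v / noise_sd if noise_sd > 0 else float("nan")
    return {"auc": float(auc), "pcnr": float(pcnr), "upslope": upslope}


def noise_sd_from_frames(series: DynamicSeries, mask: np.ndarray,
                         noise_frames: tuple[int, int]) -> float:
    """Noise sd from the difference of two noise-only frames over a mask.

    The difference of two independent noise realizations has variance
    2 sigma^2, hence the sd of the difference image is divided by sqrt(2).
    """
    i, j = noise_frames
    mask = np.asarray(mask, dtype=bool)
    diff = series.data[i][mask] - series.data[j][mask]
    sd = float(np.std(diff, ddof=1)) / math.sqrt(2.0)
    if sd == 0:
        raise InvalidInputError("zero variance in the noise-frame difference")
    return sd


def snr_curve(series: DynamicSeries, mask: np.ndarray,
              noise_frames: tuple[int, int]) -> np.ndarray:
    """SNR over time: mean signal over mask per frame / noise sd."""
    sd = noise_sd_from_frames(series, mask, noise_frames)
    mask = np.asarray(mask, dtype=bool)
    return series.data[:, mask].mean(axis=1) / sd


def snr(series: DynamicSeries, mask: np.ndarray, noise_frames: tuple[int, int],
        frame: int | None = None) -> float:
    """Scalar SNR of one frame (default: the frame of maximum mean signal)."""
    curve = snr_curve(series, mask, noise_frames)
    return float(curve[frame]) if frame is not None else float(np.max(curve))


def cnr(snr_over_time: np.ndarray, baseline_frames) -> float:
    """CNR = peak SNR minus mean baseline SNR."""
    s = np.asarray(snr_over_time, dtype=float)
    base = np.asarray(baseline_frames)
    return float(np.max(s) - s[base].mean())


def cov(values) -> float:
    """Coefficient of variance: sample sd / mean."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise InvalidInputError("CoV undefined for zero mean")
    return float(np.std(v, ddof=1) / m)


def paired_compare(a, b, alpha: float = 0.05) -> PairedComparison:
    """Paired two-sided Wilcoxon signed-rank test (exact for n <= 25).

    All-zero differences yield p = 1 with a warning.  Ties/zeros fall back to
    the normal approximation; the exact distribution is guaranteed when no
    ties or zeros occur.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidInputError("need equal-length paired 1-D samples with n >= 2")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return PairedComparison(p_value=1.0, significant=False, n=a.size)
    exact_ok = a.size <= 25 and not np.any(d == 0) and np.unique(np.abs(d)).size == d.size
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return PairedComparison(p_value=p, significant=p < alpha, n=a.size,
                            statistic=float(res.statistic))


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------


def analyze_series(series: DynamicSeries, labels: np.ndarray,
                   modality: str = "hyperpolarized",
                   noise_frames: tuple[int, int] | None = None,
                   baseline_frames: int = 10, pre_bolus_frames: int = 5,
                   plane_correct: bool = True) -> PerfusionMetrics:
    """Full pipeline: corrections, curves, fits, metrics, CoV.

    Noise frames default to the last two frames (hyperpolarized, post-bolus)
    or the first two (contrast, pre-bolus).  The plane correction reference
    is the frame of peak myocardial signal (after bolus passage for
    hyperpolarized data the late frames carry no signal to fit against).
    """
    labels = np.asarray(labels)
    n = series.n_frames
    if noise_frames is None:
        noise_frames = (n - 2, n - 1) if modality == "hyperpolarized" else (0, 1)
    myo = myocardium_mask(labels)

    raw_myo = series.data[:, myo].mean(axis=1)
    ref_frame = int(np.argmax(raw_myo))
    work = series
    if plane_correct:
        work = plane_fit_correction(series, myo, ref_frame)

    curves = extract_curves(work, labels, modality, baseline_frames, pre_bolus_frames)
    noise_sd = noise_sd_from_frames(work, myo, noise_frames)
    start, stop = first_pass_window(curves.times_s, curves.lv,
                                    baseline_frames=baseline_frames)

    auc = np.full(N_SECTORS, np.nan)
    pcnr = np.full(N_SECTORS, np.nan)
    upslope = np.full(N_SECTORS, np.nan)
    snr_sector = np.full(N_SECTORS, np.nan)
    cnr_sector = np.full(N_SECTORS, np.nan)
    fits_diag = []

    baseline_idx = (np.arange(n - baseline_frames, n) if modality == "hyperpolarized"
                    else np.arange(0, pre_bolus_frames))

    for s in range(N_SECTORS):
        y = curves.sectors[:, s]
        # extend the window for tissue curves: myocardial passage lags the LV
        if modality == "hyperpolarized":
            fit = fit_gamma_variate(curves.times_s, y, window=(start, n))
            if fit.converged:
                stop_s = min(n, max(stop, int(np.searchsorted(
                    curves.times_s, fit.peak_time_s + 3.0 * fit.c)) + 1))
            else:
                stop_s = stop
            m = semi_quant_metrics(fit, curves.times_s, noise_sd, (start, stop_s))
            fits_diag.append({"sector": s + 1, "converged": fit.converged,
                              "a": fit.a, "b": fit.b, "c": fit.c,
                              "t0_s": fit.t0_s, "residual": fit.residual})
        else:
            fit = fit_polynomial4(curves.times_s, y, window=(start, stop))
            m = semi_quant_metrics(fit, curves.times_s, noise_sd, (start, stop))
            fits_diag.append({"sector": s + 1, "degree": fit.degree,
                              "residual": fit.residual})
        auc[s], pcnr[s], upslope[s] = m["auc"], m["pcnr"], m["upslope"]
        mask_s = labels == sector_label(s + 1)
        sc = snr_curve(work, mask_s, noise_frames)
        snr_sector[s] = float(np.max(sc))
        cnr_sector[s] = cnr(sc, baseline_idx)

    covs = {}
    for name, vals in (("auc", auc), ("pcnr", pcnr), ("upslope", upslope),
                       ("snr", snr_sector), ("cnr", cnr_sector)):
        good = vals[np.isfinite(vals)]
        covs[name] = cov(good) if good.size >= 2 and good.mean() != 0 else float("nan")

    return PerfusionMetrics(
        auc=auc, pcnr=pcnr, upslope=upslope, snr=snr_sector, cnr=cnr_sector,
        cov=covs, noise_sd=noise_sd, modality=modality,
        diagnostics={"first_pass_window": [int(start), int(stop)],
                     "noise_frames": [int(noise_frames[0]), int(noise_frames[1])],
                     "plane_reference_frame": ref_frame,
                     "fits": fits_diag},
    )
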