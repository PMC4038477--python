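"""Bioluminescence time-series analysis.

Detrending and smoothing by running averages, damped-cosine rhythm
fitting, strong/weak oscillator classification, entrainment-phase
estimation from post-release peaks, and relative qPCR quantification
(2^-ddCT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class TraceError(ValueError):
    """Raised for structurally invalid traces or trace operations."""


class PeakNotFoundError(RuntimeError):
    """Raised when no local maximum exists in the requested window."""


@dataclass(frozen=True)
class LuminescenceTrace:
    """Uniformly sampled reporter time series.

    Parameters
    ----------
    time_h : ndarray
        Hours since synchronization, strictly increasing, uniformly
        spaced within 1% relative tolerance.
    value : ndarray
        Reporter counts, or the dimensionless detrended ratio.
    meta : dict
        Free-form provenance (cell line, ``detrended``/``smoothed``
        flags, generator truth, ...).
    """

    time_h: np.ndarray
    value: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise TraceError("time_h and value must be 1-D arrays of equal length")
        if t.size < 2:
            raise TraceError("trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceError("time_h must be strictly increasing")
        if (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise TraceError("sampling must be uniform within 1% tolerance")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "value", v)

    @property
    def dt_h(self) -> float:
        return float(np.mean(np.diff(self.time_h)))

    @property
    def sampling_per_h(self) -> float:
        return 1.0 / self.dt_h

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    def with_meta(self, **kv) -> "LuminescenceTrace":
        return replace(self, meta={**self.meta, **kv})


@dataclass(frozen=True)
class RhythmFit:
    """Damped-cosine fit y(t) = m + A e^(-lambda t) cos(2 pi (t - phi)/tau)."""

    tau_h: float
    amplitude: float
    phase_h: float
    damping_per_h: float
    mesor: float
    r2: float
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "tau_h": self.tau_h,
            "amplitude": self.amplitude,
            "phase_h": self.phase_h,
            "damping_per_h": self.damping_per_h,
            "mesor": self.mesor,
            "r2": self.r2,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class OscillatorClass:
    label: str  # "strong" | "weak"
    rel_amplitude_used: float
    period_band_used: tuple
    reason: str = ""


def _running_mean_full(v: np.ndarray, half: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges."""
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detrend_running_average(trace: LuminescenceTrace, window_h: float = 24.0) -> LuminescenceTrace:
    """Divide counts by the centered running average over ``window_h``.

    The first and last ``window_h / 2`` hours are trimmed so that every
    retained point has a full window.
    """
    if window_h <= 0:
        raise TraceError("window_h must be positive")
    if np.any(trace.value <= 0):
        raise TraceError("detrending requires strictly positive values")
    if trace.duration_h < 2 * window_h:
        raise TraceError(
            f"trace of {trace.duration_h:.1f} h is shorter than twice the "
            f"{window_h:.1f} h detrend window"
        )
    half = int(round(window_h / (2 * trace.dt_h)))
    mean = _running_mean_full(trace.value, half)
    # full-window region only
    sl = slice(half, trace.value.size - half)
    out = trace.value[sl] / mean[sl]
    return LuminescenceTrace(
        trace.time_h[sl], out, {**trace.meta, "detrended": True, "detrend_window_h": window_h}
    )


def smooth_running_average(trace: LuminescenceTrace, window_h: float = 4.0) -> LuminescenceTrace:
    """Centered moving mean over ``window_h``; edges use shrunken windows."""
    if window_h <= 0:
        raise TraceError("window_h must be positive")
    half = int(round(window_h / (2 * trace.dt_h)))
    if half < 1:
        warnings.warn("smoothing window shorter than sampling interval; trace returned unchanged")
        return trace.with_meta(smoothed=False)
    out = _running_mean_full(trace.value, half)
    return LuminescenceTrace(
        trace.time_h, out, {**trace.meta, "smoothed": True, "smooth_window_h": window_h}
    )


def _damped_cosine(t, m, A, lam, tau, phi):
    return m + A * np.exp(-lam * t) * np.cos(2 * np.pi * (t - phi) / tau)


# multistart grids (ties resolved toward the smallest tau)
_TAU_GRID = (20.0, 22.0, 24.0, 26.0, 28.0)
_N_PHASE_STARTS = 4


def fit_damped_cosine(
    trace: LuminescenceTrace,
    fix_damping_zero: bool = False,
    tau_grid: tuple = _TAU_GRID,
) -> RhythmFit:
    """Least-squares damped-cosine fit with a tau x phase multistart.

    Model: ``y(t) = m + A exp(-lambda t) cos(2 pi (t - phi) / tau)`` with
    ``A >= 0`` and ``lambda >= 0``; the amplitude is reported at t = 0 and
    the phase is folded into ``[0, tau)``.
    """
    if trace.duration_h < 48:
        raise TraceError("fitting requires at least 48 h of data")
    t = trace.time_h - trace.time_h[0]
    y = trace.value
    m0 = float(np.mean(y))
    a0 = max(float(np.std(y)) * np.sqrt(2.0), 1e-12)
    sst = float(np.sum((y - m0) ** 2))

    best = None
    for tau0 in tau_grid:
        for k in range(_N_PHASE_STARTS):
            phi0 = tau0 * k / _N_PHASE_STARTS
            if fix_damping_zero:
                x0 = [m0, a0, tau0, phi0]

                def resid(x):
                    return _damped_cosine(t, x[0], x[1], 0.0, x[2], x[3]) - y

                lb = [-np.inf, 0.0, 1.0, -np.inf]
                ub = [np.inf, np.inf, 1000.0, np.inf]
            else:
                x0 = [m0, a0, 0.0, tau0, phi0]

                def resid(x):
                    return _damped_cosine(t, x[0], x[1], x[2], x[3], x[4]) - y

                lb = [-np.inf, 0.0, 0.0, 1.0, -np.inf]
                ub = [np.inf, np.inf, 1.0, 1000.0, np.inf]
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
            except Exception:  # pragma: no cover - defensive
                continue
            if not sol.success:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[0] - 1e-12 or (
                abs(rss - best[0]) <= 1e-12 and _get_tau(sol.x, fix_damping_zero) < best[1]
            ):
                best = (rss, _get_tau(sol.x, fix_damping_zero), sol.x)

    if best is None:
        return RhythmFit(np.nan, np.nan, np.nan, np.nan, np.nan, -np.inf, False,
                         "no start converged")

    rss, tau, x = best
    if fix_damping_zero:
        m, A, tau, phi = x
        lam = 0.0
    else:
        m, A, lam, tau, phi = x
    phi = float(phi % tau)
    r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss < 1e-20 else 0.0)
    # flat signals: r2 of the cosine is meaningless, report ~0
    if sst <= 1e-20:
        r2 = 0.0
    return RhythmFit(float(tau), float(A), phi, float(lam), float(m), float(r2), True)


def _get_tau(x, fixed):
    return x[2] if fixed else x[3]


def classify_oscillator(
    fit: RhythmFit,
    min_rel_amplitude: float = 0.20,
    period_band: tuple = (18.0, 32.0),
    r2_min: float = 0.5,
) -> OscillatorClass:
    """Strong iff amplitude, period band and goodness-of-fit criteria all pass."""
    if not fit.converged:
        return OscillatorClass("weak", min_rel_amplitude, tuple(period_band), "no fit")
    reasons = []
    if fit.amplitude < min_rel_amplitude:
        reasons.append(f"amplitude {fit.amplitude:.3f} < {min_rel_amplitude}")
    if not (period_band[0] <= fit.tau_h <= period_band[1]):
        reasons.append(f"period {fit.tau_h:.2f} h outside band {period_band}")
    if fit.r2 < r2_min:
        reasons.append(f"r2 {fit.r2:.3f} < {r2_min}")
    label = "strong" if not reasons else "weak"
    return OscillatorClass(label, min_rel_amplitude, tuple(period_band), "; ".join(reasons))


def entrainment_phase(
    trace: LuminescenceTrace, release_time_h: float, search_window_h: float = 36.0
) -> float:
    """Hours from release to the first local maximum of the trace.

    The discrete peak is refined by quadratic interpolation through the
    three samples around it. Boundary samples are not eligible peaks.
    """
    t, v = trace.time_h, trace.value
    if release_time_h < t[0] or release_time_h + search_window_h > t[-1] + 1e-9:
        raise TraceError("trace does not cover the requested search window")
    mask = (t >= release_time_h) & (t <= release_time_h + search_window_h)
    idx = np.nonzero(mask)[0]
    for j in idx:
        if j == 0 or j == t.size - 1:
            continue
        if v[j] > v[j - 1] and v[j] >= v[j + 1]:
            # quadratic vertex through (t[j-1..j+1], v[j-1..j+1])
            y0, y1, y2 = v[j - 1], v[j], v[j + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            return float(t[j] + shift * trace.dt_h - release_time_h)
    raise PeakNotFoundError(
        f"no local maximum within {search_window_h} h after release at {release_time_h} h"
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification


class CtError(KeyError):
    """Missing reference/calibrator measurements in a CT table."""


def ddct_quantify(
    ct: pd.DataFrame,
    reference_gene: str = "GAPDH",
    calibrator_sample: str | None = None,
    calibrator_timepoint=None,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCT method.

    ``ct`` needs columns (sample, timepoint, gene, ct). dCT is computed
    against ``reference_gene`` within each (sample, timepoint); ddCT is
    calibrated to the calibrator sample's value at the calibrator
    timepoint, per gene. Defaults: first sample, earliest timepoint.
    """
    required = {"sample", "timepoint", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"CT table must have columns {sorted(required)}")
    if not np.all(np.isfinite(ct["ct"])):
        raise ValueError("CT values must be finite")
    if calibrator_sample is None:
        calibrator_sample = ct["sample"].iloc[0]
    if calibrator_timepoint is None:
        calibrator_timepoint = ct.loc[ct["sample"] == calibrator_sample, "timepoint"].min()

    ref = ct[ct["gene"] == reference_gene].set_index(["sample", "timepoint"])["ct"]
    rows = []
    for (sample, tp), grp in ct.groupby(["sample", "timepoint"], sort=False):
        if (sample, tp) not in ref.index:
            raise CtError(
                f"reference gene {reference_gene!r} missing for sample {sample!r} "
                f"at timepoint {tp!r}"
            )
        ref_ct = ref.loc[(sample, tp)]
        for _, r in grp.iterrows():
            if r["gene"] == reference_gene:
                continue
            rows.append((sample, tp, r["gene"], r["ct"] - ref_ct))
    dct = pd.DataFrame(rows, columns=["sample", "timepoint", "gene", "dct"])

    cal = dct[(dct["sample"] == calibrator_sample) & (dct["timepoint"] == calibrator_timepoint)]
    cal = cal.set_index("gene")["dct"]
    missing = set(dct["gene"]) - set(cal.index)
    if missing:
        raise CtError(
            f"calibrator sample {calibrator_sample!r} lacks genes {sorted(missing)}"
        )
    dct["ddct"] = dct["dct"] - dct["gene"].map(cal)
    dct["rel_expr"] = 2.0 ** (-dct["ddct"])
    return dct


def relative_to_reference_gene(
    expr: pd.DataFrame, reference_gene: str = "BMAL1"
) -> pd.DataFrame:
    """Divide each gene's level by the reference gene's level, per sample.

    ``expr`` is genes x samples on a linear scale.
    """
    if reference_gene not in expr.index:
        raise KeyError(f"reference gene {reference_gene!r} not in expression table")
    ref = expr.loc[reference_gene]
    if np.any(ref == 0):
        bad = list(expr.columns[ref == 0])
        raise ZeroDivisionError(f"reference gene is zero in samples {bad}")
    return expr.div(ref, axis=1)
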