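"""Fiber-photometry preprocessing and event-kernel regression.

Raw two-channel fluorescence (a dopamine-sensor signal channel and an
isosbestic background channel, optionally carrier-modulated at 211 and
531 Hz) is turned into a z-scored dF/F trace by lock-in demodulation,
median + low-pass denoising, slow high-pass bleaching correction,
regression-based motion correction against the background channel, and
division by the slow baseline. Event-locked responses and a linear
event-kernel regression (the photometry signal modelled as a sum of
per-event response kernels convolved with event indicator trains) quantify
what each behavioural event contributes, including per-regressor explained
variance by prediction-recomputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

CARRIER_FREQS = (211.0, 531.0)

#: per-event (pre, post) kernel windows in seconds
DEFAULT_KERNEL_WINDOWS = {
    "cue": (0.0, 1.0),
    "choice": (0.5, 1.5),
    "outcome": (0.0, 1.0),
    "return": (0.2, 1.5),
}


@dataclass
class PhotometrySession:
    """Raw session: two channels on a common clock plus an event log."""

    sampling_rate: float
    signal: np.ndarray
    background: np.ndarray
    events: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.signal.shape != self.background.shape:
            raise ValueError("signal and background channels must have equal length")
        span = len(self.signal) / self.sampling_rate
        for name, times in self.events.items():
            t = np.sort(np.asarray(times, dtype=float))
            if len(t) and (t[0] < 0 or t[-1] > span):
                raise ValueError(f"event {name!r} times fall outside the trace span")
            self.events[name] = t

    @property
    def duration(self) -> float:
        return len(self.signal) / self.sampling_rate


@dataclass
class ProcessedTrace:
    dff_z: np.ndarray
    sampling_rate: float


@dataclass
class KernelSpec:
    """Kernel windows per event type; sample count is (pre+post)*rate + 1."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_KERNEL_WINDOWS))

    def n_lags(self, event: str, rate: float) -> tuple[int, int]:
        pre, post = self.windows[event]
        if pre < 0 or post < 0 or pre + post <= 0:
            raise ValueError(f"invalid window for {event!r}")
        return int(round(pre * rate)), int(round(post * rate))


@dataclass
class KernelFit:
    g0: float
    kernels: dict[str, np.ndarray]
    lags: dict[str, np.ndarray]          # lag times in seconds per event
    v_full: float                        # explained variance, %
    sampling_rate: float
    trimmed: bool = False
    _trace: np.ndarray | None = None
    _design: dict | None = None


# ---------------------------------------------------------------------------
# demodulation
# ---------------------------------------------------------------------------

def demodulate(trace: np.ndarray, carrier_freqs=CARRIER_FREQS, rate: float = 10_000.0,
               lowpass_hz: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature lock-in demodulation of a dual-carrier trace.

    Each carrier is mixed with a sine and cosine reference, low-pass
    filtered, and combined into an amplitude envelope scaled so that a pure
    sinusoid of amplitude A recovers an envelope of A. Returns the
    (signal-carrier, background-carrier) envelopes.
    """
    trace = np.asarray(trace, dtype=float)
    for f in carrier_freqs:
        if rate <= 2.0 * f:
            raise ValueError(f"sampling rate {rate} Hz is not above twice the "
                             f"carrier {f} Hz")
    t = np.arange(len(trace)) / rate
    sos = sps.butter(2, lowpass_hz, btype="low", fs=rate, output="sos")
    envelopes = []
    for f in carrier_freqs:
        i_comp = sps.sosfiltfilt(sos, trace * np.sin(2 * np.pi * f * t))
        q_comp = sps.sosfiltfilt(sos, trace * np.cos(2 * np.pi * f * t))
        envelopes.append(2.0 * np.hypot(i_comp, q_comp))
    return envelopes[0], envelopes[1]


# ---------------------------------------------------------------------------
# preprocessing pipeline
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, cutoff: float, rate: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _highpass_slow(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    # subtracting the complementary slow low-pass is numerically far more
    # stable than a Butterworth high-pass with Wn ~ 1e-5
    return x - _lowpass(x, cutoff, rate)


def zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    # an effectively-constant trace (e.g. pure numerical residue after
    # filtering a constant input) must not be inflated to unit variance
    if sd < 1e-12 * max(1.0, float(np.max(np.abs(x))) if len(x) else 1.0) \
            or sd < 1e-300:
        logger.warning("z-scoring a constant trace; returning zeros")
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def preprocess(session: PhotometrySession, median_width: int = 5,
               denoise_hz: float = 10.0, bleach_hz: float = 0.001,
               baseline_post_highpass: bool = False) -> ProcessedTrace:
    """Full preprocessing: denoise, de-bleach, motion-correct, dF/F, z-score.

    Order of operations: median filter and 10 Hz low-pass on both channels;
    0.001 Hz high-pass on both to remove bleaching; linear regression of the
    corrected signal channel on the corrected background channel, with the
    fitted (motion) component subtracted; division by the slow baseline (the
    0.001 Hz low-pass of the denoised, pre-high-pass signal channel by
    default); z-score. Traces shorter than the denoising filter warm-up are
    rejected.
    """
    rate = session.sampling_rate
    if len(session.signal) < max(4 * median_width, int(rate)):
        raise ValueError("trace too short for filter warm-up")

    sig = sps.medfilt(session.signal, kernel_size=median_width)
    bg = sps.medfilt(session.background, kernel_size=median_width)
    if denoise_hz < rate / 2:
        sig = _lowpass(sig, denoise_hz, rate)
        bg = _lowpass(bg, denoise_hz, rate)

    baseline_source = sig
    sig_hp = _highpass_slow(sig, bleach_hz, rate)
    bg_hp = _highpass_slow(bg, bleach_hz, rate)
    if baseline_post_highpass:
        baseline_source = sig_hp

    # motion correction: fit background to signal, remove the fitted part
    denom = float(bg_hp @ bg_hp)
    slope = float(bg_hp @ sig_hp) / denom if denom > 0 else 0.0
    corrected = sig_hp - slope * bg_hp

    baseline = _lowpass(baseline_source, bleach_hz, rate)
    tiny = 1e-12 * max(1.0, np.max(np.abs(baseline)))
    baseline = np.where(np.abs(baseline) < tiny, tiny, baseline)
    dff = corrected / baseline
    return ProcessedTrace(dff_z=zscore(dff), sampling_rate=rate)


# ---------------------------------------------------------------------------
# event-locked responses
# ---------------------------------------------------------------------------

def extract_response(trace: np.ndarray, rate: float, window: tuple[float, float],
                     method: str = "peak") -> float:
    """Scalar response in a time window.

    ``peak`` finds the largest interior local maximum, falling back to the
    window maximum when no local peak exists; ``mean`` averages the window
    (used for signals that dip, e.g. reward omissions in ventral striatum).
    """
    t0, t1 = window
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate)) + 1
    i0 = max(i0, 0)
    i1 = min(i1, len(trace))
    if i1 - i0 < 1:
        raise ValueError("empty response window")
    seg = np.asarray(trace[i0:i1], dtype=float)
    if method == "mean":
        return float(np.mean(seg))
    if method in ("peak", "max_fallback"):
        peaks, _ = sps.find_peaks(seg)
        if method == "peak" and len(peaks):
            return float(seg[peaks].max())
        return float(seg.max())
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# kernel regression
# ---------------------------------------------------------------------------

def _indicator(times: np.ndarray, n: int, rate: float) -> np.ndarray:
    x = np.zeros(n)
    idx = np.round(np.asarray(times) * rate).astype(int)   # nearest sample
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(x, idx, 1.0)
    return x


def _design_matrix(events: dict[str, np.ndarray], n: int, rate: float,
                   spec: KernelSpec) -> tuple[np.ndarray, dict[str, slice], dict[str, np.ndarray]]:
    cols, slices, lags = [], {}, {}
    start = 1   # column 0 is the intercept
    for name in events:
        if name not in spec.windows:
            continue
        n_pre, n_post = spec.n_lags(name, rate)
        ind = _indicator(events[name], n, rate)
        block = np.empty((n, n_pre + n_post + 1))
        for j, lag in enumerate(range(-n_pre, n_post + 1)):
            # event at time t contributes kernel value at lag t' to t + t'
            block[:, j] = np.roll(ind, lag) if lag != 0 else ind
            if lag > 0:
                block[:lag, j] = 0.0
            elif lag < 0:
                block[lag:, j] = 0.0
        cols.append(block)
        slices[name] = slice(start, start + block.shape[1])
        start += block.shape[1]
        lags[name] = np.arange(-n_pre, n_post + 1) / rate
    X = np.hstack([np.ones((n, 1))] + cols) if cols else np.ones((n, 1))
    return X, slices, lags


def explained_variance_pct(y: np.ndarray, pred: np.ndarray,
                           mask: np.ndarray | None = None) -> float:
    """Coefficient of determination of a prediction, as a percentage."""
    if mask is not None:
        y, pred = y[mask], pred[mask]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    ss_res = float(np.sum((y - pred) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def fit_kernels(trace: ProcessedTrace, events: dict[str, np.ndarray],
                spec: KernelSpec | None = None, trim: bool = False) -> KernelFit:
    """Ordinary least squares fit of per-event response kernels.

    The photometry signal at each sample is modelled as an intercept plus,
    for every event type, the sum of kernel weights at all lags within that
    event's window. A rank-deficient design is solved by the least-norm
    solution with a logged warning. With ``trim`` the explained variance is
    scored only on the union of event epochs.
    """
    spec = spec or KernelSpec()
    y = np.asarray(trace.dff_z, dtype=float)
    rate = trace.sampling_rate
    used = {k: v for k, v in events.items() if k in spec.windows and len(v)}
    if not used:
        raise ValueError("no usable events for kernel regression")
    X, slices, lags = _design_matrix(used, len(y), rate, spec)

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient kernel design (%d < %d); least-norm "
                       "solution used", rank, X.shape[1])
    pred = X @ coef
    mask = _event_epoch_mask(used, len(y), rate, spec) if trim else None
    v_full = explained_variance_pct(y, pred, mask)

    kernels = {name: coef[sl].copy() for name, sl in slices.items()}
    return KernelFit(g0=float(coef[0]), kernels=kernels, lags=lags,
                     v_full=v_full, sampling_rate=rate, trimmed=trim,
                     _trace=y, _design={"X": X, "slices": slices, "coef": coef,
                                        "mask": mask})


def _event_epoch_mask(events: dict[str, np.ndarray], n: int, rate: float,
                      spec: KernelSpec) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for name, times in events.items():
        pre, post = spec.windows[name]
        for t in times:
            i0 = max(int(round((t - pre) * rate)), 0)
            i1 = min(int(round((t + post) * rate)) + 1, n)
            mask[i0:i1] = True
    return mask


def partial_explained_variance(fit: KernelFit, regressor: str) -> float:
    """Percentage of the model's explained variance lost without a regressor.

    The prediction is recomputed with the named regressor's fitted
    contribution removed (no refitting), giving v_partial; the result is
    (v_full - v_partial) / v_full * 100 — near 0 for a null regressor,
    near 100 for the sole contributor, and possibly above 100 when the
    partial prediction underperforms the intercept alone. Undefined
    (returns NaN) when v_full <= 0.
    """
    if fit._design is None or fit._trace is None:
        raise ValueError("fit does not retain its design; refit with fit_kernels")
    if regressor not in fit._design["slices"]:
        raise KeyError(f"unknown regressor {regressor!r}")
    if fit.v_full <= 0:
        logger.warning("v_full <= 0; partial explained variance undefined")
        return float("nan")
    X, coef = fit._design["X"], fit._design["coef"]
    sl = fit._design["slices"][regressor]
    pred = X @ coef - X[:, sl] @ coef[sl]
    v_partial = explained_variance_pct(fit._trace, pred, fit._design["mask"])
    return (fit.v_full - v_partial) / fit.v_full * 100.0
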