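"""Raw current-trace processing: charge integration, noise modelling,
slow direct-current removal and EPSC event detection.

All currents are in pA, times in ms, charges in pC (1 pA·ms = 1e-3 pC).
The evoked synaptic charge is measured in a 200 ms window after stimulus
onset; the background noise charge is measured in an identical window at the
end of each trace, pooled over all traces of a cell into a per-cell noise
model.  The sign convention reports inward (excitatory) charge as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

from .errors import DegenerateNoiseError

RESPONSE_WINDOW_MS = 200.0
NOISE_WINDOW_MS = 200.0
BASELINE_WINDOW_MS = 50.0
#: Default median-filter window for slow direct-current removal.  A running
#: median rejects an event only when the window is several times the event's
#: total duration, so the window must be an order of magnitude longer than
#: the fast (~2-3 ms decay) EPSCs it should preserve while remaining much
#: shorter than the slow direct current it removes.  31 ms keeps the charge
#: of such events within a few percent while slow monotone drifts pass
#: through the median unchanged and are subtracted exactly.
DEFAULT_MEDIAN_WINDOW_MS = 31.0
PA_MS_TO_PC = 1e-3


@dataclass(frozen=True)
class PhotostimTrace:
    """One digitized voltage-clamp sweep for one stimulation site and trial."""

    samples: np.ndarray  # current, pA
    dt_ms: float
    stim_onset_ms: float
    site_id: int | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be > 0, got {self.dt_ms}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.duration_ms < self.stim_onset_ms + RESPONSE_WINDOW_MS + NOISE_WINDOW_MS:
            raise ValueError(
                "trace too short: need room for the response window and a "
                "terminal noise window after stimulus onset "
                f"(duration {self.duration_ms} ms, onset {self.stim_onset_ms} ms)"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms


def _window_slice(n: int, dt_ms: float, start_ms: float, len_ms: float) -> slice:
    i0 = int(round(start_ms / dt_ms))
    i1 = int(round((start_ms + len_ms) / dt_ms))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise ValueError(
            f"window [{start_ms}, {start_ms + len_ms}) ms outside trace of "
            f"{n * dt_ms} ms"
        )
    return slice(i0, i1)


def baseline_current(
    samples: np.ndarray,
    dt_ms: float,
    stim_onset_ms: float,
    baseline_window_ms: float = BASELINE_WINDOW_MS,
) -> np.ndarray:
    """Mean current over the window preceding stimulus onset.

    Returns 0 when there is no pre-stimulus sample (onset at the very start).
    The window is clipped to the available pre-stimulus samples.
    """
    samples = np.asarray(samples, dtype=float)
    i1 = int(round(stim_onset_ms / dt_ms))
    i0 = max(0, i1 - int(round(baseline_window_ms / dt_ms)))
    if i1 <= i0:
        return np.zeros(samples.shape[:-1])
    return samples[..., i0:i1].mean(axis=-1)


def integrate_charge(
    trace: PhotostimTrace | np.ndarray,
    window_start_ms: float | None = None,
    window_len_ms: float = RESPONSE_WINDOW_MS,
    *,
    dt_ms: float | None = None,
    stim_onset_ms: float | None = None,
    baseline_window_ms: float = BASELINE_WINDOW_MS,
) -> float | np.ndarray:
    """Baseline-subtracted inward charge over a window, in pC.

    The baseline is the mean current over the 50 ms preceding stimulus
    onset.  Inward (negative) current integrates to positive charge, so
    larger excitatory responses give larger positive values.

    Accepts a :class:`PhotostimTrace` or a raw array (any leading batch
    shape, samples on the last axis, requiring ``dt_ms``/``stim_onset_ms``).
    ``window_start_ms`` defaults to the stimulus onset.
    """
    if isinstance(trace, PhotostimTrace):
        samples, dt_ms, stim_onset_ms = trace.samples, trace.dt_ms, trace.stim_onset_ms
    else:
        samples = np.asarray(trace, dtype=float)
        if dt_ms is None or stim_onset_ms is None:
            raise ValueError("raw arrays require dt_ms and stim_onset_ms")
    if window_start_ms is None:
        window_start_ms = stim_onset_ms
    w = _window_slice(samples.shape[-1], dt_ms, window_start_ms, window_len_ms)
    base = baseline_current(samples, dt_ms, stim_onset_ms, baseline_window_ms)
    q = -(samples[..., w] - np.asarray(base)[..., None]).sum(axis=-1) * dt_ms * PA_MS_TO_PC
    return float(q) if np.ndim(q) == 0 else q


def noise_window_start_ms(duration_ms: float, window_len_ms: float = NOISE_WINDOW_MS) -> float:
    """Start of the terminal noise window (the last ``window_len_ms`` of the trace)."""
    return duration_ms - window_len_ms


@dataclass(frozen=True)
class NoiseModel:
    """Per-cell noise-charge distribution: mean, SD and sample count."""

    mu_q_pC: float
    sigma_q_pC: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise DegenerateNoiseError("noise model needs >= 2 noise windows")
        if not self.sigma_q_pC > 0:
            raise DegenerateNoiseError(
                "noise-charge SD is zero; Z-scores would be undefined"
            )


class NoiseChargeEstimator(BaseEstimator):
    """Estimate a cell's noise-charge distribution from its traces.

    The integrated charge of the terminal 200 ms window of every trace of
    the cell (processed exactly like the response window, including baseline
    subtraction) is pooled; the fitted attributes ``mu_q_``, ``sigma_q_``
    give the mean and standard deviation of that pooled distribution.

    Parameters
    ----------
    window_ms : float
        Length of the terminal noise window.
    baseline_window_ms : float
        Pre-stimulus baseline window used for charge integration.
    """

    def __init__(
        self,
        window_ms: float = NOISE_WINDOW_MS,
        baseline_window_ms: float = BASELINE_WINDOW_MS,
    ) -> None:
        self.window_ms = window_ms
        self.baseline_window_ms = baseline_window_ms

    def fit(
        self,
        X,
        y=None,
        *,
        dt_ms: float | None = None,
        stim_onset_ms: float | None = None,
    ):
        """Fit from a sequence of :class:`PhotostimTrace` or a 2-D array.

        Array input is ``(n_traces, n_samples)`` with shared ``dt_ms`` and
        ``stim_onset_ms``.
        """
        charges = self.noise_charges(X, dt_ms=dt_ms, stim_onset_ms=stim_onset_ms)
        if charges.size < 2:
            raise DegenerateNoiseError("need >= 2 traces to model noise")
        self.n_ = int(charges.size)
        self.mu_q_ = float(charges.mean())
        self.sigma_q_ = float(charges.std(ddof=1))
        if not self.sigma_q_ > 0:
            raise DegenerateNoiseError(
                "noise-charge SD is zero; Z-scores would be undefined"
            )
        return self

    def noise_charges(
        self,
        X,
        *,
        dt_ms: float | None = None,
        stim_onset_ms: float | None = None,
    ) -> np.ndarray:
        if isinstance(X, np.ndarray):
            if dt_ms is None or stim_onset_ms is None:
                raise ValueError("array input requires dt_ms and stim_onset_ms")
            start = noise_window_start_ms(X.shape[-1] * dt_ms, self.window_ms)
            return np.atleast_1d(
                integrate_charge(
                    X,
                    start,
                    self.window_ms,
                    dt_ms=dt_ms,
                    stim_onset_ms=stim_onset_ms,
                    baseline_window_ms=self.baseline_window_ms,
                )
            )
        return np.array(
            [
                integrate_charge(
                    tr,
                    noise_window_start_ms(tr.duration_ms, self.window_ms),
                    self.window_ms,
                    baseline_window_ms=self.baseline_window_ms,
                )
                for tr in X
            ]
        )

    def to_model(self) -> NoiseModel:
        return NoiseModel(self.mu_q_, self.sigma_q_, self.n_)


def estimate_noise(traces, *, dt_ms=None, stim_onset_ms=None) -> NoiseModel:
    """Pool the terminal noise windows of all traces of one cell."""
    est = NoiseChargeEstimator().fit(traces, dt_ms=dt_ms, stim_onset_ms=stim_onset_ms)
    return est.to_model()


def remove_direct_current(
    trace: PhotostimTrace,
    median_window_ms: float = DEFAULT_MEDIAN_WINDOW_MS,
) -> PhotostimTrace:
    """Subtract the slow direct-current component estimated by a running median.

    Direct photostimulation of the recorded cell (Golgi-cell somata or
    basolateral dendrites) produces a slow inward current that would
    contaminate the synaptic charge.  A running median with a window several
    times longer than an EPSC tracks that slow component while rejecting the
    fast synaptic events; the slow component (less its own median, so the DC
    level of the trace is untouched) is subtracted.
    """
    if median_window_ms <= 0:
        raise ValueError("median_window_ms must be > 0")
    if median_window_ms >= RESPONSE_WINDOW_MS:
        raise ValueError("median window must be shorter than the response window")
    k = max(1, int(round(median_window_ms / trace.dt_ms)) | 1)  # odd
    slow = ndimage.median_filter(trace.samples, size=k, mode="nearest")
    cleaned = trace.samples - (slow - np.median(slow))
    return replace(trace, samples=cleaned)


def epsc_template(
    dt_ms: float,
    rise_ms: float = 1.0,
    decay_ms: float = 10.0,
    length_ms: float | None = None,
) -> np.ndarray:
    """Bi-exponential EPSC waveform (positive-going, unit peak)."""
    if length_ms is None:
        length_ms = 8.0 * decay_ms
    t = np.arange(0.0, length_ms, dt_ms)
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / k.max()


def detect_events(
    trace: PhotostimTrace,
    rise_ms: float = 1.0,
    decay_ms: float = 10.0,
    threshold_factor: float = 5.0,
    min_separation_ms: float | None = None,
) -> pd.DataFrame:
    """Detect inward EPSC onsets by matched filtering.

    The median-subtracted trace is correlated with a unit-norm bi-exponential
    template of inward polarity; peaks of the filtered signal exceeding
    ``threshold_factor`` times its robust (MAD-based) noise scale are
    reported.  Returns a DataFrame with strictly increasing ``time_ms`` and
    ``amplitude_pA`` (peak inward amplitude, positive).
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be > 0")
    x = trace.samples - np.median(trace.samples)
    tmpl = -epsc_template(trace.dt_ms, rise_ms, decay_ms)
    tmpl = tmpl / np.linalg.norm(tmpl)
    if tmpl.size > x.size:
        raise ValueError("template longer than trace")
    # y[i] = <x[i:i+L], tmpl>: maximal where an inward event starts at i
    y = signal.fftconvolve(x, tmpl[::-1], mode="valid")
    mad = np.median(np.abs(y - np.median(y)))
    sigma = 1.4826 * mad
    if sigma == 0:
        return pd.DataFrame({"time_ms": [], "amplitude_pA": []})
    if min_separation_ms is None:
        min_separation_ms = decay_ms
    distance = max(1, int(round(min_separation_ms / trace.dt_ms)))
    peaks, _ = signal.find_peaks(y, height=threshold_factor * sigma, distance=distance)
    span = tmpl.size
    amps = np.array([-(x[p : p + span].min()) for p in peaks])
    return pd.DataFrame({"time_ms": peaks * trace.dt_ms, "amplitude_pA": amps})


def count_events_in_window(
    events: pd.DataFrame, start_ms: float, len_ms: float
) -> int:
    """Number of detected events with onsets inside [start, start + len)."""
    t = events["time_ms"].to_numpy()
    return int(((t >= start_ms) & (t < start_ms + len_ms)).sum())
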