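"""Per-site Z-score connectivity maps and 1-D mediolateral input patterns.

For each stimulation site the mean evoked charge over repeats is compared to
the cell's pooled noise-charge model:

    Z_site = (mean charge at the site - mean noise charge) / noise-charge SD

Sites with Z above 3.09 (the one-sided normal quantile at p = 0.001) are
significant; a mediolateral position is silent when no depth row at that
position is significant.  The per-position maximum Z over depth rows,
placed at absolute midline coordinates, interpolated to a 1 µm support and
convolved with a unit-mass triangular kernel (half-width 18 µm), forms the
cell's mediolateral input pattern used by the population analyses.

For molecular-layer interneurons, whose responses are better captured by
counting EPSCs than by charge, an event-count Z-score compares the number
of detected events in the response window to a distant control window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateNoiseError
from .geometry import Z_THRESHOLD, GridGeometry
from .synth import CellRecording
from .traces import (
    BASELINE_WINDOW_MS,
    RESPONSE_WINDOW_MS,
    NoiseChargeEstimator,
    NoiseModel,
    PhotostimTrace,
    count_events_in_window,
    detect_events,
    integrate_charge,
    remove_direct_current,
)

KERNEL_HALFWIDTH_UM = 18.0


def site_zscore(mean_charge_pC, noise: NoiseModel):
    """Z-score of a site's mean charge against the cell's noise model."""
    if not noise.sigma_q_pC > 0:
        raise DegenerateNoiseError("noise sigma is zero")
    return (np.asarray(mean_charge_pC) - noise.mu_q_pC) / noise.sigma_q_pC


def count_zscore(response_counts, control_counts) -> float:
    """Event-count Z-score: response-window counts against control counts."""
    response_counts = np.asarray(response_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    if response_counts.size < 2 or control_counts.size < 2:
        raise ValueError("need >= 2 trials for the count Z-score")
    sd = control_counts.std(ddof=1)
    if not sd > 0:
        raise DegenerateNoiseError("control counts have zero SD")
    return float((response_counts.mean() - control_counts.mean()) / sd)


@dataclass
class ConnectivityMap:
    """Per-site mean charges and Z-scores for one cell on its grid."""

    sites: pd.DataFrame  # depth_row, ml_um (ordered by depth, position)
    mean_charge_pC: np.ndarray
    z: np.ndarray
    noise: NoiseModel
    geometry: GridGeometry | None = None
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.mean_charge_pC = np.asarray(self.mean_charge_pC, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.sites) == self.mean_charge_pC.size == self.z.size):
            raise ValueError("sites, charges and z must align")

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        out["mean_charge_pC"] = self.mean_charge_pC
        out["z"] = self.z
        return out


def classify_sites(cmap: ConnectivityMap, threshold: float = Z_THRESHOLD) -> np.ndarray:
    """Label each site 'significant' (Z strictly above threshold) or 'silent'."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return np.where(cmap.z > threshold, "significant", "silent")


def silent_positions(cmap: ConnectivityMap, threshold: float = Z_THRESHOLD) -> pd.Series:
    """Per mediolateral position: True when no depth row is significant."""
    df = cmap.to_frame()
    return df.groupby("ml_um")["z"].max() <= threshold


def max_project(cmap: ConnectivityMap) -> tuple[np.ndarray, np.ndarray]:
    """Maximal Z over depth rows at each mediolateral position.

    Returns (positions_um ascending, max Z).  Depth rows are pooled because
    mossy fibres project through the entire depth of the granule-cell
    layer, so the strongest response at a position indexes the connectivity
    strength there.
    """
    df = cmap.to_frame()
    proj = df.groupby("ml_um")["z"].max()
    return proj.index.to_numpy(dtype=float), proj.to_numpy()


@dataclass
class MediolateralPattern:
    """Smoothed per-position Z profile on a regular 1 µm support."""

    positions_um: np.ndarray  # strictly increasing, 1 µm spacing
    values: np.ndarray
    cell_id: str | None = None
    soma_position_um: float | None = None
    kernel_halfwidth_um: float = KERNEL_HALFWIDTH_UM

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_um.size != self.values.size:
            raise ValueError("positions and values must align")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")

    def resample(self, positions_um: np.ndarray) -> np.ndarray:
        return np.interp(positions_um, self.positions_um, self.values)


def triangular_kernel(halfwidth_um: float, step_um: float = 1.0) -> np.ndarray:
    """Unit-mass triangular kernel with the given half-width (half base)."""
    m = int(np.floor(halfwidth_um / step_um))
    x = np.arange(-m, m + 1) * step_um
    k = np.clip(1.0 - np.abs(x) / halfwidth_um, 0.0, None)
    return k / k.sum()


def to_pattern(
    positions_um: np.ndarray,
    values: np.ndarray,
    kernel_halfwidth_um: float = KERNEL_HALFWIDTH_UM,
    *,
    cell_id: str | None = None,
    soma_position_um: float | None = None,
) -> MediolateralPattern:
    """Interpolate site values to a 1 µm support and smooth triangularly.

    Site values sit at their absolute midline-relative coordinates, are
    linearly interpolated onto a 1 µm grid and convolved with a unit-mass
    triangular kernel.  Near the edges the kernel is renormalised over its
    in-range support, so edge values are unbiased rather than damped.
    """
    if kernel_halfwidth_um <= 0:
        raise ValueError("kernel_halfwidth_um must be > 0")
    positions_um = np.asarray(positions_um, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(positions_um)
    positions_um, values = positions_um[order], values[order]
    support = np.arange(np.ceil(positions_um[0]), np.floor(positions_um[-1]) + 1.0)
    dense = np.interp(support, positions_um, values)
    k = triangular_kernel(kernel_halfwidth_um)
    smooth = np.convolve(dense, k, mode="same")
    coverage = np.convolve(np.ones_like(dense), k, mode="same")
    return MediolateralPattern(
        positions_um=support,
        values=smooth / coverage,
        cell_id=cell_id,
        soma_position_um=soma_position_um,
        kernel_halfwidth_um=kernel_halfwidth_um,
    )


class ConnectivityMapper(BaseEstimator):
    """Estimator turning one cell's raw traces into a Z-score map and pattern.

    ``fit`` takes a :class:`~gcmap.synth.CellRecording` (traces per site and
    repeat plus grid metadata), integrates the response-window charge of
    every sweep, pools the terminal noise windows of all sweeps into the
    cell's noise model, and derives per-site Z-scores, significance labels,
    the depth-max projection and the smoothed mediolateral pattern.

    Parameters
    ----------
    threshold : float
        Significance threshold on Z (strict inequality).
    kernel_halfwidth_um : float
        Half-width of the triangular smoothing kernel.
    remove_direct : bool
        Median-filter each sweep first to remove slow direct currents
        (Golgi-cell recordings).
    median_window_ms : float or None
        Window for the direct-current median filter (None = module default).
    baseline_window_ms : float
        Pre-stimulus baseline window for charge integration.
    """

    def __init__(
        self,
        threshold: float = Z_THRESHOLD,
        kernel_halfwidth_um: float = KERNEL_HALFWIDTH_UM,
        remove_direct: bool = False,
        median_window_ms: float | None = None,
        baseline_window_ms: float = BASELINE_WINDOW_MS,
    ) -> None:
        self.threshold = threshold
        self.kernel_halfwidth_um = kernel_halfwidth_um
        self.remove_direct = remove_direct
        self.median_window_ms = median_window_ms
        self.baseline_window_ms = baseline_window_ms

    def fit(self, X: CellRecording, y=None):
        samples = X.samples
        if self.remove_direct:
            from .traces import DEFAULT_MEDIAN_WINDOW_MS

            win = self.median_window_ms or DEFAULT_MEDIAN_WINDOW_MS
            flat = samples.reshape(-1, samples.shape[-1])
            cleaned = np.stack(
                [
                    remove_direct_current(
                        PhotostimTrace(tr, X.dt_ms, X.stim_onset_ms), win
                    ).samples
                    for tr in flat
                ]
            )
            samples = cleaned.reshape(samples.shape)
        charges = integrate_charge(
            samples,
            X.stim_onset_ms,
            dt_ms=X.dt_ms,
            stim_onset_ms=X.stim_onset_ms,
            baseline_window_ms=self.baseline_window_ms,
        )  # (n_sites, n_repeats)
        noise_est = NoiseChargeEstimator(baseline_window_ms=self.baseline_window_ms)
        noise_est.fit(
            samples.reshape(-1, samples.shape[-1]),
            dt_ms=X.dt_ms,
            stim_onset_ms=X.stim_onset_ms,
        )
        self.noise_model_ = noise_est.to_model()
        self.mean_charge_ = charges.mean(axis=1)
        self.z_ = site_zscore(self.mean_charge_, self.noise_model_)
        self.map_ = ConnectivityMap(
            sites=X.sites,
            mean_charge_pC=self.mean_charge_,
            z=self.z_,
            noise=self.noise_model_,
            geometry=X.geometry,
            cell_id=X.cell_id,
        )
        self.labels_ = classify_sites(self.map_, self.threshold)
        pos, zmax = max_project(self.map_)
        self.pattern_ = to_pattern(
            pos,
            zmax,
            self.kernel_halfwidth_um,
            cell_id=X.cell_id,
            soma_position_um=X.soma_position_um,
        )
        return self

    def fit_map(self, X: CellRecording) -> ConnectivityMap:
        return self.fit(X).map_


def map_cell(recording: CellRecording, **params) -> ConnectivityMap:
    """Build the Z-score connectivity map of one cell (thin wrapper)."""
    return ConnectivityMapper(**params).fit_map(recording)


def cell_pattern(recording: CellRecording, **params) -> MediolateralPattern:
    """Build the smoothed mediolateral input pattern of one cell."""
    return ConnectivityMapper(**params).fit(recording).pattern_


def event_count_map(
    recording: CellRecording,
    control_window_start_ms: float | None = None,
    threshold_factor: float = 5.0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Per-site event-count Z-scores for interneuron-style analysis.

    Events are detected per sweep; the response-window count is compared to
    the count in a distant control window of equal length (default: the
    terminal noise window).
    """
    from .traces import noise_window_start_ms

    duration = recording.samples.shape[-1] * recording.dt_ms
    if control_window_start_ms is None:
        control_window_start_ms = noise_window_start_ms(duration)
    rows = []
    for s in range(recording.n_sites):
        resp, ctrl = [], []
        for r in range(recording.n_repeats):
            tr = PhotostimTrace(
                recording.samples[s, r], recording.dt_ms, recording.stim_onset_ms
            )
            ev = detect_events(tr, threshold_factor=threshold_factor, **detect_kwargs)
            resp.append(
                count_events_in_window(ev, recording.stim_onset_ms, RESPONSE_WINDOW_MS)
            )
            ctrl.append(
                count_events_in_window(ev, control_window_start_ms, RESPONSE_WINDOW_MS)
            )
        try:
            z = count_zscore(resp, ctrl)
        except (DegenerateNoiseError, ValueError):
            z = np.nan
        rows.append({"site_id": s, "n_resp": np.mean(resp), "n_ctrl": np.mean(ctrl), "z": z})
    return pd.DataFrame(rows)
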