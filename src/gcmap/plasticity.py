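"""Site-by-site comparison of pre- and post-induction connectivity maps.

A plasticity-induction protocol (e.g. 1 Hz parallel-fibre stimulation) can
potentiate, depress or awaken individual granule-cell sites.  The change at
each site is the difference of Z-scores, ΔZ = Z_post − Z_pre, computed with
a single per-cell noise model shared by both maps so that ΔZ reflects a
change in response rather than in noise estimation.  Sites with ΔZ above
3.09 are potentiated (awakened when also silent before induction), below
−3.09 depressed, otherwise unchanged; regressing ΔZ on the initial Z
summarises the weight dependence of plasticity (strong sites depressing,
weak sites potentiating, gives a negative slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .geometry import Z_THRESHOLD
from .mapping import ConnectivityMap

CLASSES = ("potentiated", "depressed", "awakened", "unchanged")


def delta_map(pre: ConnectivityMap, post: ConnectivityMap) -> np.ndarray:
    """Per-site ΔZ = Z_post − Z_pre over identical site sets."""
    same_sites = (
        len(pre.sites) == len(post.sites)
        and (pre.sites["ml_um"].to_numpy() == post.sites["ml_um"].to_numpy()).all()
        and (pre.sites["depth_row"].to_numpy() == post.sites["depth_row"].to_numpy()).all()
    )
    if not same_sites:
        raise ValueError("pre and post maps must share geometry and site set")
    return post.z - pre.z


def classify_changes(
    delta_z: np.ndarray,
    pre_silent: np.ndarray,
    threshold: float = Z_THRESHOLD,
) -> np.ndarray:
    """Classify each site's change: potentiated / depressed / awakened / unchanged.

    ``pre_silent`` is the per-site boolean silence mask of the initial map.
    Awakened = potentiated and silent before induction (reported as its own
    class; it refines the potentiated class in counts).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    delta_z = np.asarray(delta_z, dtype=float)
    pre_silent = np.asarray(pre_silent, dtype=bool)
    out = np.full(delta_z.shape, "unchanged", dtype=object)
    out[delta_z > threshold] = "potentiated"
    out[(delta_z > threshold) & pre_silent] = "awakened"
    out[delta_z < -threshold] = "depressed"
    return out.astype(str)


def delta_vs_initial(delta_z: np.ndarray, initial_z: np.ndarray) -> tuple[float, float]:
    """OLS slope and Pearson r of ΔZ against the initial Z."""
    delta_z = np.asarray(delta_z, dtype=float)
    initial_z = np.asarray(initial_z, dtype=float)
    if delta_z.size < 3:
        raise ValueError("need >= 3 sites for the regression")
    if initial_z.std() == 0:
        raise ValueError("initial Z has zero variance; regression undefined")
    res = stats.linregress(initial_z, delta_z)
    return float(res.slope), float(res.rvalue)


@dataclass
class PlasticityResult:
    """Per-site ΔZ, change classes and the ΔZ-vs-initial-Z regression."""

    sites: pd.DataFrame
    z_pre: np.ndarray
    z_post: np.ndarray
    delta_z: np.ndarray
    classes: np.ndarray
    slope: float
    r: float
    threshold: float = Z_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        out["z_pre"] = self.z_pre
        out["z_post"] = self.z_post
        out["delta_z"] = self.delta_z
        out["class"] = self.classes
        return out

    def counts(self) -> dict:
        c = {k: int((self.classes == k).sum()) for k in CLASSES}
        c["potentiated_total"] = c["potentiated"] + c["awakened"]
        c["changed_fraction"] = (
            c["potentiated_total"] + c["depressed"]
        ) / self.classes.size
        return c


class PlasticityClassifier(BaseEstimator):
    """Estimator comparing a pre and a post connectivity map site by site.

    ``fit(pre, post)`` computes ΔZ, the change classes (using the pre map's
    silence labels) and the ΔZ-vs-initial-Z regression; both maps are
    expected to share the cell's noise model.
    """

    def __init__(self, threshold: float = Z_THRESHOLD) -> None:
        self.threshold = threshold

    def fit(self, pre: ConnectivityMap, post: ConnectivityMap):
        self.delta_z_ = delta_map(pre, post)
        pre_silent = pre.z <= self.threshold
        self.classes_ = classify_changes(self.delta_z_, pre_silent, self.threshold)
        try:
            self.slope_, self.r_ = delta_vs_initial(self.delta_z_, pre.z)
        except ValueError:
            self.slope_ = self.r_ = float("nan")
        self.result_ = PlasticityResult(
            sites=pre.sites,
            z_pre=pre.z,
            z_post=post.z,
            delta_z=self.delta_z_,
            classes=self.classes_,
            slope=self.slope_,
            r=self.r_,
            threshold=self.threshold,
        )
        return self


def compare_maps(
    pre: ConnectivityMap, post: ConnectivityMap, threshold: float = Z_THRESHOLD
) -> PlasticityResult:
    """Classify plastic changes between two maps (thin wrapper)."""
    return PlasticityClassifier(threshold=threshold).fit(pre, post).result_
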