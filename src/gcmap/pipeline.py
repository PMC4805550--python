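"""End-to-end orchestration: simulate -> map -> correlate -> cluster.

``run_pipeline`` follows the analysis order of the mapping experiment:
per-sweep charge integration, per-cell noise model and Z-scores, depth-max
projection and triangular smoothing, sliding-window median groups, the
Pearson correlation matrix between group patterns, and spectral
co-clustering.  Every product lands in an :class:`~gcmap.io.ExperimentBundle`
whose provenance records the config hash and root seed; identical
(config, seed) reruns are deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Z_THRESHOLD
from .io import ExperimentBundle, config_hash, load_config
from .mapping import ConnectivityMapper
from .population import (
    CorrelationBiclustering,
    correlation_matrix,
    median_patterns,
    shuffle_null,
)
from .synth import NoiseSpec, make_independent_population, make_population

log = logging.getLogger("gcmap")


def simulate_bundle(config: dict | None = None, seed: int = 0) -> ExperimentBundle:
    """Generate a synthetic population bundle from a config."""
    config = config or load_config()
    noise = NoiseSpec(**config["noise"])
    pop_cfg = config["population"]
    n_depth = int(config["geometry"]["n_depth_rows"])
    if pop_cfg.get("kind", "archetypes") == "independent":
        cells = make_independent_population(
            int(pop_cfg["n_cells"]),
            seed,
            noise=noise,
            n_repeats=int(pop_cfg["n_repeats"]),
            n_depth_rows=n_depth,
        )
    else:
        cells = make_population(
            int(pop_cfg["n_cells"]),
            seed,
            noise=noise,
            n_repeats=int(pop_cfg["n_repeats"]),
            n_depth_rows=n_depth,
        )
    log.info("simulated %d cells (%d sites each)", len(cells), cells[0].n_sites)
    bundle = ExperimentBundle(
        cells={c.cell_id: c for c in cells},
        provenance={
            "config_hash": config_hash(config),
            "seed": int(seed),
            "tool_version": __version__,
        },
    )
    return bundle


def analyze_bundle(bundle: ExperimentBundle, config: dict | None = None) -> ExperimentBundle:
    """Run mapping, grouping, correlation and clustering on a bundle in place."""
    config = config or load_config()
    ana = config["analysis"]
    mapper_params = dict(
        threshold=float(ana["threshold"]),
        kernel_halfwidth_um=float(ana["kernel_halfwidth_um"]),
    )
    site_rows, patterns, positions = [], [], []
    for cid, rec in sorted(bundle.cells.items()):
        m = ConnectivityMapper(**mapper_params).fit(rec)
        df = m.map_.to_frame()
        df.insert(0, "cell_id", cid)
        df["label"] = m.labels_
        site_rows.append(df)
        patterns.append(m.pattern_)
        positions.append(rec.soma_position_um)
    site_table = pd.concat(site_rows, ignore_index=True)
    n_sig = int((site_table["label"] == "significant").sum())
    log.info(
        "mapped %d cells: %d/%d significant sites",
        bundle.n_cells,
        n_sig,
        len(site_table),
    )
    bundle.derived["sites"] = site_table

    pattern_rows = []
    for p in patterns:
        pattern_rows.append(
            pd.DataFrame(
                {"cell_id": p.cell_id, "position_um": p.positions_um, "z": p.values}
            )
        )
    bundle.derived["patterns"] = pd.concat(pattern_rows, ignore_index=True)

    groups = median_patterns(
        patterns,
        positions_um=np.asarray(positions, dtype=float),
        window_um=float(ana["group_window_um"]),
        shift_um=float(ana["group_shift_um"]),
    )
    log.info("built %d median-pattern groups", len(groups))
    bundle.derived["groups"] = pd.DataFrame(
        {
            "center_um": [g.center_um for g in groups],
            "n_members": [g.n_members for g in groups],
        }
    )
    R = correlation_matrix(groups, step_um=float(ana["correlation_step_um"]))
    bundle.derived["correlation"] = R.to_long_frame()

    clust = CorrelationBiclustering(n_clusters=ana["n_clusters"]).fit(R)
    assign = clust.assignment()
    log.info(
        "co-clustered %d groups into %d clusters (contiguous: %s)",
        len(groups),
        assign.n_clusters,
        assign.all_contiguous,
    )
    bundle.derived["clusters"] = pd.DataFrame(
        {
            "center_um": R.centers_um,
            "cluster": assign.labels,
            "contiguous": [assign.contiguous[int(k)] for k in assign.labels],
        }
    )
    bundle.provenance["n_significant_sites"] = n_sig
    bundle.provenance["n_groups"] = len(groups)
    bundle.provenance["n_clusters"] = int(assign.n_clusters)
    return bundle


def run_pipeline(
    config: dict | None = None, seed: int = 0
) -> ExperimentBundle:
    """Simulate a synthetic experiment and run the full analysis on it."""
    config = config or load_config()
    bundle = simulate_bundle(config, seed)
    return analyze_bundle(bundle, config)


# ---------------------------------------------------------------------------
# Calibration summaries used by the acceptance checks
# ---------------------------------------------------------------------------


def null_significant_fraction(
    n_sites: int = 100_000,
    seed: int = 0,
    threshold: float = Z_THRESHOLD,
    noise: NoiseSpec | None = None,
    batch_size: int = 2000,
) -> dict:
    """Fraction of noise-only single-trial sites called significant.

    Runs the charge -> noise-model -> Z pipeline on ``n_sites`` pure-noise
    sweeps (one trial each): the response-window charges of all sites are
    Z-scored against the noise model pooled from all terminal noise windows,
    and the fraction with Z above the threshold is returned with a 95%
    binomial (normal-approximation) confidence interval.  For a calibrated
    threshold of 3.09 the expected fraction is 0.001.
    """
    from .synth import synthesize_noise_charges
    from .traces import NoiseModel

    noise = noise or NoiseSpec()
    resp, ctrl = [], []
    for q_resp, q_noise in synthesize_noise_charges(n_sites, noise, seed, batch_size):
        resp.append(q_resp)
        ctrl.append(q_noise)
    resp = np.concatenate(resp)
    ctrl = np.concatenate(ctrl)
    model = NoiseModel(float(ctrl.mean()), float(ctrl.std(ddof=1)), ctrl.size)
    z = (resp - model.mu_q_pC) / model.sigma_q_pC
    frac = float((z > threshold).mean())
    se = float(np.sqrt(max(frac, 1e-12) * (1 - frac) / n_sites))
    return {
        "fraction": frac,
        "n_sites": int(n_sites),
        "ci95": (frac - 1.96 * se, frac + 1.96 * se),
        "n_noise_windows": int(ctrl.size),
    }


def shuffled_pair_summary(
    n_cells: int = 48,
    n_pairs: int = 600,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    n_repeats: int = 2,
    n_populations: int = 3,
) -> dict:
    """Mean shuffled-pair pattern correlation on independent populations.

    Generates cells with independently placed hotspots, builds their
    smoothed patterns through the full pipeline, and averages the Pearson r
    of random non-self, non-neighbour pairings.  Independence makes the
    expected mean zero.  Because pairings that share a cell are correlated,
    the Monte-Carlo error of the mean is limited by the number of cells,
    not pairs; pooling pairs over several independently generated
    populations tightens it.
    """
    rs_all = []
    for k in range(n_populations):
        pop_seed = seed + 1_000_003 * k
        cells = make_independent_population(
            n_cells, pop_seed, noise=noise, n_repeats=n_repeats
        )
        patterns = [ConnectivityMapper().fit(c).pattern_ for c in cells]
        rs_all.append(shuffle_null(patterns, n_pairs, pop_seed + 1))
    rs = np.concatenate(rs_all)
    return {
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "n_pairs": int(rs.size),
        "n_cells": int(n_cells * n_populations),
    }
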