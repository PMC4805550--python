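"""Synthetic uncaging experiments with known ground truth.

Emulates the statistical structure of the photostimulation mapping
experiment so that every analysis stage can be tested by parameter
recovery:

* a mediolateral x depth stimulation grid (default 332 µm on each side of
  the recorded cell, 41.5 µm step, 2-5 depth rows);
* connected sites carrying compound inward EPSC trains built from unitary
  connections of ~0.1 pC firing bursts of ~19.6 events, so the expected
  response-window charge of a site is ``count * q_u * burst``;
* spatial hotspots whose connection counts fall off with a Gaussian
  photostimulation-spread profile (half-width at half-maximum 45 µm,
  between the direct-spot and whole-cell spread estimates);
* white Gaussian current noise, silent sites, optional slow direct-current
  artifacts, and plasticity-modified post maps.

Mossy fibres project through the entire depth of the granule-cell layer, so
a hotspot drives every depth row at its mediolateral position equally.

All randomness derives from a single root seed split hierarchically
(cell -> site -> repeat) with :class:`numpy.random.SeedSequence`, so adding
cells to a population never perturbs the traces of existing ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError
from .geometry import GridGeometry, make_grid
from .traces import NOISE_WINDOW_MS, RESPONSE_WINDOW_MS, PA_MS_TO_PC, epsc_template

#: Unitary charge of one granule-cell connection, pC.
UNITARY_CHARGE_PC = 0.1
#: Mean / SD of the number of evoked action potentials per connection.
BURST_SIZE_MEAN = 19.6
BURST_SIZE_SD = 6.6
#: Gaussian half-width at half-maximum of the photostimulation spread, µm.
ACTIVATION_HWHM_UM = 45.0
#: Lower bound on hotspot half-widths: the direct-spot spread estimate, µm.
MIN_HOTSPOT_HALFWIDTH_UM = 33.0
#: Events are spread uniformly over this initial span of the response window.
BURST_SPAN_MS = 100.0


@dataclass(frozen=True)
class NoiseSpec:
    """Recording-noise and timing parameters of a synthetic sweep."""

    current_sd_pA: float = 10.0
    duration_ms: float = 1000.0
    sampling_khz: float = 10.0
    stim_onset_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.current_sd_pA < 0:
            raise ValueError("current_sd_pA must be >= 0")
        if self.sampling_khz <= 0:
            raise ValueError("sampling_khz must be > 0")
        if self.duration_ms < self.stim_onset_ms + RESPONSE_WINDOW_MS + NOISE_WINDOW_MS:
            raise ValueError(
                "duration must cover stimulus onset + 200 ms response window "
                "+ 200 ms terminal noise window"
            )

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sampling_khz))


@dataclass(frozen=True)
class Hotspot:
    """A patch of connected granule cells.

    ``strength`` is the connection count at the hotspot centre; counts at
    neighbouring sites scale with a Gaussian profile of the given
    half-width at half-maximum.
    """

    center_um: float
    strength: float
    halfwidth_um: float = ACTIVATION_HWHM_UM

    def __post_init__(self) -> None:
        if self.halfwidth_um < MIN_HOTSPOT_HALFWIDTH_UM:
            raise ValueError(
                f"hotspot half-width {self.halfwidth_um} µm below the "
                f"photostimulation spread lower bound "
                f"({MIN_HOTSPOT_HALFWIDTH_UM} µm)"
            )
        if self.strength < 0:
            raise ValueError("hotspot strength must be >= 0")


@dataclass
class GroundTruthMap:
    """Per-site connectivity ground truth aligned with a grid's site table."""

    counts: np.ndarray  # connection count per site, int
    q_u_pC: float = UNITARY_CHARGE_PC
    burst_size: np.ndarray | float = BURST_SIZE_MEAN  # events per connection
    hotspots: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("connection counts must be nonnegative")
        self.burst_size = np.broadcast_to(
            np.asarray(self.burst_size, dtype=float), self.counts.shape
        ).copy()
        if (self.burst_size < 0).any():
            raise ValueError("burst sizes must be nonnegative")

    @property
    def expected_charge_pC(self) -> np.ndarray:
        """Expected response-window charge per site: count * q_u * burst.

        Events are discrete, so the rendered train carries
        ``round(count * burst)`` events of ``q_u`` each.
        """
        return np.round(self.counts * self.burst_size) * self.q_u_pC

    def to_frame(self, sites: pd.DataFrame) -> pd.DataFrame:
        out = sites.copy()
        out["count"] = self.counts
        out["burst_size"] = self.burst_size
        out["expected_charge_pC"] = self.expected_charge_pC
        return out


def gaussian_profile(distance_um: np.ndarray, hwhm_um: float) -> np.ndarray:
    """Gaussian activation profile with half-width at half-maximum ``hwhm_um``."""
    return np.exp(-np.log(2.0) * (np.asarray(distance_um) / hwhm_um) ** 2)


def ground_truth_from_hotspots(
    geometry: GridGeometry,
    hotspots: list[Hotspot] | tuple,
    q_u_pC: float = UNITARY_CHARGE_PC,
    burst_size: float | np.ndarray = BURST_SIZE_MEAN,
) -> GroundTruthMap:
    """Build per-site connection counts from hotspot descriptors.

    The count at each site is the rounded sum over hotspots of
    ``strength * exp(-ln2 (d / hwhm)^2)`` with ``d`` the mediolateral
    distance from the hotspot centre; identical at every depth row.
    """
    sites = make_grid(geometry)
    ml = sites["ml_um"].to_numpy()
    strength = np.zeros(len(sites))
    for h in hotspots:
        strength += h.strength * gaussian_profile(ml - h.center_um, h.halfwidth_um)
    return GroundTruthMap(
        counts=np.round(strength).astype(int),
        q_u_pC=q_u_pC,
        burst_size=burst_size,
        hotspots=tuple(hotspots),
    )


@dataclass
class CellRecording:
    """Traces and metadata for one synthetic (or loaded) cell.

    ``samples`` has shape (n_sites, n_repeats, n_samples) in pA, site order
    matching ``sites`` (ordered by depth row, then mediolateral position).
    """

    cell_id: str
    samples: np.ndarray
    dt_ms: float
    stim_onset_ms: float
    sites: pd.DataFrame
    geometry: GridGeometry | None = None
    truth: GroundTruthMap | None = None
    cell_type: str = "PC"
    band: str | None = None
    soma_position_um: float | None = None
    archetype_id: int | None = None

    @property
    def n_sites(self) -> int:
        return self.samples.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.samples.shape[1]


def _cell_seed_sequence(seed: int, cell_index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,))


def _render_site_trace(
    rng: np.random.Generator,
    count: int,
    burst: float,
    q_u_pC: float,
    noise: NoiseSpec,
    kernel: np.ndarray,
    direct_current_pA: float = 0.0,
) -> np.ndarray:
    n = noise.n_samples
    dt = noise.dt_ms
    x = (
        rng.normal(0.0, noise.current_sd_pA, n)
        if noise.current_sd_pA > 0
        else np.zeros(n)
    )
    n_events = int(round(count * burst))
    if n_events > 0:
        onsets_ms = noise.stim_onset_ms + rng.uniform(0.0, BURST_SPAN_MS, n_events)
        idx = np.round(onsets_ms / dt).astype(int)
        for i in idx:
            stop = min(n, i + kernel.size)
            x[i:stop] += kernel[: stop - i]
    if direct_current_pA:
        # slow direct-stimulation artifact: smooth inward transient spanning
        # several hundred ms after onset (Golgi-cell case)
        t = np.arange(n) * dt - noise.stim_onset_ms
        tau_rise, tau_decay = 50.0, 400.0
        env = np.where(t > 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
        env /= env.max()
        x += -direct_current_pA * env
    return x


def synthesize_cell(
    truth: GroundTruthMap,
    geometry: GridGeometry,
    noise: NoiseSpec,
    n_repeats: int = 1,
    seed: int | np.random.SeedSequence | None = None,
    *,
    cell_id: str = "cell0",
    cell_type: str = "PC",
    direct_current_pA: float = 0.0,
    archetype_id: int | None = None,
) -> CellRecording:
    """Render one cell's traces from its ground-truth map.

    Each connected site receives ``round(count * burst)`` inward EPSC events
    of charge ``q_u`` at times uniform over the first 100 ms of the response
    window, on top of white Gaussian current noise; unconnected sites are
    noise only.  The expected response-window charge of a site is therefore
    ``count * q_u * burst``.  A seed is mandatory: identical seeds reproduce
    identical traces, and each (site, repeat) draws from its own
    hierarchically split stream.
    """
    if seed is None:
        raise ValueError("seed is required: synthesize_cell must be deterministic")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    sites = make_grid(geometry)
    if truth.counts.shape[0] != len(sites):
        raise InvalidGeometryError(
            f"ground truth has {truth.counts.shape[0]} sites, "
            f"grid has {len(sites)}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(sites) * n_repeats)
    # inward event kernel scaled so its discrete charge is exactly q_u
    kern = epsc_template(noise.dt_ms)
    kern = -kern * (truth.q_u_pC / (kern.sum() * noise.dt_ms * PA_MS_TO_PC))
    samples = np.empty((len(sites), n_repeats, noise.n_samples))
    for s in range(len(sites)):
        for r in range(n_repeats):
            rng = np.random.default_rng(children[s * n_repeats + r])
            samples[s, r] = _render_site_trace(
                rng,
                int(truth.counts[s]),
                float(truth.burst_size[s]),
                truth.q_u_pC,
                noise,
                kern,
                direct_current_pA=direct_current_pA,
            )
    return CellRecording(
        cell_id=cell_id,
        samples=samples,
        dt_ms=noise.dt_ms,
        stim_onset_ms=noise.stim_onset_ms,
        sites=sites,
        geometry=geometry,
        truth=truth,
        cell_type=cell_type,
        soma_position_um=geometry.midline_offset_um,
        archetype_id=archetype_id,
    )


def apply_plasticity(
    truth: GroundTruthMap,
    rule=None,
    awaken_sites: list[int] | tuple = (),
    awaken_count: int = 10,
) -> GroundTruthMap:
    """Derive a post-induction ground truth from a pre-induction one.

    ``rule`` maps the initial per-site strength (expected charge, pC) to a
    multiplicative change applied to the site's burst size, so expected
    charges scale exactly by the multiplier.  Sites listed in
    ``awaken_sites`` have their connection count raised from 0 to
    ``awaken_count``; an awaken site that is already connected triggers a
    warning and follows the rule instead.
    """
    counts = truth.counts.copy()
    burst = np.asarray(truth.burst_size, dtype=float).copy()
    if rule is not None:
        mult = np.array([float(rule(q)) for q in truth.expected_charge_pC])
        if (mult < 0).any():
            raise ValueError("plasticity multipliers must be >= 0")
        burst *= mult
    for s in awaken_sites:
        if truth.counts[s] > 0:
            warnings.warn(
                f"awaken site {s} is already connected; applying the rule instead",
                stacklevel=2,
            )
            continue
        counts[s] = awaken_count
        burst[s] = BURST_SIZE_MEAN if np.isnan(burst[s]) or burst[s] == 0 else burst[s]
    return GroundTruthMap(
        counts=counts, q_u_pC=truth.q_u_pC, burst_size=burst, hotspots=truth.hotspots
    )


# ---------------------------------------------------------------------------
# Population generation: per-cluster connectivity archetypes with jitter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeSet:
    """Cross-animal connectivity archetypes with per-cell jitter.

    Each archetype is a template list of hotspots (absolute midline
    coordinates) shared by all cells whose soma falls in its mediolateral
    span.  Individual cells jitter hotspot centres (Gaussian SD
    ``center_jitter_sd_um``) and strengths (lognormal-free fractional SD
    ``strength_jitter_sd``).
    """

    templates: tuple  # tuple of tuples of Hotspot
    spans: tuple  # (lo_um, hi_um) soma range per archetype
    center_jitter_sd_um: float = 8.0
    strength_jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.spans):
            raise ValueError("one soma span per archetype template")
        if self.center_jitter_sd_um < 0 or self.strength_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")

    @property
    def n_archetypes(self) -> int:
        return len(self.templates)

    def archetype_for_position(self, soma_um: float) -> int:
        for i, (lo, hi) in enumerate(self.spans):
            if lo <= soma_um < hi:
                return i
        raise ValueError(f"soma position {soma_um} µm outside all archetype spans")


def default_archetypes() -> ArchetypeSet:
    """Four archetypes spanning the midline-to-P2+ mediolateral range.

    Each template carries the qualitative motifs of the recovered input
    maps — a local patch plus a distal (sometimes contralateral) hotspot
    separated by silent stretches — with hotspot positions disjoint between
    archetypes so that the planted cluster identity is recoverable from
    pattern correlations.
    """
    return ArchetypeSet(
        templates=(
            (Hotspot(40.0, 8.0), Hotspot(-220.0, 5.0)),
            (Hotspot(135.0, 3.0), Hotspot(-60.0, 6.0)),
            (Hotspot(225.0, 8.0), Hotspot(430.0, 5.0)),
            (Hotspot(320.0, 7.0), Hotspot(560.0, 4.0)),
        ),
        spans=((0.0, 90.0), (90.0, 180.0), (180.0, 270.0), (270.0, 360.1)),
    )


def planted_group_labels(groups, archetype_by_cell: dict) -> np.ndarray:
    """Planted archetype of each median-pattern group, -1 where ambiguous.

    A group inherits the archetype of the strict majority of its member
    cells; sliding windows that straddle an archetype boundary with no
    strict majority have no well-defined planted identity and are marked -1
    (to be excluded from recovery scoring).
    """
    from collections import Counter

    labels = np.empty(len(groups), dtype=int)
    for i, g in enumerate(groups):
        counts = Counter(archetype_by_cell[m] for m in g.member_ids)
        (top, n_top), *rest = counts.most_common()
        if rest and rest[0][1] == n_top or n_top * 2 <= g.n_members:
            labels[i] = -1
        else:
            labels[i] = top
    return labels


def jitter_hotspots(
    template, archetypes: ArchetypeSet, rng: np.random.Generator
) -> tuple:
    out = []
    for h in template:
        c = h.center_um + rng.normal(0.0, archetypes.center_jitter_sd_um)
        s = max(0.0, h.strength * (1.0 + rng.normal(0.0, archetypes.strength_jitter_sd)))
        out.append(Hotspot(c, s, h.halfwidth_um))
    return tuple(out)


def make_population(
    n_cells: int,
    seed: int,
    archetypes: ArchetypeSet | None = None,
    noise: NoiseSpec | None = None,
    n_repeats: int = 2,
    n_depth_rows: int = 2,
    burst_jitter: bool = True,
) -> list[CellRecording]:
    """Generate a population of cells drawn from the archetype set.

    Cells are assigned round-robin to archetypes; each cell's soma position
    is uniform within its archetype's span, its hotspots are the jittered
    template, and its per-site burst sizes are drawn around the mean burst
    (truncated at 1).  Cell ``i`` always sees the same random stream
    regardless of ``n_cells``.
    """
    archetypes = archetypes or default_archetypes()
    noise = noise or NoiseSpec()
    cells = []
    for i in range(n_cells):
        ss = _cell_seed_sequence(seed, i)
        meta_rng = np.random.default_rng(ss.spawn(1)[0])
        a = i % archetypes.n_archetypes
        lo, hi = archetypes.spans[a]
        soma = meta_rng.uniform(lo, hi)
        geometry = GridGeometry(n_depth_rows=n_depth_rows, midline_offset_um=soma)
        hotspots = jitter_hotspots(archetypes.templates[a], archetypes, meta_rng)
        if burst_jitter:
            burst = np.clip(
                meta_rng.normal(BURST_SIZE_MEAN, BURST_SIZE_SD, geometry.n_sites),
                1.0,
                None,
            )
        else:
            burst = BURST_SIZE_MEAN
        truth = ground_truth_from_hotspots(geometry, hotspots, burst_size=burst)
        cells.append(
            synthesize_cell(
                truth,
                geometry,
                noise,
                n_repeats=n_repeats,
                seed=ss.spawn(2)[1],
                cell_id=f"cell{i:03d}",
                archetype_id=a,
            )
        )
    return cells


def make_independent_population(
    n_cells: int,
    seed: int,
    n_hotspots: int = 4,
    noise: NoiseSpec | None = None,
    n_repeats: int = 2,
    n_depth_rows: int = 2,
    soma_span_um: tuple = (0.0, 360.0),
    hotspot_offset_um: float = 332.0,
    strength_range: tuple = (2.0, 8.0),
) -> list[CellRecording]:
    """Population with independently placed hotspots (no shared archetypes).

    Each cell's hotspot centres are uniform within ``hotspot_offset_um`` of
    its soma (by default the full grid span, so no part of the mapped range
    is systematically empty) and independent of every other cell's, making
    the expected between-cell pattern correlation zero — the construction
    behind the shuffled-pair null.
    """
    noise = noise or NoiseSpec()
    cells = []
    for i in range(n_cells):
        ss = _cell_seed_sequence(seed, i)
        meta_rng = np.random.default_rng(ss.spawn(1)[0])
        soma = meta_rng.uniform(*soma_span_um)
        geometry = GridGeometry(n_depth_rows=n_depth_rows, midline_offset_um=soma)
        hotspots = tuple(
            Hotspot(
                meta_rng.uniform(soma - hotspot_offset_um, soma + hotspot_offset_um),
                meta_rng.uniform(*strength_range),
            )
            for _ in range(n_hotspots)
        )
        truth = ground_truth_from_hotspots(geometry, hotspots)
        cells.append(
            synthesize_cell(
                truth,
                geometry,
                noise,
                n_repeats=n_repeats,
                seed=ss.spawn(2)[1],
                cell_id=f"cell{i:03d}",
            )
        )
    return cells


def synthesize_noise_charges(
    n_sites: int,
    noise: NoiseSpec,
    seed: int,
    batch_size: int = 1000,
):
    """Yield (response_charge, noise_charge) arrays for noise-only sites.

    Generates ``n_sites`` single-trial noise-only sweeps in batches and
    integrates both the response window and the terminal noise window of
    each, using the same baseline subtraction as the real pipeline.  Used
    for large-scale null calibration without holding all traces in memory.
    """
    from .traces import integrate_charge, noise_window_start_ms

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    done = 0
    while done < n_sites:
        m = min(batch_size, n_sites - done)
        x = rng.normal(0.0, noise.current_sd_pA, (m, noise.n_samples))
        q_resp = integrate_charge(
            x, noise.stim_onset_ms, dt_ms=noise.dt_ms, stim_onset_ms=noise.stim_onset_ms
        )
        q_noise = integrate_charge(
            x,
            noise_window_start_ms(noise.duration_ms),
            dt_ms=noise.dt_ms,
            stim_onset_ms=noise.stim_onset_ms,
        )
        yield q_resp, q_noise
        done += m
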