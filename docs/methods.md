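# Methods

## The measurement model

A photostimulation mapping experiment yields, per recorded cell, a set of
current sweeps indexed by stimulation site and repeat.  The analysis treats
each sweep as

    I(t) = baseline + synaptic current + slow artifact + noise,

and reduces it to a single charge: the baseline-subtracted integral of the
current over a 200 ms response window starting at stimulus onset, with the
sign convention that inward (excitatory) charge is positive.  The baseline
is the mean current over the 50 ms preceding onset.  The same integral
applied to the terminal 200 ms of every sweep of the cell — a window far
from any evoked response — yields the cell's noise-charge sample; its mean
μ_Q and standard deviation σ_Q (pooled over all sweeps of the cell) form
the noise model.

The connectivity statistic is the per-site Z-score

    Z_site = (mean evoked charge at the site − μ_Q) / σ_Q,

with significance declared for Z strictly above 3.09, the one-sided
standard-normal quantile at p = 0.001.  No multiple-testing correction is
applied: the fixed per-site threshold is a deliberate property of the
method being implemented, and its false-positive rate is instead verified
directly by null calibration (below).  When several mapping repeats are
averaged, Z remains normalised by the single-window σ_Q, which makes the
statistic conservative rather than anticonservative.

Two further per-trace operations support the non-PC cell types:

* **Slow direct-current removal (GoC recordings).**  Direct stimulation of
  Golgi-cell somata produces a slow inward transient.  A running median
  estimates it: the median-filtered trace (minus its own median, so the DC
  level is untouched) is subtracted.  A running median passes slow
  monotone drifts exactly and rejects an event only when the window is
  several times the event's duration, so the window (default 31 ms) is an
  order of magnitude longer than the fast ~2–3 ms-decay EPSCs it must
  preserve; numeric checks show ≤ 5% charge loss for such events and exact
  ramp removal.  A window matched instead to slow compound currents with a
  ~10 ms decay cannot satisfy both requirements — a running median tracks
  the monotone decay tail of the event itself (15–90% charge loss over
  windows of 15–190 ms) — which is why the default targets fast unitary
  events.
* **Event counting (MLI recordings).**  EPSC onsets are detected by
  matched filtering against a bi-exponential template (rise 1 ms, decay
  10 ms by default), thresholded at 5 robust (MAD-based) SDs of the
  filtered trace.  The count Z-score compares response-window counts to a
  distant control window of equal length:
  `Z = (⟨n_resp⟩ − ⟨n_ctrl⟩) / SD(n_ctrl)`.

## Patterns, groups and clusters

Depth rows at a mediolateral position are pooled by the maximum Z (taken
on Z, not raw charge), reflecting that mossy fibres innervate the full
depth of the granule-cell layer.  The resulting per-position profile is
placed at absolute midline-relative coordinates, linearly interpolated
onto a 1 µm support and convolved with a unit-mass triangular kernel of
18 µm half-width; near the support edges the kernel is renormalised over
its in-range part, so edges are unbiased rather than damped.  Thresholding
is done on unsmoothed site Z; smoothing enters only the correlation and
median analyses.

Cells from different animals are registered into a standard mediolateral
frame built from average zebrin-band widths (P1+ 48.5, P1− 275.6, P2+
64.6, P2− 445.2 µm from the midline), positioning each cell
proportionally within its band.  Registered cells are grouped by sliding
windows (100 µm wide, shifted by 10 µm, minimum one member); each group's
pattern is the per-position median across members (median absolute
deviation as dispersion), computed on the intersection of member supports.
Pairwise Pearson correlations between group patterns — evaluated on the
intersection of supports resampled at 10 µm — form a symmetric correlation
matrix with unit diagonal; undefined entries (zero variance, no overlap)
propagate as missing, never as zero.

The matrix is biclustered by bipartite spectral graph partitioning:
entries are mapped monotonically to nonnegative weights via
r → (r + 1) / 2, the bistochastically normalised matrix is decomposed by
SVD, and k-means on the leading singular-vector embedding partitions rows
and columns simultaneously (for a symmetric matrix the two partitions
coincide).  The implementation delegates to
`sklearn.cluster.SpectralCoclustering` with its randomised SVD and a fixed
random state; the ARPACK solver was found to mis-converge on
near-block-structured correlation matrices and is not used.  Each cluster
is flagged for contiguity along the position axis.  The number of clusters
defaults to 4 (the replication preset); `n_clusters="auto"` scans k = 2…8
and keeps the k maximising mean within-cluster minus mean between-cluster
correlation.

The soma-centered control translates every pattern so its soma sits at
offset zero, normalises to unit peak and averages per offset: when hotspot
positions are tied to absolute location, centering misaligns everything
except the local input, so the mean shows a single central peak and no
secondary structure — separating position-specific organisation from
cell-centred organisation.

## Plasticity deltas

Pre- and post-induction maps over the same grid are compared site by site
with ΔZ = Z_post − Z_pre.  Both maps should share one per-cell noise model
so ΔZ reflects response change rather than noise re-estimation (each map's
own pooled model differs only by sampling noise).  Classification uses the
same 3.09 threshold: potentiated (ΔZ > 3.09), depressed (ΔZ < −3.09),
awakened (potentiated and silent pre-induction; a refinement of
potentiated in counts), otherwise unchanged.  An ordinary least-squares
regression of ΔZ on the initial Z summarises weight dependence; a rule
where strong sites depress and weak sites potentiate yields a negative
slope and negative r.  Only the direction of this relationship is asserted
anywhere in the package: printed magnitudes of such regressions are
treated as unsigned summaries.

## The synthetic experiment

The generator renders what the analysis assumes, with known ground truth:

* **Grid.** 332 µm half-extent, 41.5 µm step (17 positions, 664 µm mapped
  width), 2–5 depth rows → 34–85 sites.
* **Connectivity.** Hotspots (centre, strength, half-width) set per-site
  connection counts through a Gaussian activation profile with 45 µm
  half-width at half-maximum — between the 33 µm direct-spot and 59.6 µm
  whole-cell estimates of photostimulation spread; hotspot half-widths
  below 33 µm are rejected.  Counts are identical across depth rows
  (mossy fibres span the full layer depth).
* **Responses.** A connected site's sweep carries
  `round(count × burst)` inward bi-exponential events (rise 1 ms, decay
  10 ms — kinetics are a modelling choice; only charges are constrained),
  each scaled to exactly q_u = 0.1 pC of discrete charge, at times uniform
  over the first 100 ms of the response window.  Burst size defaults to
  19.6 events per connection (SD 6.6 when jittered).  Expected site charge
  is therefore `round(count × burst) × q_u`, and with zero noise the
  integrated charge matches it to better than 1%.
* **Noise.** White Gaussian current noise (default SD 10 pA at 10 kHz
  sampling, 1000 ms sweeps, onset at 200 ms).  Recorded noise is coloured;
  the Z-score operates on integrated charge, where the central-limit
  behaviour of the integral justifies the simplification.  At these
  defaults σ_Q ≈ 0.1 pC, so one unitary connection's burst (~2 pC) gives
  Z ≈ 20 — comfortably detectable, as in the experiment.
* **Populations.** Four archetype templates (a local hotspot plus a
  distal, sometimes contralateral one) tile the 0–360 µm soma range in
  90 µm spans; cells are assigned round-robin, with per-cell jitter of
  hotspot centres (SD 8 µm) and strengths (fractional SD 0.15).  Hotspot
  positions are disjoint between archetypes so the planted cluster
  identity is recoverable from pattern correlations; a hotspot shared by
  all archetypes (as the real data show in P2+) would make the planted
  partition partially unidentifiable.  An alternative population places
  every cell's hotspots independently (uniform within ±300 µm of the
  soma), giving exactly zero expected between-cell correlation — the
  construction behind the shuffle null.
* **Plasticity.** A rule maps initial site strength to a multiplicative
  change (applied to burst size, so expected charge scales exactly);
  awaken lists raise silent sites to a configured count, warning if a
  site is already connected.
* **Determinism.** One root seed is split hierarchically
  (cell → site → repeat) with `numpy.random.SeedSequence`; adding cells to
  a population never perturbs existing ones, and identical (config, seed)
  reruns are byte-identical.

What the generator does **not** emulate: dendritic filtering and receptor
kinetics, series-resistance artifacts, coloured noise, inhibitory
circuitry (inhibition was blocked in the mapping experiments), trial-to-
trial release variability beyond event-time jitter, and any anatomical
statistics of the bands themselves.  Passing recovery tests therefore
demonstrates the correctness of the analysis under its own statistical
assumptions, not robustness to every feature of real recordings.

## Calibration and recovery checks

* **Threshold.** Φ⁻¹(0.999) = 3.0902 ≈ 3.09.
* **Null calibration.** 100,000 noise-only single-trial sites, with the
  noise model pooled from their 100,000 terminal windows, yield a
  significant fraction whose 95% binomial CI covers 0.001.  Because the
  terminal window is processed identically to the response window
  (including baseline subtraction), the Z statistic is exactly calibrated
  under the null.
* **Shuffle null.** In independent populations (48 cells each, hotspots
  uniform over the full grid span so no part of the mapped range is
  systematically empty; 600 random non-self, non-neighbour pairings per
  population, pairing without replacement per round, neighbours = somata
  closer than 50 µm, minimum 100 µm of common support), the mean
  shuffled-pair r is zero within Monte-Carlo error.  Pairings sharing a
  cell are correlated, so the error of the mean is limited by the cell
  count; the acceptance summary pools pairs from three independently
  generated populations.
* **Recovery.** At default noise, planted hotspots with expected Z ≥ 5
  are significant and their pattern peaks lie within one grid step
  (41.5 µm) of the planted centres; on the default 49-cell population,
  co-clustering with k = 4 recovers the planted archetypes with adjusted
  Rand index ≥ 0.9 over groups with a strict-majority planted identity
  (a 100 µm window straddling an archetype boundary with a 50/50 member
  split has no well-defined planted label) and all clusters contiguous.
* **Plasticity.** Planted awaken/depress/potentiate rules at expected
  |ΔZ| ≫ 3 effect sizes are re-classified with ≥ 95% per-site accuracy,
  and the ΔZ-vs-Z regression recovers the planted sign.

## Problem sizes and defaults

The shipped defaults are the study conditions: 49 cells (the PC sample
size of the mapping dataset), 34-site grids, 10 kHz synthetic sampling
(acquisition hardware sampled faster; for integrated-charge statistics the
rate only sets the noise-charge variance, which the noise model absorbs),
2 mapping repeats per cell in the population pipeline, 100,000 sites for
null calibration and 3 x 48 cells / 1,800 pooled pairs for the shuffle
null.  Every
numeric default lives in the YAML config (`gcmap.io.DEFAULT_CONFIG`) and
can be overridden per run.

## Known limitations

* The band-order of the standard frame (P1+, P1−, P2+, P2− from the
  midline) is configurable in case a different reading is required.
* Group windows near population edges contain few cells; groups report
  membership so consumers can filter.
* No uncertainty is attached to the cluster count: the auto-k score is a
  heuristic, and no gap statistic or consensus clustering is attempted.
* The shuffle null excludes same-cell and neighbour pairings but not
  higher-order dependence (e.g. shared animals), which the synthetic
  population does not model.
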