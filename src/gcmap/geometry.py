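"""Stimulation-grid geometry and the zebrin-band mediolateral coordinate frame.

The uncaging experiment scans a rectangular grid over the granule-cell layer:
a row of mediolateral positions centred on the recorded cell (default
332 µm of extent on each side in 41.5 µm steps, i.e. 17 positions spanning
664 µm) repeated at 2–5 depth rows.  Mediolateral coordinates are signed
micrometres from the cerebellar midline, ipsilateral positive; depth rows are
0-based indices.

Cross-animal comparison requires a common mediolateral frame.  The zebrin
(aldolase C) band boundaries provide it: each cell's position is expressed as
a proportional location within its band and mapped into a standard frame
built from the average band widths (P1+, P1−, P2+, P2− from the midline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError

#: Default significance threshold: one-sided standard-normal quantile at
#: p = 0.001, rounded to two decimals.
Z_THRESHOLD = 3.09


@dataclass(frozen=True)
class GridGeometry:
    """Photostimulation grid: mediolateral extent, step and depth rows.

    Parameters
    ----------
    half_extent_um : float
        Extent of the grid on each side of the recorded cell (µm).
    step_um : float
        Mediolateral spacing between neighbouring sites (µm).
    n_depth_rows : int
        Number of rows sampled at different depths of the granule-cell layer.
    midline_offset_um : float
        Signed mediolateral position of the recorded cell's soma relative to
        the midline (µm, ipsilateral positive).
    """

    half_extent_um: float = 332.0
    step_um: float = 41.5
    n_depth_rows: int = 2
    midline_offset_um: float = 0.0

    def __post_init__(self) -> None:
        if self.step_um <= 0:
            raise InvalidGeometryError(f"step_um must be > 0, got {self.step_um}")
        if self.half_extent_um < 0:
            raise InvalidGeometryError(
                f"half_extent_um must be >= 0, got {self.half_extent_um}"
            )
        if self.n_depth_rows < 1:
            raise InvalidGeometryError(
                f"n_depth_rows must be >= 1, got {self.n_depth_rows}"
            )

    @property
    def n_half_steps(self) -> int:
        return int(round(self.half_extent_um / self.step_um)) if self.half_extent_um else 0

    @property
    def n_positions(self) -> int:
        """Number of mediolateral positions (symmetric about the soma)."""
        return 2 * self.n_half_steps + 1

    @property
    def n_sites(self) -> int:
        return self.n_positions * self.n_depth_rows

    @property
    def width_um(self) -> float:
        """Total mapped mediolateral width (distance between extreme sites)."""
        return 2 * self.n_half_steps * self.step_um

    def positions_um(self) -> np.ndarray:
        """Mediolateral site positions in µm from the midline, ascending."""
        rel = np.arange(-self.n_half_steps, self.n_half_steps + 1) * self.step_um
        return self.midline_offset_um + rel


def make_grid(geometry: GridGeometry) -> pd.DataFrame:
    """Enumerate stimulation sites for a grid geometry.

    Returns a DataFrame ordered by (depth_row, mediolateral position) with
    columns ``site_id``, ``depth_row``, ``ml_um`` (µm from the midline) and
    ``rel_um`` (µm from the recorded cell).
    """
    pos = geometry.positions_um()
    depth = np.repeat(np.arange(geometry.n_depth_rows), geometry.n_positions)
    ml = np.tile(pos, geometry.n_depth_rows)
    rel = ml - geometry.midline_offset_um
    return pd.DataFrame(
        {
            "site_id": np.arange(geometry.n_sites),
            "depth_row": depth,
            "ml_um": ml,
            "rel_um": rel,
        }
    )


@dataclass(frozen=True)
class BandCoordinateFrame:
    """Standard mediolateral frame built from average zebrin-band widths.

    Bands are ordered from the midline outward.  Defaults are the average
    widths measured in lobules III/IV: P1+ 48.5 µm, P1− 275.6 µm,
    P2+ 64.6 µm, P2− 445.2 µm.
    """

    band_names: tuple = ("P1+", "P1-", "P2+", "P2-")
    widths_um: tuple = (48.5, 275.6, 64.6, 445.2)

    def __post_init__(self) -> None:
        if len(self.band_names) != len(self.widths_um):
            raise InvalidGeometryError("band_names and widths_um length mismatch")
        if any(w <= 0 for w in self.widths_um):
            raise InvalidGeometryError("band widths must be positive")

    @property
    def boundaries_um(self) -> np.ndarray:
        """Cumulative band boundaries from the midline, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.widths_um)])

    def band_start_um(self, band: str) -> float:
        return float(self.boundaries_um[self._index(band)])

    def band_width_um(self, band: str) -> float:
        return float(self.widths_um[self._index(band)])

    def _index(self, band: str) -> int:
        try:
            return self.band_names.index(band)
        except ValueError:
            raise InvalidGeometryError(
                f"unknown band {band!r}; expected one of {self.band_names}"
            ) from None


def register_position(
    band: str,
    fraction: float | None = None,
    frame: BandCoordinateFrame | None = None,
    *,
    offset_um: float | None = None,
    measured_width_um: float | None = None,
) -> float:
    """Map a cell position into the standard band coordinate frame.

    The cell's location is expressed proportionally within its zebrin band
    (``fraction`` in [0, 1] from the medial edge), either directly or as a
    measured offset within a band of measured width, and placed at the same
    proportional position in the standard frame.

    Examples
    --------
    A cell at the midline edge of P1+ registers at 0 µm; a cell at the
    P1+/P1− boundary registers at 48.5 µm.
    """
    frame = frame or BandCoordinateFrame()
    if fraction is None:
        if offset_um is None or measured_width_um is None:
            raise ValueError("provide fraction, or offset_um with measured_width_um")
        if measured_width_um <= 0:
            raise InvalidGeometryError("measured band width must be positive")
        fraction = offset_um / measured_width_um
    return frame.band_start_um(band) + fraction * frame.band_width_um(band)
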