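"""Ice-ring histogram plots.

Each candidate ice-ring resolution window of a reflection set is turned into
an 80x80 two-dimensional histogram of observed value against resolution.
The lettered window table gives the tight d-spacing intervals in which a
hexagonal-ice powder ring can appear; each plot displays that interval plus
a symmetric margin of ``x_pad`` ring-widths on either side, so an actual
ice spike stands in the central columns against the window's own clean
baseline.  The x axis is uniform in 1/d^2 (reflections are roughly uniform
in reciprocal volume, so this gives even occupancy and a constant plot size
regardless of window width); the y axis spans the 0.5th-95th percentile of
the displayed values (extreme outliers are excluded, not clamped).  The raw
count grid is max-normalized to [0, 1] for the network.

Grid orientation: row 0 is the lowest value bin (bottom of the plot),
column 0 is the window's low-resolution edge (largest d).  Sensitivity maps
computed downstream share this orientation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .reflection_io import ReflectionSet, ValueKind

__all__ = [
    "IceRingRange",
    "PlotConfig",
    "IceRingPlot",
    "load_ranges",
    "default_ranges",
    "select_ranges",
    "clip_limits",
    "is_blank",
    "make_plot",
    "make_plots",
    "average_plots",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Too few reflections to form a meaningful plot."""


@dataclass(frozen=True)
class IceRingRange:
    """One lettered d-spacing window where a hexagonal-ice ring can appear."""

    label: str
    d_high: float  # low-resolution edge, A
    d_low: float  # high-resolution edge, A

    def __post_init__(self) -> None:
        if not 0 < self.d_low < self.d_high:
            raise ValueError(f"need 0 < d_low < d_high: {self}")

    @property
    def s_lo(self) -> float:
        """Window start in 1/d^2 (A^-2)."""
        return 1.0 / self.d_high**2

    @property
    def s_hi(self) -> float:
        """Window end in 1/d^2 (A^-2)."""
        return 1.0 / self.d_low**2

    def contains(self, d: np.ndarray) -> np.ndarray:
        s = 1.0 / np.asarray(d, dtype=float) ** 2
        return (s >= self.s_lo) & (s <= self.s_hi)

    def display_interval(self, pad: float) -> tuple[float, float]:
        """Plot x-range in 1/d^2: the ring interval widened by ``pad`` ring
        widths on each side (the ring occupies the central columns)."""
        width = self.s_hi - self.s_lo
        return self.s_lo - pad * width, self.s_hi + pad * width

    def display_contains(self, d: np.ndarray, pad: float) -> np.ndarray:
        lo, hi = self.display_interval(pad)
        s = 1.0 / np.asarray(d, dtype=float) ** 2
        return (s >= lo) & (s <= hi)


def load_ranges(path: str | Path) -> list[IceRingRange]:
    """Load a window table CSV (columns label,inv_d2_lo,inv_d2_hi or
    label,d_high,d_low); returns windows sorted by increasing 1/d^2."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(filter(lambda ln: not ln.startswith("#"), fh))]
    out = []
    for r in rows:
        if "inv_d2_lo" in r:
            lo, hi = float(r["inv_d2_lo"]), float(r["inv_d2_hi"])
            out.append(IceRingRange(r["label"], d_high=lo**-0.5, d_low=hi**-0.5))
        else:
            out.append(IceRingRange(r["label"], d_high=float(r["d_high"]), d_low=float(r["d_low"])))
    out.sort(key=lambda w: w.s_lo)
    for prev, nxt in zip(out, out[1:]):
        if nxt.s_lo < prev.s_hi:
            raise ValueError(f"overlapping windows {prev.label} and {nxt.label}")
    return out


def default_ranges() -> list[IceRingRange]:
    """The shipped lettered (A-H) hexagonal-ice window table."""
    with resources.as_file(resources.files("icering.data") / "ice_ring_ranges.csv") as p:
        return load_ranges(p)


@dataclass(frozen=True)
class PlotConfig:
    """Histogram parameters.

    80x80 bins with a [0.5, 95] percentile value window; windows holding
    fewer than ``min_reflections`` usable reflections are flagged
    nonpredictable rather than classified.
    """

    n_bins_x: int = 80
    n_bins_y: int = 80
    lo_percentile: float = 0.5
    hi_percentile: float = 95.0
    min_reflections: int = 30
    x_pad: float = 1.0  # display margin, in ring widths per side
    blank_bins: int = 5  # sub-bins used by the blank discriminator
    blank_eps: float = 0.01  # mean-value threshold, relative to set-wide mean

    def __post_init__(self) -> None:
        if self.n_bins_x <= 0 or self.n_bins_y <= 0:
            raise ValueError("bin counts must be positive")
        if not 0 <= self.lo_percentile < self.hi_percentile <= 100:
            raise ValueError("need 0 <= lo < hi <= 100 percentiles")


@dataclass
class IceRingPlot:
    """The 80x80 histogram of one window plus its provenance."""

    counts: np.ndarray  # (n_bins_y, n_bins_x) raw counts
    grid: np.ndarray = field(init=False)  # max-normalized copy in [0, 1]
    range_label: str = ""
    clip_lo: float = 0.0
    clip_hi: float = 0.0
    n_in_range: int = 0
    blank: bool = False
    low_count: bool = False
    kind: ValueKind = ValueKind.INTENSITY

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        peak = self.counts.max()
        self.grid = self.counts / peak if peak > 0 else np.zeros_like(self.counts)

    @property
    def predictable(self) -> bool:
        return not self.blank and not self.low_count


def select_ranges(
    rset: ReflectionSet, table: list[IceRingRange], pad: float = PlotConfig().x_pad
) -> list[IceRingRange]:
    """Windows whose full displayed interval lies inside the data span.

    Windows the data only partially reach (e.g. sets whose maximum
    resolution truncates the ring) are excluded rather than plotted.
    """
    if len(rset) == 0:
        raise InsufficientDataError("empty reflection set")
    s_min = 1.0 / rset.d_max**2
    s_max = 1.0 / rset.d_min**2
    out = []
    for w in table:
        lo, hi = w.display_interval(pad)
        if s_min <= lo and hi <= s_max:
            out.append(w)
    return out


def clip_limits(values: np.ndarray, cfg: PlotConfig = PlotConfig()) -> tuple[float, float]:
    """Value-axis limits: the (lo, hi) percentiles under linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < max(1, cfg.min_reflections):
        raise InsufficientDataError(
            f"{values.size} values < min_reflections={cfg.min_reflections}"
        )
    lo, hi = np.percentile(values, [cfg.lo_percentile, cfg.hi_percentile])
    return float(lo), float(hi)


def is_blank(
    rset: ReflectionSet,
    window: IceRingRange,
    n_bins: int = 5,
    eps: float = 0.01,
    pad: float = PlotConfig().x_pad,
) -> bool:
    """Detect (partially) blank windows, e.g. shells omitted in integration.

    The displayed interval is cut into ``n_bins`` equal sub-bins in 1/d^2
    and flagged blank when any sub-bin's mean observed value falls below
    ``eps`` times the set-wide mean.  An *empty* sub-bin is evidence only
    when the window is dense enough (>= 5 reflections per sub-bin on
    average) that emptiness is surprising; sparse data never trip the
    discriminator.  A window with no reflections at all is blank trivially.
    """
    mask = window.display_contains(rset.d, pad)
    n_window = int(mask.sum())
    if n_window == 0:
        return True
    global_mean = float(np.mean(rset.value))
    if global_mean <= 0:
        global_mean = float(np.mean(np.abs(rset.value))) or 1.0
    s = 1.0 / rset.d[mask] ** 2
    v = rset.value[mask]
    s_lo, s_hi = window.display_interval(pad)
    edges = np.linspace(s_lo, s_hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    dense = n_window >= 5 * n_bins
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            if dense:
                return True
            continue
        if float(v[sel].mean()) < eps * global_mean:
            return True
    return False


def make_plot(
    rset: ReflectionSet, window: IceRingRange, cfg: PlotConfig = PlotConfig()
) -> IceRingPlot:
    """Histogram one window of a reflection set.

    Reflections in the displayed interval (ring plus ``cfg.x_pad`` margin)
    are binned on (1/d^2, value); values outside the percentile clip window
    are excluded.  A window with zero reflections yields a blank all-zero
    plot; one with fewer than ``cfg.min_reflections`` is marked low-count
    (nonpredictable) but still histogrammed.
    """
    mask = window.display_contains(rset.d, cfg.x_pad)
    v = rset.value[mask]
    s = 1.0 / rset.d[mask] ** 2
    if v.size == 0:
        return IceRingPlot(
            counts=np.zeros((cfg.n_bins_y, cfg.n_bins_x)),
            range_label=window.label,
            blank=True,
            kind=rset.kind,
        )
    s_lo, s_hi = window.display_interval(cfg.x_pad)
    lo, hi = np.percentile(v, [cfg.lo_percentile, cfg.hi_percentile])
    if hi <= lo:
        hi = lo  # constant input: everything lands in one row
    counts, _, _ = np.histogram2d(
        v,
        s,
        bins=[cfg.n_bins_y, cfg.n_bins_x],
        range=[[lo, hi if hi > lo else lo + 1.0], [s_lo, s_hi]],
    )
    blank = is_blank(rset, window, n_bins=cfg.blank_bins, eps=cfg.blank_eps, pad=cfg.x_pad)
    return IceRingPlot(
        counts=counts,
        range_label=window.label,
        clip_lo=float(lo),
        clip_hi=float(hi),
        n_in_range=int(v.size),
        blank=blank,
        low_count=v.size < cfg.min_reflections,
        kind=rset.kind,
    )


def make_plots(
    rset: ReflectionSet,
    table: list[IceRingRange] | None = None,
    cfg: PlotConfig = PlotConfig(),
) -> list[IceRingPlot]:
    """One plot per window selected for this set (convenience wrapper)."""
    table = default_ranges() if table is None else table
    return [make_plot(rset, w, cfg) for w in select_ranges(rset, table, pad=cfg.x_pad)]


def average_plots(plots: list[IceRingPlot]) -> np.ndarray:
    """Element-wise mean of the normalized grids (same shape and kind)."""
    if not plots:
        raise ValueError("cannot average an empty plot list")
    kinds = {p.kind for p in plots}
    if len(kinds) > 1:
        raise ValueError("cannot average plots of mixed value kinds")
    shapes = {p.grid.shape for p in plots}
    if len(shapes) > 1:
        raise ValueError("cannot average plots of mixed shapes")
    return np.mean([p.grid for p in plots], axis=0)
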