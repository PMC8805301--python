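"""Synthetic reflection data with controllable ice-ring contamination.

The simulator produces merged reflection sets whose (resolution, value)
marginals look like real data to the classifier: unique Miller indices are
enumerated to a resolution limit, mean intensity follows a Wilson falloff
<I>(d) = A exp(-B / (2 d^2)), per-reflection intensities are acentric
(exponential) draws around that mean with Gaussian measurement noise, and
ice contamination multiplies the intensities of a seeded fraction f of the
reflections inside a chosen window by a spike factor s >= 1.  Amplitude
sets take F = sqrt(max(I, 0)).  Whole windows can also be blanked (omitted
or zeroed), emulating resolution shells excluded during integration.

Ground-truth window labels are decided by the same visibility rule a human
annotator applies to the histograms: a window counts as contaminated only
if the spike changes the occupancy of at least 1% of the grid cells
(overlaying the plot with and without the spike); sub-visible spikes are
labelled clean.  Blank windows are labelled blank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plotgen import IceRingRange, PlotConfig, default_ranges, make_plot
from .reflection_io import ReflectionSet, UnitCell, ValueKind, d_spacings

__all__ = [
    "SimulationParams",
    "Contamination",
    "simulate_reflections",
    "enumerate_hkl",
    "make_corpus",
    "AREA_CRITERION_FRACTION",
    "DIFFICULTY_BANDS",
]

# minimum fraction of grid cells whose occupancy the spike must change for
# the window to be labelled contaminated (the "1% of the plot area" rule)
AREA_CRITERION_FRACTION = 0.01

# spike-factor and affected-fraction bands per difficulty class; the "weak"
# band deliberately straddles the visibility rule so some weak spikes are
# demoted to clean labels
DIFFICULTY_BANDS: dict[str, dict[str, tuple[float, float]]] = {
    "strong": {"spike": (4.0, 8.0), "fraction": (0.8, 1.0)},
    "weak": {"spike": (1.8, 3.0), "fraction": (0.5, 1.0)},
    "accumulating": {"spike": (3.0, 6.0), "fraction": (0.3, 0.6)},
}


@dataclass(frozen=True)
class Contamination:
    """One contaminated window: spike factor s >= 1 on a fraction f of its
    reflections ('accumulating' ice corresponds to f < 1)."""

    label: str
    spike: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.spike < 1.0:
            raise ValueError("spike factor must be >= 1")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("affected fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    cell: UnitCell = UnitCell(70.0, 70.0, 70.0)
    d_min: float = 1.6  # resolution limit, A
    scale: float = 100.0  # Wilson scale A, arbitrary units
    wilson_b: float = 20.0  # Wilson temperature factor, A^2
    sigma_fraction: float = 0.1  # noise sd as a fraction of <I>(d)
    kind: ValueKind = ValueKind.INTENSITY
    contaminated_ranges: tuple[Contamination, ...] = ()
    blank_ranges: tuple[str, ...] = ()
    blank_mode: str = "omit"  # "omit" drops the shell, "zero" zeroes values
    n_target: int | None = None  # subsample cap on the reflection count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.blank_mode not in ("omit", "zero"):
            raise ValueError("blank_mode must be 'omit' or 'zero'")


def enumerate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All unique Miller indices (one hemisphere) with d >= d_min."""
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(0, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    # one hemisphere: l > 0, or l == 0 and k > 0, or l == k == 0 and h > 0
    hemi = (hkl[:, 2] > 0) | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0)
    )
    hkl = hkl[hemi]
    d = d_spacings(hkl, cell)
    # keep exact-boundary shells despite float jitter in the metric tensor
    return hkl[d >= d_min * (1.0 - 1e-9)]


def _area_criterion(
    contaminated: np.ndarray,
    pristine: np.ndarray,
    s_coord: np.ndarray,
    window: IceRingRange,
    cfg: PlotConfig,
) -> bool:
    """Does the spike change the occupancy of >= 1% of grid cells?

    Both value sets are histogrammed on one shared grid (the window's full
    displayed interval) whose value axis is clipped on the *observed*
    (contaminated) data, mirroring what the plot generator and an annotator
    would see.
    """
    lo, hi = np.percentile(contaminated, [cfg.lo_percentile, cfg.hi_percentile])
    if hi <= lo:
        return False
    s_lo, s_hi = window.display_interval(cfg.x_pad)
    rng_spec = [[lo, hi], [s_lo, s_hi]]
    bins = [cfg.n_bins_y, cfg.n_bins_x]
    g1, _, _ = np.histogram2d(contaminated, s_coord, bins=bins, range=rng_spec)
    g0, _, _ = np.histogram2d(pristine, s_coord, bins=bins, range=rng_spec)
    changed = np.count_nonzero((g1 > 0) != (g0 > 0))
    return changed >= AREA_CRITERION_FRACTION * g1.size


def simulate_reflections(
    p: SimulationParams,
    table: list[IceRingRange] | None = None,
    cfg: PlotConfig = PlotConfig(),
) -> tuple[ReflectionSet, dict[str, str]]:
    """Simulate one merged reflection set plus ground-truth window labels.

    Returns the set and a mapping window label -> "clean" | "contaminated"
    | "blank" for every window fully contained in the data's resolution
    span.  Labels follow the grid-overlay visibility rule (see module
    docstring), so a nominally contaminated window with a sub-visible spike
    is labelled clean.
    """
    table = default_ranges() if table is None else table
    rng = np.random.default_rng(p.seed)
    hkl = enumerate_hkl(p.cell, p.d_min)
    if hkl.shape[0] == 0:
        raise ValueError(f"no lattice points with d >= {p.d_min} A for this cell")
    if p.n_target is not None and hkl.shape[0] > p.n_target:
        keep = np.sort(rng.choice(hkl.shape[0], size=p.n_target, replace=False))
        hkl = hkl[keep]
    d = d_spacings(hkl, p.cell)

    mean_i = p.scale * np.exp(-p.wilson_b / (2.0 * d * d))
    intensity = rng.exponential(mean_i)
    sigma = p.sigma_fraction * mean_i
    intensity = intensity + rng.normal(0.0, sigma)
    pristine = intensity.copy()

    windows = {w.label: w for w in table}
    spiked: dict[str, float] = {}
    for cont in p.contaminated_ranges:
        w = windows[cont.label]
        idx = np.flatnonzero(w.contains(d))
        n_hit = int(round(cont.fraction * idx.size))
        if n_hit == 0 or cont.spike <= 1.0:
            continue
        hit = rng.choice(idx, size=n_hit, replace=False)
        intensity[hit] *= cont.spike
        spiked[cont.label] = cont.spike

    keep = np.ones(len(d), dtype=bool)
    for label in p.blank_ranges:
        in_w = windows[label].contains(d)
        if p.blank_mode == "omit":
            keep &= ~in_w
        else:
            intensity[in_w] = 0.0
            pristine[in_w] = 0.0

    hkl, d = hkl[keep], d[keep]
    intensity, pristine, sigma = intensity[keep], pristine[keep], sigma[keep]

    if p.kind == ValueKind.AMPLITUDE:
        value = np.sqrt(np.clip(intensity, 0.0, None))
        pristine_v = np.sqrt(np.clip(pristine, 0.0, None))
        sigma_v = np.where(value > 0, sigma / (2.0 * np.maximum(value, 1e-12)), sigma)
    else:
        value, pristine_v, sigma_v = intensity, pristine, sigma

    rset = ReflectionSet(
        p.cell, p.kind, hkl, value, sigma_v, source_label=f"synthetic seed={p.seed}"
    )

    labels: dict[str, str] = {}
    s_all = 1.0 / d**2
    s_min, s_max = 1.0 / rset.d_max**2, 1.0 / rset.d_min**2
    for w in table:
        disp_lo, disp_hi = w.display_interval(cfg.x_pad)
        if not (s_min <= disp_lo and disp_hi <= s_max):
            continue
        if w.label in p.blank_ranges:
            labels[w.label] = "blank"
            continue
        verdict = "clean"
        if w.label in spiked:
            m = w.display_contains(d, cfg.x_pad)
            if m.any() and _area_criterion(value[m], pristine_v[m], s_all[m], w, cfg):
                verdict = "contaminated"
        labels[w.label] = verdict
    return rset, labels


def _random_params(rng: np.random.Generator, kind: ValueKind, low_count: bool) -> SimulationParams:
    """Draw one dataset's cell, falloff, noise and size."""
    # macromolecular-scale cells: large enough that reciprocal-lattice shells
    # are dense across every ice window (small cells leave striped histograms)
    cell = UnitCell(*(rng.uniform(55.0, 85.0, size=3)), 90.0, 90.0, 90.0)
    return SimulationParams(
        cell=cell,
        d_min=float(rng.uniform(1.55, 1.75)),
        scale=float(10.0 ** rng.uniform(1.0, 3.0)),
        wilson_b=float(rng.uniform(10.0, 35.0)),
        sigma_fraction=float(rng.uniform(0.05, 0.25)),
        kind=kind,
        n_target=int(rng.integers(800, 3000)) if low_count else 15000,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_corpus(
    n_sets: int,
    fraction_contaminated: float = 0.075,
    difficulty_mix: dict[str, float] | None = None,
    seed: int = 0,
    kind: ValueKind = ValueKind.AMPLITUDE,
    table: list[IceRingRange] | None = None,
    cfg: PlotConfig = PlotConfig(),
    blank_fraction: float = 0.02,
    low_count_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a labelled plot corpus from ``n_sets`` simulated datasets.

    Each window of each dataset is independently contaminated with
    probability ``fraction_contaminated`` (default mirrors the ~7.5% plot
    imbalance of real annotated corpora); the contamination difficulty is
    drawn from ``difficulty_mix`` (weights over DIFFICULTY_BANDS keys).
    Returns (grids, labels, manifest): normalized (M, ny, nx) grids and 0/1
    labels for the predictable plots only, plus a manifest row for every
    generated plot including the blank/low-count ones that were held out.
    """
    if n_sets < 2:
        raise ValueError("need at least 2 datasets")
    mix = difficulty_mix or {"strong": 0.5, "weak": 0.25, "accumulating": 0.25}
    bad = set(mix) - set(DIFFICULTY_BANDS)
    if bad or not mix or sum(mix.values()) <= 0:
        raise ValueError(f"bad difficulty mix: {mix}")
    names = sorted(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    probs /= probs.sum()
    table = default_ranges() if table is None else table

    root = np.random.default_rng(np.random.SeedSequence([seed, 0x1CE]))
    grids, labels, rows = [], [], []
    for i_set in range(n_sets):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        low_count = bool(rng.random() < low_count_fraction)
        p = _random_params(rng, kind, low_count)
        conts, blanks, difficulties = [], [], {}
        for w in table:
            if rng.random() < blank_fraction:
                blanks.append(w.label)
            elif rng.random() < fraction_contaminated:
                diff = names[int(rng.choice(len(names), p=probs))]
                band = DIFFICULTY_BANDS[diff]
                conts.append(
                    Contamination(
                        w.label,
                        spike=float(rng.uniform(*band["spike"])),
                        fraction=float(rng.uniform(*band["fraction"])),
                    )
                )
                difficulties[w.label] = diff
        p = replace(p, contaminated_ranges=tuple(conts), blank_ranges=tuple(blanks))
        rset, truth = simulate_reflections(p, table, cfg)
        for w in table:
            if w.label not in truth:
                continue
            plot = make_plot(rset, w, cfg)
            status = truth[w.label]
            usable = plot.predictable and status != "blank"
            rows.append(
                {
                    "set": i_set,
                    "window": w.label,
                    "label": status,
                    "difficulty": difficulties.get(w.label, ""),
                    "n_in_range": plot.n_in_range,
                    "predictable": plot.predictable,
                    "used": usable,
                    "seed": p.seed,
                    "kind": kind.value,
                }
            )
            if usable:
                grids.append(plot.grid)
                labels.append(1 if status == "contaminated" else 0)
    manifest = pd.DataFrame(rows)
    return np.asarray(grids, dtype=np.float32), np.asarray(labels, dtype=np.int64), manifest
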