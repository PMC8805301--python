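"""Reading and writing merged reflection data.

Reflection data arrive as integrated, scaled and merged observations: Miller
indices (h, k, l) with an observed intensity I_obs (preferred) or structure-
factor amplitude F_obs and, usually, an uncertainty.  Two on-disk forms are
supported behind one entry point:

* MTZ, the standard binary reflection container of macromolecular
  crystallography (read through :mod:`gemmi`);
* a tiny plain-text dialect used for fixtures and interchange, documented in
  :func:`write_reflections`.

Every reflection is assigned its d-spacing from the unit cell so downstream
code can place it on a resolution axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "UnitCell",
    "ValueKind",
    "ReflectionSet",
    "ReflectionError",
    "resolution_of",
    "d_spacings",
    "read_reflections",
    "write_reflections",
]


class ReflectionError(ValueError):
    """Raised for invalid cells, degenerate indices or unusable files."""


class ValueKind(str, Enum):
    """Which observable a reflection set carries."""

    INTENSITY = "intensity"
    AMPLITUDE = "amplitude"


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not all(x > 0 for x in (self.a, self.b, self.c)):
            raise ReflectionError(f"cell lengths must be positive: {self}")
        if not all(0.0 < x < 180.0 for x in (self.alpha, self.beta, self.gamma)):
            raise ReflectionError(f"cell angles must lie in (0, 180): {self}")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        # volume factor; positive iff the metric tensor is positive definite
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise ReflectionError(f"cell angles give a degenerate metric: {self}")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(v2)

    def reciprocal_metric(self) -> np.ndarray:
        """3x3 reciprocal-space metric tensor G* (units 1/A^2).

        For a reflection (h,k,l), 1/d^2 = (h,k,l) G* (h,k,l)^T.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sa, sb, sg = (math.sin(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v = self.volume
        astar = self.b * self.c * sa / v
        bstar = self.a * self.c * sb / v
        cstar = self.a * self.b * sg / v
        ca_s = (cb * cg - ca) / (sb * sg)
        cb_s = (ca * cg - cb) / (sa * sg)
        cg_s = (ca * cb - cg) / (sa * sb)
        return np.array(
            [
                [astar * astar, astar * bstar * cg_s, astar * cstar * cb_s],
                [astar * bstar * cg_s, bstar * bstar, bstar * cstar * ca_s],
                [astar * cstar * cb_s, bstar * cstar * ca_s, cstar * cstar],
            ]
        )


def d_spacings(hkl: np.ndarray, cell: UnitCell) -> np.ndarray:
    """d-spacings in Angstrom for an (N, 3) integer index array."""
    hkl = np.asarray(hkl, dtype=float)
    gstar = cell.reciprocal_metric()
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
    if np.any(inv_d2 <= 0):
        raise ReflectionError("zero scattering vector (0,0,0) has no d-spacing")
    return 1.0 / np.sqrt(inv_d2)


def resolution_of(h: int, k: int, l: int, cell: UnitCell) -> float:
    """d-spacing of reflection (h,k,l) from the general triclinic formula.

    Symmetric under negation of all indices; raises for (0,0,0).
    """
    if h == 0 and k == 0 and l == 0:
        raise ReflectionError("(0,0,0) is the direct beam, not a reflection")
    return float(d_spacings(np.array([[h, k, l]]), cell)[0])


@dataclass
class ReflectionSet:
    """Merged reflections with one observed value (I or F) per unique index."""

    cell: UnitCell
    kind: ValueKind
    hkl: np.ndarray  # (N, 3) int
    value: np.ndarray  # (N,) float, I_obs or F_obs on arbitrary scale
    sigma: np.ndarray | None = None  # (N,) float, same units as value
    source_label: str = ""
    d: np.ndarray = field(init=False)  # (N,) resolution in Angstrom

    def __post_init__(self) -> None:
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=np.int64))
        self.value = np.asarray(self.value, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self.kind = ValueKind(self.kind)
        if self.hkl.shape[1] != 3 or self.hkl.shape[0] != self.value.shape[0]:
            raise ReflectionError("hkl and value shapes disagree")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ReflectionError("(0,0,0) present in reflection list")
        if not np.all(np.isfinite(self.value)):
            raise ReflectionError("non-finite observed values; clean first")
        self.d = d_spacings(self.hkl, self.cell)

    def __len__(self) -> int:
        return self.hkl.shape[0]

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    @property
    def d_max(self) -> float:
        return float(self.d.max())


def _clean(
    hkl: np.ndarray, value: np.ndarray, sigma: np.ndarray | None, label: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Drop reflections with non-finite value or negative/non-finite sigma.

    Negative observed intensities are kept: they are legitimate post-merging
    values and the percentile clipping downstream handles outliers.
    """
    keep = np.isfinite(value)
    keep &= ~np.all(hkl == 0, axis=1)
    if sigma is not None:
        keep &= np.isfinite(sigma) & (sigma >= 0)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("%s: dropped %d unusable reflections", label, n_drop)
    return hkl[keep], value[keep], None if sigma is None else sigma[keep]


# ---------------------------------------------------------------------------
# plain-text dialect

_TEXT_MAGIC = "# icering reflections v1"


def write_reflections(rset: ReflectionSet, path: str | Path) -> None:
    """Write the plain-text dialect.

    Format: a magic comment, ``cell a b c alpha beta gamma``, ``kind
    intensity|amplitude``, then one ``h k l value sigma`` row per reflection
    (sigma written as ``nan`` when absent).  Floats use repr precision so the
    round-trip is exact.
    """
    c = rset.cell
    lines = [
        _TEXT_MAGIC,
        "cell " + " ".join(repr(float(x)) for x in (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)),
        f"kind {rset.kind.value}",
    ]
    sig = rset.sigma if rset.sigma is not None else np.full(len(rset), np.nan)
    for (h, k, l), v, s in zip(rset.hkl, rset.value, sig):
        lines.append(f"{h} {k} {l} {float(v)!r} {float(s)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_text(path: Path, source_label: str) -> ReflectionSet:
    tokens: list[list[str]] = []
    cell: UnitCell | None = None
    kind: ValueKind | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "cell":
            cell = UnitCell(*(float(x) for x in parts[1:7]))
        elif parts[0] == "kind":
            kind = ValueKind(parts[1])
        else:
            tokens.append(parts)
    if cell is None or kind is None:
        raise ReflectionError(f"{path}: missing cell or kind header")
    if not tokens:
        raise ReflectionError(f"{path}: no reflections")
    arr = np.array([[float(x) for x in row[:5]] for row in tokens])
    hkl = arr[:, :3].astype(np.int64)
    value, sigma = arr[:, 3], arr[:, 4]
    sigma_opt = None if np.all(np.isnan(sigma)) else sigma
    hkl, value, sigma_opt = _clean(hkl, value, sigma_opt, str(path))
    return ReflectionSet(cell, kind, hkl, value, sigma_opt, source_label=source_label)


# ---------------------------------------------------------------------------
# MTZ

def _read_mtz(path: Path, source_label: str) -> ReflectionSet:
    import gemmi

    mtz = gemmi.read_mtz_file(str(path))
    cell = UnitCell(
        mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma
    )
    # Observed-intensity columns (MTZ type J) are preferred over amplitude
    # columns (type F); within a type the first column in file order wins,
    # which for multi-wavelength depositions is the first-listed dataset.
    chosen = None
    kind = None
    for ctype, vkind in (("J", ValueKind.INTENSITY), ("F", ValueKind.AMPLITUDE)):
        cols = [c for c in mtz.columns if c.type == ctype]
        if cols:
            chosen, kind = cols[0], vkind
            break
    if chosen is None:
        raise ReflectionError(f"{path}: no observed intensity or amplitude column")
    data = np.asarray(mtz, dtype=float)
    labels = [c.label for c in mtz.columns]
    hkl = data[:, [labels.index("H"), labels.index("K"), labels.index("L")]].astype(np.int64)
    value = data[:, labels.index(chosen.label)]
    sigma = None
    for sig_label in (f"SIG{chosen.label}", chosen.label.replace("F", "SIGF").replace("I", "SIGI")):
        if sig_label in labels:
            sigma = data[:, labels.index(sig_label)]
            break
    hkl, value, sigma = _clean(hkl, value, sigma, str(path))
    if hkl.shape[0] == 0:
        raise ReflectionError(f"{path}: no usable reflections")
    return ReflectionSet(cell, kind, hkl, value, sigma, source_label=source_label)


def read_reflections(path: str | Path) -> ReflectionSet:
    """Read reflections from MTZ or the plain-text dialect (by file signature).

    Intensity columns are preferred over amplitude columns; the set's
    ``kind`` records which observable was found.
    """
    path = Path(path)
    if not path.is_file():
        raise ReflectionError(f"no such file: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"MTZ ":
        return _read_mtz(path, source_label=path.name)
    return _read_text(path, source_label=path.name)
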