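"""Discrete 2-D cross-section of the nanochannel chip pressed onto nerve tissue.

The model rasterizes, onto a regular grid, a vertical slice through the
device-tissue interface: an electrolyte reservoir on top (the microchannel /
reservoir compartment, lumped into a single conductive band), a silicon plate
pierced by nanochannels, conical needles protruding from the plate's tissue
side, and nerve tissue below.  Each nanochannel is independently open
(electrolyte-filled) or blocked, sampled without replacement so that exactly
``round(open_fraction * n_nanochannels)`` channels conduct.

Coordinates follow image convention: row 0 is the reservoir (cathode) side,
the last row is deep tissue (anode side), so anionic cargo such as plasmid
DNA migrates downward into the nerve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import ConfigurationError, ResolutionError

__all__ = [
    "Material",
    "ChipSpec",
    "GridSpec",
    "MaterialGrid",
    "ConductivityGrid",
    "DEFAULT_CONDUCTIVITIES",
    "build_geometry",
    "tissue_mask",
    "conductivity_map",
]


class Material(IntEnum):
    """Cell material labels."""

    SILICON = 0
    LUMEN_OPEN = 1
    LUMEN_BLOCKED = 2
    RESERVOIR = 3
    TISSUE = 4


#: Default electrical conductivities in S/m.  The lumen and reservoir carry
#: physiological saline (~1.4 S/m), tissue a bulk nerve value (0.5 S/m), and
#: silicon / nitride-coated surfaces are treated as near-perfect insulators.
DEFAULT_CONDUCTIVITIES: dict[Material, float] = {
    Material.SILICON: 1e-12,
    Material.LUMEN_OPEN: 1.4,
    Material.LUMEN_BLOCKED: 1e-12,
    Material.RESERVOIR: 1.4,
    Material.TISSUE: 0.5,
}


@dataclass(frozen=True)
class ChipSpec:
    """Chip geometry in micrometres.

    Defaults are the fabricated device's nominal dimensions: 150 µm wide /
    185 µm deep microchannels, 0.9 µm wide / 11 µm deep nanochannels, and
    4 µm base / 4.5 µm high cones on a 200 µm wafer.  The microchannel
    dimensions are stored and validated but the 2-D raster lumps the
    microchannel/reservoir compartment into the conductive band above the
    nanochannel plate.
    """

    microchannel_width: float = 150.0
    microchannel_depth: float = 185.0
    nanochannel_width: float = 0.9
    nanochannel_depth: float = 11.0
    cone_base: float = 4.0
    cone_height: float = 4.5
    n_nanochannels: int = 20
    pitch: float = 6.0
    wafer_thickness: float = 200.0

    def __post_init__(self):
        lengths = {
            "microchannel_width": self.microchannel_width,
            "microchannel_depth": self.microchannel_depth,
            "nanochannel_width": self.nanochannel_width,
            "nanochannel_depth": self.nanochannel_depth,
            "cone_base": self.cone_base,
            "cone_height": self.cone_height,
            "pitch": self.pitch,
            "wafer_thickness": self.wafer_thickness,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ConfigurationError(f"ChipSpec.{name} must be > 0, got {value}")
        if self.n_nanochannels < 1:
            raise ConfigurationError("ChipSpec.n_nanochannels must be >= 1")
        if self.microchannel_depth + self.nanochannel_depth > self.wafer_thickness:
            raise ConfigurationError(
                "microchannel_depth + nanochannel_depth exceeds wafer_thickness"
            )


@dataclass(frozen=True)
class GridSpec:
    """Simulation grid: cell counts and physical extent (µm).

    The default 100 x 100 grid spans 120 µm x 120 µm, i.e. 1.2 µm cells,
    fine enough that a 0.9 µm nanochannel rounds to one cell.  Spacing must
    be isotropic.
    """

    n_rows: int = 100
    n_cols: int = 100
    extent_x: float = 120.0
    extent_y: float = 120.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ConfigurationError("grid extents must be positive")
        sx = self.extent_x / self.n_cols
        sy = self.extent_y / self.n_rows
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise ConfigurationError(
                f"anisotropic cell spacing not supported ({sx:g} x {sy:g} um)"
            )

    @property
    def spacing(self) -> float:
        """Cell size in µm (isotropic)."""
        return self.extent_y / self.n_rows


@dataclass
class MaterialGrid:
    """Label matrix plus the bookkeeping needed downstream.

    ``bands`` records the row ranges of reservoir / plate / cone regions;
    ``channel_cols`` holds per-channel ``(first_col, width_cells)``;
    ``open_channels`` the sorted indices of conducting channels;
    ``mouth_row`` the first row below the cone tips where the lumen opens
    into tissue.
    """

    labels: np.ndarray
    spacing: float
    open_fraction: float
    seed: int
    chip: ChipSpec
    grid: GridSpec
    bands: dict = field(default_factory=dict)
    channel_cols: list = field(default_factory=list)
    open_channels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    mouth_row: int = 0

    def mouth_cells(self) -> list[tuple[int, int]]:
        """(row, col) of each open channel's tissue-side mouth centre."""
        out = []
        for ch in self.open_channels:
            c0, w = self.channel_cols[ch]
            out.append((self.mouth_row, c0 + w // 2))
        return out

    def label_counts(self) -> dict[Material, int]:
        return {m: int(np.count_nonzero(self.labels == m)) for m in Material}


@dataclass
class ConductivityGrid:
    """Per-cell electrical conductivity (S/m) on the simulation grid."""

    sigma: np.ndarray
    spacing: float

    def __post_init__(self):
        if np.any(self.sigma < 0):
            raise ConfigurationError("conductivity must be non-negative")


def _cells(length_um: float, spacing: float) -> int:
    return int(round(length_um / spacing))


def build_geometry(
    chip: ChipSpec,
    grid: GridSpec,
    open_fraction: float = 0.65,
    seed: int = 0,
    reservoir_depth: float = 12.0,
) -> MaterialGrid:
    """Rasterize the chip-nerve cross-section and sample open channels.

    Parameters
    ----------
    chip, grid
        Geometry and discretization.
    open_fraction
        Fraction of nanochannels that conduct; exactly
        ``round(open_fraction * n_nanochannels)`` channels are opened,
        chosen by seeded uniform sampling without replacement.
    seed
        Seed for the channel selection; the build is bit-reproducible.
    reservoir_depth
        Depth (µm) of the lumped reservoir/microchannel band at the top.

    Raises
    ------
    ResolutionError
        If a nanochannel rounds to zero cells at this spacing, channels
        overlap or fall outside the grid, or no tissue rows remain.
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ConfigurationError("open_fraction must lie in [0, 1]")
    h = grid.spacing

    w_cells = _cells(chip.nanochannel_width, h)
    if w_cells < 1:
        raise ResolutionError(
            f"nanochannel width {chip.nanochannel_width} um rounds to 0 cells "
            f"at {h:g} um spacing; refine the grid"
        )

    r_res = _cells(reservoir_depth, h)
    r_plate = r_res + _cells(chip.nanochannel_depth, h)
    r_cone = r_plate + _cells(chip.cone_height, h)
    if r_plate <= r_res:
        raise ResolutionError("nanochannel plate rounds to 0 rows; refine the grid")
    if r_cone >= grid.n_rows:
        raise ResolutionError("no tissue rows remain below the chip at this extent")

    labels = np.full((grid.n_rows, grid.n_cols), Material.TISSUE, dtype=np.int8)
    labels[:r_res, :] = Material.RESERVOIR
    labels[r_res:r_plate, :] = Material.SILICON

    # Channel layout: n channels at the stated pitch, centred horizontally.
    span = (chip.n_nanochannels - 1) * chip.pitch
    start = (grid.extent_x - span) / 2.0
    channel_cols: list[tuple[int, int]] = []
    for i in range(chip.n_nanochannels):
        centre = start + i * chip.pitch
        c0 = int(round(centre / h - w_cells / 2.0))
        if c0 < 0 or c0 + w_cells > grid.n_cols:
            raise ResolutionError(
                f"channel {i} falls outside the grid; widen extent_x or reduce pitch"
            )
        channel_cols.append((c0, w_cells))
    for (a0, aw), (b0, _bw) in zip(channel_cols, channel_cols[1:]):
        if b0 < a0 + aw:
            raise ResolutionError("adjacent nanochannels overlap at this resolution")

    n_open = int(round(open_fraction * chip.n_nanochannels))
    rng = np.random.default_rng(seed)
    open_idx = np.sort(rng.choice(chip.n_nanochannels, size=n_open, replace=False))
    open_set = set(int(i) for i in open_idx)

    cone_rows = r_cone - r_plate
    for i, (c0, w) in enumerate(channel_cols):
        lumen = Material.LUMEN_OPEN if i in open_set else Material.LUMEN_BLOCKED
        labels[r_res:r_plate, c0 : c0 + w] = lumen
        centre_col = c0 + (w - 1) / 2.0
        for d in range(cone_rows):
            # staircase cone: width tapers linearly from the base to the tip
            width_um = chip.cone_base * (1.0 - (d + 0.5) / cone_rows)
            cw = max(_cells(width_um, h), 0)
            if cw > 0:
                cc0 = int(round(centre_col - (cw - 1) / 2.0))
                cc0 = max(cc0, 0)
                labels[r_plate + d, cc0 : min(cc0 + cw, grid.n_cols)] = Material.SILICON
            # lumen continues through the cone core
            labels[r_plate + d, c0 : c0 + w] = lumen

    return MaterialGrid(
        labels=labels,
        spacing=h,
        open_fraction=open_fraction,
        seed=seed,
        chip=chip,
        grid=grid,
        bands={"reservoir": (0, r_res), "plate": (r_res, r_plate), "cone": (r_plate, r_cone)},
        channel_cols=channel_cols,
        open_channels=open_idx,
        mouth_row=r_cone,
    )


def tissue_mask(grid: GridSpec, orientation: str = "lower_left") -> np.ndarray:
    """Lower-triangular nerve-tissue domain mask.

    True exactly where ``row >= col`` (default orientation), i.e. the lower
    triangle including the diagonal: n(n+1)/2 cells on an n x n grid.
    ``orientation='lower_right'`` mirrors the triangle horizontally.
    """
    if orientation not in ("lower_left", "lower_right"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    rows = np.arange(grid.n_rows)[:, None]
    cols = np.arange(grid.n_cols)[None, :]
    if orientation == "lower_left":
        return rows >= cols
    return rows >= (grid.n_cols - 1 - cols)


def conductivity_map(
    materials: MaterialGrid,
    props: dict[Material, float] | None = None,
) -> ConductivityGrid:
    """Map material labels to per-cell conductivity (S/m) by table lookup."""
    if props is None:
        props = DEFAULT_CONDUCTIVITIES
    present = np.unique(materials.labels)
    lut = np.zeros(len(Material), dtype=float)
    for m in present:
        mat = Material(int(m))
        if mat not in props:
            raise ConfigurationError(f"no conductivity given for material {mat.name}")
        lut[mat] = props[mat]
    if any(props.get(m, 0.0) < 0 for m in Material):
        raise ConfigurationError("conductivities must be non-negative")
    sigma = lut[materials.labels]
    return ConductivityGrid(sigma=sigma.astype(float), spacing=materials.spacing)
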