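"""Virtual tissue volumes of point-like fluorescent cells, and stack rendering.

The digital-sectioning experiments all run on programmatically generated
"virtual volumes": a tissue slab of thickness S um holding point
fluorophores, each with a depth from the original top surface, an optional
lateral (u, v) position, and per-cell optical parameters.  Three families
are provided:

* *compliant* volumes satisfying the model's assumptions exactly — one
  cell per 1-um depth bin (at bin centres), identical intensity and
  attenuation, unique lateral positions (no overlap);
* *perturbed* volumes where per-cell attenuation or intensity receives a
  zero-mean normal deviate, emulating inhomogeneous tissue or variable
  cell brightness;
* *overlap* volumes where cells land uniformly at random on a discrete
  lateral column grid, so that the subsurface tails of cells sharing a
  column can merge.

:func:`render_image_stack` turns a volume into a synthetic block-face
grayscale image stack (exponential subsurface decay, optional additive
noise), the fixture format consumed by the stack pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .model import UM_PER_CM, surface_intensity

__all__ = [
    "ModelCell",
    "VirtualVolume",
    "ImageStack",
    "EmptyVolumeError",
    "build_compliant_volume",
    "build_spaced_volume",
    "perturb_attenuation",
    "perturb_intensity",
    "build_overlap_volume",
    "render_image_stack",
]


class EmptyVolumeError(ValueError):
    """Raised when an operation requires a volume with at least one cell."""


@dataclass(frozen=True)
class ModelCell:
    """A single point fluorophore inside the tissue slab."""

    id: int
    depth: float  # um from the original top surface
    intensity: float  # per-cell I_fluo, gray levels
    attenuation: float  # per-cell mu_T, cm^-1
    lateral: tuple[float, float] | None = None  # (u, v) in um


@dataclass
class VirtualVolume:
    """A tissue slab with its cells stored as parallel numpy arrays.

    ``laterals`` is an (N, 2) array of (u, v) positions in um, or None for
    depth-only simulations.  ``provenance`` records generator parameters
    and seeds so that every volume is reproducible.
    """

    thickness: float  # S, um
    ids: np.ndarray
    depths: np.ndarray
    intensities: np.ndarray
    attenuations: np.ndarray
    laterals: np.ndarray | None = None
    cell_spacing: float | None = None  # t, um, for regular placements
    area_cm2: float | None = None
    density: float | None = None  # cells/cm^2
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.depths = np.asarray(self.depths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.attenuations = np.asarray(self.attenuations, dtype=float)
        n = self.ids.size
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if len({a.shape[0] for a in (self.depths, self.intensities, self.attenuations)} | {n}) != 1:
            raise ValueError("cell arrays must have equal length")
        if np.unique(self.ids).size != n:
            raise ValueError("cell ids must be unique")
        if np.any(self.depths < 0) or np.any(self.depths >= self.thickness):
            raise ValueError("cell depths must lie in [0, thickness)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if np.any(self.attenuations <= 0):
            raise ValueError("attenuations must be > 0")
        if self.laterals is not None:
            self.laterals = np.asarray(self.laterals, dtype=float)
            if self.laterals.shape != (n, 2):
                raise ValueError("laterals must be an (N, 2) array")

    @property
    def n_cells(self) -> int:
        return int(self.ids.size)

    @property
    def cells(self) -> Iterator[ModelCell]:
        for i in range(self.n_cells):
            lat = tuple(self.laterals[i]) if self.laterals is not None else None
            yield ModelCell(
                id=int(self.ids[i]),
                depth=float(self.depths[i]),
                intensity=float(self.intensities[i]),
                attenuation=float(self.attenuations[i]),
                lateral=lat,
            )

    def subsurface_lengths(self, threshold: float) -> np.ndarray:
        """Per-cell detectable tail length e (um); -inf for cells below T."""
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.log(self.intensities / threshold) / self.attenuations * UM_PER_CM
        return np.where(self.intensities >= threshold, e, -np.inf)

    def to_frame(self):
        """One row per cell: id, depth_um, u_um, v_um, intensity, attenuation_cm1."""
        import pandas as pd

        lat = self.laterals if self.laterals is not None else np.full((self.n_cells, 2), np.nan)
        return pd.DataFrame(
            {
                "id": self.ids,
                "depth_um": self.depths,
                "u_um": lat[:, 0],
                "v_um": lat[:, 1],
                "intensity": self.intensities,
                "attenuation_cm1": self.attenuations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, thickness: float) -> "VirtualVolume":
        import pandas as pd

        df = pd.read_csv(path)
        laterals = None
        if not df[["u_um", "v_um"]].isna().any().any():
            laterals = df[["u_um", "v_um"]].to_numpy()
        return cls(
            thickness=thickness,
            ids=df["id"].to_numpy(),
            depths=df["depth_um"].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            attenuations=df["attenuation_cm1"].to_numpy(),
            laterals=laterals,
        )


def _grid_laterals(n: int, spacing: float) -> np.ndarray:
    """Unique lateral positions on a square grid with the given pitch (um)."""
    ncols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    return np.column_stack(((idx % ncols) * spacing, (idx // ncols) * spacing)).astype(float)


def build_compliant_volume(
    thickness: float,
    intensity: float,
    attenuation: float,
    lateral_spacing: float = 30.0,
) -> VirtualVolume:
    """Volume satisfying all model assumptions: one cell per 1-um depth bin.

    Cells sit at bin centres (i - 0.5 um for i = 1..S), so N = S.  All
    share the same intensity and attenuation, and each occupies a distinct
    lateral grid position (no signal overlap).
    """
    if thickness <= 0 or thickness != int(thickness):
        raise ValueError("thickness must be a positive integer number of um")
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    n = int(thickness)
    return VirtualVolume(
        thickness=float(thickness),
        ids=np.arange(n),
        depths=np.arange(n) + 0.5,
        intensities=np.full(n, float(intensity)),
        attenuations=np.full(n, float(attenuation)),
        laterals=_grid_laterals(n, lateral_spacing),
        cell_spacing=1.0,
        provenance={
            "kind": "compliant",
            "thickness_um": float(thickness),
            "intensity": float(intensity),
            "attenuation_cm1": float(attenuation),
            "lateral_spacing_um": float(lateral_spacing),
        },
    )


def build_spaced_volume(
    thickness: float,
    n_cells: int,
    spacing: float,
    intensity: float,
    attenuation: float,
    lateral_spacing: float = 30.0,
) -> VirtualVolume:
    """N cells at a fixed depth interval t, at (i - 1/2) t for i = 1..N.

    The worked-example configuration: non-overlapping cells evenly spaced
    through the slab, one per depth interval.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    depths = (np.arange(n_cells) + 0.5) * spacing
    if depths[-1] >= thickness:
        raise ValueError("cells do not fit inside the volume at this spacing")
    return VirtualVolume(
        thickness=float(thickness),
        ids=np.arange(n_cells),
        depths=depths,
        intensities=np.full(n_cells, float(intensity)),
        attenuations=np.full(n_cells, float(attenuation)),
        laterals=_grid_laterals(n_cells, lateral_spacing),
        cell_spacing=float(spacing),
        provenance={
            "kind": "spaced",
            "thickness_um": float(thickness),
            "n_cells": int(n_cells),
            "spacing_um": float(spacing),
            "intensity": float(intensity),
            "attenuation_cm1": float(attenuation),
        },
    )


def perturb_attenuation(volume: VirtualVolume, sigma: float, seed: int) -> VirtualVolume:
    """Give each cell an attenuation of base + N(0, sigma), clipped at 1 cm^-1.

    Emulates inhomogeneous tissue (a mix of tissue types along the sample).
    The clip keeps the coefficient physical; sigma = 0 returns the volume
    unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    new = dataclasses.replace(volume)
    if sigma == 0:
        return new
    rng = np.random.default_rng(seed)
    new.attenuations = np.clip(
        volume.attenuations + rng.normal(0.0, sigma, volume.n_cells), 1.0, None
    )
    new.provenance = {
        **volume.provenance,
        "attenuation_sigma_cm1": float(sigma),
        "attenuation_seed": int(seed),
    }
    return new


def perturb_intensity(volume: VirtualVolume, sigma: float, seed: int) -> VirtualVolume:
    """Give each cell an intensity of base + N(0, sigma), clipped at 0.

    Emulates brightness variability (label loss, photobleaching, cell
    division...).  Cells falling below the detection threshold become
    permanently undetectable at any slice thickness.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    new = dataclasses.replace(volume)
    if sigma == 0:
        return new
    rng = np.random.default_rng(seed)
    new.intensities = np.clip(
        volume.intensities + rng.normal(0.0, sigma, volume.n_cells), 0.0, None
    )
    new.provenance = {
        **volume.provenance,
        "intensity_sigma": float(sigma),
        "intensity_seed": int(seed),
    }
    return new


def build_overlap_volume(
    thickness: float,
    density: float,
    area_cm2: float,
    intensity: float,
    attenuation: float,
    seed: int,
    grid_shape: tuple[int, int] = (100, 100),
    min_depth_separation: float = 1.0,
) -> VirtualVolume:
    """Randomly placed cells on a discrete lateral column grid.

    N = round(density * area) cells receive uniform depths on
    [0, thickness) and uniform positions on a ``grid_shape`` column grid
    over the area, so distinct cells can share a lateral column and their
    subsurface tails can merge.  Within a shared column, depths closer
    than ``min_depth_separation`` (default 1 um) are redrawn, so that
    sectioning at 1 um always resolves every cell.
    """
    if density <= 0 or area_cm2 <= 0:
        raise ValueError("density and area must be > 0")
    n = int(round(density * area_cm2))
    if n == 0:
        raise EmptyVolumeError("density * area rounds to zero cells")
    rng = np.random.default_rng(seed)
    side_um = np.sqrt(area_cm2) * UM_PER_CM
    pitch = (side_um / grid_shape[0], side_um / grid_shape[1])
    cols = rng.integers(0, grid_shape[0], n)
    rows = rng.integers(0, grid_shape[1], n)
    depths = rng.uniform(0.0, thickness, n)
    col_key = cols * grid_shape[1] + rows
    for _ in range(1000):
        order = np.lexsort((depths, col_key))
        same_col = col_key[order][1:] == col_key[order][:-1]
        too_close = np.diff(depths[order]) < min_depth_separation
        bad = order[1:][same_col & too_close]
        if bad.size == 0:
            break
        depths[bad] = rng.uniform(0.0, thickness, bad.size)
    else:  # pragma: no cover - only reachable at absurd densities
        raise RuntimeError("could not satisfy the per-column depth separation")
    laterals = np.column_stack((cols * pitch[0], rows * pitch[1]))
    return VirtualVolume(
        thickness=float(thickness),
        ids=np.arange(n),
        depths=depths,
        intensities=np.full(n, float(intensity)),
        attenuations=np.full(n, float(attenuation)),
        laterals=laterals,
        area_cm2=float(area_cm2),
        density=float(density),
        provenance={
            "kind": "overlap",
            "thickness_um": float(thickness),
            "density_cells_per_cm2": float(density),
            "area_cm2": float(area_cm2),
            "intensity": float(intensity),
            "attenuation_cm1": float(attenuation),
            "grid_shape": list(grid_shape),
            "min_depth_separation_um": float(min_depth_separation),
            "seed": int(seed),
        },
    )


@dataclass
class ImageStack:
    """Block-face grayscale volume: slices x rows x cols, with metadata."""

    voxels: np.ndarray
    slice_thickness: float  # X, um
    pixel_size: float  # um
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a slices x rows x cols array")
        if np.any(self.voxels < 0):
            raise ValueError("voxel values must be >= 0")
        if self.slice_thickness <= 0 or self.pixel_size <= 0:
            raise ValueError("slice_thickness and pixel_size must be > 0")

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])


def _disc_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr**2 + dc**2 <= r**2
    return np.column_stack((dr[keep], dc[keep]))


def render_image_stack(
    volume: VirtualVolume,
    slice_thickness: float,
    pixel_size: float,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    footprint_radius: int = 0,
    shape: tuple[int, int] | None = None,
) -> ImageStack:
    """Render the slice-and-image acquisition of a virtual volume.

    One image is produced per block-face at depths 0, X, 2X, ... (the face
    before the first cut is imaged), ceil(S/X) in total.  A cell still in
    the block (cell depth >= face depth; a cell exactly at the cut plane
    is just exposed, at maximal brightness) contributes its attenuated
    surface intensity at its lateral pixel; contributions meeting at one
    pixel sum.  Optional additive Gaussian noise is clipped at zero.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if volume.laterals is None:
        raise ValueError("the volume needs lateral positions to be rendered")
    margin = int(footprint_radius)
    rr = np.rint(volume.laterals[:, 1] / pixel_size).astype(int) + margin
    cc = np.rint(volume.laterals[:, 0] / pixel_size).astype(int) + margin
    if shape is None:
        shape = (int(rr.max()) + margin + 1, int(cc.max()) + margin + 1) if rr.size else (1, 1)
    elif rr.size and (rr.max() + margin >= shape[0] or cc.max() + margin >= shape[1]):
        raise ValueError("pixel grid is smaller than the lateral extent of the volume")
    n_slices = int(np.ceil(volume.thickness / slice_thickness))
    voxels = np.full((n_slices, *shape), float(background))
    offsets = _disc_offsets(footprint_radius)
    for k in range(n_slices):
        z = k * slice_thickness
        present = volume.depths >= z
        if present.any():
            vals = surface_intensity(
                volume.intensities[present],
                volume.attenuations[present],
                volume.depths[present] - z,
            )
            for dr, dc in offsets:
                np.add.at(voxels[k], (rr[present] + dr, cc[present] + dc), vals)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        voxels = np.clip(voxels + rng.normal(0.0, noise_sd, voxels.shape), 0.0, None)
    return ImageStack(
        voxels=voxels,
        slice_thickness=float(slice_thickness),
        pixel_size=float(pixel_size),
        provenance={
            "generator": "render_image_stack",
            "volume": dict(volume.provenance),
            "n_cells": volume.n_cells,
            "background": float(background),
            "noise_sd": float(noise_sd),
            "seed": int(seed),
            "footprint_radius_px": int(footprint_radius),
        },
    )
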