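"""Digital sectioning of virtual volumes and sensitivity-curve diagnostics.

The sectioning engine walks the block-faces of a virtual volume at depths
0, X, 2X, ... (the face before the first cut is imaged) and, at each face,
marks every remaining cell whose attenuated surface signal reaches the
detection threshold.  A cell counts once no matter how many faces see its
subsurface tail:

* in depth-only / non-overlapping volumes, de-duplication is by cell
  identity (each cell has its own lateral position, so its detections can
  never merge with a neighbour's);
* in overlap volumes, cells sharing a lateral column are merged when no
  block-face separates them — the count per column is the number of
  distinct disappearance events among detectable cells, which is exactly
  what connected-component grouping of the rendered signal would resolve.

Thickness and intensity sweeps produce :class:`SensitivityCurve` objects,
from which the empirical optimal thickness (breakpoint) and the log-log
slope of the sub-optimal tail are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import surface_intensity
from .volume import EmptyVolumeError, VirtualVolume, build_compliant_volume

__all__ = [
    "DetectionReport",
    "SensitivityCurve",
    "run_digital_sectioning",
    "run_overlap_sectioning",
    "sweep_thickness",
    "sweep_intensity",
    "find_optimal_thickness",
    "fit_loglog_slope",
    "averaged_sweep",
]


@dataclass
class DetectionReport:
    """Truth versus detection for one sectioning run."""

    n_true: int
    n_detected: int
    slice_thickness: float
    first_face: np.ndarray  # per-cell first block-face index seen, -1 if never
    last_face: np.ndarray  # per-cell last block-face index seen, -1 if never

    def __post_init__(self) -> None:
        if not 0 <= self.n_detected <= self.n_true:
            raise ValueError("n_detected must be in [0, n_true]")

    @property
    def n_missed(self) -> int:
        return self.n_true - self.n_detected

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_true


@dataclass
class SensitivityCurve:
    """Paired sweep-value / sensitivity / count series.

    ``values`` ascend and are slice thicknesses (um) for a thickness sweep
    or cell intensities (gray) for an intensity sweep.
    """

    values: np.ndarray
    sensitivities: np.ndarray
    counts: np.ndarray
    n_true: int
    sweep_kind: str  # "thickness" | "intensity"
    sensitivity_sd: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (self.values.size == self.sensitivities.size == self.counts.size):
            raise ValueError("curve series must have equal length")
        if np.any(self.sensitivities < 0) or np.any(self.sensitivities > 1):
            raise ValueError("sensitivities must lie in [0, 1]")
        if self.sweep_kind not in ("thickness", "intensity"):
            raise ValueError("sweep_kind must be 'thickness' or 'intensity'")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "sweep_value": self.values,
                "sensitivity": self.sensitivities,
                "count": self.counts,
                "n_true": np.full(self.values.size, self.n_true),
                "replicate": np.full(self.values.size, self.provenance.get("replicates", 1)),
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _block_faces(thickness: float, slice_thickness: float) -> np.ndarray:
    """Depths of the imaged block-faces: 0, X, 2X, ... while material remains."""
    n_faces = int(np.ceil(thickness / slice_thickness))
    return np.arange(n_faces) * slice_thickness


def run_digital_sectioning(
    volume: VirtualVolume, slice_thickness: float, threshold: float
) -> DetectionReport:
    """Section a volume at thickness X and count detected cells by identity.

    At each block-face z every remaining cell (depth >= z) whose surface
    intensity reaches the threshold is marked detected; a cell counts once
    regardless of how many faces see it.  Valid under the non-overlap
    assumption (unique lateral positions).
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if volume.n_cells == 0:
        raise EmptyVolumeError("volume holds no cells")
    n = volume.n_cells
    first = np.full(n, -1)
    last = np.full(n, -1)
    # cells dimmer than the threshold are undetectable at every depth
    bright = volume.intensities >= threshold
    for k, z in enumerate(_block_faces(volume.thickness, slice_thickness)):
        present = bright & (volume.depths >= z)
        if not (volume.depths >= z).any():
            break
        seen = np.zeros(n, dtype=bool)
        if present.any():
            seen[present] = (
                surface_intensity(
                    volume.intensities[present],
                    volume.attenuations[present],
                    volume.depths[present] - z,
                )
                >= threshold
            )
        first[seen & (first < 0)] = k
        last[seen] = k
    return DetectionReport(
        n_true=n,
        n_detected=int((first >= 0).sum()),
        slice_thickness=float(slice_thickness),
        first_face=first,
        last_face=last,
    )


def run_overlap_sectioning(
    volume: VirtualVolume, slice_thickness: float, threshold: float
) -> DetectionReport:
    """Section a volume whose cells may share lateral columns.

    Cells in the same column whose signals are never separated by a
    block-face merge into one detection: the count per column is the
    number of distinct disappearance events (distinct slabs of detectable
    cells).  At X = 1 um any placement with >= 1 um depth separation is
    fully resolved.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if volume.laterals is None:
        raise ValueError("overlap sectioning needs lateral positions")
    if volume.n_cells == 0:
        raise EmptyVolumeError("volume holds no cells")
    n = volume.n_cells
    x_at_last_face = np.mod(volume.depths, slice_thickness)
    detectable = x_at_last_face <= volume.subsurface_lengths(threshold)
    slab = np.floor(volume.depths / slice_thickness).astype(int)
    _, col = np.unique(volume.laterals, axis=0, return_inverse=True)
    pairs = np.unique(np.column_stack((col[detectable], slab[detectable])), axis=0)
    last = np.where(detectable, slab, -1)
    return DetectionReport(
        n_true=n,
        n_detected=int(pairs.shape[0]),
        slice_thickness=float(slice_thickness),
        first_face=last.copy(),  # per-column grouping: the disappearance face
        last_face=last,
    )


def sweep_thickness(
    volume: VirtualVolume,
    thickness_list,
    threshold: float,
    counting: str = "identity",
) -> SensitivityCurve:
    """Run one sectioning per thickness on the same frozen volume.

    ``counting`` selects identity de-duplication (non-overlapping volumes)
    or the per-column merge rule (``"overlap"``).
    """
    thicknesses = np.sort(np.asarray(list(thickness_list), dtype=float))
    if thicknesses.size == 0 or np.any(thicknesses <= 0):
        raise ValueError("thickness_list must be non-empty and positive")
    runner = {"identity": run_digital_sectioning, "overlap": run_overlap_sectioning}[counting]
    counts = np.array([runner(volume, x, threshold).n_detected for x in thicknesses])
    return SensitivityCurve(
        values=thicknesses,
        sensitivities=counts / volume.n_cells,
        counts=counts,
        n_true=volume.n_cells,
        sweep_kind="thickness",
        provenance={"counting": counting, "threshold": threshold, **volume.provenance},
    )


def sweep_intensity(
    thickness: float,
    intensity_list,
    attenuation: float,
    threshold: float,
    volume_thickness: float,
) -> SensitivityCurve:
    """Fix the slice thickness, vary the cell intensity.

    One compliant volume and one sectioning run per intensity; cells dimmer
    than the threshold yield zero sensitivity, and sensitivity reaches 1
    once the intensity passes the optimal intensity T exp(mu_T X).
    """
    intensities = np.sort(np.asarray(list(intensity_list), dtype=float))
    if intensities.size == 0 or np.any(intensities <= 0):
        raise ValueError("intensity_list must be non-empty and positive")
    counts = []
    for i in intensities:
        vol = build_compliant_volume(volume_thickness, i, attenuation)
        counts.append(run_digital_sectioning(vol, thickness, threshold).n_detected)
    counts = np.asarray(counts)
    n_true = int(volume_thickness)
    return SensitivityCurve(
        values=intensities,
        sensitivities=counts / n_true,
        counts=counts,
        n_true=n_true,
        sweep_kind="intensity",
        provenance={
            "slice_thickness_um": float(thickness),
            "attenuation_cm1": float(attenuation),
            "threshold": float(threshold),
            "volume_thickness_um": float(volume_thickness),
        },
    )


def find_optimal_thickness(curve: SensitivityCurve, tolerance: float = 0.0) -> float:
    """Largest swept thickness whose sensitivity is >= 1 - tolerance (um)."""
    if curve.sweep_kind != "thickness":
        raise ValueError("breakpoint search needs a thickness sweep")
    ok = curve.sensitivities >= 1.0 - tolerance - 1e-12
    if not ok.any():
        raise LookupError("no swept thickness attains the sensitivity criterion")
    return float(curve.values[ok].max())


def fit_loglog_slope(curve: SensitivityCurve, thickness_range: tuple[float, float]) -> float:
    """OLS slope of log(sensitivity) vs log(thickness) on (lo, hi].

    The sub-optimal branch of a compliant curve has slope -1; attenuation
    variability flattens it toward 0 while intensity variability does not.
    """
    lo, hi = thickness_range
    keep = (curve.values > lo) & (curve.values <= hi) & (curve.sensitivities > 0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive-sensitivity points in the range")
    slope, _ = np.polyfit(np.log(curve.values[keep]), np.log(curve.sensitivities[keep]), 1)
    return float(slope)


def averaged_sweep(
    volumes: list[VirtualVolume],
    thickness_list,
    threshold: float,
    counting: str = "identity",
) -> SensitivityCurve:
    """Mean sensitivity curve over replicate volumes (e.g. perturbation seeds).

    The member volumes are typically the same base volume perturbed with a
    list of seeds; the returned curve carries the per-thickness standard
    deviation across replicates.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    curves = [sweep_thickness(v, thickness_list, threshold, counting) for v in volumes]
    sens = np.vstack([c.sensitivities for c in curves])
    counts = np.vstack([c.counts for c in curves])
    return SensitivityCurve(
        values=curves[0].values,
        sensitivities=sens.mean(axis=0),
        counts=counts.mean(axis=0),
        n_true=curves[0].n_true,
        sweep_kind="thickness",
        sensitivity_sd=sens.std(axis=0, ddof=1) if len(volumes) > 1 else None,
        provenance={"replicates": len(volumes), **curves[0].provenance},
    )
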