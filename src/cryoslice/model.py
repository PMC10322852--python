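"""Closed-form optics of fluorescent-cell detection under block-face sectioning.

In slice-and-image (cryo-imaging) systems, a fluorophore sitting at depth
``x`` below the freshly exposed block-face is imaged through the overlying
tissue.  Absorption and scattering of both the excitation and the emission
light are collapsed into one effective Beer-Lambert attenuation, so the
signal reaching the camera is

    I(x) = I_fluo * exp(-mu_T * x)

where ``I_fluo`` is the unattenuated cell intensity (gray levels) and
``mu_T`` the effective tissue attenuation coefficient (cm^-1).  A cell is
detected when ``I(x) >= T`` for a detector threshold ``T``.  Everything
else in this module follows from that pair of statements: the optimal
(largest loss-free) slice thickness, the minimum loss-free cell intensity
at a fixed thickness, the piecewise sensitivity-versus-thickness law and
its log-log linearization, the expected detected count under uniform cell
placement, the under-sampling correction factor, and the generalisations
to mixed cell intensities and non-uniform depth distributions.

Unit contract
-------------
Attenuation coefficients are stored in cm^-1, exactly as practitioners
quote them; all depths and thicknesses are in micrometres.  The
micrometre-to-centimetre factor (1e-4) is applied in exactly one place,
:func:`surface_intensity`, and in the closed-form inverses that mirror it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UM_PER_CM",
    "OpticalParams",
    "DepthDistribution",
    "IntensityMixture",
    "UndetectableCellError",
    "EmptySliceError",
    "surface_intensity",
    "is_detected",
    "optimal_thickness",
    "discrete_optimal_thickness",
    "optimal_intensity",
    "subsurface_length",
    "sensitivity_piecewise",
    "expected_count",
    "corrected_count",
    "mixture_sensitivity",
    "distribution_sensitivity",
    "pool_distributions",
]

#: micrometres per centimetre; depth arguments are um, attenuation is cm^-1
UM_PER_CM = 1.0e4


class UndetectableCellError(ValueError):
    """Raised when cells are dimmer than the detection threshold.

    Such cells are lost at every depth, independently of slice thickness;
    no optimal thickness exists for them.
    """


class EmptySliceError(ValueError):
    """Raised when a depth distribution carries no mass inside the slice."""


@dataclass(frozen=True)
class OpticalParams:
    """The composite optical triple governing detectability.

    Parameters
    ----------
    cell_intensity
        Unattenuated cell signal I_fluo at the block-face (gray levels).
    attenuation
        Effective tissue attenuation coefficient mu_T (cm^-1), combining
        excitation- and emission-path absorption and scattering.
    threshold
        Detector threshold T (gray levels).
    """

    cell_intensity: float
    attenuation: float
    threshold: float

    def __post_init__(self) -> None:
        if self.cell_intensity <= 0:
            raise ValueError(f"cell_intensity must be > 0, got {self.cell_intensity}")
        if self.attenuation <= 0:
            raise ValueError(f"attenuation must be > 0, got {self.attenuation}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")


def surface_intensity(cell_intensity, attenuation, depth):
    """Signal at the block-face from a cell ``depth`` um below it.

    Evaluates ``I(x) = I_fluo * exp(-mu_T * x)`` with ``mu_T`` in cm^-1 and
    ``x`` in um.  Accepts scalars or numpy arrays (broadcasting).

    Raises
    ------
    ValueError
        If any depth is negative or any parameter non-positive.
    """
    cell_intensity = np.asarray(cell_intensity, dtype=float)
    attenuation = np.asarray(attenuation, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(cell_intensity <= 0):
        raise ValueError("cell_intensity must be > 0")
    if np.any(attenuation <= 0):
        raise ValueError("attenuation must be > 0")
    if np.any(depth < 0):
        raise ValueError("depth must be >= 0")
    out = cell_intensity * np.exp(-attenuation * depth / UM_PER_CM)
    return out if out.ndim else float(out)


def is_detected(intensity, threshold):
    """Detection criterion ``I(x) >= T`` (inclusive at the boundary)."""
    intensity = np.asarray(intensity, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if np.any(intensity < 0) or np.any(threshold < 0):
        raise ValueError("intensity and threshold must be >= 0")
    out = intensity >= threshold
    return out if out.ndim else bool(out)


def optimal_thickness(params: OpticalParams) -> float:
    """Largest loss-free slice thickness, X_optimal = -ln(T/I_fluo)/mu_T (um).

    This is the depth at which the block-face signal has decayed exactly to
    the threshold; cells anywhere inside a slice no thicker than this are
    all detected.

    Raises
    ------
    UndetectableCellError
        If the cells are dimmer than the threshold: they are never detected
        and no finite loss-free thickness exists.
    """
    if params.cell_intensity < params.threshold:
        raise UndetectableCellError(
            f"cell_intensity {params.cell_intensity} is below threshold "
            f"{params.threshold}: such cells are lost at any slice thickness"
        )
    return math.log(params.cell_intensity / params.threshold) / params.attenuation * UM_PER_CM


def subsurface_length(params: OpticalParams) -> float:
    """Length e of a cell's detectable subsurface tail; identical to X_optimal."""
    return optimal_thickness(params)


def discrete_optimal_thickness(params: OpticalParams, bin_width: float = 1.0) -> float:
    """Optimal thickness as seen by a simulation with binned cell depths (um).

    With one cell per ``bin_width`` um placed at bin centres, the breakpoint
    of the sensitivity-thickness curve is the number of bin centres within
    the continuous X_optimal, i.e. ``floor(X_optimal/w + 1/2) * w``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    x_opt = optimal_thickness(params)
    return float(math.floor(x_opt / bin_width + 0.5 + 1e-12)) * bin_width


def optimal_intensity(threshold: float, attenuation: float, slice_thickness: float) -> float:
    """Minimum loss-free cell intensity at a fixed thickness, T*exp(mu_T*X).

    The inverse of :func:`optimal_thickness`: cells at least this bright are
    all detected when sectioning at ``slice_thickness`` um.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if attenuation <= 0:
        raise ValueError("attenuation must be > 0")
    if slice_thickness < 0:
        raise ValueError("slice_thickness must be >= 0")
    return threshold * math.exp(attenuation * slice_thickness / UM_PER_CM)


def sensitivity_piecewise(slice_thickness: float, x_optimal: float) -> float:
    """Detection sensitivity n/N under uniform cell placement.

    Equals 1 for ``X <= X_optimal`` and ``X_optimal / X`` beyond; the
    function is continuous at the breakpoint, and on log-log axes the
    sub-optimal branch is a line of slope -1.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if x_optimal < 0:
        raise ValueError("x_optimal must be >= 0")
    if slice_thickness <= x_optimal:
        return 1.0
    return x_optimal / slice_thickness


def expected_count(subsurface_length: float, slice_thickness: float, n_cells: int) -> int:
    """Expected detected count n = ceil((e/X) N), capped at N.

    Over-sampling (X <= e) resolves every cell (connected-component grouping
    removes the duplicates), hence the cap.
    """
    if subsurface_length <= 0 or slice_thickness <= 0 or n_cells <= 0:
        raise ValueError("all arguments must be > 0")
    raw = subsurface_length / slice_thickness * n_cells
    # guard against float noise pushing an exact ratio over the next integer
    return min(int(n_cells), math.ceil(raw - 1e-9))


def corrected_count(observed_count: float, sensitivity: float) -> float:
    """Under-sampling correction Count(X_optimal) = Count(X) / Sens(X).

    Returns a real-valued estimate; rounding is left to reporting.
    """
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    if sensitivity == 0:
        raise ZeroDivisionError("sensitivity is 0: the corrected count is undefined")
    if not 0 < sensitivity <= 1:
        raise ValueError(f"sensitivity must be in (0, 1], got {sensitivity}")
    return observed_count / sensitivity


@dataclass(frozen=True)
class IntensityMixture:
    """Cell population with K discrete intensity groups (I_fluo_j, N_j)."""

    groups: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("mixture must contain at least one group")
        object.__setattr__(self, "groups", tuple((float(i), int(n)) for i, n in self.groups))
        for intensity, count in self.groups:
            if count <= 0:
                raise ValueError("group_count must be > 0")
            if intensity <= 0:
                raise ValueError("group_intensity must be > 0")

    @property
    def n_total(self) -> int:
        return sum(n for _, n in self.groups)


def mixture_sensitivity(
    mixture: IntensityMixture,
    slice_thickness: float,
    attenuation: float,
    threshold: float,
) -> float:
    """Population sensitivity Sens = sum_j (N_j/N) Sens(I_fluo_j).

    Groups dimmer than the threshold contribute zero regardless of slice
    thickness; detectable groups contribute their piecewise sensitivity.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    total = mixture.n_total
    acc = 0.0
    for intensity, count in mixture.groups:
        if intensity < threshold:
            continue  # permanently undetectable group
        x_opt = optimal_thickness(OpticalParams(intensity, attenuation, threshold))
        acc += count / total * sensitivity_piecewise(slice_thickness, x_opt)
    return acc


@dataclass(frozen=True)
class DepthDistribution:
    """Probability density p(x) of cell depth within a slice, on a fixed grid.

    ``grid`` holds ascending depth values (um, >= 0) and ``density`` the
    density per um at each grid point; the trapezoidal integral over the
    grid must be 1 within 1e-6.  ``components`` optionally records the
    (count, density) pairs this distribution was pooled from.
    """

    grid: np.ndarray
    density: np.ndarray
    components: tuple[tuple[int, np.ndarray], ...] | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)
        if grid.ndim != 1 or grid.shape != density.shape:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if grid.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if grid[0] < 0:
            raise ValueError("grid depths must be >= 0")
        if np.any(density < 0):
            raise ValueError("density must be >= 0 everywhere")
        total = float(np.trapezoid(density, grid))
        if not (1 - 1e-6 <= total <= 1 + 1e-6):
            raise ValueError(f"density must integrate to 1 (got {total:.8f})")

    @staticmethod
    def uniform(upper: float, resolution: float = 0.1) -> "DepthDistribution":
        """Uniform density on [0, upper] at the given grid resolution (um)."""
        n = max(2, int(round(upper / resolution)) + 1)
        grid = np.linspace(0.0, upper, n)
        return DepthDistribution(grid, np.full(n, 1.0 / upper))


def _partial_integral(grid: np.ndarray, density: np.ndarray, upper: float) -> float:
    """Trapezoidal integral of the density from 0 to ``upper``."""
    inside = grid < upper
    xs = np.append(grid[inside], upper)
    ys = np.interp(xs, grid, density)
    return float(np.trapezoid(ys, xs))


def distribution_sensitivity(
    dist: DepthDistribution, slice_thickness: float, x_optimal: float
) -> float:
    """Sensitivity as the ratio of p(x) integrals over [0, X_opt] and [0, X].

    Reduces to the piecewise law for a uniform density; computed by
    deterministic trapezoidal quadrature on the stored grid (with the two
    cut points added as interpolation nodes).
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if x_optimal >= slice_thickness:
        return 1.0
    if dist.grid[-1] < slice_thickness - 1e-9:
        raise ValueError(
            f"distribution grid ends at {dist.grid[-1]} um but the slice is "
            f"{slice_thickness} um thick"
        )
    denom = _partial_integral(dist.grid, dist.density, slice_thickness)
    if denom <= 0:
        raise EmptySliceError("no cell-depth probability mass inside the slice")
    num = _partial_integral(dist.grid, dist.density, x_optimal)
    return min(1.0, num / denom)


def pool_distributions(
    components: list[tuple[int, DepthDistribution]],
) -> DepthDistribution:
    """Pool per-slice depth densities, p(x) = sum_i (N_i/N) p_i(x).

    All components must share the same grid; the weights are the per-slice
    cell counts normalised by the total.
    """
    if len(components) == 0:
        raise ValueError("need at least one component")
    counts = [int(n) for n, _ in components]
    if any(n <= 0 for n in counts):
        raise ValueError("component counts must be > 0")
    grid = components[0][1].grid
    for _, dist in components[1:]:
        if not np.array_equal(dist.grid, grid):
            raise ValueError("all components must share the same depth grid")
    total = sum(counts)
    density = np.zeros_like(grid)
    for n, dist in components:
        density += (n / total) * dist.density
    return DepthDistribution(
        grid, density, components=tuple((n, d.density) for n, d in components)
    )
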