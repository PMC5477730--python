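"""Dose-volume histogram computation and plan metric extraction.

Doses live on a scalar voxel grid in Gy with a prescription reference
(70 Gy by default, the conventional definitive head-and-neck prescription).
Metrics follow the Dx% convention: D95% is the dose received by at least 95%
of a structure's volume, read off a cumulative DVH with linear interpolation
between bin edges.  Plans are normalized so that the target's D95% equals the
prescription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .structures import (
    GridMismatchError,
    StructureMask,
    read_scalar_nrrd,
    write_scalar_nrrd,
)

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "DoseMetrics",
    "OarComparison",
    "compute_dvh",
    "dose_at_volume",
    "hotspot_outside",
    "normalize_to_d95",
    "extract_metrics",
    "compare_oar_metrics",
]

DEFAULT_PRESCRIPTION = 70.0  # Gy
DEFAULT_BIN_WIDTH = 0.01  # Gy; Table-style one-decimal % needs <=0.07 Gy
HOTSPOT_VOLUME_CM3 = 0.03


@dataclass
class DoseGrid:
    """Scalar dose grid (Gy) with the same voxel-center geometry as masks."""

    origin: np.ndarray
    spacing: np.ndarray
    dose: np.ndarray
    prescription: float = DEFAULT_PRESCRIPTION

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be a 3D array")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape

    def same_grid(self, mask: StructureMask) -> bool:
        return (
            self.shape == mask.shape
            and np.allclose(self.origin, mask.origin)
            and np.allclose(self.spacing, mask.spacing)
        )

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.origin.copy(), self.spacing.copy(), self.dose * factor, self.prescription)

    def save_nrrd(self, path) -> None:
        write_scalar_nrrd(self.dose, self.origin, self.spacing, path)

    @classmethod
    def load_nrrd(cls, path, prescription: float = DEFAULT_PRESCRIPTION) -> "DoseGrid":
        arr, origin, spacing = read_scalar_nrrd(path)
        return cls(origin, spacing, arr, prescription)


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= dose.

    ``cumulative_volume_fraction[j]`` is the fraction at ``dose_edges[j]``;
    the curve is non-increasing and equals 1.0 at dose 0.
    """

    dose_edges: np.ndarray
    cumulative_volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.cumulative_volume_fraction = np.asarray(
            self.cumulative_volume_fraction, dtype=float
        )
        if np.any(np.diff(self.cumulative_volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    """Dose values at the mask's occupied voxel centers.

    When grids coincide this is direct indexing; otherwise the dose is
    trilinearly resampled at the mask's voxel centers.
    """
    if mask.is_empty:
        raise ValueError("structure mask is empty")
    if dose.same_grid(mask):
        return dose.dose[mask.occupancy]
    centers = mask.centers()[mask.occupancy.ravel()]
    coords = (centers - dose.origin) / dose.spacing
    return map_coordinates(dose.dose, coords.T, order=1, mode="nearest")


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVHCurve:
    """Cumulative DVH from voxel-center dose values (default 0.01 Gy bins)."""
    vals = _structure_doses(dose, mask)
    n_bins = int(np.ceil(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    frac = np.concatenate([(counts[::-1].cumsum()[::-1] / len(vals)), [0.0]])
    return DVHCurve(dose_edges=edges, cumulative_volume_fraction=frac)


def dose_at_volume(dvh: DVHCurve, volume_fraction: float) -> float:
    """Dx%: largest dose with cumulative fraction >= ``volume_fraction``.

    Linearly interpolated between the bracketing bin edges.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume fraction must be in (0, 1]")
    frac = dvh.cumulative_volume_fraction
    edges = dvh.dose_edges
    above = np.flatnonzero(frac >= volume_fraction)
    if len(above) == 0:
        return 0.0
    j = above[-1]
    if j + 1 >= len(edges) or frac[j] == frac[j + 1]:
        return float(edges[j])
    t = (frac[j] - volume_fraction) / (frac[j] - frac[j + 1])
    return float(edges[j] + t * (edges[j + 1] - edges[j]))


def hotspot_outside(
    dose: DoseGrid,
    target: StructureMask,
    volume_cm3: float = HOTSPOT_VOLUME_CM3,
) -> float:
    """Dose (Gy) to the hottest ``volume_cm3`` outside the target.

    Whole voxels are accumulated from the hottest downwards until the
    threshold volume is reached; the returned value is the minimum dose among
    those voxels (D_{volume} of the target complement).  No partial-voxel
    interpolation is performed, keeping results bit-stable.
    """
    if not dose.same_grid(target):
        raise GridMismatchError("dose and target grids differ")
    outside = dose.dose[~target.occupancy]
    voxel_mm3 = float(np.prod(dose.spacing))
    needed = volume_cm3 * 1000.0
    if outside.size * voxel_mm3 < needed:
        raise ValueError("target complement smaller than hot-spot volume")
    n_vox = int(np.ceil(needed / voxel_mm3))
    hottest = np.partition(outside, outside.size - n_vox)[outside.size - n_vox :]
    return float(hottest.min())


def _exact_dose_at_fraction(vals: np.ndarray, volume_fraction: float) -> float:
    """Largest dose received by at least ``volume_fraction`` of the voxels.

    Exact order statistic (no binning): used for normalization so that
    normalizing is idempotent and commutes with uniform scaling.
    """
    n = len(vals)
    k = int(np.ceil(volume_fraction * n))
    return float(np.sort(vals)[::-1][k - 1])


def normalize_to_d95(
    dose: DoseGrid,
    target: StructureMask,
    prescription: float | None = None,
) -> DoseGrid:
    """Scale the whole grid so the target's D95% equals the prescription.

    D95% is taken as the exact empirical quantile of the target's voxel
    doses (rather than read off the binned curve), which makes the operation
    exactly idempotent and scale-invariant.
    """
    rx = dose.prescription if prescription is None else prescription
    d95 = _exact_dose_at_fraction(_structure_doses(dose, target), 0.95)
    if d95 <= 0:
        raise ValueError("target D95% is zero; cannot normalize")
    out = dose.scaled(rx / d95)
    out.prescription = rx
    return out


@dataclass
class DoseMetrics:
    """Dx% metrics in percent of prescription, plus the external hot spot."""

    d2: float
    d5: float
    d95: float
    d98: float
    hotspot_outside: float | None = None

    def __post_init__(self) -> None:
        if not self.d2 >= self.d5 >= self.d95 >= self.d98 >= 0:
            raise ValueError("Dx metrics must satisfy d2 >= d5 >= d95 >= d98 >= 0")

    def as_mapping(self) -> dict[str, float]:
        out = {"d2": self.d2, "d5": self.d5, "d95": self.d95, "d98": self.d98}
        if self.hotspot_outside is not None:
            out["hotspot"] = self.hotspot_outside
        return out


def extract_metrics(
    dose: DoseGrid,
    structure: StructureMask,
    target_for_hotspot: StructureMask | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DoseMetrics:
    """D2/D5/D95/D98 (% of prescription) for a structure, and optionally the
    hot spot outside a target."""
    dvh = compute_dvh(dose, structure, bin_width)
    pct = 100.0 / dose.prescription
    hotspot = None
    if target_for_hotspot is not None:
        hotspot = hotspot_outside(dose, target_for_hotspot) * pct
    return DoseMetrics(
        d2=dose_at_volume(dvh, 0.02) * pct,
        d5=dose_at_volume(dvh, 0.05) * pct,
        d95=dose_at_volume(dvh, 0.95) * pct,
        d98=dose_at_volume(dvh, 0.98) * pct,
        hotspot_outside=hotspot,
    )


@dataclass
class OarComparison:
    """Absolute per-metric OAR dose differences between two plans."""

    differences: pd.DataFrame  # index: OAR, columns: metric names
    median: float
    min: float
    max: float


def compare_oar_metrics(
    metrics_a: dict[str, dict[str, float]],
    metrics_b: dict[str, dict[str, float]],
) -> OarComparison:
    """Compare per-OAR metric maps (values in % of prescription).

    Differences are absolute, in percentage points of the prescription; the
    summary aggregates the median/min/max across all OAR-metric pairs.
    """
    if set(metrics_a) != set(metrics_b):
        raise KeyError("OAR sets differ between plans")
    rows = {}
    for oar in sorted(metrics_a):
        if set(metrics_a[oar]) != set(metrics_b[oar]):
            raise KeyError(f"metric names differ for OAR {oar!r}")
        rows[oar] = {
            m: abs(metrics_a[oar][m] - metrics_b[oar][m]) for m in metrics_a[oar]
        }
    # OARs may carry different metric names (Dmax vs Dmean); summarize over
    # the defined entries only
    vals = np.array([v for row in rows.values() for v in row.values()])
    return OarComparison(
        differences=pd.DataFrame(rows).T,
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
    )
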