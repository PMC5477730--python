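"""Optional DICOM readers: RTSTRUCT contours to masks, RTDOSE to dose grids.

Single-dialect by design: RTSTRUCT is expected to carry one CLOSED_PLANAR
contour per axial slice per ROI (no holes, no out-of-plane contours), the
common export shape of clinical planning systems.  Anything else should be
converted upstream.
"""

from __future__ import annotations

import numpy as np
import pydicom
import shapely

from .dosimetry import DEFAULT_PRESCRIPTION, DoseGrid
from .structures import StructureMask

__all__ = ["read_rtstruct_masks", "read_rtdose"]


def read_rtstruct_masks(path, template: StructureMask) -> dict[str, StructureMask]:
    """Rasterize every ROI of an RTSTRUCT file onto ``template``'s grid.

    Returns a mapping ROI name → mask.  Voxel centers strictly inside a
    slice's contour polygon are occupied; contours are matched to the nearest
    template slice (within half a slice spacing).
    """
    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    xs = template.axis_centers(0)
    ys = template.axis_centers(1)
    zs = template.axis_centers(2)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    out: dict[str, StructureMask] = {}
    for roi in ds.ROIContourSequence:
        occ = np.zeros(template.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            if str(getattr(contour, "ContourGeometricType", "CLOSED_PLANAR")) != "CLOSED_PLANAR":
                raise ValueError("only CLOSED_PLANAR contours are supported")
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.median(pts[:, 2]))
            k = int(np.argmin(np.abs(zs - z)))
            if abs(zs[k] - z) > template.spacing[2] / 2 + 1e-6:
                continue
            poly = shapely.Polygon(pts[:, :2])
            occ[:, :, k] |= shapely.contains_xy(
                poly, gx.ravel(), gy.ravel()
            ).reshape(gx.shape)
        name = names.get(int(roi.ReferencedROINumber), str(roi.ReferencedROINumber))
        out[name] = template.with_occupancy(occ)
    return out


def read_rtdose(path, prescription: float = DEFAULT_PRESCRIPTION) -> DoseGrid:
    """Read an RTDOSE file (grid scaling applied) into a :class:`DoseGrid`."""
    ds = pydicom.dcmread(str(path))
    dose = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)  # (z, y, x)
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(np.diff(offsets).mean()) if len(offsets) > 1 else 1.0
    spacing = np.array([col_spacing, row_spacing, dz])
    return DoseGrid(origin, spacing, dose.transpose(2, 1, 0), prescription)
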