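"""Synthetic head-and-neck phantom: paired S/L targets, barriers, and doses.

The generator emulates the geometric situation in which window-based
delineation differences arise: a C-shaped soft-tissue target (annular sector)
wrapping a cylindrical air cavity inside a cylindrical "neck".  The
soft-tissue-window structure (GTV_S) is the plain sector; the lung-window
structure (GTV_L) additionally carries an "iceberg" — a radial extension
toward the air cavity over part of the C's angular extent, the region where
tumor blends into the air interface and only becomes visible on a lung
window.  The iceberg depth is either given directly or solved so the L/S
volume increase hits a configured fraction (default 9%).

Plans are stood in for by an analytic conformal dose: prescription times a
logistic function of the signed Euclidean distance to the target surface
(penumbra scale ``penumbra_sigma``), normalized so the target's D95% equals
the prescription.  Plan_S conforms to CTV_S and Plan_L to CTV_L, so CTV_Δ
(= CTV_L − CTV_S) lies in Plan_S's penumbra by construction.

All randomness (HU texture, cohort parameter draws) is seeded; the same seed
reproduces bit-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dosimetry import DEFAULT_PRESCRIPTION, DoseGrid, normalize_to_d95
from .structures import (
    LUNG_WINDOW,
    BarrierSet,
    StructureMask,
    build_ctv,
    mask_to_mesh,
    subtract,
    write_mask_nrrd,
    write_scalar_nrrd,
)
from scipy.ndimage import distance_transform_edt

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "generate_conformal_dose",
    "generate_cohort",
    "solve_iceberg_depth",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic S/L structure and dose generator.

    Lengths in mm, angles in degrees, doses in Gy.  The target is an annular
    sector (inner/outer radius, angular extent, z-extent) centered on the
    air-cavity axis (the z-axis); the iceberg extends the inner radius toward
    the cavity over the central ``iceberg_angular_fraction`` of the sector.
    Exactly one of ``iceberg_depth`` / ``volume_increase_fraction`` drives
    the L structure; when the fraction is given the depth is solved exactly.
    """

    # grid
    origin: tuple = (-48.0, -48.0, -31.0)
    spacing: tuple = (1.0, 1.0, 2.0)
    shape: tuple = (96, 96, 32)
    # anatomy
    body_radius: float = 45.0
    cavity_radius: float = 4.0
    bone_center: tuple = (0.0, -38.0)
    bone_radius: float = 7.0
    # target
    inner_radius: float = 16.0
    outer_radius: float = 27.0
    angular_extent_deg: float = 270.0
    z_extent: float = 28.0
    iceberg_angular_fraction: float = 1.0 / 3.0
    iceberg_depth: float | None = None
    volume_increase_fraction: float | None = 0.09
    # planning
    margin: float = 8.0
    penumbra_sigma: float = 3.0
    prescription: float = DEFAULT_PRESCRIPTION
    seed: int = 0


def solve_iceberg_depth(spec: PhantomSpec) -> float:
    """Iceberg depth realizing a :class:`PhantomSpec` (given directly or
    solved from the volume-increase fraction).

    For an annular sector of angular extent φ, the iceberg over a sub-extent
    φ_ice adds ΔV = (φ_ice/2)·d·(2·r_in − d)·h, so the fractional increase
    f = ΔV/V_S inverts to ``d = r_in − sqrt(r_in² − f·(φ/φ_ice)·(r_out² −
    r_in²))``.  Raises if the requested extension would cross the air cavity.
    """
    gap = spec.inner_radius - spec.cavity_radius
    if spec.iceberg_depth is not None:
        d = float(spec.iceberg_depth)
    else:
        if spec.volume_increase_fraction is None:
            raise ValueError("need iceberg_depth or volume_increase_fraction")
        f = spec.volume_increase_fraction
        ring = spec.outer_radius**2 - spec.inner_radius**2
        disc = spec.inner_radius**2 - f / spec.iceberg_angular_fraction * ring
        if disc < 0:
            raise ValueError("volume-increase fraction unreachable for this sector")
        d = spec.inner_radius - float(np.sqrt(disc))
    if d < 0:
        raise ValueError("iceberg depth must be non-negative")
    if d > gap + 1e-9:
        raise ValueError(
            f"iceberg depth {d:.2f} mm exceeds the {gap:.2f} mm gap to the air cavity"
        )
    return d


def _analytic_volumes(spec: PhantomSpec, depth: float) -> dict[str, float]:
    phi = np.radians(spec.angular_extent_deg)
    ring = spec.outer_radius**2 - spec.inner_radius**2
    v_s = 0.5 * phi * ring * spec.z_extent
    dv = (
        0.5
        * phi
        * spec.iceberg_angular_fraction
        * depth
        * (2 * spec.inner_radius - depth)
        * spec.z_extent
    )
    return {
        "gtv_s_volume_mm3": v_s,
        "gtv_l_volume_mm3": v_s + dv,
        "volume_increase_fraction": dv / v_s,
        "iceberg_depth_mm": depth,
        "hd_gtv_mm": depth,
    }


@dataclass
class PhantomBundle:
    """One generated phantom: image, structures, barriers, plans, truth.

    ``ground_truth`` carries the exact analytic volumes, the iceberg depth
    (which equals the S/L Hausdorff distance of the parametric shapes) and the
    achieved volume-increase fraction.
    """

    spec: PhantomSpec
    origin: np.ndarray
    spacing: np.ndarray
    hu: np.ndarray
    gtv_s: StructureMask
    gtv_l: StructureMask
    barriers: BarrierSet
    ctv_s: StructureMask
    ctv_l: StructureMask
    ctv_delta: StructureMask
    dose_plan_s: DoseGrid
    dose_plan_l: DoseGrid
    ground_truth: dict = field(default_factory=dict)

    def save(self, outdir) -> dict:
        """Serialize the bundle (NRRD grids, STL target meshes, JSON truth).

        Returns a manifest of written file names.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        write_scalar_nrrd(self.hu, self.origin, self.spacing, outdir / "hu.nrrd")
        files["hu"] = "hu.nrrd"
        masks = {
            "gtv_s": self.gtv_s,
            "gtv_l": self.gtv_l,
            "ctv_s": self.ctv_s,
            "ctv_l": self.ctv_l,
            "ctv_delta": self.ctv_delta,
            "barrier_air": self.barriers.air,
            "barrier_bone": self.barriers.bone,
            "barrier_anatomical": self.barriers.anatomical,
        }
        for name, m in masks.items():
            write_mask_nrrd(m, outdir / f"{name}.nrrd")
            files[name] = f"{name}.nrrd"
        for name, d in (("dose_plan_s", self.dose_plan_s), ("dose_plan_l", self.dose_plan_l)):
            d.save_nrrd(outdir / f"{name}.nrrd")
            files[name] = f"{name}.nrrd"
        for name in ("gtv_s", "gtv_l"):
            mask_to_mesh(masks[name]).save(outdir / f"{name}.stl")
            files[f"{name}_mesh"] = f"{name}.stl"
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2)
        )
        files["ground_truth"] = "ground_truth.json"
        return files


def generate_conformal_dose(
    target: StructureMask,
    penumbra_sigma: float = 3.0,
    prescription: float = DEFAULT_PRESCRIPTION,
) -> DoseGrid:
    """Analytic conformal dose around a target with a logistic penumbra.

    The dose is ``Rx · σ((s0 − s)/w)`` of the signed Euclidean distance s to
    the target surface (positive outside), with penumbra scale
    ``w = penumbra_sigma/2`` and an outward shift ``s0 = 2.4·penumbra_sigma``
    that keeps the whole target in the flat shoulder; the grid is then
    normalized so the target's D95% equals the prescription.  Voxels beyond
    5·penumbra_sigma outside receive <5% of the prescription.
    """
    if target.is_empty:
        raise ValueError("cannot plan on an empty target")
    occ = target.occupancy
    d_out = distance_transform_edt(~occ, sampling=target.spacing)
    d_in = distance_transform_edt(occ, sampling=target.spacing)
    signed = d_out - d_in
    w = penumbra_sigma / 2.0
    s0 = 2.4 * penumbra_sigma
    with np.errstate(over="ignore"):
        dose = prescription / (1.0 + np.exp((signed - s0) / w))
    grid = DoseGrid(target.origin, target.spacing, dose, prescription)
    return normalize_to_d95(grid, target, prescription)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Build one phantom bundle; deterministic given ``spec.seed``.

    HU ranges: air cavity [−1000, −950], soft tissue [20, 60], bone
    [800, 1200], outside the body −1000.  The air barrier is defined through
    the lung-window preset ([−1000, 0] HU) restricted to the body, the
    anatomical barrier is the body's exterior, and the bone barrier is the
    bone cylinder.
    """
    spec = spec or PhantomSpec()
    depth = solve_iceberg_depth(spec)
    template = StructureMask.empty(spec.origin, spec.spacing, spec.shape)
    xs = template.axis_centers(0)
    ys = template.axis_centers(1)
    zs = template.axis_centers(2)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    r = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)

    body = r <= spec.body_radius
    cavity = r <= spec.cavity_radius
    bone = (
        np.hypot(gx - spec.bone_center[0], gy - spec.bone_center[1])
        <= spec.bone_radius
    ) & body

    phi_half = np.radians(spec.angular_extent_deg) / 2.0
    in_sector = np.abs(theta) <= phi_half
    in_z = np.abs(gz) <= spec.z_extent / 2.0
    gtv_s_occ = (
        (r >= spec.inner_radius) & (r <= spec.outer_radius) & in_sector & in_z
    )
    ice_half = phi_half * spec.iceberg_angular_fraction
    iceberg = (
        (r >= spec.inner_radius - depth)
        & (r < spec.inner_radius)
        & (np.abs(theta) <= ice_half)
        & in_z
    )
    gtv_l_occ = gtv_s_occ | iceberg

    rng = np.random.default_rng(spec.seed)
    hu = np.full(spec.shape, -1000.0)
    hu[body] = rng.uniform(20.0, 60.0, int(body.sum()))
    hu[cavity & body] = rng.uniform(-1000.0, -950.0, int((cavity & body).sum()))
    hu[bone] = rng.uniform(800.0, 1200.0, int(bone.sum()))

    air_occ = body & LUNG_WINDOW.contains(hu)
    barriers = BarrierSet(
        air=template.with_occupancy(air_occ),
        bone=template.with_occupancy(bone),
        anatomical=template.with_occupancy(~body),
    )
    gtv_s = template.with_occupancy(gtv_s_occ)
    gtv_l = template.with_occupancy(gtv_l_occ)
    if (gtv_l.occupancy & barriers.air.occupancy).any():
        raise ValueError("GTV_L intersects the air cavity")

    ctv_s = build_ctv(gtv_s, spec.margin, barriers)
    ctv_l = build_ctv(gtv_l, spec.margin, barriers)
    ctv_delta = subtract(ctv_l, ctv_s)

    dose_s = generate_conformal_dose(ctv_s, spec.penumbra_sigma, spec.prescription)
    dose_l = generate_conformal_dose(ctv_l, spec.penumbra_sigma, spec.prescription)

    truth = _analytic_volumes(spec, depth)
    truth["measured_volume_increase_fraction"] = (
        gtv_l.volume_mm3 - gtv_s.volume_mm3
    ) / gtv_s.volume_mm3
    return PhantomBundle(
        spec=spec,
        origin=template.origin,
        spacing=template.spacing,
        hu=hu,
        gtv_s=gtv_s,
        gtv_l=gtv_l,
        barriers=barriers,
        ctv_s=ctv_s,
        ctv_l=ctv_l,
        ctv_delta=ctv_delta,
        dose_plan_s=dose_s,
        dose_plan_l=dose_l,
        ground_truth=truth,
    )


#: Uniform half-ranges the cohort generator draws from (around the defaults).
COHORT_RANGES = {
    "inner_radius": (16.0, 18.0),
    "outer_ring": (9.0, 11.0),  # outer_radius = inner_radius + outer_ring
    "z_extent": (24.0, 32.0),
    "angular_extent_deg": (240.0, 300.0),
    "volume_increase_fraction": (0.05, 0.13),
    "penumbra_sigma": (2.5, 3.5),
}


def generate_cohort(
    n: int,
    base: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomBundle]:
    """Seeded cohort of phantoms with parameters drawn uniformly from
    :data:`COHORT_RANGES`; per-bundle HU seeds are fixed offsets of ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    bundles = []
    for i in range(n):
        inner = rng.uniform(*COHORT_RANGES["inner_radius"])
        spec = replace(
            base,
            inner_radius=inner,
            outer_radius=inner + rng.uniform(*COHORT_RANGES["outer_ring"]),
            z_extent=rng.uniform(*COHORT_RANGES["z_extent"]),
            angular_extent_deg=rng.uniform(*COHORT_RANGES["angular_extent_deg"]),
            volume_increase_fraction=rng.uniform(
                *COHORT_RANGES["volume_increase_fraction"]
            ),
            penumbra_sigma=rng.uniform(*COHORT_RANGES["penumbra_sigma"]),
            iceberg_depth=None,
            seed=seed * 1000 + i,
        )
        bundles.append(generate_phantom(spec))
    return bundles
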