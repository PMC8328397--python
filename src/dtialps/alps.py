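"""ALPS index computation: ROI geometry, directional diffusivities, QC.

The diffusion-along-perivascular-space (ALPS) index probes water mobility
along the left-right (x) axis — the direction deep medullary veins and their
perivascular spaces run at the level of the lateral-ventricle body — using
two white-matter sites where the fiber axis is orthogonal to x:

* **projection fibers** (principal axis inferior-superior, z), and
* **association fibers** (principal axis anterior-posterior, y).

In each, diffusivity along x mixes perivascular and isotropic contributions
while the non-fiber, non-x axis (y for projection, z for association) serves
as the reference.  The index is::

    ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)

computed from the diagonal tensor elements averaged over four 7-voxel
crosshair ROIs (left/right x projection/association).  A value of 1 means no
preferential perivascular diffusion; healthy white matter typically sits
around 1.4-1.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MNI_2MM, GeometryError, TensorVolume, VolumeGeometry

__all__ = [
    "DEFAULT_ROI_CENTERS_MNI",
    "RoiSet",
    "DiffusivitySample",
    "QcReport",
    "AlpsResult",
    "AlpsComputationError",
    "make_crosshair_roi",
    "default_roi_set",
    "mean_diffusivities",
    "alps_index",
    "compute_alps",
    "orientation_qc",
    "wmh_overlap",
    "brain_to_icv",
]

#: Crosshair centers on the 2 mm MNI152 grid (0-based voxel indices):
#: left association, left projection, right association, right projection.
DEFAULT_ROI_CENTERS_MNI = {
    "left_assoc": (25, 52, 50),
    "left_proj": (31, 52, 50),
    "right_assoc": (64, 52, 50),
    "right_proj": (58, 52, 50),
}

ROI_LABELS = ("left_assoc", "left_proj", "right_assoc", "right_proj")

#: Expected principal-fiber axis per ROI kind: z for projection, y for
#: association fibers.
_EXPECTED_AXIS = {"proj": np.array([0.0, 0.0, 1.0]), "assoc": np.array([0.0, 1.0, 0.0])}


class AlpsComputationError(ValueError):
    """Raised when diffusivity extraction or the ALPS ratio is degenerate."""


def make_crosshair_roi(
    center: tuple[int, int, int], geometry: VolumeGeometry
) -> frozenset[tuple[int, int, int]]:
    """The 7-voxel 3-D crosshair: a center voxel plus its six face neighbors.

    At 2 mm isotropic resolution this is the 56 mm^3 ROI of the standard
    ALPS protocol.  Raises if any of the 7 voxels would fall outside the
    grid — ROIs are never silently clipped.
    """
    center = tuple(int(c) for c in center)
    offsets = [(0, 0, 0)]
    for ax in range(3):
        for step in (-1, 1):
            off = [0, 0, 0]
            off[ax] = step
            offsets.append(tuple(off))
    voxels = frozenset(tuple(c + o for c, o in zip(center, off)) for off in offsets)
    outside = [v for v in voxels if not geometry.contains(v)]
    if outside:
        raise GeometryError(
            f"crosshair at center {center} leaves the grid {geometry.shape}: {sorted(outside)}"
        )
    return voxels


@dataclass(frozen=True)
class RoiSet:
    """The four ALPS ROIs as voxel-index sets, keyed by label."""

    rois: dict[str, frozenset[tuple[int, int, int]]]
    centers: dict[str, tuple[int, int, int]]
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        if set(self.rois) != set(ROI_LABELS) or set(self.centers) != set(ROI_LABELS):
            raise ValueError(f"RoiSet requires exactly the labels {ROI_LABELS}")
        seen: set[tuple[int, int, int]] = set()
        for label in ROI_LABELS:
            vox = self.rois[label]
            if len(vox) < 1:
                raise ValueError(f"ROI {label!r} is empty")
            for v in vox:
                if not self.geometry.contains(v):
                    raise GeometryError(f"ROI {label!r} voxel {v} outside grid")
            if seen & set(vox):
                raise ValueError(f"ROI {label!r} overlaps another ROI")
            seen |= set(vox)

    @property
    def all_voxels(self) -> frozenset[tuple[int, int, int]]:
        out: set[tuple[int, int, int]] = set()
        for vox in self.rois.values():
            out |= set(vox)
        return frozenset(out)

    def shifted(self, shifts: dict[str, tuple[int, int, int]]) -> "RoiSet":
        """Return a copy with each ROI translated by its integer shift."""
        new_rois = {}
        new_centers = {}
        for label in ROI_LABELS:
            s = shifts.get(label, (0, 0, 0))
            new_centers[label] = tuple(c + d for c, d in zip(self.centers[label], s))
            new_rois[label] = frozenset(
                tuple(v + d for v, d in zip(vox, s)) for vox in self.rois[label]
            )
        return RoiSet(rois=new_rois, centers=new_centers, geometry=self.geometry)


def default_roi_set(
    geometry: VolumeGeometry = MNI_2MM,
    centers: dict[str, tuple[int, int, int]] | None = None,
) -> RoiSet:
    """Build the four default 7-voxel crosshair ROIs.

    Without ``centers`` the standard-protocol coordinates on the 2 mm MNI
    grid are used; phantom grids pass their own centers.
    """
    if centers is None:
        centers = DEFAULT_ROI_CENTERS_MNI
    missing = set(ROI_LABELS) - set(centers)
    if missing:
        raise ValueError(f"centers missing labels: {sorted(missing)}")
    rois = {label: make_crosshair_roi(centers[label], geometry) for label in ROI_LABELS}
    return RoiSet(rois=rois, centers={k: tuple(centers[k]) for k in ROI_LABELS}, geometry=geometry)


def mean_diffusivities(
    tensors: TensorVolume, roi
) -> tuple[float, float, float]:
    """Arithmetic means of (Dxx, Dyy, Dzz) over the ROI voxels."""
    roi = sorted(roi)
    if not roi:
        raise AlpsComputationError("ROI is empty")
    idx = np.array(roi)
    for v in roi:
        if not tensors.geometry.contains(v):
            raise GeometryError(f"ROI voxel {v} outside tensor grid {tensors.geometry.shape}")
    diag = tensors.diagonal()[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not np.isfinite(diag).all():
        raise AlpsComputationError(f"non-finite diffusivities inside ROI of {len(roi)} voxels")
    means = diag.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def alps_index(dx_proj: float, dx_assoc: float, dy_proj: float, dz_assoc: float) -> float:
    """The ALPS ratio: mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)."""
    for name, v in (
        ("Dx_proj", dx_proj),
        ("Dx_assoc", dx_assoc),
        ("Dy_proj", dy_proj),
        ("Dz_assoc", dz_assoc),
    ):
        if not np.isfinite(v) or v < 0:
            raise AlpsComputationError(f"{name} must be finite and >= 0, got {v}")
    denom = (dy_proj + dz_assoc) / 2.0
    if denom <= 0:
        raise AlpsComputationError("degenerate diffusivities: zero denominator in ALPS ratio")
    return ((dx_proj + dx_assoc) / 2.0) / denom


@dataclass(frozen=True)
class DiffusivitySample:
    """Per-hemisphere directional diffusivities entering the ALPS ratio."""

    hemisphere: str
    dx_proj: float
    dy_proj: float
    dx_assoc: float
    dz_assoc: float
    n_voxels: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class QcRoiEntry:
    alignment_fraction: float
    shift: tuple[int, int, int]
    n_valid: int
    n_total: int
    passed: bool


@dataclass(frozen=True)
class QcReport:
    """Orientation QC: per-ROI principal-eigenvector alignment and shift."""

    entries: dict[str, QcRoiEntry]
    angle_tol_deg: float
    pass_threshold: float

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries.values())


@dataclass(frozen=True)
class AlpsResult:
    alps_left: float
    alps_right: float
    alps_mean: float
    left: DiffusivitySample
    right: DiffusivitySample
    qc: QcReport | None = None

    def to_dict(self) -> dict:
        out = {
            "alps_left": self.alps_left,
            "alps_right": self.alps_right,
            "alps_mean": self.alps_mean,
        }
        for samp in (self.left, self.right):
            h = samp.hemisphere
            out[f"dx_proj_{h}"] = samp.dx_proj
            out[f"dy_proj_{h}"] = samp.dy_proj
            out[f"dx_assoc_{h}"] = samp.dx_assoc
            out[f"dz_assoc_{h}"] = samp.dz_assoc
        if self.qc is not None:
            out["qc"] = {
                label: {
                    "alignment_fraction": e.alignment_fraction,
                    "shift": list(e.shift),
                    "passed": e.passed,
                }
                for label, e in self.qc.entries.items()
            }
        return out


def _hemisphere_sample(tensors: TensorVolume, rois: RoiSet, hemi: str) -> DiffusivitySample:
    proj = rois.rois[f"{hemi}_proj"]
    assoc = rois.rois[f"{hemi}_assoc"]
    try:
        dxx_p, dyy_p, _ = mean_diffusivities(tensors, proj)
        dxx_a, _, dzz_a = mean_diffusivities(tensors, assoc)
    except AlpsComputationError as exc:
        raise AlpsComputationError(f"{hemi} hemisphere: {exc}") from exc
    return DiffusivitySample(
        hemisphere=hemi,
        dx_proj=dxx_p,
        dy_proj=dyy_p,
        dx_assoc=dxx_a,
        dz_assoc=dzz_a,
        n_voxels={"proj": len(proj), "assoc": len(assoc)},
    )


def compute_alps(
    tensors: TensorVolume,
    rois: RoiSet,
    qc_angle_tol_deg: float = 20.0,
    qc_pass_threshold: float = 0.8,
    with_qc: bool = True,
) -> AlpsResult:
    """Per-hemisphere ALPS (each by the ratio formula) and their mean.

    Each hemisphere's index is computed from its own ratio first and the two
    ratios are then averaged — matching the bilateral protocol in which the
    left and right indices are also reported separately.
    """
    left = _hemisphere_sample(tensors, rois, "left")
    right = _hemisphere_sample(tensors, rois, "right")
    alps_left = alps_index(left.dx_proj, left.dx_assoc, left.dy_proj, left.dz_assoc)
    alps_right = alps_index(right.dx_proj, right.dx_assoc, right.dy_proj, right.dz_assoc)
    qc = None
    if with_qc:
        _, qc = orientation_qc(
            tensors,
            rois,
            angle_tol_deg=qc_angle_tol_deg,
            search_radius_voxels=0,
            pass_threshold=qc_pass_threshold,
        )
    return AlpsResult(
        alps_left=alps_left,
        alps_right=alps_right,
        alps_mean=(alps_left + alps_right) / 2.0,
        left=left,
        right=right,
        qc=qc,
    )


def _alignment_fraction(
    tensors: TensorVolume,
    voxels,
    axis: np.ndarray,
    cos_tol: float,
) -> tuple[float, int, int]:
    """Share of ROI voxels whose principal eigenvector is within tolerance.

    Voxels with degenerate (non-positive, non-finite) tensors are excluded
    from the numerator but kept in the denominator.
    """
    idx = np.array(sorted(voxels))
    mats = tensors.as_matrices()[idx[:, 0], idx[:, 1], idx[:, 2]]
    n_total = len(idx)
    finite = np.isfinite(mats).all(axis=(1, 2))
    aligned = 0
    n_valid = 0
    if finite.any():
        evals, evecs = np.linalg.eigh(mats[finite])
        principal = evecs[:, :, -1]
        lead = evals[:, -1]
        # degenerate (zero/negative) tensors are excluded but still counted
        # in the denominator; isotropic voxels are valid yet can never be
        # aligned (their principal axis is undefined)
        valid = lead > 0
        n_valid = int(valid.sum())
        if n_valid:
            anis = lead - evals[:, 1]
            oriented = valid & (anis > 1e-12 * np.maximum(lead, 1e-30))
            cosines = np.abs(np.einsum("ij,j->i", principal, axis))
            aligned = int((oriented & (cosines >= cos_tol)).sum())
    frac = aligned / n_total
    return frac, n_valid, n_total


def orientation_qc(
    tensors: TensorVolume,
    rois: RoiSet,
    angle_tol_deg: float = 20.0,
    search_radius_voxels: int = 2,
    pass_threshold: float = 0.8,
) -> tuple[RoiSet, QcReport]:
    """Automated surrogate for the visual ROI-placement check.

    In the manual protocol an observer inspects color-coded eigenvector maps
    and nudges each ROI by a voxel or two until it sits fully inside its
    fiber tract.  Here, for each ROI we score every integer shift within the
    search radius by the fraction of voxels whose principal eigenvector lies
    within ``angle_tol_deg`` of the expected fiber axis (z for projection,
    y for association), and keep the best (ties: smallest shift norm, then
    lexicographic order).  An ROI whose best fraction stays below
    ``pass_threshold`` is flagged.

    With ``search_radius_voxels=0`` the ROI set is returned unchanged.
    """
    cos_tol = float(np.cos(np.deg2rad(angle_tol_deg)))
    r = int(search_radius_voxels)
    shifts_grid = [
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-r, r + 1)
    ]
    # deterministic tie-break: best fraction, then smallest norm, then lexicographic
    shifts_grid.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2 + s[2] ** 2, s))
    best_shifts: dict[str, tuple[int, int, int]] = {}
    entries: dict[str, QcRoiEntry] = {}
    for label in ROI_LABELS:
        kind = "proj" if label.endswith("proj") else "assoc"
        axis = _EXPECTED_AXIS[kind]
        base = rois.rois[label]
        best = None
        for shift in shifts_grid:
            shifted = [tuple(v + d for v, d in zip(vox, shift)) for vox in base]
            if not all(tensors.geometry.contains(v) for v in shifted):
                continue
            frac, n_valid, n_total = _alignment_fraction(tensors, shifted, axis, cos_tol)
            if n_valid == 0 and shift == (0, 0, 0) and r == 0:
                raise AlpsComputationError(f"ROI {label!r}: all tensors degenerate")
            if best is None or frac > best[0]:
                best = (frac, shift, n_valid, n_total)
        if best is None:
            raise AlpsComputationError(f"ROI {label!r}: no admissible shift inside the grid")
        frac, shift, n_valid, n_total = best
        if n_valid == 0 and frac == 0.0 and r > 0:
            # re-check the unshifted ROI for the all-degenerate contract
            _, nv0, _ = _alignment_fraction(tensors, base, axis, cos_tol)
            if nv0 == 0:
                raise AlpsComputationError(f"ROI {label!r}: all tensors degenerate")
        best_shifts[label] = shift
        entries[label] = QcRoiEntry(
            alignment_fraction=frac,
            shift=shift,
            n_valid=n_valid,
            n_total=n_total,
            passed=frac >= pass_threshold,
        )
    report = QcReport(entries=entries, angle_tol_deg=angle_tol_deg, pass_threshold=pass_threshold)
    return rois.shifted(best_shifts), report


def wmh_overlap(wmh_mask, rois: RoiSet, geometry: VolumeGeometry | None = None) -> float:
    """Overlap volume (mm^3) between a lesion mask and the union of ROIs.

    White-matter hyperintensities intersecting the ALPS ROIs perturb the
    measured diffusivities; the overlap volume is carried into the cohort
    analysis as a covariate.
    """
    if geometry is None:
        geometry = rois.geometry
    if geometry.shape != rois.geometry.shape:
        raise GeometryError(
            f"mask grid {geometry.shape} does not match ROI grid {rois.geometry.shape}"
        )
    overlap = set(wmh_mask) & set(rois.all_voxels)
    return len(overlap) * geometry.voxel_volume_mm3


def brain_to_icv(gm_ml: float, wm_ml: float, csf_ml: float) -> tuple[float, float, float]:
    """(ICV, brain volume, brain/ICV ratio) from tissue volumes in ml.

    ICV = GM + WM + CSF; brain = GM + WM.  The ratio is an atrophy index.
    """
    for name, v in (("gm_ml", gm_ml), ("wm_ml", wm_ml), ("csf_ml", csf_ml)):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    icv = gm_ml + wm_ml + csf_ml
    if icv <= 0:
        raise ValueError("zero intracranial volume")
    brain = gm_ml + wm_ml
    return float(icv), float(brain), float(brain / icv)
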