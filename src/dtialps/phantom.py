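"""Synthetic periventricular DWI phantoms with known analytic ALPS.

The phantom emulates the tissue configuration the ALPS protocol relies on at
the level of the lateral-ventricle body: a CSF-filled ventricle slab at the
center of the x (left-right) axis, flanked on each side by a projection-fiber
band (principal diffusion axis z) and, lateral to it, an association-fiber
band (principal axis y).  A perivascular water compartment is modeled as an
extra diffusivity ``g`` added along x — the direction the deep medullary
veins run — inside both fiber bands, separately per hemisphere so asymmetric
glymphatic function can be planted.

Planted tensors (diagonal, in mm^2/s):

=============  =====================================================
region         tensor
=============  =====================================================
projection     diag(lambda_perp + g,  lambda_perp,     lambda_parallel)
association    diag(lambda_perp + g,  lambda_parallel, lambda_perp)
ventricle      d_csf * I
background     d_background * I
=============  =====================================================

so each hemisphere's true ALPS is ``(lambda_perp + g) / lambda_perp`` and the
whole simulate -> fit -> measure pipeline can be validated against a closed
form.  Signals follow the monoexponential tensor model
``S = S0 * exp(-b g^T D g)`` with Rician magnitude noise at a chosen SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._gradients import DIRECTIONS_30
from .alps import AlpsResult, RoiSet, compute_alps, default_roi_set, make_crosshair_roi
from .io import TensorVolume, VolumeGeometry

__all__ = [
    "PhantomSpec",
    "GradientScheme",
    "DwiVolume",
    "default_phantom_spec",
    "default_scheme",
    "region_map",
    "build_phantom_tensors",
    "expected_alps",
    "simulate_dwi",
    "fit_tensor",
    "phantom_to_alps",
]

REGION_CODES = {"background": 0, "ventricle": 1, "proj_left": 2, "proj_right": 3,
                "assoc_left": 4, "assoc_right": 5}

_ROI_REGION = {
    "left_proj": "proj_left",
    "right_proj": "proj_right",
    "left_assoc": "assoc_left",
    "right_assoc": "assoc_right",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, region extents, planted diffusivities and ROI centers.

    Band extents are half-open ``[lo, hi)`` voxel ranges along x; all bands
    share the ``band_y`` / ``band_z`` extents.  ``g_perivascular`` is the
    (left, right) pair of added x-axis diffusivities.
    """

    geometry: VolumeGeometry = field(
        default_factory=lambda: VolumeGeometry(shape=(40, 40, 20), voxel_size_mm=(2.0, 2.0, 2.0))
    )
    ventricle_x: tuple[int, int] = (16, 24)
    proj_x_left: tuple[int, int] = (9, 16)
    proj_x_right: tuple[int, int] = (24, 31)
    assoc_x_left: tuple[int, int] = (2, 9)
    assoc_x_right: tuple[int, int] = (31, 38)
    band_y: tuple[int, int] = (4, 36)
    band_z: tuple[int, int] = (2, 18)
    lambda_parallel: float = 1.4e-3
    lambda_perp: float = 0.4e-3
    g_perivascular: tuple[float, float] = (0.2e-3, 0.2e-3)
    d_csf: float = 3.0e-3
    d_background: float = 0.8e-3
    roi_centers: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "left_assoc": (5, 20, 10),
            "left_proj": (12, 20, 10),
            "right_proj": (27, 20, 10),
            "right_assoc": (34, 20, 10),
        }
    )

    def __post_init__(self) -> None:
        if not (self.lambda_parallel > self.lambda_perp > 0):
            raise ValueError(
                f"need lambda_parallel > lambda_perp > 0, got "
                f"{self.lambda_parallel} / {self.lambda_perp}"
            )
        if any(g < 0 for g in self.g_perivascular):
            raise ValueError(f"g_perivascular must be >= 0, got {self.g_perivascular}")
        if self.d_csf <= 0 or self.d_background <= 0:
            raise ValueError("d_csf and d_background must be > 0")
        regions = region_map(self, validate_rois=False)
        for label, center in self.roi_centers.items():
            expected = REGION_CODES[_ROI_REGION[label]]
            for vox in make_crosshair_roi(center, self.geometry):
                if regions[vox] != expected:
                    raise ValueError(
                        f"ROI {label!r} voxel {vox} lies outside its fiber band "
                        f"({_ROI_REGION[label]})"
                    )


def default_phantom_spec(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def region_map(spec: PhantomSpec, validate_rois: bool = True) -> np.ndarray:
    """Integer region-code volume (see :data:`REGION_CODES`)."""
    del validate_rois  # only __post_init__ skips ROI checks, to avoid recursion
    shape = spec.geometry.shape
    out = np.zeros(shape, dtype=np.int8)
    ys = slice(*spec.band_y)
    zs = slice(*spec.band_z)
    for name, xr in (
        ("ventricle", spec.ventricle_x),
        ("proj_left", spec.proj_x_left),
        ("proj_right", spec.proj_x_right),
        ("assoc_left", spec.assoc_x_left),
        ("assoc_right", spec.assoc_x_right),
    ):
        out[slice(*xr), ys, zs] = REGION_CODES[name]
    return out


def build_phantom_tensors(spec: PhantomSpec) -> TensorVolume:
    """Planted diagonal tensor field for the phantom regions."""
    regions = region_map(spec)
    lp, lpar = spec.lambda_perp, spec.lambda_parallel
    gl, gr = spec.g_perivascular
    diag_by_region = {
        REGION_CODES["background"]: (spec.d_background,) * 3,
        REGION_CODES["ventricle"]: (spec.d_csf,) * 3,
        REGION_CODES["proj_left"]: (lp + gl, lp, lpar),
        REGION_CODES["proj_right"]: (lp + gr, lp, lpar),
        REGION_CODES["assoc_left"]: (lp + gl, lpar, lp),
        REGION_CODES["assoc_right"]: (lp + gr, lpar, lp),
    }
    data = np.zeros((*spec.geometry.shape, 6), dtype=np.float64)
    for code, (dxx, dyy, dzz) in diag_by_region.items():
        sel = regions == code
        data[sel, 0] = dxx
        data[sel, 3] = dyy
        data[sel, 5] = dzz
    return TensorVolume(data=data, geometry=spec.geometry)


def _expected_hemisphere(spec: PhantomSpec, hemi: str) -> float:
    g = spec.g_perivascular[0 if hemi == "left" else 1]
    dx_proj = dx_assoc = spec.lambda_perp + g
    dy_proj = dz_assoc = spec.lambda_perp
    return ((dx_proj + dx_assoc) / 2.0) / ((dy_proj + dz_assoc) / 2.0)


def expected_alps(spec: PhantomSpec) -> float:
    """Analytic ALPS of the planted field: (lambda_perp + g)/lambda_perp
    per hemisphere, averaged over hemispheres."""
    return (_expected_hemisphere(spec, "left") + _expected_hemisphere(spec, "right")) / 2.0


@dataclass(frozen=True)
class GradientScheme:
    """b-values (s/mm^2) and unit gradient directions, row-aligned."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=np.float64)
        bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(f"bvecs shape {bvecs.shape} vs {bvals.size} b-values")
        if bvals.size < 7:
            raise ValueError("need at least 7 measurements for a tensor fit")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if weighted.any() and not np.allclose(norms[weighted], 1.0, atol=1e-6):
            raise ValueError("gradient directions of weighted volumes must be unit-norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def design_matrix(self) -> np.ndarray:
        """(N, 7) log-linear design: [1, -b gx^2, -b gy^2, -b gz^2,
        -2b gx gy, -2b gx gz, -2b gy gz]."""
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [np.ones_like(b), -b * gx**2, -b * gy**2, -b * gz**2,
             -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz]
        )

    def save(self, bval_path, bvec_path) -> None:
        """Plain whitespace-separated b-value / b-vector text files
        (one row per axis in the b-vector file)."""
        np.savetxt(bval_path, self.bvals[None, :], fmt="%g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.10f")


def default_scheme(b: float = 1000.0) -> GradientScheme:
    """One b=0 volume plus 30 fixed directions at a single shell.

    Only the low shell enters the tensor fit by default; acquisitions with a
    second, higher shell drop it before fitting because the monoexponential
    tensor model breaks down there.
    """
    bvals = np.concatenate([[0.0], np.full(len(DIRECTIONS_30), float(b))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], DIRECTIONS_30])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class DwiVolume:
    """Per-voxel DWI signals, one 4th-dim entry per scheme row."""

    data: np.ndarray
    s0: float
    snr: float
    geometry: VolumeGeometry


def simulate_dwi(
    tensors: TensorVolume,
    scheme: GradientScheme,
    s0: float = 1000.0,
    snr: float = 40.0,
    seed: int | None = None,
) -> DwiVolume:
    """Monoexponential tensor signal with Rician magnitude noise.

    Noise model: two independent Gaussian channels with sigma = s0/SNR added
    to the (real) signal, magnitude taken.  ``snr=np.inf`` gives the
    noiseless signal.
    """
    if snr <= 0:
        raise ValueError(f"snr must be > 0 (or np.inf), got {snr}")
    mats = tensors.as_matrices()
    evals = np.linalg.eigvalsh(mats.reshape(-1, 3, 3))
    if (evals < -1e-15).any():
        n_bad = int((evals.min(axis=1) < -1e-15).sum())
        raise ValueError(f"{n_bad} voxel(s) have negative-eigenvalue tensors")
    quad = np.einsum("...ij,nj,ni->...n", mats, scheme.bvecs, scheme.bvecs)
    signal = s0 * np.exp(-scheme.bvals * quad)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt(re**2 + im**2)
    return DwiVolume(data=signal, s0=float(s0), snr=float(snr), geometry=tensors.geometry)


def fit_tensor(
    dwi: DwiVolume, scheme: GradientScheme, signal_floor: float = 1e-6
) -> TensorVolume:
    """Log-linear least-squares tensor fit, voxel-wise.

    Solves ``ln S = ln S0 - b g^T D g`` by unweighted least squares on the
    7-column design.  Signals are floored at ``signal_floor * s0`` before the
    log so Rician noise cannot produce -inf.
    """
    X = scheme.design_matrix()
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("degenerate gradient scheme: tensor design is rank-deficient")
    floor = signal_floor * dwi.s0
    logs = np.log(np.maximum(dwi.data, floor))
    shape3 = dwi.data.shape[:3]
    coef = logs.reshape(-1, X.shape[0]) @ np.linalg.pinv(X).T
    # design column order: lnS0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[:, i] for i in range(1, 7))
    data = np.stack([dxx, dxy, dxz, dyy, dyz, dzz], axis=-1).reshape(*shape3, 6)
    return TensorVolume(data=data, geometry=dwi.geometry)


def phantom_to_alps(
    spec: PhantomSpec,
    scheme: GradientScheme | None = None,
    snr: float = np.inf,
    seed: int | None = None,
    s0: float = 1000.0,
) -> tuple[AlpsResult, float]:
    """End-to-end: plant tensors, simulate DWI, refit, measure ALPS.

    Returns the measured :class:`AlpsResult` and the analytic expected ratio.
    """
    if scheme is None:
        scheme = default_scheme()
    tensors = build_phantom_tensors(spec)
    dwi = simulate_dwi(tensors, scheme, s0=s0, snr=snr, seed=seed)
    fitted = fit_tensor(dwi, scheme)
    rois = default_roi_set(spec.geometry, centers=spec.roi_centers)
    result = compute_alps(fitted, rois)
    return result, expected_alps(spec)
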