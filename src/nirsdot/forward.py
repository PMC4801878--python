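"""Layered head phantoms, optode layouts and channel light-sensitivity profiles.

The forward problem of continuous-wave fNIRS is modelled here with the
semi-infinite diffusion approximation: photon fluence from a surface source is
the Green's function of the diffusion equation with an extrapolated-boundary
image source, and the sensitivity of a source-detector channel to a local
absorption change follows the adjoint (Rytov/Born) product

    S(r) ∝ G(src, r) · G(r, det) / G(src, det),

evaluated with volume-averaged in-head optical properties and normalized so
that the map integrates to the channel's total pathlength factor
(-d ln G_sd / d mu_a).  This deterministic substitute preserves the spatial
structure (banana-shaped channel sensitivity, monotone depth decay,
source-detector reciprocity) that montage optimization and tomographic
inversion rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUES",
    "TISSUE_CODES",
    "HeadModel",
    "OptodeLayout",
    "OpticalProperties",
    "SensitivityMap",
    "make_slab_phantom",
    "enumerate_candidates",
    "channel_sensitivity",
    "voi_sensitivity",
    "default_optical_properties",
    "standard_layout",
]

#: in-head tissue classes, ordered from the surface inwards; NIfTI label codes
#: are 1-based in this order, 0 = outside the head.
TISSUES = ("scalp", "skull", "csf", "gray", "white")
TISSUE_CODES = {name: i + 1 for i, name in enumerate(TISSUES)}


@dataclass
class HeadModel:
    """Voxelized five-tissue head volume.

    Axis convention: 0-based voxel indices; world coordinates in mm with
    x = left->right, y = posterior->anterior, z = inferior->superior. The
    midsagittal plane sits at voxel index (nx - 1) / 2.  For slab phantoms the
    scalp face is the top (max-z) plane and depth increases downward.
    """

    voxel_size: float
    tissue_label: np.ndarray  # (nx, ny, nz) uint8, codes 0..5

    def __post_init__(self) -> None:
        self.tissue_label = np.asarray(self.tissue_label, dtype=np.uint8)
        if self.tissue_label.ndim != 3:
            raise ValueError("tissue_label must be a 3-D volume")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tissue_label.shape

    @property
    def gray_mask(self) -> np.ndarray:
        return self.tissue_label == TISSUE_CODES["gray"]

    @property
    def head_mask(self) -> np.ndarray:
        return self.tissue_label > 0

    @property
    def surface_z_mm(self) -> float:
        """World z of the outer scalp plane (top face of the head region)."""
        in_head = np.any(self.head_mask, axis=(0, 1))
        top = int(np.nonzero(in_head)[0].max())
        return (top + 1) * self.voxel_size

    def scalp_surface(self) -> np.ndarray:
        """Voxel coordinates (N, 3) of scalp voxels on the outer head boundary."""
        scalp = self.tissue_label == TISSUE_CODES["scalp"]
        top = int(round(self.surface_z_mm / self.voxel_size)) - 1
        idx = np.argwhere(scalp[:, :, top : top + 1])
        idx[:, 2] += top
        return idx

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx*ny*nz, 3) world coordinates of voxel centers, C-order."""
        nx, ny, nz = self.grid_shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5
        return centers * self.voxel_size

    # --- NIfTI round trip -------------------------------------------------
    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(self.tissue_label.astype(np.uint8), affine)
        img.header["descrip"] = b"tissue codes 0=outside 1=scalp 2=skull 3=csf 4=gray 5=white"
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "HeadModel":
        import nibabel as nib

        img = nib.load(str(path))
        voxel = float(img.header.get_zooms()[0])
        return cls(voxel_size=voxel, tissue_label=np.asarray(img.dataobj))


def make_slab_phantom(
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    layer_thicknesses: tuple[float, float, float, float, float] | dict,
) -> HeadModel:
    """Flat layered phantom: scalp->skull->CSF->gray->white from the top face.

    ``layer_thicknesses`` gives each tissue's thickness in mm (the last,
    white-matter, entry may be ``None`` to fill the remaining depth). A
    zero-thickness layer is allowed and simply omitted.
    """
    if isinstance(layer_thicknesses, dict):
        thick = [layer_thicknesses[t] for t in TISSUES]
    else:
        thick = list(layer_thicknesses)
    if len(thick) != 5:
        raise ValueError("need one thickness per tissue (5 entries)")
    nx, ny, nz = grid_shape
    depth_mm = nz * voxel_size
    if thick[-1] is None:
        used = sum(thick[:-1])
        if used > depth_mm:
            raise ValueError(
                f"layer thicknesses ({used} mm) exceed grid depth ({depth_mm} mm)"
            )
        thick[-1] = depth_mm - used
    if sum(thick) > depth_mm + 1e-9:
        raise ValueError(
            f"layer thicknesses ({sum(thick)} mm) exceed grid depth ({depth_mm} mm)"
        )
    label = np.zeros(grid_shape, dtype=np.uint8)
    # depth measured from the top face downwards
    z_top = nz
    bounds = np.cumsum([0.0] + thick)
    for code, (d0, d1) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        k1 = z_top - int(round(d0 / voxel_size))
        k0 = z_top - int(round(d1 / voxel_size))
        label[:, :, max(k0, 0) : k1] = code
    return HeadModel(voxel_size=voxel_size, tissue_label=label)


@dataclass
class OptodeLayout:
    """Scalp positions available for optodes, with the EEG-reserved subset.

    The 10/05-style layout used throughout bundles 311 named positions of
    which exactly 63 (the 10/10 subset) are reserved for EEG electrodes,
    leaving 248 optode candidates.
    """

    names: list[str]
    coords_mm: np.ndarray  # (N, 3)
    is_10_10: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        self.is_10_10 = np.asarray(self.is_10_10, dtype=bool)
        if len(set(self.names)) != len(self.names):
            raise ValueError("position names must be unique")
        if not (len(self.names) == len(self.coords_mm) == len(self.is_10_10)):
            raise ValueError("inconsistent layout field lengths")

    def coord_of(self, name: str) -> np.ndarray:
        return self.coords_mm[self.names.index(name)]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "name": self.names,
                "x_mm": self.coords_mm[:, 0],
                "y_mm": self.coords_mm[:, 1],
                "z_mm": self.coords_mm[:, 2],
                "is_10_10": self.is_10_10.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OptodeLayout":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            names=df["name"].astype(str).tolist(),
            coords_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            is_10_10=df["is_10_10"].to_numpy() != 0,
        )


def standard_layout(head: HeadModel, n_total: int = 311, n_reserved: int = 63) -> OptodeLayout:
    """Deterministic 10/05-style layout on a slab phantom's scalp face.

    Positions are laid out on the top face with a Vogel (sunflower) spiral —
    an even angular subdivision standing in for a digitized 10/05 set — and
    every ~5th position (63 of 311 by default) is flagged as belonging to the
    10/10 subset reserved for EEG electrodes.
    """
    nx, ny, _ = head.grid_shape
    v = head.voxel_size
    cx, cy = nx * v / 2.0, ny * v / 2.0
    radius = 0.48 * min(nx, ny) * v
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_total)
    r = radius * np.sqrt((k + 0.5) / n_total)
    th = k * golden
    x = cx + r * np.cos(th)
    y = cy + r * np.sin(th)
    z = np.full(n_total, head.surface_z_mm)
    names = [f"P{i + 1:03d}" for i in range(n_total)]
    reserved = np.zeros(n_total, dtype=bool)
    reserved[np.round(np.linspace(0, n_total - 1, n_reserved)).astype(int)] = True
    assert reserved.sum() == n_reserved
    return OptodeLayout(names=names, coords_mm=np.stack([x, y, z], axis=1), is_10_10=reserved)


def enumerate_candidates(layout: OptodeLayout) -> list[str]:
    """Positions available for optodes: everything not reserved for EEG.

    Order is stable by name.
    """
    return sorted(n for n, r in zip(layout.names, layout.is_10_10) if not r)


@dataclass
class OpticalProperties:
    """Absorption and reduced scattering per tissue at one wavelength (mm^-1)."""

    wavelength: float
    mu_a: dict[str, float]
    mu_s_prime: dict[str, float]

    def __post_init__(self) -> None:
        for table in (self.mu_a, self.mu_s_prime):
            for t in TISSUES:
                if table.get(t, 0.0) <= 0:
                    raise ValueError(f"optical coefficient for {t!r} must be > 0")

    def volume_averaged(self, head: HeadModel) -> tuple[float, float]:
        """In-head volume-weighted (mu_a, mu_s') for the homogeneous substitute."""
        counts = np.bincount(head.tissue_label.ravel(), minlength=6)[1:]
        w = counts / counts.sum()
        mua = float(sum(w[i] * self.mu_a[t] for i, t in enumerate(TISSUES)))
        musp = float(sum(w[i] * self.mu_s_prime[t] for i, t in enumerate(TISSUES)))
        return mua, musp


# Literature-standard adult head coefficients (mm^-1); bundled fixture, the
# source study does not tabulate its Monte-Carlo inputs.
_MU_A = {
    690: {"scalp": 0.0159, "skull": 0.0101, "csf": 0.0004, "gray": 0.0178, "white": 0.0167},
    830: {"scalp": 0.0191, "skull": 0.0136, "csf": 0.0026, "gray": 0.0186, "white": 0.0208},
}
_MU_SP = {
    690: {"scalp": 0.80, "skull": 1.00, "csf": 0.01, "gray": 1.25, "white": 1.18},
    830: {"scalp": 0.66, "skull": 0.86, "csf": 0.01, "gray": 1.11, "white": 1.01},
}


def default_optical_properties(wavelength: int) -> OpticalProperties:
    if wavelength not in _MU_A:
        raise ValueError(f"no bundled coefficients at {wavelength} nm")
    return OpticalProperties(
        wavelength=float(wavelength), mu_a=dict(_MU_A[wavelength]), mu_s_prime=dict(_MU_SP[wavelength])
    )


@dataclass
class SensitivityMap:
    """Per-voxel sensitivity of one channel at one wavelength (mm pathlength)."""

    source: str
    detector: str
    wavelength: float
    values: np.ndarray  # (nx, ny, nz), >= 0, zero outside the head
    separation_mm: float = 0.0
    flagged: bool = field(default=False)  # separation outside channel bounds

    def to_nifti(self, path, voxel_size: float) -> None:
        import nibabel as nib

        affine = np.diag([voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


def _green_semi_infinite(rho2_plus_dz2: np.ndarray, mu_eff: float, D: float) -> np.ndarray:
    r = np.sqrt(rho2_plus_dz2)
    r = np.maximum(r, 1e-6)
    return np.exp(-mu_eff * r) / (4.0 * np.pi * D * r)


def _fluence(points: np.ndarray, optode_xy: np.ndarray, depth: np.ndarray,
             z0: float, zb: float, mu_eff: float, D: float) -> np.ndarray:
    """Semi-infinite fluence at ``points`` (depth below surface) from a surface optode."""
    rho2 = np.sum((points[:, :2] - optode_xy) ** 2, axis=1)
    real = _green_semi_infinite(rho2 + (depth - z0) ** 2, mu_eff, D)
    image = _green_semi_infinite(rho2 + (depth + z0 + 2.0 * zb) ** 2, mu_eff, D)
    return real - image


def _surface_green(sep_mm: float, mu_a: float, mu_sp: float) -> float:
    """Fluence Green's function between two surface points, separation sep_mm."""
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = float(np.sqrt(mu_a / D))
    z0 = 1.0 / mu_sp
    # extrapolated boundary with effective reflection coefficient ~0.493 (n=1.4)
    reff = 0.493
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    r1 = np.sqrt(sep_mm**2 + z0**2)
    r2 = np.sqrt(sep_mm**2 + (z0 + 2 * zb) ** 2)
    return float(
        np.exp(-mu_eff * r1) / (4 * np.pi * D * r1)
        - np.exp(-mu_eff * r2) / (4 * np.pi * D * r2)
    )


def total_pathlength(sep_mm: float, mu_a: float, mu_sp: float) -> float:
    """Mean photon pathlength -d ln G / d mu_a of a channel (mm).

    Computed by central finite difference; this is DPF x separation for the
    homogeneous semi-infinite medium.
    """
    h = 1e-6
    gp = _surface_green(sep_mm, mu_a + h, mu_sp)
    gm = _surface_green(sep_mm, mu_a - h, mu_sp)
    return float(-(np.log(gp) - np.log(gm)) / (2 * h))


def channel_sensitivity(
    head: HeadModel,
    props: OpticalProperties,
    src_xyz: np.ndarray,
    det_xyz: np.ndarray,
    src_name: str = "S",
    det_name: str = "D",
    distance_bounds: tuple[float, float] | None = None,
) -> SensitivityMap:
    """Adjoint-product sensitivity profile of one source-detector channel.

    Symmetric in source and detector (reciprocity holds exactly), nonnegative,
    zero outside the head, and normalized so the in-head sum equals the
    channel's total pathlength factor.
    """
    src_xyz = np.asarray(src_xyz, float)
    det_xyz = np.asarray(det_xyz, float)
    sep = float(np.linalg.norm(det_xyz[:2] - src_xyz[:2]))
    if sep < 1e-9:
        raise ValueError("source and detector positions coincide")
    flagged = False
    if distance_bounds is not None:
        lo, hi = distance_bounds
        flagged = not (lo <= sep <= hi)

    mu_a, mu_sp = props.volume_averaged(head)
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = float(np.sqrt(mu_a / D))
    z0 = 1.0 / mu_sp
    reff = 0.493
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)

    centers = head.voxel_centers_mm()
    depth = head.surface_z_mm - centers[:, 2]
    phi_s = _fluence(centers, src_xyz[:2], depth, z0, zb, mu_eff, D)
    phi_d = _fluence(centers, det_xyz[:2], depth, z0, zb, mu_eff, D)
    g_sd = _surface_green(sep, mu_a, mu_sp)
    vals = phi_s * phi_d / g_sd
    vals = np.clip(vals, 0.0, None)
    vals = vals.reshape(head.grid_shape)
    vals[~head.head_mask] = 0.0
    total = vals.sum()
    if total > 0:
        vals *= total_pathlength(sep, mu_a, mu_sp) / total
    return SensitivityMap(
        source=src_name,
        detector=det_name,
        wavelength=props.wavelength,
        values=vals,
        separation_mm=sep,
        flagged=flagged,
    )


def voi_sensitivity(smap: SensitivityMap, voi_mask: np.ndarray) -> float:
    """Summed channel sensitivity inside a voxel mask."""
    voi_mask = np.asarray(voi_mask, bool)
    if voi_mask.shape != smap.values.shape:
        raise ValueError("VOI mask shape does not match the sensitivity grid")
    if not voi_mask.any():
        warnings.warn("empty VOI: sensitivity defined as 0", stacklevel=2)
        return 0.0
    return float(smap.values[voi_mask].sum())
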