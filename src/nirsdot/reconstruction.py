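"""Minimum-norm diffuse optical tomography with ReML-tuned regularization.

Two-wavelength optical-density epochs are mapped to voxelwise Delta[HbO] /
Delta[HbR] inside the montage's field of view by inverting the chromophore-
coupled Jacobian

    J[(lambda, ch), (c, v)] = eps(c, lambda) * A_lambda(ch, v),

where A is the channel sensitivity matrix and eps the base-e molar
extinction table.  The inverse is plain minimum norm,
W = J^T (J J^T + lambda C)^{-1}, with the noise/source variance ratio lambda
estimated by restricted maximum likelihood (two-hyperparameter EM) on the
averaged IED epoch and then frozen for every single-event reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import SensitivityMap

__all__ = [
    "CHROMOPHORES",
    "ExtinctionTable",
    "ForwardOperator",
    "InverseOperator",
    "HemoImage",
    "default_extinction",
    "restrict_fov",
    "assemble_forward",
    "assemble_inverse",
    "fit_reml",
    "apply_inverse",
]

CHROMOPHORES = ("HbO", "HbR")


@dataclass
class ExtinctionTable:
    """Base-e molar extinction, mm^-1 uM^-1, per chromophore and wavelength."""

    eps: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        if not self.eps[("HbR", 690)] > self.eps[("HbO", 690)]:
            raise ValueError("expected HbR to dominate absorption at 690 nm")
        if not self.eps[("HbO", 830)] > self.eps[("HbR", 830)]:
            raise ValueError("expected HbO to dominate absorption at 830 nm")

    def __call__(self, chromophore: str, wavelength: int) -> float:
        return self.eps[(chromophore, wavelength)]


def default_extinction() -> ExtinctionTable:
    """Standard compilation values converted to base-e mm^-1 uM^-1.

    (Base-10 cm^-1 M^-1 values 276/2051.96 at 690 nm and 974/693.04 at
    830 nm for HbO/HbR, scaled by ln(10) * 1e-7.)
    """
    s = np.log(10) * 1e-7
    return ExtinctionTable(
        eps={
            ("HbO", 690): 276.0 * s,
            ("HbR", 690): 2051.96 * s,
            ("HbO", 830): 974.0 * s,
            ("HbR", 830): 693.04 * s,
        }
    )


def restrict_fov(
    maps: list[SensitivityMap],
    gray_mask: np.ndarray,
    fraction: float = 0.90,
    mode: str = "cumulative",
) -> np.ndarray:
    """Field of view: the gray voxels the montage meaningfully senses.

    ``mode='cumulative'`` (default): gray voxels sorted by aggregate
    (channel-summed) sensitivity, keeping the minimal prefix holding
    ``fraction`` of the total. ``mode='count'``: the most sensitive
    ``fraction`` of gray voxels by count.  Returns ordered voxel indices
    (n_fov, 3), most sensitive first.
    """
    if not maps:
        raise ValueError("no sensitivity maps")
    agg = np.zeros_like(maps[0].values)
    for m in maps:
        agg = agg + m.values
    gray_idx = np.argwhere(gray_mask)
    vals = agg[gray_mask]
    if vals.sum() <= 0:
        raise ValueError("montage has zero aggregate sensitivity over gray matter")
    order = np.argsort(vals)[::-1]
    if mode == "cumulative":
        csum = np.cumsum(vals[order])
        n_keep = int(np.searchsorted(csum, fraction * csum[-1]) + 1)
    elif mode == "count":
        n_keep = max(1, int(np.ceil(fraction * len(vals))))
    else:
        raise ValueError(f"unknown FOV mode {mode!r}")
    return gray_idx[order[:n_keep]]


@dataclass
class ForwardOperator:
    """Stacked chromophore-coupled Jacobian over the FOV.

    Rows: channels x wavelengths (wavelength-major); columns: FOV voxels x
    chromophores (chromophore-major: all HbO then all HbR), in uM units.
    """

    J: np.ndarray  # (n_wl * n_ch, 2 * n_fov)
    fov_voxels: np.ndarray  # (n_fov, 3)
    channels: list[tuple[str, str]]
    wavelengths: tuple[int, ...]

    @property
    def n_fov(self) -> int:
        return len(self.fov_voxels)


def assemble_forward(
    maps: dict[tuple[str, str], dict[int, SensitivityMap]],
    extinction: ExtinctionTable,
    fov_voxels: np.ndarray,
    wavelengths: tuple[int, int] = (690, 830),
) -> ForwardOperator:
    """Blockwise J: J[lambda-block, chromophore-block] = eps(c, lambda) A(lambda)."""
    channels = sorted(maps)
    fov_voxels = np.asarray(fov_voxels, int)
    ix, iy, iz = fov_voxels.T
    n_ch, n_fov = len(channels), len(fov_voxels)
    J = np.zeros((len(wavelengths) * n_ch, 2 * n_fov))
    for wi, wl in enumerate(wavelengths):
        A = np.empty((n_ch, n_fov))
        for ci, ch in enumerate(channels):
            if wl not in maps[ch]:
                raise ValueError(f"channel {ch} lacks a {wl} nm sensitivity map")
            A[ci] = maps[ch][wl].values[ix, iy, iz]
        for ci_c, c in enumerate(CHROMOPHORES):
            J[wi * n_ch : (wi + 1) * n_ch, ci_c * n_fov : (ci_c + 1) * n_fov] = (
                extinction(c, wl) * A
            )
    return ForwardOperator(J=J, fov_voxels=fov_voxels, channels=channels, wavelengths=tuple(wavelengths))


@dataclass
class InverseOperator:
    """Frozen minimum-norm inverse W = R J^T (J R J^T + lambda C)^{-1}."""

    W: np.ndarray
    lambda_reg: float
    reml_iterations: int
    converged: bool
    fov_voxels: np.ndarray
    noise_scale: np.ndarray  # diagonal of C^(1/2)


def fit_reml(
    fwd: ForwardOperator,
    averaged_epoch: np.ndarray,
    noise_cov_diag: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> InverseOperator:
    """Two-hyperparameter EM/ReML fit of source and noise variances.

    The model is y_t = J x_t + e_t with x ~ N(0, q I) and e ~ N(0, s2 C),
    C diagonal (identity unless ``noise_cov_diag`` is given, e.g. estimated
    from pre-event samples).  EM alternates posterior source estimates with
    closed-form variance updates; lambda = s2 / q at the last iterate.
    """
    J = fwd.J
    n_ch, n_src = J.shape
    Y = np.asarray(averaged_epoch, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != n_ch:
        raise ValueError("epoch channel dimension does not match the forward operator")
    T = Y.shape[1]
    if noise_cov_diag is None:
        cdiag = np.ones(n_ch)
    else:
        cdiag = np.asarray(noise_cov_diag, float)
        cdiag = np.maximum(cdiag, 1e-12 * cdiag.max())
    w = 1.0 / np.sqrt(cdiag)
    Jw = J * w[:, None]
    Yw = Y * w[:, None]
    U, s, _ = np.linalg.svd(Jw, full_matrices=False)
    s2vals = s**2
    UtY = U.T @ Yw
    uty2 = (UtY**2).sum(axis=1)  # per singular direction, summed over time
    y2 = float((Yw**2).sum())
    resid_out = y2 - float(uty2.sum())  # energy outside the column space of Jw

    total_var = y2 / (n_ch * T)
    q = 0.5 * total_var / max(s2vals.mean(), 1e-300)
    sigma2 = 0.5 * total_var
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        d = q * s2vals + sigma2
        # E-step sufficient statistics in the singular basis
        xhat2 = float(((q * s / d) ** 2 * uty2).sum())
        tr_P = q * n_src - q**2 * float((s2vals / d).sum())
        resid_in = float((((sigma2 / d) ** 2) * uty2).sum())
        tr_JPJt = float((q * sigma2 * s2vals / d).sum())
        q_new = (xhat2 + T * tr_P) / (n_src * T)
        sigma2_new = (resid_in + resid_out + T * tr_JPJt) / (n_ch * T)
        rel = max(abs(q_new - q) / max(q, 1e-300), abs(sigma2_new - sigma2) / max(sigma2, 1e-300))
        q, sigma2 = q_new, sigma2_new
        if rel < tol:
            converged = True
            break
    lam = sigma2 / max(q, 1e-300)
    W = assemble_inverse(J, lam, cdiag)
    return InverseOperator(
        W=W,
        lambda_reg=float(lam),
        reml_iterations=iterations,
        converged=converged,
        fov_voxels=fwd.fov_voxels,
        noise_scale=np.sqrt(cdiag),
    )


def assemble_inverse(
    J: np.ndarray, lam: float, noise_cov_diag: np.ndarray | None = None
) -> np.ndarray:
    """Minimum-norm inverse W = J^T (J J^T + lam C)^{-1} with diagonal C.

    At lam = 0 and orthogonal square J this reduces to J^T (the exact
    inverse); it is the operator fit_reml freezes after hyperparameter
    estimation.
    """
    n_ch = J.shape[0]
    cdiag = np.ones(n_ch) if noise_cov_diag is None else np.asarray(noise_cov_diag, float)
    gram = J @ J.T + lam * np.diag(cdiag)
    return J.T @ np.linalg.solve(gram, np.eye(n_ch))


@dataclass
class HemoImage:
    """Voxel x chromophore x time concentration image for one event (uM)."""

    values: np.ndarray  # (n_fov, 2, n_time)
    fov_voxels: np.ndarray
    fs: float
    event_id: str = ""

    def chromophore(self, name: str) -> np.ndarray:
        return self.values[:, CHROMOPHORES.index(name), :]


def apply_inverse(
    inv: InverseOperator,
    epochs: np.ndarray,
    fs: float,
    event_ids: list[str] | None = None,
) -> list[HemoImage]:
    """Apply the frozen operator to one or more OD epochs (..., channels, time)."""
    E = np.asarray(epochs, float)
    single = E.ndim == 2
    if single:
        E = E[None]
    n_ev, n_ch, n_t = E.shape
    if inv.W.shape[1] != n_ch:
        raise ValueError("epoch channel dimension does not match the inverse operator")
    n_fov = len(inv.fov_voxels)
    X = inv.W @ E.transpose(1, 0, 2).reshape(n_ch, n_ev * n_t)
    X = X.reshape(2, n_fov, n_ev, n_t).transpose(2, 1, 0, 3)  # (ev, fov, chrom, t)
    ids = event_ids or [f"event-{i}" for i in range(n_ev)]
    return [
        HemoImage(values=X[i], fov_voxels=inv.fov_voxels, fs=fs, event_id=ids[i])
        for i in range(n_ev)
    ]
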