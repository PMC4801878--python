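"""Spatio-temporal cluster detection and Monte-Carlo permutation testing.

Voxel x time t-maps (one-sample, two-sided, alpha = 5%) are thresholded and
grouped into clusters under 6-connectivity in space combined with adjacency
in time: (v, t) ~ (v', t') iff the voxels are spatial 6-neighbors at the same
sample, or the same voxel at consecutive samples.  Cluster strength is the
sum of |t| over members — no minimum spatial extent.  Specificity against
control events is assessed by pooling event-wise responses, redrawing
pseudo-IED sets, and comparing observed strengths to the permutation
distribution of the maximum cluster strength (family-wise error controlling
by construction).  The module is modality-agnostic: any event x voxel x time
dataset (e.g. BOLD epochs) can be fed to the same functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "TMap",
    "Cluster",
    "ResponseSummary",
    "downsample_for_clustering",
    "decimate_time",
    "compute_tmap",
    "form_clusters",
    "cluster_strength",
    "permutation_test",
    "cluster_timecourse",
    "trace_support",
    "summarize_response",
    "summarize_cohort",
]

#: 4-D structuring element: spatial 6-neighbors at equal time + temporal
#: neighbors at equal voxel, no spatio-temporal diagonals.
_STRUCTURE_4D = ndimage.generate_binary_structure(4, 1)


def downsample_for_clustering(
    images: np.ndarray,
    voxel_size_mm: float,
    fs: float,
    target_mm: float = 2.0,
    target_fs: float = 2.0,
) -> tuple[np.ndarray, float, float]:
    """Block-mean to 2 mm voxels and decimate to 2 samples/s.

    ``images`` is dense (..., nx, ny, nz, nt).  Spatial factors must divide
    the grid; the time axis is block-averaged (the signal is already band-
    limited far below the target Nyquist).  Identity when already at target.
    """
    f_sp = int(round(target_mm / voxel_size_mm))
    f_t = int(round(fs / target_fs))
    if f_sp < 1 or f_t < 1:
        raise ValueError("target resolutions must be coarser than the input")
    out = np.asarray(images, float)
    if f_sp > 1:
        *lead, nx, ny, nz, nt = out.shape
        if nx % f_sp or ny % f_sp or nz % f_sp:
            raise ValueError("spatial block factor must divide the grid shape")
        out = out.reshape(
            *lead, nx // f_sp, f_sp, ny // f_sp, f_sp, nz // f_sp, f_sp, nt
        ).mean(axis=(-2, -4, -6))
    if f_t > 1:
        nt = out.shape[-1]
        n_blocks = nt // f_t
        out = out[..., : n_blocks * f_t].reshape(*out.shape[:-1], n_blocks, f_t).mean(axis=-1)
    return out, voxel_size_mm * f_sp, fs / f_t


@dataclass
class TMap:
    """One-sample t statistics per voxel-time point with significance mask."""

    t: np.ndarray  # (nx, ny, nz, nt); 0 where undefined
    n_events: int
    alpha: float
    sig_mask: np.ndarray  # bool, same shape
    excluded: np.ndarray | None = None  # zero-variance points, if any


def _as_dense_mask(
    event_images: np.ndarray,
    valid_mask: np.ndarray | None,
    fov_voxels: np.ndarray | None,
    grid_shape: tuple[int, int, int] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize input to flat (n_ev, n_vox, nt) + dense bool mask.

    Accepts either dense (n_ev, nx, ny, nz, nt) images with an optional
    ``valid_mask``, or flat (n_ev, n_vox, nt) images over ``fov_voxels``
    (n_vox, 3) on a ``grid_shape`` grid.
    """
    X = np.asarray(event_images, float)
    if X.ndim == 5:
        vm = (
            np.asarray(valid_mask, bool)
            if valid_mask is not None
            else np.ones(X.shape[1:4], dtype=bool)
        )
        return X[:, vm, :], vm
    if X.ndim == 3:
        if fov_voxels is None or grid_shape is None:
            raise ValueError("flat images need fov_voxels and grid_shape")
        vm = np.zeros(grid_shape, dtype=bool)
        fov_voxels = np.asarray(fov_voxels, int)
        vm[fov_voxels[:, 0], fov_voxels[:, 1], fov_voxels[:, 2]] = True
        # reorder flat voxel axis to match boolean-mask (C-order) indexing
        order = np.lexsort((fov_voxels[:, 2], fov_voxels[:, 1], fov_voxels[:, 0]))
        return X[:, order, :], vm
    raise ValueError("event images must be (ev, nx, ny, nz, nt) or (ev, n_vox, nt)")


def compute_tmap(
    event_images: np.ndarray,
    alpha: float = 0.05,
    valid_mask: np.ndarray | None = None,
    fov_voxels: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> TMap:
    """Two-sided one-sample t-test against zero at every voxel-time point.

    ``event_images`` is dense (n_events, nx, ny, nz, nt) or flat
    (n_events, n_vox, nt) over ``fov_voxels``.  Points with zero variance
    are excluded from the significance mask.
    """
    flat, vm = _as_dense_mask(event_images, valid_mask, fov_voxels, grid_shape)
    n = flat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 events for a t-map")
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    sig = (np.abs(t) > tcrit) & ~bad
    nt = flat.shape[-1]
    shape4 = vm.shape + (nt,)
    t_dense = np.zeros(shape4)
    sig_dense = np.zeros(shape4, dtype=bool)
    bad_dense = np.zeros(shape4, dtype=bool)
    t_dense[vm] = t
    sig_dense[vm] = sig
    bad_dense[vm] = bad
    return TMap(
        t=t_dense,
        n_events=n,
        alpha=alpha,
        sig_mask=sig_dense,
        excluded=bad_dense if bad.any() else None,
    )


@dataclass
class Cluster:
    """Connected set of significant voxel-time points."""

    members: tuple[np.ndarray, ...]  # (ix, iy, iz, it) index arrays
    strength: float
    p_perm: float | None = None

    @property
    def size(self) -> int:
        return len(self.members[0])

    def time_extent(self) -> tuple[int, int]:
        it = self.members[3]
        return int(it.min()), int(it.max())

    def voxel_footprint(self) -> np.ndarray:
        """Unique (ix, iy, iz) voxels touched by the cluster."""
        vox = np.stack(self.members[:3], axis=1)
        return np.unique(vox, axis=0)


def form_clusters(tmap: TMap) -> list[Cluster]:
    """Connected components of the significance mask, strengths filled."""
    labels, n = ndimage.label(tmap.sig_mask, structure=_STRUCTURE_4D)
    clusters = []
    for lab in range(1, n + 1):
        members = np.nonzero(labels == lab)
        strength = float(np.abs(tmap.t[members]).sum())
        clusters.append(Cluster(members=members, strength=strength))
    clusters.sort(key=lambda c: -c.strength)
    return clusters


def cluster_strength(cluster: Cluster, tmap: TMap) -> float:
    """Independent recomputation of sum |t| over the cluster's members."""
    return float(np.abs(tmap.t[cluster.members]).sum())


def _max_strengths(sig: np.ndarray, abst: np.ndarray) -> float:
    labels, n = ndimage.label(sig, structure=_STRUCTURE_4D)
    if n == 0:
        return 0.0
    sums = ndimage.sum_labels(abst, labels, index=np.arange(1, n + 1))
    return float(np.max(sums))


def permutation_test(
    ied_images: np.ndarray,
    control_images: np.ndarray,
    n_perm: int = 4000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    valid_mask: np.ndarray | None = None,
    fov_voxels: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    null_statistic: str = "max",
) -> tuple[list[Cluster], np.ndarray]:
    """Cluster-level Monte-Carlo permutation test against control events.

    Observed clusters come from the IED images alone.  Each permutation pools
    IED and control responses, draws a pseudo-IED subset of the original IED
    count without replacement, recomputes the t-map and clusters, and records
    the maximum cluster strength (``null_statistic='max'``, family-wise error
    controlling; ``'all'`` records every cluster strength).  p_perm follows
    the (1 + b) / (1 + m) convention; a cluster is significant iff
    p_perm <= alpha.  Images may be dense or flat (see ``compute_tmap``).
    """
    ied = np.asarray(ied_images, float)
    ctl = np.asarray(control_images, float)
    if ied.shape[1:] != ctl.shape[1:]:
        raise ValueError("IED and control images have mismatched dimensions")
    if len(ied) == 0 or len(ctl) == 0:
        raise ValueError("both event sets must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable p-values", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tmap = compute_tmap(
        ied, alpha=alpha, valid_mask=valid_mask, fov_voxels=fov_voxels, grid_shape=grid_shape
    )
    observed = form_clusters(tmap)

    flat_i, vm = _as_dense_mask(ied, valid_mask, fov_voxels, grid_shape)
    flat_c, _ = _as_dense_mask(ctl, valid_mask, fov_voxels, grid_shape)
    pool = np.concatenate([flat_i, flat_c], axis=0)
    n_pool, n_ied = len(pool), len(flat_i)
    if n_pool < n_ied + 1:
        raise ValueError("degenerate pooled event set")
    nvox, nt = pool.shape[1], pool.shape[2]
    shape4 = vm.shape + (nt,)
    flat = pool.reshape(n_pool, -1)  # (pool, n_vox_valid * nt)
    flat2 = flat**2
    tcrit = stats.t.ppf(1 - alpha / 2, df=n_ied - 1)

    null: list[float] = []
    batch = 64
    sig_buf = np.zeros(shape4, dtype=bool)
    abst_buf = np.zeros(shape4)
    for start in range(0, n_perm, batch):
        b = min(batch, n_perm - start)
        sel = np.zeros((b, n_pool))
        for i in range(b):
            sel[i, rng.choice(n_pool, size=n_ied, replace=False)] = 1.0
        s1 = sel @ flat
        s2 = sel @ flat2
        mean = s1 / n_ied
        var = np.maximum(s2 - n_ied * mean**2, 0.0) / (n_ied - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n_ied)
        t[~np.isfinite(t)] = 0.0
        for i in range(b):
            ti = np.abs(t[i]).reshape(nvox, nt)
            abst_buf[vm] = ti
            sig_buf[vm] = ti > tcrit
            if null_statistic == "max":
                null.append(_max_strengths(sig_buf, abst_buf))
            else:
                labels, n = ndimage.label(sig_buf, structure=_STRUCTURE_4D)
                if n == 0:
                    null.append(0.0)
                else:
                    null.extend(
                        float(v)
                        for v in ndimage.sum_labels(abst_buf, labels, index=np.arange(1, n + 1))
                    )
    null_arr = np.asarray(null)
    for c in observed:
        b_ge = int((null_arr >= c.strength - 1e-12).sum())
        c.p_perm = (1 + b_ge) / (1 + len(null_arr))
    return observed, null_arr


def decimate_time(values: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    """Block-mean temporal decimation of (..., time) to ``target_fs``."""
    f = int(round(fs / target_fs))
    if f < 1:
        raise ValueError("target rate must be coarser")
    if f == 1:
        return np.asarray(values, float), fs
    nt = values.shape[-1]
    nb = nt // f
    out = np.asarray(values, float)[..., : nb * f].reshape(*values.shape[:-1], nb, f).mean(axis=-1)
    return out, fs / f


def cluster_timecourse(
    cluster: Cluster,
    event_images: np.ndarray,
    spatial_factor: int = 1,
    fov_voxels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- SE response over the cluster footprint at original resolution.

    ``event_images``: full-resolution (n_events, nx, ny, nz, nt) — or flat
    (n_events, n_vox, nt) over ``fov_voxels`` — for one chromophore.
    ``spatial_factor`` maps clustering-grid voxels back to the full grid
    (each coarse voxel expands to a block).  Per time sample the signal is
    first averaged over member voxels, then mean/SE taken across events.
    """
    if cluster.size == 0:
        raise ValueError("empty cluster")
    vox = cluster.voxel_footprint()
    E = np.asarray(event_images, float)
    n_ev = E.shape[0]
    f = spatial_factor
    if E.ndim == 5:
        sel = np.zeros(E.shape[1:4], dtype=bool)
        for x, y, z in vox:
            sel[x * f : (x + 1) * f, y * f : (y + 1) * f, z * f : (z + 1) * f] = True
        per_event = E[:, sel, :].mean(axis=1)  # (n_events, nt)
    else:
        if fov_voxels is None:
            raise ValueError("flat images need fov_voxels")
        coarse = np.asarray(fov_voxels, int) // f
        member = {tuple(v) for v in vox}
        cols = [i for i, v in enumerate(coarse) if tuple(v) in member]
        if not cols:
            raise ValueError("cluster footprint does not intersect the FOV voxels")
        per_event = E[:, cols, :].mean(axis=1)
    mean = per_event.mean(axis=0)
    se = per_event.std(axis=0, ddof=1) / np.sqrt(n_ev) if n_ev > 1 else np.zeros_like(mean)
    return mean, se


def trace_support(
    trace: np.ndarray,
    times_s: np.ndarray,
    level: float = 0.05,
) -> tuple[float, float, float]:
    """(onset, peak, end) of a response trace at ``level`` x its peak.

    Walks outward from the absolute peak until the trace magnitude first
    falls below the level; matches the 5 %-of-peak support convention used
    to define a simulated response's onset and duration, so recovered and
    simulated supports are directly comparable.
    """
    x = np.abs(np.asarray(trace, float))
    k = int(np.argmax(x))
    thr = level * x[k]
    i = k
    while i > 0 and x[i - 1] >= thr:
        i -= 1
    j = k
    while j < len(x) - 1 and x[j + 1] >= thr:
        j += 1
    return float(times_s[i]), float(times_s[k]), float(times_s[j])


@dataclass
class ResponseSummary:
    """Onset/peak/end of the significant response, in seconds."""

    onset_s: float
    peak_s: float
    end_s: float
    duration_s: float
    polarity: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not np.isfinite(self.onset_s)


def summarize_response(
    trace: np.ndarray,
    trace_times_s: np.ndarray,
    sig_intervals: list[tuple[float, float]],
) -> ResponseSummary:
    """Operational onset/peak/end from significant cluster intervals.

    onset = first significant time, end = last, peak = time of max |HbO|
    within [onset, end], duration = end - onset; polarity from the sign of
    the trace at each interval's own peak.
    """
    if not sig_intervals:
        return ResponseSummary(np.nan, np.nan, np.nan, np.nan, [])
    onset = min(a for a, _ in sig_intervals)
    end = max(b for _, b in sig_intervals)
    inside = (trace_times_s >= onset) & (trace_times_s <= end)
    ti = trace_times_s[inside]
    xi = trace[inside]
    peak = float(ti[np.argmax(np.abs(xi))])
    polarity = []
    for a, b in sorted(sig_intervals):
        m = (trace_times_s >= a) & (trace_times_s <= b)
        if m.any():
            v = trace[m][np.argmax(np.abs(trace[m]))]
            polarity.append("HbO up" if v >= 0 else "HbO down")
    return ResponseSummary(
        onset_s=float(onset),
        peak_s=peak,
        end_s=float(end),
        duration_s=float(end - onset),
        polarity=polarity,
    )


def summarize_cohort(values: np.ndarray) -> dict[str, float]:
    """Mean, SE (n-1 sd / sqrt(n)), median, min, max of one summary field."""
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no records")
    out = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "n": float(len(x)),
    }
    out["se"] = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return out
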