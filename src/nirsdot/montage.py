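"""Optimal optode placement over a target volume of interest.

Sources and detectors are chosen among the non-reserved 10/05 candidate
positions to maximize the summed channel sensitivity to the target VOI plus
its mirrored contralateral homolog, under the acquisition constraints (exact
optode counts, no two optodes on one position, source-detector separation
within channel bounds).  The problem is a mixed-integer linear program solved
exactly with branch and bound (HiGHS through scipy); an exhaustive oracle is
provided for verification on toy instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .forward import HeadModel, OptodeLayout, OpticalProperties, channel_sensitivity, voi_sensitivity

__all__ = [
    "VOISpec",
    "MontageSpec",
    "Montage",
    "mirror_voi",
    "pair_sensitivity_table",
    "optimize_montage",
    "brute_force_montage",
    "check_montage",
]


@dataclass
class VOISpec:
    """Target volume and its contralateral homolog (both within gray matter)."""

    target_mask: np.ndarray
    contralateral_mask: np.ndarray
    threshold_fraction: float = 0.70  # source-map threshold used to define the VOI

    def __post_init__(self) -> None:
        self.target_mask = np.asarray(self.target_mask, bool)
        self.contralateral_mask = np.asarray(self.contralateral_mask, bool)
        if not self.target_mask.any():
            raise ValueError("target VOI is empty")
        if (self.target_mask & self.contralateral_mask).any():
            raise ValueError("target and contralateral VOIs must be disjoint")


@dataclass
class MontageSpec:
    """Acquisition constraints: 8 sources and 16 detectors by default."""

    n_sources: int = 8
    n_detectors: int = 16
    channel_distance_bounds: tuple[float, float] = (15.0, 45.0)
    candidate_names: list[str] = field(default_factory=list)
    per_side_quota: bool = False  # split counts evenly between hemispheres

    def __post_init__(self) -> None:
        if self.n_sources < 1 or self.n_detectors < 1:
            raise ValueError("optode counts must be >= 1")
        lo, hi = self.channel_distance_bounds
        if not (0 < lo < hi):
            raise ValueError("channel distance bounds must satisfy 0 < min < max")


@dataclass
class Montage:
    sources: list[str]
    detectors: list[str]
    channels: list[tuple[str, str]]
    objective_value: float

    def to_tsv(self, path, layout: OptodeLayout) -> None:
        import pandas as pd

        rows = []
        for role, names in (("source", self.sources), ("detector", self.detectors)):
            for n in names:
                x, y, z = layout.coord_of(n)
                rows.append({"role": role, "name": n, "x_mm": x, "y_mm": y, "z_mm": z})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def mirror_voi(target_mask: np.ndarray, head: HeadModel) -> np.ndarray:
    """Reflect a mask across the midsagittal plane and clip to gray matter.

    The reflection of voxel index i along x is (nx - 1) - i.  Voxels of the
    reflection that fall on the original target are assigned to the target
    only and removed here.
    """
    target_mask = np.asarray(target_mask, bool)
    if target_mask.shape != head.grid_shape:
        raise ValueError("mask shape does not match the head grid")
    reflected = target_mask[::-1, :, :].copy()
    reflected &= head.gray_mask
    reflected &= ~target_mask
    return reflected


def pair_sensitivity_table(
    head: HeadModel,
    layout: OptodeLayout,
    voi: VOISpec,
    spec: MontageSpec,
    props_by_wavelength: dict[int, OpticalProperties],
    contralateral_weight: float = 1.0,
) -> dict[tuple[str, str], float]:
    """VOI sensitivity of every admissible candidate pair.

    The pair score averages over wavelengths the summed sensitivity in the
    target VOI plus ``contralateral_weight`` times the contralateral VOI.
    Only unordered pairs within the channel distance bounds are tabulated
    (both orientations score identically by reciprocity).
    """
    names = spec.candidate_names or layout.names
    coords = {n: layout.coord_of(n) for n in names}
    lo, hi = spec.channel_distance_bounds
    table: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(names), 2):
        sep = float(np.linalg.norm(coords[a][:2] - coords[b][:2]))
        if not (lo <= sep <= hi):
            continue
        score = 0.0
        for wl, props in props_by_wavelength.items():
            smap = channel_sensitivity(head, props, coords[a], coords[b], a, b)
            score += voi_sensitivity(smap, voi.target_mask)
            score += contralateral_weight * voi_sensitivity(smap, voi.contralateral_mask)
        table[(a, b)] = score / max(len(props_by_wavelength), 1)
    return table


def _admissible_pairs(pair_table: dict[tuple[str, str], float]) -> tuple[list[str], dict]:
    """Candidate name list (sorted) and a symmetric lookup of pair scores."""
    names = sorted({n for pair in pair_table for n in pair})
    sym: dict[tuple[str, str], float] = {}
    for (a, b), w in pair_table.items():
        sym[(a, b)] = w
        sym[(b, a)] = w
    return names, sym


def _montage_objective(sources, detectors, sym) -> tuple[float, list[tuple[str, str]]]:
    channels = []
    total = 0.0
    for s in sources:
        for d in detectors:
            if (s, d) in sym:
                channels.append((s, d))
                total += sym[(s, d)]
    return total, channels


def optimize_montage(
    pair_table: dict[tuple[str, str], float],
    spec: MontageSpec,
    sides: dict[str, int] | None = None,
) -> Montage:
    """Provably optimal placement by branch and bound (MILP, gap 0).

    Binary variables: s_k / d_k place a source / detector on candidate k;
    y_sd indicates an admissible channel and is linearized with y <= s,
    y <= d.  Constraints: sum(s) = n_sources, sum(d) = n_detectors,
    s_k + d_k <= 1 (one optode per position).  With ``sides`` (candidate ->
    0/1 hemisphere) and ``spec.per_side_quota``, counts are split evenly.
    """
    names, sym = _admissible_pairs(pair_table)
    n = len(names)
    if spec.n_sources + spec.n_detectors > n:
        raise ValueError(
            f"infeasible: {spec.n_sources}+{spec.n_detectors} optodes requested "
            f"but only {n} candidate positions are admissible"
        )
    idx = {nm: i for i, nm in enumerate(names)}
    pairs = [((a, b), w) for (a, b), w in pair_table.items()]
    npair = len(pairs)
    # variable layout: [s_0..s_{n-1}, d_0..d_{n-1}, y_0..y_{2*npair-1}]
    # each unordered pair contributes two oriented channels (a->b and b->a)
    nvar = 2 * n + 2 * npair
    c = np.zeros(nvar)
    rows, cols, data = [], [], []
    lb_con, ub_con = [], []
    r = 0

    def add_row(entries, lo, hi):
        nonlocal r
        for j, v in entries:
            rows.append(r)
            cols.append(j)
            data.append(v)
        lb_con.append(lo)
        ub_con.append(hi)
        r += 1

    add_row([(i, 1.0) for i in range(n)], spec.n_sources, spec.n_sources)
    add_row([(n + i, 1.0) for i in range(n)], spec.n_detectors, spec.n_detectors)
    for i in range(n):
        add_row([(i, 1.0), (n + i, 1.0)], -np.inf, 1.0)
    if spec.per_side_quota:
        if sides is None:
            raise ValueError("per_side_quota requires a sides mapping")
        left = [i for i, nm in enumerate(names) if sides[nm] == 0]
        add_row([(i, 1.0) for i in left], spec.n_sources // 2, spec.n_sources // 2)
        add_row([(n + i, 1.0) for i in left], spec.n_detectors // 2, spec.n_detectors // 2)
    for p, ((a, b), w) in enumerate(pairs):
        for orient, (src, det) in enumerate(((a, b), (b, a))):
            y = 2 * n + 2 * p + orient
            c[y] = -w  # milp minimizes
            add_row([(y, 1.0), (idx[src], -1.0)], -np.inf, 0.0)
            add_row([(y, 1.0), (n + idx[det], -1.0)], -np.inf, 0.0)

    A = sparse.csr_matrix((data, (rows, cols)), shape=(r, nvar))
    res = milp(
        c,
        constraints=LinearConstraint(A, lb_con, ub_con),
        integrality=np.ones(nvar),
        bounds=(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    x = np.round(res.x).astype(int)
    sources = [names[i] for i in range(n) if x[i] == 1]
    detectors = [names[i] for i in range(n) if x[n + i] == 1]
    objective, channels = _montage_objective(sources, detectors, sym)
    montage = Montage(
        sources=sources, detectors=detectors, channels=channels, objective_value=objective
    )
    check_montage(montage, spec, sym)
    return montage


def brute_force_montage(
    pair_table: dict[tuple[str, str], float],
    spec: MontageSpec,
    max_placements: int = 10**6,
) -> Montage:
    """Exhaustive search oracle; refuses spaces above ``max_placements``.

    Deterministic lexicographic tie-break: the first maximizer in sorted
    enumeration order is returned.
    """
    names, sym = _admissible_pairs(pair_table)
    n = len(names)
    if spec.n_sources + spec.n_detectors > n:
        raise ValueError("infeasible optode counts for the candidate set")
    from math import comb

    space = comb(n, spec.n_sources) * comb(n - spec.n_sources, spec.n_detectors)
    if space > max_placements:
        raise ValueError(f"search space {space} exceeds {max_placements} placements")
    best = None
    for srcs in itertools.combinations(names, spec.n_sources):
        rest = [nm for nm in names if nm not in srcs]
        for dets in itertools.combinations(rest, spec.n_detectors):
            total, channels = _montage_objective(srcs, dets, sym)
            if best is None or total > best[0] + 1e-12:
                best = (total, list(srcs), list(dets), channels)
    total, srcs, dets, channels = best
    return Montage(sources=srcs, detectors=dets, channels=channels, objective_value=total)


def check_montage(montage: Montage, spec: MontageSpec, sym: dict | None = None) -> None:
    """Independent constraint audit; raises on any violation."""
    if len(montage.sources) != spec.n_sources:
        raise AssertionError("wrong source count")
    if len(montage.detectors) != spec.n_detectors:
        raise AssertionError("wrong detector count")
    if set(montage.sources) & set(montage.detectors):
        raise AssertionError("a position holds two optodes")
    for s, d in montage.channels:
        if s not in montage.sources or d not in montage.detectors:
            raise AssertionError("channel references an unplaced optode")
    if sym is not None:
        recomputed = sum(sym[ch] for ch in montage.channels)
        if abs(recomputed - montage.objective_value) > 1e-9 * max(1.0, abs(recomputed)):
            raise AssertionError("objective does not match recomputation")
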