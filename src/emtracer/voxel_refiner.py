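"""Global voxel-size (magnification) calibration from placed SSE templates.

Microscope magnification errors mis-state a map's voxel size by up to ~5%,
which physically stretches or shrinks every distance measured in the map.
With no deposited model to compare against, the placed helix/strand
templates act as the calibration ruler: their geometry is known in ångström.
The original voxel size ``v_ori`` is multiplied by every factor ``m`` in
{0.900, 0.901, ..., 1.100} (201 values).  Changing the voxel size expands or
shrinks the whole grid about its origin, so each placement's translation is
rescaled by ``m`` (offset compensation) and its pose re-refined at the trial
scale before scoring — the refinement at every factor is essential: a pose
optimised only at the native scale has already partially absorbed the
magnification error, which anchors the score profile at m = 1.  Per-factor
scores are accumulated over placements and the refined voxel size is
``v_new = v_ori * argmax_m Σ_n CC_mn``.
Helix- and strand-derived estimates are combined by a weighted average with
weights equal to the number of "good" (CC > 0.3) SSEs of each kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ss_engine import CC_MIN, Placement, refine_pose, scoring_points, weighted_cc
from .template_builder import Template
from .volio import GridMap

__all__ = [
    "FACTOR_GRID",
    "VoxelScanResult",
    "scan_factor",
    "combine_kinds",
    "apply_voxel",
]

#: the scan grid: 0.9 to 1.1 in 0.001 steps, 201 entries
FACTOR_GRID = np.arange(900, 1101) / 1000.0

#: maximum per-placement argmax dispersion for a scan to count as reliable
RELIABLE_DISPERSION = 0.015


@dataclass
class VoxelScanResult:
    kind: str
    factors: np.ndarray  # (201,)
    cc_matrix: np.ndarray  # (201, n_placements)
    v_ori: float
    best_factor: float
    v_new: float
    n_good: int  # placements with CC > 0.3 at the best factor
    boundary: bool = False  # argmax on the scan boundary: unreliable

    @property
    def accumulated(self) -> np.ndarray:
        return self.cc_matrix.sum(axis=1)

    @property
    def per_placement_argmax(self) -> np.ndarray:
        return self.factors[np.argmax(self.cc_matrix, axis=0)]

    @property
    def dispersion(self) -> float:
        """Standard deviation of the per-placement argmax factors — how
        much the individual SSEs disagree about the magnification."""
        return float(np.std(self.per_placement_argmax))

    @property
    def reliable(self) -> bool:
        """A scan is trustworthy when its peak is interior and the
        per-placement estimates agree to ~2%: a kind whose individual SSEs
        scatter much more than the precision sought carries no coherent
        scale signal (short strands often do at small map sizes)."""
        return not self.boundary and self.dispersion <= RELIABLE_DISPERSION


def scan_factor(
    gmap: GridMap,
    placements: list[Placement],
    template: Template,
    anchor_step: int = 10,
    refine_maxiter: int = 250,
    max_points: int | None = 900,
    order: str = "linear",
) -> VoxelScanResult:
    """Scan the magnification factor for one template kind.

    For each factor the trial voxel is ``v_ori * m``; sampling positions
    are divided by ``m`` so the data grid never needs resampling, and each
    placement's translation is rescaled by ``m`` about the grid origin
    (offset compensation).  Poses are re-refined by a translation-only
    simplex at *anchor* factors (every ``anchor_step`` grid steps, marching
    outward from m = 1 with warm starts); between anchors the pose is
    interpolated and the weighted CC is evaluated on the full 201-point
    grid.  Anchored refinement keeps the per-factor positional optimisation
    the scan needs while confining optimiser truncation noise to a few
    well-converged solves; rotations stay at their native-scale refined
    values because a uniform magnification error never rotates features.
    """
    if not placements:
        raise ValueError("no placements to scan")
    from scipy.spatial.transform import Rotation

    v_ori = float(np.mean(gmap.voxel_size))
    factors = FACTOR_GRID
    points = scoring_points(template, max_points=max_points)
    n = len(placements)
    cc = np.zeros((len(factors), n))
    i_center = int(np.argmin(np.abs(factors - 1.0)))
    up = range(i_center, len(factors), anchor_step)
    down = range(i_center, -1, -anchor_step)
    for pi, p in enumerate(placements):
        # anchor poses, stored compensation-free (native v_ori units)
        anchors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for seq in (up, down):
            prev: int | None = None
            for ai in seq:
                m = factors[ai]
                if prev is None:
                    R0, t0 = p.rotation, p.translation * m
                else:
                    R0, tn = anchors[prev]
                    t0 = tn * m
                # the centre anchor re-converges the full 6D pose at native
                # scale; outer anchors adjust translation only (a uniform
                # magnification never rotates features)
                centre = prev is None and ai == i_center
                r = refine_pose(
                    gmap,
                    template,
                    (R0, t0),
                    points=points,
                    voxel_factor=m,
                    maxiter=500 if centre else refine_maxiter,
                    rot_step=0.02,
                    trans_step=0.05,
                    order=order,
                    fatol=1e-8 if centre else 1e-7,
                    translate_only=not centre,
                )
                anchors[ai] = (r.rotation, r.translation / m)
                prev = ai
        ais = sorted(anchors)
        if ais[-1] != len(factors) - 1:
            ais.append(len(factors) - 1)
            anchors[ais[-1]] = anchors[ais[-2]]
        if ais[0] != 0:
            ais.insert(0, 0)
            anchors[0] = anchors[ais[1]]
        for i0, i1 in zip(ais[:-1], ais[1:]):
            R0, t0 = anchors[i0]
            R1, t1 = anchors[i1]
            rv = Rotation.from_matrix(R1 @ R0.T).as_rotvec()
            for mi in range(i0, i1 + 1):
                a = (mi - i0) / (i1 - i0) if i1 > i0 else 0.0
                R = Rotation.from_rotvec(a * rv).as_matrix() @ R0
                t = ((1.0 - a) * t0 + a * t1) * factors[mi]
                cc[mi, pi] = weighted_cc(
                    gmap, template, (R, t), points,
                    voxel_factor=factors[mi], order=order,
                )
    acc = cc.sum(axis=1)
    best_i = int(np.argmax(acc))
    best = float(factors[best_i])
    boundary = best_i in (0, len(factors) - 1)
    if boundary:
        warnings.warn(
            f"{template.kind} voxel scan peaked at the boundary ({best}); unreliable",
            stacklevel=2,
        )
    n_good = int((cc[best_i] > CC_MIN).sum())
    return VoxelScanResult(
        kind=template.kind,
        factors=factors,
        cc_matrix=cc,
        v_ori=v_ori,
        best_factor=best,
        v_new=v_ori * best,
        n_good=n_good,
        boundary=boundary,
    )


def combine_kinds(
    helix_result: VoxelScanResult | None, strand_result: VoxelScanResult | None
) -> float:
    """Overall voxel size: average of the per-kind estimates weighted by the
    number of good (CC > 0.3) SSEs of each kind."""
    n_h = helix_result.n_good if helix_result is not None else 0
    n_s = strand_result.n_good if strand_result is not None else 0
    if n_h + n_s == 0:
        raise ValueError("no good SSEs of either kind; voxel size unchanged")
    v_h = helix_result.v_new if n_h else 0.0
    v_s = strand_result.v_new if n_s else 0.0
    return (n_h * v_h + n_s * v_s) / (n_h + n_s)


def apply_voxel(gmap: GridMap, v_new: float) -> GridMap:
    """Set the header voxel size to ``v_new`` (isotropic), rescaling the
    origin by the same ratio; the data array is untouched."""
    if v_new <= 0:
        raise ValueError("voxel size must be > 0")
    v_ori = float(np.mean(gmap.voxel_size))
    out = gmap.copy()
    out.voxel_size = np.full(3, v_new)
    out.origin = gmap.origin * (v_new / v_ori)
    return out
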