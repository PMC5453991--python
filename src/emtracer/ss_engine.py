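"""Secondary-structure template search in a density map.

Three steps, mirroring the usual template-matching workflow at 2.5–3.5 Å:

1. :func:`fast_search` — a deliberately imprecise pre-screen that scores a
   coarse grid of orientations × translations using only the map values at
   the template's Cα/CB positions (a handful of look-ups per pose instead of
   a full correlation).
2. :func:`weighted_cc` — the real score: the Pearson correlation between the
   map (cubic-interpolated on the transformed standard grid) and the
   template mean map, weighted per point by the template correlation map
   (negative weights clamped to zero).
3. :func:`refine_pose` — six-dimensional Nelder–Mead (rotation vector +
   translation) maximising the weighted CC from each candidate pose.

Poses are kept as ``Placement`` records (proper rotation, translation, CC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .template_builder import Template
from .volio import GridMap, interpolate

__all__ = [
    "Placement",
    "fast_search",
    "search_orientations",
    "weighted_cc",
    "refine_pose",
    "select_top",
    "scoring_points",
    "filter_cross_kind",
    "placements_to_model",
]

CC_MIN = 0.3  # minimum weighted CC for a "good" SSE
N_TOP = 20  # placements kept per kind
DEDUP_COM = 2.0  # Å: poses closer than this ...
DEDUP_AXIS = 15.0  # ... and axis-aligned within this are duplicates


@dataclass
class Placement:
    """A rigid pose of a template in the map frame: x_map = R @ x_std + t."""

    template_kind: str
    rotation: np.ndarray  # (3,3) proper
    translation: np.ndarray  # (3,)
    cc: float = 0.0
    refined: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def com(self) -> np.ndarray:
        """Template COM in the map frame (standard frame is COM-centred)."""
        return self.translation

    @property
    def axis(self) -> np.ndarray:
        """Segment axis (standard frame z) in the map frame."""
        return self.rotation[:, 2]


# --------------------------------------------------------------------------
# scoring


#: scoring support: standard-grid points within this distance (Å) of a
#: standard-segment atom, per template kind.  Helices are scored on their
#: own density footprint only — wider support couples neighbouring-molecule
#: context into the score and biases the voxel-size scan.  Strands are
#: scored with enough support to reach the neighbouring strands of their
#: sheet: an isolated short strand is nearly scale-degenerate along its
#: axis, and the inter-strand spacing carries most of a sheet's geometric
#: information.
SCORING_DIST_MAX = {"helix": 2.0, "strand": 6.0}


def scoring_points(
    template: Template,
    weight_min: float = 0.05,
    max_points: int | None = None,
    dist_max: float | None | str = "auto",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The template points that actually contribute to the weighted CC.

    Points with clamped weight ``max(corr, 0) <= weight_min`` contribute
    (almost) nothing and are dropped, as are points farther than
    ``dist_max`` from the standard segment ("auto" looks the radius up by
    template kind; pass None to keep the full 15 Å support); an optional
    deterministic stride caps the point count for speed-critical inner
    loops.
    """
    if dist_max == "auto":
        dist_max = SCORING_DIST_MAX.get(template.kind)
    w = np.maximum(template.corr_map, 0.0)
    keep = w > weight_min
    if dist_max is not None and template.distances is not None:
        keep &= template.distances <= dist_max
    sel = np.flatnonzero(keep)
    if max_points is not None and len(sel) > max_points:
        stride = int(np.ceil(len(sel) / max_points))
        sel = sel[::stride]
    return template.grid[sel], template.mean_map[sel], w[sel]


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all correlation-map weights are zero")
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    dx, dy = x - mx, y - my
    cov = (w * dx * dy).sum()
    vx = (w * dx * dx).sum()
    vy = (w * dy * dy).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def weighted_cc(
    gmap: GridMap,
    template: Template,
    pose: tuple[np.ndarray, np.ndarray] | Placement,
    points: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    voxel_factor: float = 1.0,
    order: str = "cubic",
) -> float:
    """Correlation-map-weighted Pearson CC between map and template mean map
    at a pose.

    ``voxel_factor`` evaluates the score as if the map header voxel were
    multiplied by ``m``: sampling positions are divided by ``m`` (the data
    grid itself never moves).  Outside-map points count as zero density.
    """
    if isinstance(pose, Placement):
        R, t = pose.rotation, pose.translation
    else:
        R, t = pose
    if points is None:
        points = scoring_points(template, weight_min=0.0, dist_max=None)
    grid, mean_vals, w = points
    pts = grid @ R.T + t
    if voxel_factor != 1.0:
        pts = pts / voxel_factor
    vals = interpolate(gmap, pts, order=order)
    vals = np.nan_to_num(vals, nan=0.0)
    return _weighted_pearson(vals, mean_vals, w)


# --------------------------------------------------------------------------
# fast pre-screen


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def search_orientations(
    kind: str, n_directions: int = 92, n_spins: int = 8
) -> np.ndarray:
    """A coarse SO(3) grid: Fibonacci-sphere axis directions × uniform spins
    about the segment axis (~600 orientations at the defaults).  For
    helices/strands the axis is signed ±z, so only the upper hemisphere of
    directions is needed after including the spin."""
    dirs = _fibonacci_directions(n_directions)
    spins = np.linspace(0.0, 2.0 * np.pi, n_spins, endpoint=False)
    z = np.array([0.0, 0.0, 1.0])
    out = []
    for d in dirs:
        v = np.cross(z, d)
        s, c = np.linalg.norm(v), float(z @ d)
        if s < 1e-9:
            R_align = np.eye(3) if c > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
        else:
            R_align = Rotation.from_rotvec(v / s * np.arctan2(s, c)).as_matrix()
        for a in spins:
            R_spin = Rotation.from_rotvec(z * a).as_matrix()
            out.append(R_align @ R_spin)
    return np.array(out)


def fast_search(
    gmap: GridMap,
    template: Template,
    n_keep: int = 50,
    translation_stride: int = 2,
    orientations: np.ndarray | None = None,
) -> list[Placement]:
    """Coarse candidate poses from a few-point score.

    For every orientation the template's Cα (and CB) positions are rotated
    once; every strided voxel of the map is then scored as the summed
    nearest-voxel density at those positions.  The best-scoring orientation
    per voxel survives, and the voxel score field is greedily peak-picked
    with a minimum spacing to return ``n_keep`` non-redundant candidates.
    """
    probe = template.standard_coords.coords(atom_names={"CA", "CB"})
    if any(n < p for n, p in zip(gmap.shape, (2, 2, 2))):
        raise ValueError("map smaller than template support")
    shape = np.array(gmap.shape)
    if np.any(shape * gmap.voxel_size < 8.0):
        raise ValueError("map extent smaller than template support")
    if orientations is None:
        orientations = search_orientations(template.kind)
    stride = translation_stride
    # pad with zeros so every probe offset resolves to a plain strided slice
    pad = int(np.ceil(np.max(np.abs(probe)) / float(np.min(gmap.voxel_size)))) + 1
    padded = np.pad(gmap.data, pad, mode="constant")
    n_out = [len(range(0, shape[d], stride)) for d in range(3)]
    best_score = np.full(n_out, -np.inf)
    best_ori = np.zeros(n_out, dtype=int)
    for oi, R in enumerate(orientations):
        # probe offsets in voxel units for this orientation
        off = np.round((probe @ R.T) / gmap.voxel_size).astype(int)  # (P,3)
        score = np.zeros(n_out)
        for o in off:
            sl = tuple(
                slice(pad + o[d], pad + o[d] + shape[d], stride) for d in range(3)
            )
            score += padded[sl]
        better = score > best_score
        best_score[better] = score[better]
        best_ori[better] = oi
    grid_idx = np.stack(
        np.meshgrid(
            np.arange(0, shape[0], stride),
            np.arange(0, shape[1], stride),
            np.arange(0, shape[2], stride),
            indexing="ij",
        ),
        axis=-1,
    )  # (gx,gy,gz,3)
    flat = np.argsort(best_score.ravel())[::-1]
    min_sep = max(3.0, 0.75 * DEDUP_COM)  # Å between candidate COMs
    picked: list[Placement] = []
    picked_xyz: list[np.ndarray] = []
    low_confidence = not np.any(best_score > 0)
    for f in flat:
        if len(picked) >= n_keep:
            break
        ijk = np.unravel_index(f, best_score.shape)
        xyz = gmap.index_to_xyz(grid_idx[ijk])
        if any(np.linalg.norm(xyz - p) < min_sep for p in picked_xyz):
            continue
        picked_xyz.append(xyz)
        picked.append(
            Placement(
                template.kind,
                orientations[best_ori[ijk]],
                xyz,
                cc=0.0,
                flagged=low_confidence,
            )
        )
    return picked


# --------------------------------------------------------------------------
# simplex refinement


def refine_pose(
    gmap: GridMap,
    template: Template,
    pose: Placement | tuple[np.ndarray, np.ndarray],
    points: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    voxel_factor: float = 1.0,
    maxiter: int = 300,
    rot_step: float = 0.1,
    trans_step: float = 0.5,
    order: str = "cubic",
    fatol: float = 1e-4,
    translate_only: bool = False,
) -> Placement:
    """Nelder–Mead over (rotation vector about the current pose, translation)
    maximising the weighted CC.  The returned CC never falls below the
    starting CC; non-convergence returns best-so-far, flagged.

    ``translate_only`` restricts the simplex to the 3 translation
    parameters — the right degrees of freedom when re-scoring a pose under
    a trial magnification, since a uniform scale change moves features but
    never rotates them.
    """
    if isinstance(pose, Placement):
        R0, t0 = pose.rotation, pose.translation
    else:
        R0, t0 = pose
    if points is None:
        points = scoring_points(template)
    cc0 = weighted_cc(gmap, template, (R0, t0), points, voxel_factor, order)

    if translate_only:

        def objective(p):
            return -weighted_cc(
                gmap, template, (R0, t0 + p), points, voxel_factor, order
            )

        x0 = np.zeros(3)
        steps = [trans_step] * 3
    else:

        def objective(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix() @ R0
            return -weighted_cc(
                gmap, template, (R, t0 + p[3:]), points, voxel_factor, order
            )

        x0 = np.zeros(6)
        steps = [rot_step] * 3 + [trans_step] * 3

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "fatol": fatol,
            "xatol": 1e-3,
            "initial_simplex": _initial_simplex(steps),
        },
    )
    cc1 = -res.fun
    if cc1 >= cc0:
        p = res.x
        if translate_only:
            R, t = R0, t0 + p
        else:
            R = Rotation.from_rotvec(p[:3]).as_matrix() @ R0
            t = t0 + p[3:]
    else:  # keep the starting pose: refinement must never lose ground
        R, t, cc1 = R0, t0, cc0
    return Placement(
        template.kind, R, t, cc=cc1, refined=True, flagged=not res.success and cc1 < cc0
    )


def _initial_simplex(steps: list[float]) -> np.ndarray:
    k = len(steps)
    sim = np.zeros((k + 1, k))
    for i, s in enumerate(steps):
        sim[i + 1, i] = s
    return sim


def select_top(
    placements: list[Placement],
    cc_min: float = CC_MIN,
    n_top: int = N_TOP,
) -> list[Placement]:
    """Keep the best non-redundant placements: drop cc <= cc_min, collapse
    duplicates (COM within 2 Å and axis within 15°, sign-insensitive for the
    segment axis), then truncate to the top ``n_top`` by CC."""
    good = sorted(
        (p for p in placements if p.cc > cc_min), key=lambda p: p.cc, reverse=True
    )
    kept: list[Placement] = []
    cos_tol = np.cos(np.deg2rad(DEDUP_AXIS))
    for p in good:
        dup = False
        for q in kept:
            if np.linalg.norm(p.com - q.com) < DEDUP_COM and abs(
                float(p.axis @ q.axis)
            ) > cos_tol:
                dup = True
                break
        if not dup:
            kept.append(p)
        if len(kept) >= n_top:
            break
    return kept


def filter_cross_kind(
    placements: dict[str, list[Placement]],
    templates: dict[str, Template] | None = None,
    claim_radius: float = 5.0,
) -> dict[str, list[Placement]]:
    """Arbitrate between template kinds claiming the same density.

    A helix template laid across a β-sheet (or a strand template along a
    helix) can score above the CC threshold, but the region is explained
    better by the other kind.  Each placement claims the ball of
    ``claim_radius`` Å around its COM; within a claimed region only the
    best-scoring kind survives.
    """
    out: dict[str, list[Placement]] = {}
    for kind, ps in placements.items():
        others = [q for ok, qs in placements.items() if ok != kind for q in qs]
        out[kind] = [
            p
            for p in ps
            if not any(
                q.cc > p.cc and np.linalg.norm(q.com - p.com) < claim_radius
                for q in others
            )
        ]
    return out


def placements_to_model(placements: list[Placement], template_for):
    """Placed standard segments as one AtomModel (diagnostic output)."""
    from .volio import AtomModel

    chains = []
    names = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
    for i, p in enumerate(placements):
        tpl = template_for(p.template_kind)
        placed = tpl.standard_coords.transformed(p.rotation, p.translation)
        ch = placed.chains[0]
        ch.name = names[i % len(names)]
        chains.append(ch)
    return AtomModel(chains)
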