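"""Cα-stage model building: likelihood targets, chain extension, sequence
assignment and evaluation.

The Cα log-likelihood target is an oriented density fingerprint learned from
the scaled reference map and its deposited model.  Around every interior Cα
a canonical orthonormal frame is built from the Cα(i−1), Cα(i), Cα(i+1)
triplet; the map is sampled at a fixed set of offsets (a 4 Å-radius ball at
1 Å spacing, ~250 points) expressed in that frame, and per-offset mean and
variance are accumulated.  A candidate pose is then scored with the Gaussian
log-likelihood

    score = −Σ_j [ (ρ_j − μ_j)² / (2 σ²_j) + ½ ln σ²_j ],

so high scores mean the local density looks like the density around a real
Cα.  Starting from placed secondary-structure segments, chains are grown one
Cα at a time in both directions: candidate positions on a spherical shell at
3.8 ± 0.4 Å obeying the Cα(i−1)–Cα(i+1) ≥ 4.5 Å opening constraint are
scored, the best is accepted while it stays above an adaptive threshold
calibrated on the seed region, and growth stops on threshold failure, map
exit or collision.  Per-residue-type targets built the same way support
optional sequence docking onto traced fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .volio import Atom, AtomModel, Chain, GridMap, Residue, interpolate

__all__ = [
    "LLKTarget",
    "ChainFragment",
    "offset_ball",
    "ca_frame",
    "train_llk",
    "llk_score",
    "extend_chain",
    "ExtensionParams",
    "merge_fragments",
    "assign_sequence",
    "evaluate_model",
    "fragments_to_model",
]

CA_CA_MIN, CA_CA_MAX = 3.0, 4.2  # Å, consecutive Cα distance window
CLASH_MIN = 3.0  # Å, minimum non-consecutive Cα separation
OPENING_MIN = 4.5  # Å, minimum Cα(i-1)-Cα(i+1) distance
STEP_RADII = (3.4, 3.8, 4.2)  # Å, candidate shell radii

_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA3 = {v: k for k, v in _AA1.items()}


def offset_ball(radius: float = 4.0, spacing: float = 1.0) -> np.ndarray:
    """The fixed offset set of the likelihood target: lattice points of a
    ball around the Cα, in the canonical local frame.  (J, 3) Å."""
    n = int(np.floor(radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def ca_frame(prev: np.ndarray, ca: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Orthonormal frame (columns) at a Cα from its triplet: z along
    Cα(i+1)−Cα(i−1), x toward the triplet bisector, y = z × x."""
    z = nxt - prev
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("degenerate triplet")
    z = z / nz
    bis = 0.5 * (prev + nxt) - ca
    x = bis - (bis @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # collinear triplet: any perpendicular will do, but make
        # the choice deterministic
        x = np.cross(z, [1.0, 0.0, 0.0])
        if np.linalg.norm(x) < 1e-9:
            x = np.cross(z, [0.0, 1.0, 0.0])
        x = x / np.linalg.norm(x)
    else:
        x = x / nx
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


@dataclass
class LLKTarget:
    """Per-offset density statistics in the canonical Cα frame."""

    offsets: np.ndarray  # (J, 3)
    mu: np.ndarray  # (J,)
    sigma2: np.ndarray  # (J,), floored
    kind: str = "ca"  # "ca" or a residue type ("TRP", ...)
    n_samples: int = 0

    def __post_init__(self) -> None:
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive (floored)")


@dataclass
class ChainFragment:
    """An ordered Cα trace with per-Cα scores.

    Geometry invariants: consecutive Cα 3.0–4.2 Å apart; non-consecutive
    pairs at least 3.0 Å apart.
    """

    ca: np.ndarray  # (L, 3)
    scores: np.ndarray  # (L,)
    source: str = ""
    residue_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float).reshape(-1, 3)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        if len(self.ca) != len(self.scores):
            raise ValueError("one score per Cα required")

    def __len__(self) -> int:
        return len(self.ca)

    def check_geometry(self) -> None:
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        if len(d) and (d.min() < CA_CA_MIN - 1e-9 or d.max() > CA_CA_MAX + 1e-9):
            raise ValueError("consecutive Cα distance outside [3.0, 4.2] Å")
        if len(self.ca) > 2:
            tree = cKDTree(self.ca)
            for i, j in tree.query_pairs(CLASH_MIN - 1e-9):
                if abs(i - j) > 1:
                    raise ValueError("non-consecutive Cα pair closer than 3.0 Å")

    def reversed(self) -> "ChainFragment":
        return replace(
            self,
            ca=self.ca[::-1].copy(),
            scores=self.scores[::-1].copy(),
            residue_types=None
            if self.residue_types is None
            else list(reversed(self.residue_types)),
        )


# --------------------------------------------------------------------------
# target training


def _model_triplets(model: AtomModel):
    for ch in model.chains:
        ca = [r.ca for r in ch.residues]
        for i in range(1, len(ch.residues) - 1):
            if ca[i - 1] is None or ca[i] is None or ca[i + 1] is None:
                continue
            yield ch.residues[i], ca[i - 1].pos, ca[i].pos, ca[i + 1].pos


def train_llk(
    scaled_reference: GridMap,
    reference_model: AtomModel,
    offsets: np.ndarray | None = None,
    residue_types: bool = True,
    sigma2_floor_frac: float = 1e-6,
) -> tuple[LLKTarget, dict[str, LLKTarget]]:
    """Accumulate the Cα target (and per-residue-type targets) from a scaled
    reference map and its model.

    The variance floor is ``sigma2_floor_frac`` times the map variance —
    purely numerical, it only guards offsets whose density is constant over
    the training set.
    """
    offsets = offset_ball() if offsets is None else np.asarray(offsets, dtype=float)
    triplets = list(_model_triplets(reference_model))
    if len(triplets) < 10:
        raise ValueError(f"only {len(triplets)} Cα triplets; need at least 10")
    if len(triplets) < 100:
        warnings.warn(
            f"{len(triplets)} Cα triplets is few; target statistics will be noisy",
            stacklevel=2,
        )
    floor = max(sigma2_floor_frac * float(scaled_reference.data.var()), 1e-12)
    J = len(offsets)
    sums = np.zeros(J)
    sqs = np.zeros(J)
    count = 0
    by_type: dict[str, list[np.ndarray]] = {}
    for res, prev, ca, nxt in triplets:
        frame = ca_frame(prev, ca, nxt)
        pts = ca + offsets @ frame.T
        vals = interpolate(scaled_reference, pts, order="cubic")
        if np.isnan(vals).mean() > 0.2:
            continue
        vals = np.nan_to_num(vals, nan=0.0)
        sums += vals
        sqs += vals**2
        count += 1
        if residue_types:
            by_type.setdefault(res.name, []).append(vals)
    if count == 0:
        raise ValueError("no usable triplets inside the map")
    mu = sums / count
    sigma2 = np.maximum(sqs / count - mu**2, floor)
    ca_target = LLKTarget(offsets, mu, sigma2, kind="ca", n_samples=count)
    type_targets: dict[str, LLKTarget] = {}
    for name, rows in by_type.items():
        if len(rows) < 3:
            continue
        arr = np.array(rows)
        tmu = arr.mean(axis=0)
        tsig = np.maximum(arr.var(axis=0), floor)
        type_targets[name] = LLKTarget(
            offsets, tmu, tsig, kind=name, n_samples=len(rows)
        )
    return ca_target, type_targets


def llk_score(
    gmap: GridMap,
    target: LLKTarget,
    position: np.ndarray,
    orientation: np.ndarray,
) -> float:
    """Gaussian log-likelihood of the density around a posed Cα frame.

    Offsets falling outside the map are scored as zero density, which is a
    strong penalty wherever the target expects signal; a pose entirely
    outside still returns a finite (very poor) score.
    """
    pts = np.asarray(position, dtype=float) + target.offsets @ np.asarray(orientation).T
    vals = interpolate(gmap, pts, order="cubic")
    vals = np.nan_to_num(vals, nan=0.0)
    resid = (vals - target.mu) ** 2 / (2.0 * target.sigma2)
    return float(-(resid + 0.5 * np.log(target.sigma2)).sum())


# --------------------------------------------------------------------------
# chain extension


@dataclass
class ExtensionParams:
    """Tunables of the Cα growth loop (all distances in Å)."""

    n_directions: int = 60
    radii: tuple[float, ...] = STEP_RADII
    threshold_nsigma: float = 2.0  # accept while score > μ_seed − nσ_seed
    max_steps: int = 500
    min_threshold_scores: int = 2


def _candidate_shell(n_directions: int, radii, seed: int = 0) -> np.ndarray:
    """Deterministic unit directions (Fibonacci sphere) × shell radii."""
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return np.concatenate([rad * dirs for rad in radii], axis=0)


def _seed_threshold(
    gmap: GridMap, target: LLKTarget, ca: np.ndarray, nsigma: float
) -> float:
    scores = []
    for i in range(1, len(ca) - 1):
        frame = ca_frame(ca[i - 1], ca[i], ca[i + 1])
        scores.append(llk_score(gmap, target, ca[i], frame))
    if not scores:
        raise ValueError("seed must provide at least one interior triplet")
    s = np.array(scores)
    sd = s.std() if len(s) > 1 else abs(s[0]) * 0.1 + 1.0
    return float(s.mean() - nsigma * sd)


def extend_chain(
    gmap: GridMap,
    target: LLKTarget,
    seed: np.ndarray | ChainFragment,
    params: ExtensionParams | None = None,
    avoid: np.ndarray | None = None,
    threshold: float | None = None,
) -> ChainFragment:
    """Grow a Cα trace from both ends of a seed.

    ``seed`` is an ordered (L ≥ 2, 3) Cα array (e.g. the Cαs of a placed
    SSE template) or an existing fragment.  ``avoid`` adds external Cα
    positions treated as collisions (already-built fragments).
    """
    params = params or ExtensionParams()
    ca = seed.ca.copy() if isinstance(seed, ChainFragment) else np.asarray(seed, float)
    if ca.ndim != 2 or len(ca) < 2:
        raise ValueError("seed must provide at least 2 ordered Cα positions")
    if threshold is None:
        if len(ca) >= 3:
            threshold = _seed_threshold(gmap, target, ca, params.threshold_nsigma)
        else:
            raise ValueError("a 2-Cα seed needs an explicit threshold")
    shell = _candidate_shell(params.n_directions, params.radii)
    # grow forward, then flip and grow the other way
    for _ in range(2):
        ca = _grow_one_direction(gmap, target, ca, shell, threshold, params, avoid)
        ca = ca[::-1].copy()
    scores = np.zeros(len(ca))
    for i in range(1, len(ca) - 1):
        scores[i] = llk_score(gmap, target, ca[i], ca_frame(ca[i - 1], ca[i], ca[i + 1]))
    if len(ca) > 1:
        scores[0] = scores[1]
        scores[-1] = scores[-2]
    frag = ChainFragment(ca, scores)
    frag.check_geometry()
    return frag


def _grow_one_direction(
    gmap, target, ca, shell, threshold, params, avoid
) -> np.ndarray:
    pts = [row for row in ca]
    tree_pts = None
    lo = np.asarray(gmap.origin)
    hi = lo + (np.array(gmap.shape) - 1) * gmap.voxel_size
    for _ in range(params.max_steps):
        last = pts[-1]
        prev = pts[-2]
        cand = last + shell
        # opening constraint and map bounds
        ok = np.linalg.norm(cand - prev, axis=1) >= OPENING_MIN
        ok &= np.all((cand >= lo) & (cand <= hi), axis=1)
        # collisions against the trace built so far (and external fragments)
        existing = np.array(pts[:-1])
        if avoid is not None and len(avoid):
            existing = np.vstack([existing, avoid])
        tree_pts = cKDTree(existing)
        ok &= tree_pts.query(cand)[0] >= CLASH_MIN
        cand = cand[ok]
        if len(cand) == 0:
            break
        best_score, best_pos = -np.inf, None
        for c in cand:
            frame = ca_frame(prev, last, c)
            s = llk_score(gmap, target, last, frame)
            if s > best_score:
                best_score, best_pos = s, c
        if best_score < threshold or best_pos is None:
            break
        pts.append(best_pos)
    return np.array(pts)


# --------------------------------------------------------------------------
# fragment merging


def merge_fragments(fragments: list[ChainFragment]) -> list[ChainFragment]:
    """Join end-to-end continuable fragments and drop overlapping traces.

    Overlap: two fragments sharing > 40% of the shorter one's Cαs within
    2 Å are duplicates; the one with the higher mean score survives.  After
    deduplication, ends within bonding distance (3.0–4.2 Å) are greedily
    joined when the joint passes the geometry check.
    """
    if not fragments:
        raise ValueError("no fragments to merge")
    frags = sorted(fragments, key=lambda f: float(f.scores.mean()), reverse=True)
    kept: list[ChainFragment] = []
    for f in frags:
        dup = False
        for k in kept:
            shorter, longer = (f, k) if len(f) <= len(k) else (k, f)
            d, _ = cKDTree(longer.ca).query(shorter.ca)
            if (d < 2.0).mean() > 0.4:
                dup = True
                break
        if not dup:
            kept.append(f)
    # greedy end-to-end joining
    changed = True
    while changed:
        changed = False
        for i in range(len(kept)):
            for j in range(len(kept)):
                if i == j:
                    continue
                joined = _try_join(kept[i], kept[j])
                if joined is not None:
                    kept = [k for idx, k in enumerate(kept) if idx not in (i, j)]
                    kept.append(joined)
                    changed = True
                    break
            if changed:
                break
    return kept


def _try_join(a: ChainFragment, b: ChainFragment) -> ChainFragment | None:
    for a2 in (a, a.reversed()):
        for b2 in (b, b.reversed()):
            gap = np.linalg.norm(b2.ca[0] - a2.ca[-1])
            if CA_CA_MIN <= gap <= CA_CA_MAX:
                cand = ChainFragment(
                    np.vstack([a2.ca, b2.ca]),
                    np.concatenate([a2.scores, b2.scores]),
                    source=a2.source or b2.source,
                )
                try:
                    cand.check_geometry()
                except ValueError:
                    continue
                return cand
    return None


# --------------------------------------------------------------------------
# sequence assignment


def assign_sequence(
    gmap: GridMap,
    fragments: list[ChainFragment],
    sequence: str,
    type_targets: dict[str, LLKTarget],
    margin_frac: float = 0.05,
) -> list[ChainFragment]:
    """Dock the target sequence onto each fragment.

    Every alignment of the sequence along the fragment, in both directions,
    is scored as the mean per-position residue-type log-likelihood; the best
    alignment is accepted only when it beats the runner-up by more than
    ``margin_frac`` of the spread (best − worst) of all alignment scores.
    The spread is the natural scale here: log-likelihoods carry an
    arbitrary additive offset, so a margin taken as a fraction of the best
    score itself would depend on that offset.  Fragments longer than the
    sequence, or with an ambiguous best alignment, stay unassigned.
    """
    out = []
    seq = sequence.strip().upper()
    for frag in fragments:
        L = len(frag)
        if L > len(seq) or L < 3:
            out.append(replace(frag, residue_types=None))
            continue
        scored: list[tuple[float, int, bool]] = []
        for rev in (False, True):
            fr = frag.reversed() if rev else frag
            frames = _fragment_frames(fr.ca)
            for off in range(len(seq) - L + 1):
                total = 0.0
                usable = 0
                for i in range(L):
                    tname = _AA3.get(seq[off + i])
                    tgt = type_targets.get(tname) if tname else None
                    if tgt is None or frames[i] is None:
                        continue
                    total += llk_score(gmap, tgt, fr.ca[i], frames[i])
                    usable += 1
                if usable >= max(3, L // 2):
                    scored.append((total / usable, off, rev))
        if len(scored) < 2:
            out.append(replace(frag, residue_types=None))
            continue
        scored.sort(key=lambda x: x[0], reverse=True)
        best, second = scored[0], scored[1]
        spread = best[0] - scored[-1][0]
        if spread <= 0 or best[0] - second[0] <= margin_frac * spread:
            out.append(replace(frag, residue_types=None))
            continue
        _, off, rev = best
        fr = frag.reversed() if rev else frag
        types = [_AA3.get(seq[off + i], "ALA") for i in range(L)]
        out.append(replace(fr, residue_types=types))
    return out


def _fragment_frames(ca: np.ndarray) -> list[np.ndarray | None]:
    frames: list[np.ndarray | None] = [None] * len(ca)
    for i in range(1, len(ca) - 1):
        frames[i] = ca_frame(ca[i - 1], ca[i], ca[i + 1])
    return frames


# --------------------------------------------------------------------------
# output and evaluation


def fragments_to_model(fragments: list[ChainFragment]) -> AtomModel:
    """Cα-only model: poly-ALA, or typed residues where assigned."""
    names = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    chains = []
    for fi, frag in enumerate(fragments):
        residues = []
        for i, pos in enumerate(frag.ca):
            rname = (
                frag.residue_types[i]
                if frag.residue_types is not None
                else "ALA"
            )
            residues.append(
                Residue(rname, i + 1, [Atom("CA", "C", pos, b_factor=20.0)])
            )
        chains.append(Chain(names[fi % len(names)], residues))
    return AtomModel(chains)


def evaluate_model(
    built: AtomModel, truth: AtomModel
) -> tuple[float, float, float]:
    """Model quality against ground truth.

    For every built Cα the distance to the nearest truth Cα is measured;
    returns (% within 1 Å, % within 2 Å, RMSD over those nearest-neighbour
    pairs), matching the usual Cα-completeness bookkeeping.
    """
    b = built.ca_coords()
    t = truth.ca_coords()
    if len(b) == 0 or len(t) == 0:
        raise ValueError("both models must contain Cα atoms")
    d, _ = cKDTree(t).query(b)
    within1 = 100.0 * float((d < 1.0).mean())
    within2 = 100.0 * float((d < 2.0).mean())
    rmsd = float(np.sqrt((d**2).mean()))
    return within1, within2, rmsd


def coverage(built: AtomModel, truth: AtomModel, cutoff: float = 2.0) -> float:
    """Fraction (%) of *truth* Cαs that have a built Cα within ``cutoff``."""
    b = built.ca_coords()
    t = truth.ca_coords()
    if len(b) == 0 or len(t) == 0:
        raise ValueError("both models must contain Cα atoms")
    d, _ = cKDTree(b).query(t)
    return 100.0 * float((d < cutoff).mean())
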