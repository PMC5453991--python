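"""Volume and coordinate I/O plus the geometric primitives shared by the pipeline.

Density maps are held as :class:`GridMap`: a 3D array in canonical ``x, y, z``
index order (axis 0 along x) together with the voxel size and the position of
grid index ``(0, 0, 0)`` in ångström.  Any axis permutation present in an
MRC/CCP4 file is resolved at read time, so every conversion between grid
indices and physical coordinates is permutation-free.

Atomic models are held as :class:`AtomModel`, a minimal ordered
chain/residue/atom container with optional per-residue secondary-structure
labels.  File parsing and writing go through gemmi; this module only owns the
in-memory representation and the numerics (interpolation, superposition,
Fourier low-pass filtering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "GridMap",
    "Atom",
    "Residue",
    "Chain",
    "AtomModel",
    "MapFormatError",
    "read_map",
    "write_map",
    "interpolate",
    "read_model",
    "write_model",
    "superpose",
    "lowpass_filter",
]

# rough electron counts used as atom weights in simulated density
ELEMENT_WEIGHTS = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0}


class MapFormatError(ValueError):
    """Raised when a volume file header is malformed."""


@dataclass
class GridMap:
    """A 3D density grid with physical metadata.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Density values, canonical x,y,z index order.
    voxel_size : ndarray, shape (3,)
        Å per grid step along x, y, z.  All components > 0.
    origin : ndarray, shape (3,)
        Position of grid index (0,0,0) in Å.
    resolution_hint : float or None
        Nominal resolution in Å when known (header- or user-supplied).
    """

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution_hint: float | None = None
    _spline_coeffs: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).copy()
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("map data must be 3D with >= 2 samples per axis")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self, data: np.ndarray | None = None) -> "GridMap":
        return replace(
            self,
            data=self.data.copy() if data is None else data,
            voxel_size=self.voxel_size.copy(),
            origin=self.origin.copy(),
            _spline_coeffs=None,
        )

    def index_to_xyz(self, idx: np.ndarray) -> np.ndarray:
        """Fractional grid index -> Å position."""
        return np.asarray(idx, dtype=float) * self.voxel_size + self.origin

    def xyz_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Å position -> fractional grid index."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def spline_coefficients(self) -> np.ndarray:
        """Cached cubic-spline coefficient grid for fast repeated sampling."""
        if self._spline_coeffs is None:
            self._spline_coeffs = ndimage.spline_filter(
                self.data.astype(np.float64), order=3, mode="constant"
            )
        return self._spline_coeffs


# --------------------------------------------------------------------------
# atomic models


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å
    b_factor: float = 20.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    name: str
    seq_num: int
    atoms: list[Atom] = field(default_factory=list)
    ss: str = "other"  # helix | strand | other

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    name: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class AtomModel:
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ch in self.chains:
            nums = [r.seq_num for r in ch.residues]
            if nums != sorted(nums) or len(set(nums)) != len(nums):
                raise ValueError(
                    f"residues in chain {ch.name} must be strictly ordered"
                )

    def residues(self):
        for ch in self.chains:
            yield from ch.residues

    def atoms(self):
        for r in self.residues():
            yield from r.atoms

    def coords(self, atom_names=None) -> np.ndarray:
        sel = (
            [a.pos for a in self.atoms()]
            if atom_names is None
            else [
                a.pos
                for r in self.residues()
                for a in r.atoms
                if a.name in atom_names
            ]
        )
        return np.array(sel).reshape(-1, 3)

    def ca_coords(self) -> np.ndarray:
        return self.coords(atom_names={"CA"})

    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomModel":
        """Return a copy with every atom mapped through ``R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains = []
        for ch in self.chains:
            residues = []
            for r in ch.residues:
                atoms = [
                    Atom(a.name, a.element, R @ a.pos + t, a.b_factor)
                    for a in r.atoms
                ]
                residues.append(Residue(r.name, r.seq_num, atoms, r.ss))
            chains.append(Chain(ch.name, residues))
        return AtomModel(chains)


# --------------------------------------------------------------------------
# map I/O


def _check_orthogonal(cell: gemmi.UnitCell) -> None:
    for ang, name in ((cell.alpha, "alpha"), (cell.beta, "beta"), (cell.gamma, "gamma")):
        if abs(ang - 90.0) > 1e-3:
            raise MapFormatError(
                f"non-orthogonal cell angle {name}={ang:.2f}; only P1 orthogonal maps are supported"
            )


def read_map(path: str, resolution_hint: float | None = None) -> GridMap:
    """Read an MRC2014/CCP4 map into canonical x,y,z order.

    The voxel size is the unit-cell edge divided by the grid sampling per
    axis.  The physical origin honours the ORIGIN header fields when any is
    non-zero, otherwise the start-index (NXSTART...) fields; a conflict
    (both set, disagreeing) is resolved in favour of ORIGIN with a warning.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    # resolve mapc/mapr/maps axis permutation; keep the stored extent
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = ccp4.grid
    _check_orthogonal(grid.unit_cell)
    data = np.array(grid, copy=True).astype(np.float64)  # (nu,nv,nw) == x,y,z
    if data.ndim != 3 or min(data.shape) < 2:
        raise MapFormatError("grid dimensions must be >= 2 along every axis")
    voxel = np.array(
        [
            grid.unit_cell.a / grid.nu,
            grid.unit_cell.b / grid.nv,
            grid.unit_cell.c / grid.nw,
        ]
    )
    if np.any(voxel <= 0):
        raise MapFormatError("header cell/grid imply non-positive voxel size")
    if np.ptp(voxel) > 1e-4 * voxel.mean():
        warnings.warn(f"non-cubic voxels: {voxel}", stacklevel=2)
    origin_field = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
    start_origin = nstart * voxel
    if np.any(origin_field != 0.0):
        origin = origin_field
        if np.any(nstart != 0) and not np.allclose(origin_field, start_origin, atol=1e-3):
            warnings.warn(
                "ORIGIN and NXSTART headers disagree; honouring ORIGIN",
                stacklevel=2,
            )
    else:
        origin = start_origin
    return GridMap(data, voxel, origin, resolution_hint=resolution_hint)


def write_map(gmap: GridMap, path: str) -> None:
    """Write an MRC2014 file (mode 2, P1, canonical axis order)."""
    nx, ny, nz = gmap.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(gmap.data, dtype=np.float32))
    grid.unit_cell = gemmi.UnitCell(
        nx * gmap.voxel_size[0],
        ny * gmap.voxel_size[1],
        nz * gmap.voxel_size[2],
        90.0,
        90.0,
        90.0,
    )
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), gmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


# --------------------------------------------------------------------------
# interpolation

#: Value returned for points outside the grid.  Callers treat it as
#: "no density here" (e.g. the search engines score it as zero/penalty).
OUTSIDE = np.nan


def interpolate(
    gmap: GridMap, points: np.ndarray, order: str = "cubic"
) -> np.ndarray:
    """Sample the map at Å positions.

    ``order='cubic'`` (the default) is separable third-order spline
    interpolation; ``'linear'`` is trilinear.  Points outside the grid
    return NaN (the *no density* sentinel).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return np.empty(0)
    idx = gmap.xyz_to_index(pts)
    shape = np.array(gmap.shape, dtype=float)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    out = np.full(len(pts), OUTSIDE)
    if np.any(inside):
        if order == "cubic":
            out[inside] = ndimage.map_coordinates(
                gmap.spline_coefficients(),
                idx[inside].T,
                order=3,
                prefilter=False,
                mode="constant",
            )
        elif order == "linear":
            out[inside] = _trilinear(gmap.data, idx[inside])
        else:
            raise ValueError(f"unknown interpolation order {order!r}")
    return out


def _trilinear(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorised trilinear interpolation at fractional in-bounds indices."""
    shape = np.array(data.shape)
    i0 = np.floor(idx).astype(np.intp)
    i0 = np.minimum(i0, shape - 2)  # points exactly on the upper face
    f = idx - i0
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    return (
        data[x0, y0, z0] * gx * gy * gz
        + data[x0, y0, z0 + 1] * gx * gy * fz
        + data[x0, y0 + 1, z0] * gx * fy * gz
        + data[x0, y0 + 1, z0 + 1] * gx * fy * fz
        + data[x0 + 1, y0, z0] * fx * gy * gz
        + data[x0 + 1, y0, z0 + 1] * fx * gy * fz
        + data[x0 + 1, y0 + 1, z0] * fx * fy * gz
        + data[x0 + 1, y0 + 1, z0 + 1] * fx * fy * fz
    )


# --------------------------------------------------------------------------
# superposition


def superpose(
    mobile: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets (Kabsch).

    Returns ``(R, t, rmsd)`` such that ``R @ mobile[i] + t`` best fits
    ``fixed[i]``; R is a proper rotation (det = +1).
    """
    X = np.asarray(mobile, dtype=float).reshape(-1, 3)
    Y = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape or len(X) < 3:
        raise ValueError("need equal-length paired sets with n >= 3")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave a free rotation about the common axis
    if S[1] < 1e-9 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    delta = (X0 @ R.T) - Y0
    rmsd = float(np.sqrt((delta**2).sum() / len(X)))
    return R, t, rmsd


# --------------------------------------------------------------------------
# Fourier low-pass


def lowpass_filter(gmap: GridMap, resolution: float) -> GridMap:
    """Low-pass filter to ``resolution`` Å with a smooth cosine edge.

    Amplitudes beyond the 1/resolution cutoff fall to zero across a
    cosine-shaped edge two Fourier pixels wide (avoids real-space
    ringing).  The DC term is untouched, so the map mean is preserved.
    """
    if resolution <= 2.0 * float(np.max(gmap.voxel_size)):
        raise ValueError(
            f"resolution {resolution} Å is at or below Nyquist for voxel {gmap.voxel_size}"
        )
    data = gmap.data.astype(np.float64)
    F = np.fft.rfftn(data)
    s = _freq_magnitude(gmap.shape, gmap.voxel_size, rfft=True)
    cutoff = 1.0 / resolution
    # edge width: two Fourier pixels of the largest box dimension
    extent = max(n * v for n, v in zip(gmap.shape, gmap.voxel_size))
    width = 2.0 / extent
    mask = np.ones_like(s)
    edge = (s >= cutoff) & (s < cutoff + width)
    mask[s >= cutoff + width] = 0.0
    mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (s[edge] - cutoff) / width))
    out = np.fft.irfftn(F * mask, s=gmap.shape, axes=(0, 1, 2))
    new = gmap.copy(data=out)
    return new


def _freq_magnitude(shape, voxel, rfft: bool = False) -> np.ndarray:
    """|s| (Å⁻¹) on the (r)FFT frequency grid of a map."""
    fx = np.fft.fftfreq(shape[0], d=voxel[0])
    fy = np.fft.fftfreq(shape[1], d=voxel[1])
    fz = (
        np.fft.rfftfreq(shape[2], d=voxel[2])
        if rfft
        else np.fft.fftfreq(shape[2], d=voxel[2])
    )
    return np.sqrt(
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )


# --------------------------------------------------------------------------
# model I/O (PDB via gemmi)


def read_model(path: str) -> AtomModel:
    """Read a PDB file; HELIX/SHEET records become per-residue SS labels.

    A residue without a CA atom is kept (it may still carry useful side-chain
    density) but triggers a warning so tracing callers can skip it.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    helix_ranges: list[tuple[str, int, int]] = []
    strand_ranges: list[tuple[str, int, int]] = []
    for h in st.helices:
        helix_ranges.append(
            (h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num)
        )
    for sheet in st.sheets:
        for s in sheet.strands:
            strand_ranges.append(
                (s.start.chain_name, s.start.res_id.seqid.num, s.end.res_id.seqid.num)
            )

    def label(chain: str, num: int) -> str:
        for c, a, b in helix_ranges:
            if c == chain and a <= num <= b:
                return "helix"
        for c, a, b in strand_ranges:
            if c == chain and a <= num <= b:
                return "strand"
        return "other"

    chains = []
    model = st[0]
    for gch in model:
        residues = []
        for gres in gch:
            atoms = [
                Atom(
                    ga.name,
                    ga.element.name if ga.element.name else "C",
                    np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    ga.b_iso,
                )
                for ga in gres
            ]
            res = Residue(
                gres.name,
                gres.seqid.num,
                atoms,
                ss=label(gch.name, gres.seqid.num),
            )
            if res.ca is None:
                warnings.warn(
                    f"residue {gch.name}/{gres.seqid.num} has no CA atom",
                    stacklevel=2,
                )
            residues.append(res)
        chains.append(Chain(gch.name, residues))
    return AtomModel(chains)


def write_model(model: AtomModel, path: str) -> None:
    """Write a PDB file, emitting HELIX/SHEET records from the SS labels."""
    st = gemmi.Structure()
    st.name = "emtracer"
    gmodel = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.name)
        for r in ch.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_num, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.b_iso = a.b_factor
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        gmodel.add_chain(gch)
    st.add_model(gmodel)
    for ch in model.chains:
        for start, end in _ss_runs(ch, "helix"):
            h = gemmi.Helix()
            h.start = _anchor(ch, start)
            h.end = _anchor(ch, end)
            st.helices.append(h)
        strands = list(_ss_runs(ch, "strand"))
        if strands:
            sheet = gemmi.Sheet(f"S{ch.name}")
            for start, end in strands:
                s = gemmi.Sheet.Strand()
                s.start = _anchor(ch, start)
                s.end = _anchor(ch, end)
                s.sense = 0
                sheet.strands.append(s)
            st.sheets.append(sheet)
    st.setup_entities()
    st.write_pdb(str(path))


def _ss_runs(chain: Chain, kind: str):
    """Yield (start_seqnum, end_seqnum) of maximal runs labelled ``kind``."""
    run: list[int] = []
    for r in chain.residues:
        if r.ss == kind:
            run.append(r.seq_num)
        elif run:
            yield run[0], run[-1]
            run = []
    if run:
        yield run[0], run[-1]


def _anchor(chain: Chain, seq_num: int) -> gemmi.AtomAddress:
    res = next(r for r in chain.residues if r.seq_num == seq_num)
    addr = gemmi.AtomAddress()
    addr.chain_name = chain.name
    addr.res_id = gemmi.ResidueId()
    addr.res_id.seqid = gemmi.SeqId(seq_num, " ")
    addr.res_id.name = res.name
    return addr
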