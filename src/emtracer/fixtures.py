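"""Synthetic maps and models with known ground truth.

Real benchmark maps are hundreds of megabytes; every pipeline stage here is
instead exercised on simulated data: poly-peptide segments built from ideal
backbone geometry, assembled into a small toy protein, and converted to
density by placing one normalised 3D Gaussian per atom (weight proportional
to atomic number, width set by an isotropic B-factor) followed by low-pass
filtering.  The forward model is self-consistent — templates and likelihood
targets are trained and evaluated on the same kind of density — which is
exactly what property-based testing of the pipeline requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volio import (
    ELEMENT_WEIGHTS,
    Atom,
    AtomModel,
    Chain,
    GridMap,
    Residue,
    lowpass_filter,
    superpose,
)

__all__ = [
    "SimulationSpec",
    "make_ideal_helix",
    "make_ideal_strand",
    "toy_protein",
    "training_protein",
    "simulate_map",
    "perturb_voxel_size",
    "template_training_structure",
    "model_map_pair",
]

# ideal backbone geometry (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
_HELIX_PHI, _HELIX_PSI = -57.8, -47.0
_STRAND_PHI, _STRAND_PSI = -130.0, 125.0

# heavy side-chain atoms beyond CB, used to give residue types distinct
# density footprints in simulated maps
_SIDE_LEN = {
    "GLY": -1, "ALA": 0, "SER": 1, "CYS": 1, "THR": 2, "VAL": 2, "PRO": 2,
    "LEU": 3, "ILE": 3, "ASN": 3, "ASP": 3, "MET": 4, "GLN": 4, "GLU": 4,
    "LYS": 4, "HIS": 5, "ARG": 5, "PHE": 6, "TYR": 7, "TRP": 9,
}
_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _place_atom(a, b, c, bond, angle, torsion):
    """NeRF placement: position of atom d with given internal coordinates
    relative to the chain a-b-c."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_segment(n_residues, phi, psi, sequence=None, ss="other", chain="A"):
    if n_residues < 4:
        raise ValueError("segments need at least 4 residues")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    seq = sequence or "A" * n_residues
    # seed the first residue backbone
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    C = _place_atom(np.array([-1.0, 1.0, 0.0]), N, CA, _B_CA_C, _A_N_CA_C, 60.0)
    backbone = [(N, CA, C)]
    for _ in range(1, n_residues):
        Np, CAp, Cp = backbone[-1]
        Nn = _place_atom(Np, CAp, Cp, _B_C_N, _A_CA_C_N, psi)
        CAn = _place_atom(CAp, Cp, Nn, _B_N_CA, _A_C_N_CA, 180.0)  # omega
        Cn = _place_atom(Cp, Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((Nn, CAn, Cn))
    residues = []
    for i, (N_, CA_, C_) in enumerate(backbone):
        name = _AA3.get(seq[i].upper(), "ALA")
        atoms = [Atom("N", "N", N_), Atom("CA", "C", CA_), Atom("C", "C", C_)]
        # carbonyl O: trans to the next N
        if i + 1 < n_residues:
            atoms.append(
                Atom("O", "O", _place_atom(backbone[i + 1][0], N_, C_, _B_C_O, _A_CA_C_O, 0.0))
            )
        else:
            atoms.append(Atom("O", "O", _place_atom(CA_, N_, C_, _B_C_O, _A_CA_C_O, 180.0)))
        n_side = _SIDE_LEN.get(name, 0)
        if n_side >= 0:
            # CB roughly tetrahedral off the N-CA-C plane
            b1 = (N_ - CA_) / np.linalg.norm(N_ - CA_)
            b2 = (C_ - CA_) / np.linalg.norm(C_ - CA_)
            bis = -(b1 + b2)
            bis /= np.linalg.norm(bis)
            perp = np.cross(b2, b1)
            perp /= np.linalg.norm(perp)
            cb_dir = np.cos(np.deg2rad(54.0)) * bis + np.sin(np.deg2rad(54.0)) * perp
            CB = CA_ + _B_CA_CB * cb_dir
            atoms.append(Atom("CB", "C", CB))
            # schematic side chain: a short zig-zag of carbons along cb_dir,
            # length scaled with the residue's heavy-atom count
            zig = np.cross(cb_dir, b2)
            zig /= np.linalg.norm(zig)
            for k in range(1, min(n_side, 5) + 1):
                pos = CB + 1.25 * k * cb_dir + 0.5 * (k % 2) * zig
                atoms.append(Atom(f"CG{k}", "C", pos))
        residues.append(Residue(name, i + 1, atoms, ss=ss))
    model = AtomModel([Chain(chain, residues)])
    return _to_local_frame(model)


def _to_local_frame(model: AtomModel) -> AtomModel:
    """Centre the segment on its Cα COM and align the Cα axis with z."""
    ca = model.ca_coords()
    com = ca.mean(axis=0)
    centred = ca - com
    # screw axis: Cα second differences are perpendicular to it for an
    # ideal helix (and nearly so for a pleated strand), so take the null
    # direction of their span
    d2 = ca[2:] - 2.0 * ca[1:-1] + ca[:-2]
    _, _, Vt2 = np.linalg.svd(d2, full_matrices=True)
    axis = Vt2[-1]
    # residual of the null direction; if the second differences do not span
    # a plane (near-straight chain) use the trace PCA axis instead
    if np.abs(d2 @ axis).max() > 0.3 * np.linalg.norm(d2, axis=1).max():
        _, _, Vt = np.linalg.svd(centred)
        axis = Vt[0]
    if axis @ (centred[-1] - centred[0]) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return model.transformed(R, -R @ com)


def make_ideal_helix(n_residues: int, sequence: str | None = None) -> AtomModel:
    """Ideal poly-peptide α-helix (rise ≈ 1.5 Å, ~100°/residue, Cα radius
    ≈ 2.3 Å), centred on its Cα COM with the helix axis along z."""
    return _build_segment(n_residues, _HELIX_PHI, _HELIX_PSI, sequence, ss="helix")


def make_ideal_strand(n_residues: int, sequence: str | None = None) -> AtomModel:
    """Ideal extended β-strand (rise ≈ 3.3–3.4 Å per residue), centred and
    aligned like :func:`make_ideal_helix`."""
    return _build_segment(n_residues, _STRAND_PHI, _STRAND_PSI, sequence, ss="strand")


def _place(model: AtomModel, rotation: np.ndarray, translation: np.ndarray,
           chain: str, first_seq: int = 1) -> Chain:
    placed = model.transformed(rotation, translation)
    ch = placed.chains[0]
    ch.name = chain
    for i, r in enumerate(ch.residues):
        r.seq_num = first_seq + i
    return ch


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


#: canonical sheet geometry of the synthetic world: inter-strand spacing and
#: the alternating (stagger) offsets perpendicular to the strand direction
SHEET_SPACING = 4.8  # Å between neighbouring strand axes
SHEET_STAGGER = (1.1, 0.4)  # Å alternating offsets along/out of the sheet plane


def make_sheet(
    n_strands: int,
    n_residues: int,
    sequences: list[str] | None = None,
    origin: np.ndarray | None = None,
    chain_names: str = "ABCDEFGH",
) -> list[Chain]:
    """An idealised antiparallel-style flat sheet: parallel extended strands
    at the canonical spacing with alternating stagger offsets, strand axes
    along x.  One geometry convention is used for every sheet in the
    synthetic fixtures so that the inter-strand spacing — the feature that
    carries the sheet's length-scale information — is consistent between
    template training and test structures."""
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    sheet_R = _rot([0, 1, 0], 90.0)
    chains = []
    for j in range(n_strands):
        seq = sequences[j] if sequences is not None else None
        t = origin + np.array(
            [
                SHEET_STAGGER[0] * (j % 2),
                SHEET_SPACING * j,
                SHEET_STAGGER[1] * (j % 2),
            ]
        )
        chains.append(
            _place(make_ideal_strand(n_residues, seq), sheet_R, t, chain=chain_names[j])
        )
    return chains


def toy_protein() -> AtomModel:
    """The default test structure: a 3-helix bundle plus a 4-strand sheet.

    74 residues in 7 chains, with mixed sequences so residue types have
    distinct simulated side-chain density.  All residues carry SS labels.
    """
    h_seqs = ["AAWLAFKAALEWAA", "LAKFAAEWAALFAA", "AFAELAWKAAFALA"]
    s_seqs = ["AVLFWAVA", "LAVYAFAV", "VAFALWAV", "AVLAVFAA"]
    chains = []
    helix_sites = [
        (np.array([0.0, 0.0, 0.0]), _rot([1, 0, 0], 0.0)),
        (np.array([10.5, 2.0, 0.0]), _rot([1, 0, 0], 8.0)),
        (np.array([5.0, 10.0, 1.0]), _rot([0, 1, 0], -8.0)),
    ]
    for i, ((t, R), seq) in enumerate(zip(helix_sites, h_seqs)):
        chains.append(_place(make_ideal_helix(14, seq), R, t, chain="ABC"[i]))
    chains.extend(
        make_sheet(4, 8, s_seqs, origin=np.array([26.0, -5.0, 0.0]), chain_names="DEFG")
    )
    return AtomModel(chains)


def training_protein() -> AtomModel:
    """An independent, larger fixture (120 residues) used to train
    likelihood targets so tracing is never tested on its own training set."""
    h_seqs = [
        "LEKAFAWDAVLNAKEQFA",
        "AVRELAFKWAADLEAKAA",
        "FAALEKVAWQAALDFAKA",
        "KAAFELAWVADAKQLAEA",
    ]
    s_seqs = ["AVLFWAVAYLAV", "LAVYAFAVWALV", "VAFALWAVLYAA", "AVLAVFAAWLVA"]
    chains = []
    names = "ABCDEFGH"
    for i, seq in enumerate(h_seqs):
        t = np.array([11.0 * (i % 2), 10.0 * (i // 2), 1.5 * i])
        R = _rot([1, 0, 0], 6.0 * i - 9.0)
        chains.append(_place(make_ideal_helix(18, seq), R, t, chain=names[i]))
    sheet_R = _rot([0, 1, 0], 90.0)
    for j, seq in enumerate(s_seqs):
        t = np.array([28.0 + 1.1 * (j % 2), 4.8 * j - 4.0, 0.4 * j])
        chains.append(_place(make_ideal_strand(12, seq), sheet_R, t, chain=names[4 + j]))
    return AtomModel(chains)


def template_training_structure() -> AtomModel:
    """Clean fixture for template construction: one isolated helix (14
    residues) and a 5-strand sheet (10 residues each), far apart, all with
    representative mixed sequences.

    Stands in for a well-determined experimental map/model pair.  Two
    details matter for templates that are faithful to their targets:
    mixed sequences give the mean map an average side-chain sheath matching
    the radial density profile of real SSE instances (a side-chain-free
    template is systematically "thinner" than its targets, which skews the
    voxel-size scan); and strands are trained inside a sheet so the strand
    template carries the canonical inter-strand spacing — an isolated
    strand is nearly scale-degenerate along its axis.
    """
    helix = _place(
        make_ideal_helix(14, "ALAEWAKFALEKAA"), np.eye(3), np.array([0.0, 10.0, 0.0]), chain="H"
    )
    # the sheet uses the canonical motif dimensions (4 strands x 8 residues)
    # shared by every sheet in the synthetic world: the strand template's
    # scale information lives in the sheet's transverse structure, so the
    # template must be trained on the same sheet motif it will encounter
    sheet = make_sheet(
        4,
        8,
        ["AVLFAWAV", "LAVAYAFV", "VAFALWAV", "AVLAVFAW"],
        origin=np.array([30.0, 0.0, 0.0]),
        chain_names="ABCD",
    )
    return AtomModel([helix] + sheet)


@dataclass
class SimulationSpec:
    """Parameters of the Gaussian-atom forward model.

    ``b_factor`` (Å²) sets the atomic Gaussian width via σ² = B/(8π²) plus a
    small anti-alias term tied to the voxel size; ``noise_sigma`` is the
    standard deviation of additive Gaussian noise as a fraction of the peak
    signal.  A fixed ``seed`` gives bit-identical output.
    """

    model: AtomModel
    voxel_size: float = 1.0
    box: tuple[int, int, int] | None = None
    resolution: float = 2.5
    b_factor: float = 20.0
    noise_sigma: float = 0.0
    seed: int = 0
    origin: np.ndarray | None = None
    margin: float = 7.0

    def __post_init__(self) -> None:
        if self.resolution < 2.0 * self.voxel_size:
            raise ValueError("resolution must be >= 2 * voxel_size")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def simulate_map(spec: SimulationSpec) -> GridMap:
    """Render the model as density: one normalised Gaussian per atom
    (weight ∝ atomic number), low-passed to ``spec.resolution``, plus
    optional noise.  The integral of the noise-free density equals the sum
    of atom weights (times unit volume)."""
    coords = spec.model.coords()
    weights = np.array(
        [ELEMENT_WEIGHTS.get(a.element, 6.0) for a in spec.model.atoms()]
    )
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    v = float(spec.voxel_size)
    if spec.origin is None:
        origin = lo - spec.margin
    else:
        origin = np.asarray(spec.origin, dtype=float)
    if spec.box is None:
        box = tuple(int(np.ceil((hi - origin + spec.margin)[i] / v)) for i in range(3))
    else:
        box = spec.box
    upper = origin + np.array(box) * v
    if np.any(coords < origin + 5.0 - 1e-9) or np.any(coords > upper - 5.0 + 1e-9):
        raise ValueError("model does not fit inside the box with a 5 Å margin")

    sigma2 = spec.b_factor / (8.0 * np.pi**2) + (0.8 * v) ** 2
    sigma = np.sqrt(sigma2)
    norm = (2.0 * np.pi * sigma2) ** -1.5
    cut = int(np.ceil(5.0 * sigma / v)) + 1
    data = np.zeros(box)
    axes = [origin[i] + v * np.arange(box[i]) for i in range(3)]
    for w, pos in zip(weights, coords):
        ctr = np.round((pos - origin) / v).astype(int)
        sl = [slice(max(c - cut, 0), min(c + cut + 1, b)) for c, b in zip(ctr, box)]
        dx = axes[0][sl[0]] - pos[0]
        dy = axes[1][sl[1]] - pos[1]
        dz = axes[2][sl[2]] - pos[2]
        g = np.exp(
            -(dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
            / (2.0 * sigma2)
        )
        data[sl[0], sl[1], sl[2]] += w * norm * g
    gmap = GridMap(data, np.full(3, v), origin, resolution_hint=spec.resolution)
    gmap = lowpass_filter(gmap, spec.resolution)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        peak = float(gmap.data.max())
        gmap.data = gmap.data + rng.normal(
            0.0, spec.noise_sigma * peak, size=gmap.data.shape
        )
    gmap.resolution_hint = spec.resolution
    return gmap


def model_map_pair(
    model: AtomModel | None = None, resolution: float = 2.5, **kwargs
) -> tuple[AtomModel, GridMap]:
    """Convenience: the toy protein and its simulated map."""
    model = model if model is not None else toy_protein()
    spec = SimulationSpec(model=model, resolution=resolution, **kwargs)
    return model, simulate_map(spec)


def perturb_voxel_size(gmap: GridMap, factor: float) -> GridMap:
    """Emulate a microscope magnification error: multiply the header voxel
    size (and origin, which lives in the same miscalibrated units) by
    ``factor`` while leaving the data untouched."""
    if not (0.9 <= factor <= 1.1):
        warnings.warn(
            f"voxel perturbation factor {factor} outside the ±10% regime",
            stacklevel=2,
        )
    out = gmap.copy()
    out.voxel_size = gmap.voxel_size * factor
    out.origin = gmap.origin * factor
    return out
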