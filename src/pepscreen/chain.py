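"""Reduced-representation peptide/protein chains in internal coordinates.

A chain is represented by a backbone N–Cα–C trace built from the torsions
phi and psi (the peptide-bond torsion omega is held fixed at trans), plus
zero to three side-chain pseudo-atoms per residue driven by the torsions
chi1/chi2.  All bond lengths and bond angles are held fixed at the values
of a single ideal-geometry table shipped with the package; the degrees of
freedom are torsion angles and the rigid-body pose of each chain.

Every residue formally carries 7 internal degrees of freedom — phi, psi
and chi1..chi5 — regardless of its type.  Angles a residue type does not
use ("phantom" angles) have no effect on geometry or energy but are kept
in the state vector so that mutational Monte Carlo moves between residue
types with different numbers of real degrees of freedom remain exactly
balanced: on mutation the new type inherits all 7 angles unchanged.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import ATOMS_PER_RES

#: The 20 canonical amino acid types, one-letter codes in alphabetical
#: order.  Integer codes used throughout the package are indices into
#: this string; the ordering is fixed.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_TYPES = 20

#: Number of side-chain pseudo-atoms per residue type (0..3): the count
#: of heavy atoms along the side chain, capped at three.  Glycine has
#: none, alanine a lone CB, the short/branched types two sites, and all
#: longer or aromatic types three.
SIDE_COUNTS = {
    "G": 0,
    "A": 1,
    "S": 2, "C": 2, "T": 2, "V": 2, "P": 2,
    "D": 3, "N": 3, "L": 3, "I": 3, "H": 3, "F": 3, "M": 3,
    "E": 3, "Q": 3, "K": 3, "R": 3, "W": 3, "Y": 3,
}

#: Physico-chemical classes used by the side-chain contact energy and for
#: reporting: 0 hydrophobic, 1 polar, 2 amide, 3 basic, 4 acidic.
CLASS_NAMES = ("hydrophobic", "polar", "amide", "basic", "acidic")
CLASS_OF_TYPE = {
    "A": 0, "V": 0, "L": 0, "I": 0, "P": 0, "W": 0, "F": 0, "M": 0, "Y": 0,
    "G": 1, "S": 1, "T": 1, "C": 1,
    "Q": 2, "N": 2,
    "K": 3, "R": 3, "H": 3,
    "D": 4, "E": 4,
}

SIDE_COUNTS_ARR = np.array([SIDE_COUNTS[a] for a in ALPHABET], dtype=np.int64)
CLASS_ARR = np.array([CLASS_OF_TYPE[a] for a in ALPHABET], dtype=np.int64)

#: Number of real chi angles per type: pseudo-atoms beyond the first are
#: each placed by one chi torsion.
N_CHI_USED = np.maximum(SIDE_COUNTS_ARR - 1, 0)


def aa_index(code: str) -> int:
    """Integer code of a one-letter amino acid type."""
    i = ALPHABET.find(code.upper())
    if i < 0:
        raise ValueError(f"unknown amino acid type: {code!r}")
    return i


def wrap_angle(x):
    """Wrap angle(s) to the interval (-pi, pi]."""
    y = np.asarray(x, dtype=float)
    out = y - 2.0 * np.pi * np.floor((y + np.pi) / (2.0 * np.pi))
    out = np.where(out <= -np.pi, out + 2.0 * np.pi, out)
    if np.ndim(x) == 0:
        return float(out)
    return out


def load_ideal_geometry() -> dict:
    """Read the shipped ideal-geometry table (lengths in A, angles in deg)."""
    text = (importlib.resources.files("pepscreen") / "data" / "ideal_geometry.txt").read_text()
    table = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, val = line.split()
        table[key] = float(val)
    return table


def geometry_params(table: dict | None = None) -> np.ndarray:
    """Pack the ideal-geometry table into the kernel parameter vector
    (lengths in A, angles converted to radians)."""
    t = table if table is not None else load_ideal_geometry()
    d = np.pi / 180.0
    return np.array([
        t["bond_n_ca"], t["bond_ca_c"], t["bond_c_n"],
        t["bond_ca_cb"], t["bond_side"],
        t["angle_n_ca_c"] * d, t["angle_ca_c_n"] * d, t["angle_c_n_ca"] * d,
        t["angle_n_ca_cb"] * d, t["angle_side"] * d,
        t["dihedral_cb"] * d, t["omega"] * d,
    ])


GEOM = geometry_params()


@dataclass
class SequenceState:
    """Peptide sequence with a mask of mutable positions.

    Parameters
    ----------
    residues
        Integer codes (indices into :data:`ALPHABET`), one per position.
    variable_mask
        Boolean per position; fixed positions never change during a run.
    """

    residues: np.ndarray
    variable_mask: np.ndarray

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=np.int64)
        self.variable_mask = np.asarray(self.variable_mask, dtype=bool)
        if self.residues.ndim != 1 or len(self.residues) < 1:
            raise ValueError("sequence must have length >= 1")
        if self.variable_mask.shape != self.residues.shape:
            raise ValueError("variable_mask length mismatch")
        if np.any(self.residues < 0) or np.any(self.residues >= N_TYPES):
            raise ValueError("residue code out of range")

    @classmethod
    def from_string(cls, s: str, variable: str | None = None) -> "SequenceState":
        """Build from a one-letter string; ``variable`` marks mutable
        positions with ``x`` (e.g. ``from_string("KKEAAA", "...xxx")``)."""
        res = np.array([aa_index(c) for c in s], dtype=np.int64)
        if variable is None:
            mask = np.zeros(len(s), dtype=bool)
        else:
            if len(variable) != len(s):
                raise ValueError("variable mask string length mismatch")
            mask = np.array([c in "xX*" for c in variable], dtype=bool)
        return cls(res, mask)

    @property
    def n_res(self) -> int:
        return len(self.residues)

    @property
    def variable_positions(self) -> np.ndarray:
        return np.nonzero(self.variable_mask)[0].astype(np.int64)

    def to_string(self) -> str:
        return "".join(ALPHABET[t] for t in self.residues)

    def copy(self) -> "SequenceState":
        return SequenceState(self.residues.copy(), self.variable_mask.copy())


@dataclass
class FormalDofVector:
    """The 7 formal torsional degrees of freedom per residue.

    phi/psi are arrays of shape (n_res,), chi of shape (n_res, 5); all in
    radians, wrapped to (-pi, pi].  phi of the first residue, psi of the
    last, and chi angles beyond a residue type's real count are phantom
    angles: carried, sampled, but inert.
    """

    phi: np.ndarray
    psi: np.ndarray
    chi: np.ndarray

    def __post_init__(self):
        self.phi = wrap_angle(np.asarray(self.phi, dtype=float))
        self.psi = wrap_angle(np.asarray(self.psi, dtype=float))
        self.chi = wrap_angle(np.asarray(self.chi, dtype=float))
        n = len(self.phi)
        if self.psi.shape != (n,) or self.chi.shape != (n, 5):
            raise ValueError("inconsistent dof shapes")
        if not (np.all(np.isfinite(self.phi)) and np.all(np.isfinite(self.psi))
                and np.all(np.isfinite(self.chi))):
            raise ValueError("non-finite angle")

    @classmethod
    def extended(cls, n_res: int) -> "FormalDofVector":
        """All-trans extended backbone (phi = psi = pi), chi = pi."""
        return cls(np.full(n_res, np.pi), np.full(n_res, np.pi),
                   np.full((n_res, 5), np.pi))

    def copy(self) -> "FormalDofVector":
        return FormalDofVector(self.phi.copy(), self.psi.copy(), self.chi.copy())


@dataclass
class ChainPose:
    """Rigid-body orientation (proper rotation) and translation in A."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("bad pose shapes")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def copy(self) -> "ChainPose":
        return ChainPose(self.rotation.copy(), self.translation.copy())


@dataclass
class SimulationBox:
    """Cubic simulation box; the default side matches the 50 A screening
    box with periodic boundary conditions."""

    side_length: float = 50.0
    periodic: bool = True

    def __post_init__(self):
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")


@dataclass
class Conformation:
    """Cartesian coordinates derived from (sequence, dofs, pose).

    ``coords`` has one row per atom slot (``ATOMS_PER_RES`` slots per
    residue: N, CA, C, S1..S3); unused side slots are pinned to the CA.
    """

    coords: np.ndarray
    dofs: FormalDofVector
    pose: ChainPose

    @property
    def n_res(self) -> int:
        return self.coords.shape[0] // ATOMS_PER_RES

    def ca_coords(self) -> np.ndarray:
        return self.coords[1::ATOMS_PER_RES].copy()

    def backbone_coords(self) -> np.ndarray:
        idx = np.arange(self.coords.shape[0])
        return self.coords[(idx % ATOMS_PER_RES) < 3].copy()

    def atom_coords(self, residue: int, slot: int) -> np.ndarray:
        return self.coords[residue * ATOMS_PER_RES + slot].copy()


def build_coordinates(seq: SequenceState, dofs: FormalDofVector,
                      pose: ChainPose | None = None) -> Conformation:
    """Deterministically rebuild Cartesian coordinates from internal
    coordinates.

    Only the angles a residue type actually uses affect its geometry;
    phantom angles are inert.
    """
    if pose is None:
        pose = ChainPose()
    n = seq.n_res
    if len(dofs.phi) != n:
        raise ValueError("dof length does not match sequence length")
    coords = np.empty((n * ATOMS_PER_RES, 3))
    _kernels.build_chain(seq.residues, SIDE_COUNTS_ARR, dofs.phi, dofs.psi,
                         dofs.chi, GEOM, pose.rotation, pose.translation,
                         coords)
    return Conformation(coords, dofs.copy(), pose.copy())


def apply_mutation(conf: Conformation, seq: SequenceState, position: int,
                   new_type: int | str) -> tuple[Conformation, SequenceState]:
    """Mutate one variable position and rebuild the chain.

    All 7 formal angles at the position are inherited unchanged by the
    new residue type, so mutating a->b->a restores the prior coordinates
    exactly.
    """
    if isinstance(new_type, str):
        new_type = aa_index(new_type)
    if not 0 <= new_type < N_TYPES:
        raise ValueError("unknown residue type")
    if not seq.variable_mask[position]:
        raise ValueError(f"position {position} is fixed; mutations are only "
                         "allowed at variable positions")
    new_seq = seq.copy()
    new_seq.residues[position] = new_type
    new_conf = build_coordinates(new_seq, conf.dofs, conf.pose)
    return new_conf, new_seq


def minimum_image(displacement, box: SimulationBox) -> np.ndarray:
    """Minimum-image convention: map each displacement component into
    [-L/2, L/2)."""
    if not box.periodic:
        return np.asarray(displacement, dtype=float).copy()
    d = np.asarray(displacement, dtype=float)
    L = box.side_length
    out = d - L * np.floor(d / L + 0.5)
    out = np.where(out >= 0.5 * L, out - L, out)
    return out


def measure_dihedral(a, b, c, d) -> float:
    """Dihedral angle a-b-c-d in radians, IUPAC sign convention."""
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def measure_angle(a, b, c) -> float:
    """Bond angle a-b-c in radians."""
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))
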