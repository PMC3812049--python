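"""Loading native receptor-peptide complexes from PDB files.

Only coordinate records are used: the receptor chain's Cα atoms become
typed, restrained interaction sites, and the peptide chain's Cα atoms
define the native reference coordinates (RMSD frame, constraint anchor).
"""

from __future__ import annotations

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .analysis import BindingDefinition, ConstraintSpec
from .chain import (CLASS_OF_TYPE, ChainPose, FormalDofVector,
                    SequenceState, SimulationBox)
from .system import PeptideSystem, ReceptorSites

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


def load_native_complex(path, protein_chain: str, peptide_chain: str,
                        variable: str | None = None, box_side: float = 50.0,
                        rmsd_cutoff: float = 6.0,
                        constraint: ConstraintSpec | None = None,
                        ) -> tuple[PeptideSystem, BindingDefinition]:
    """Read a native complex and prepare it for screening.

    The whole system is re-centered so the peptide C-terminal Cα (the
    constraint anchor) sits at the center of the periodic box.  The
    peptide starts from an extended conformation with its C-terminal Cα
    at the anchor; ``variable`` marks mutable peptide positions with
    'x' (default: all fixed).
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    chains = set(arr.chain_id)
    for cid, role in ((protein_chain, "protein"), (peptide_chain, "peptide")):
        if cid not in chains:
            raise ValueError(f"{role} chain {cid!r} not found in {path}")

    def _ca(chain_id):
        m = (arr.chain_id == chain_id) & (arr.atom_name == "CA")
        sub = arr[m]
        if sub.array_length() == 0:
            raise ValueError(f"no CA records in chain {chain_id!r}")
        return sub

    prot = _ca(protein_chain)
    pep = _ca(peptide_chain)

    center = np.full(3, box_side / 2.0)
    anchor_native = np.asarray(pep.coord[-1], dtype=float)
    shift = center - anchor_native

    prot_one = [_THREE_TO_ONE.get(rn, "S") for rn in prot.res_name]
    site_class = np.array([CLASS_OF_TYPE[c] for c in prot_one], dtype=np.int64)
    receptor = ReceptorSites(
        xyz=np.asarray(prot.coord, dtype=float) + shift,
        site_class=site_class,
        strength=np.ones(prot.array_length()),
        radius=np.full(prot.array_length(), 2.0))

    native_ca = np.asarray(pep.coord, dtype=float) + shift
    binding = BindingDefinition(native_ca=native_ca, rmsd_cutoff=rmsd_cutoff)

    pep_one = "".join(_THREE_TO_ONE.get(rn, "A") for rn in pep.res_name)
    seq = SequenceState.from_string(pep_one, variable)
    if len(native_ca) != seq.n_res:
        raise ValueError("native reference count does not match peptide "
                         "residue count")
    dofs = FormalDofVector.extended(seq.n_res)

    # pose the extended peptide so its C-terminal CA hits the anchor
    from .chain import build_coordinates
    probe = build_coordinates(seq, dofs, ChainPose())
    trans = binding.anchor - probe.atom_coords(seq.n_res - 1, 1)
    pose = ChainPose(np.eye(3), trans)

    system = PeptideSystem(
        seq=seq, dofs=dofs, pose=pose,
        box=SimulationBox(box_side, periodic=True),
        receptor=receptor, binding=binding,
        constraint=constraint if constraint is not None else ConstraintSpec())
    return system, binding
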