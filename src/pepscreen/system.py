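"""System containers: a peptide chain plus an optional receptor.

The receptor is represented as a set of typed interaction sites (one per
receptor residue when loaded from a structure; engineered sites for the
synthetic fixture).  Sites are harmonically restrained to their native
positions, which both keeps the receptor near its reference structure
and anchors the frame in which the peptide RMSD is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import BindingDefinition, ConstraintSpec
from .chain import ChainPose, FormalDofVector, SequenceState, SimulationBox


@dataclass
class ReceptorSites:
    """Typed receptor interaction sites.

    ``site_class`` uses the same 5 physico-chemical classes as peptide
    residues; ``strength`` scales a site's contact energies (engineered
    pocket sites use > 1).
    """

    xyz: np.ndarray
    site_class: np.ndarray
    strength: np.ndarray
    radius: np.ndarray
    native_xyz: np.ndarray = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = self.xyz.shape[0]
        self.site_class = np.asarray(self.site_class, dtype=np.int64)
        self.strength = np.asarray(self.strength, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.native_xyz is None:
            self.native_xyz = self.xyz.copy()
        self.native_xyz = np.asarray(self.native_xyz, dtype=float)
        for arr, shape in ((self.site_class, (n,)), (self.strength, (n,)),
                           (self.radius, (n,)), (self.native_xyz, (n, 3))):
            if arr.shape != shape:
                raise ValueError("inconsistent receptor array shapes")

    @property
    def n_sites(self) -> int:
        return self.xyz.shape[0]

    def copy(self) -> "ReceptorSites":
        return ReceptorSites(self.xyz.copy(), self.site_class.copy(),
                             self.strength.copy(), self.radius.copy(),
                             self.native_xyz.copy())


@dataclass
class PeptideSystem:
    """One peptide (sequence + internal coordinates + pose) in a periodic
    box, optionally together with a receptor and a binding definition."""

    seq: SequenceState
    dofs: FormalDofVector
    pose: ChainPose = field(default_factory=ChainPose)
    box: SimulationBox = field(default_factory=SimulationBox)
    receptor: ReceptorSites | None = None
    binding: BindingDefinition | None = None
    constraint: ConstraintSpec | None = None

    def unbound(self) -> "PeptideSystem":
        """The unbound reference system: the free peptide alone, with no
        receptor interactions, binding definition or pocket constraint."""
        return PeptideSystem(self.seq.copy(), self.dofs.copy(),
                             self.pose.copy(), self.box,
                             receptor=None, binding=None, constraint=None)

    def copy(self) -> "PeptideSystem":
        return PeptideSystem(
            self.seq.copy(), self.dofs.copy(), self.pose.copy(), self.box,
            self.receptor.copy() if self.receptor is not None else None,
            self.binding, self.constraint)


def make_free_peptide(sequence: str, variable: str | None = None,
                      box: SimulationBox | None = None) -> PeptideSystem:
    """Convenience constructor: an extended free peptide at the box
    center (variable positions marked with 'x')."""
    seq = SequenceState.from_string(sequence, variable)
    dofs = FormalDofVector.extended(seq.n_res)
    box = box if box is not None else SimulationBox()
    pose = ChainPose(translation=np.full(3, box.side_length / 2.0))
    return PeptideSystem(seq, dofs, pose, box)
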