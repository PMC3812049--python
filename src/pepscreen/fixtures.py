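"""Synthetic receptor fixtures with engineered, recoverable specificity.

The generator builds a receptor as typed interaction sites around the
native pose of a template peptide: a small "pocket" of sites placed
just beyond chosen peptide side chains, whose physico-chemical class
and strength set which residue classes the pocket energetically
prefers, plus a plane of mild decoy surface sites.  Because the
preference is engineered into the contact classes, screening runs can
be checked against the manifest: the preferred class must dominate the
recovered profile at the engineered position.

The default spec is a walled binding groove (steric ridge channel with
a cul-de-sac past the C-terminus) holding a tripeptide with all three
positions variable; recognition sites beside the C-terminal CB prefer
hydrophobic side chains, attract basic ones and repel acidic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .analysis import BindingDefinition, ConstraintSpec
from .chain import (CLASS_NAMES, ChainPose, FormalDofVector, SequenceState,
                    SIDE_COUNTS, SimulationBox, aa_index, build_coordinates)
from .system import PeptideSystem, ReceptorSites


@dataclass
class SyntheticReceptorSpec:
    """Blueprint of a synthetic receptor-peptide system.

    ``preferences`` maps peptide position -> (class name, strength) or a
    list of such pairs: pocket sites of those classes are placed around
    the native side chain at that position; ``strength`` multiplies
    their contact energies.
    """

    template: str = "AGL"
    variable: str = "xxx"
    preferences: dict = field(default_factory=lambda: {
        2: [("hydrophobic", 2.2), ("acidic", 1.8)],
    })
    sites_per_preference: int = 3
    pocket_distance: float = 3.5
    anchor_sites: int = 2
    anchor_strength: float = 0.8
    anchor_distance: float = 3.8
    groove_strength: float = 0.3
    groove_distance: float = 4.2
    ridge_offset: float = 5.2
    ridge_spacing: float = 2.5
    wall_distance: float = 4.0
    n_decoy: int = 16
    decoy_spacing: float = 5.0
    decoy_strength: float = 0.5
    box_side: float = 50.0
    rmsd_cutoff: float = 6.0
    constraint_strength: float = 1.0
    constraint_onset: float = 10.0
    site_radius: float = 2.0
    jitter: float = 0.3

    def __post_init__(self):
        if len(self.variable) != len(self.template):
            raise ValueError("variable mask length mismatch")
        for pos in self.preferences:
            for cls, _ in self._pref_list(pos):
                if cls not in CLASS_NAMES:
                    raise ValueError(f"unknown residue class {cls!r}")
            if not 0 <= pos < len(self.template):
                raise ValueError(f"preference position {pos} out of range")

    def _pref_list(self, pos) -> list:
        p = self.preferences[pos]
        if isinstance(p, tuple):
            return [p]
        return [tuple(e) for e in p]


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
        [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
        [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
    ])


def generate_fixture(spec: SyntheticReceptorSpec | None = None,
                     seed: int = 0) -> tuple[PeptideSystem, dict]:
    """Build the synthetic system deterministically for a seed.

    Returns the ready-to-simulate :class:`PeptideSystem` (peptide started
    in its native pose, variable positions set to alanine) and a manifest
    recording the engineered preferences for later assertion.
    """
    spec = spec if spec is not None else SyntheticReceptorSpec()
    rng = np.random.default_rng(seed)

    native_seq = SequenceState.from_string(spec.template, spec.variable)
    n_res = native_seq.n_res
    dofs = FormalDofVector.extended(n_res)
    native_conf = build_coordinates(native_seq, dofs, ChainPose())

    # shift so the C-terminal CA sits at the box center
    center = np.full(3, spec.box_side / 2.0)
    shift = center - native_conf.atom_coords(n_res - 1, 1)
    pose = ChainPose(np.eye(3), shift)
    native_conf = build_coordinates(native_seq, dofs, pose)
    native_ca = native_conf.ca_coords()

    cls_index = {name: i for i, name in enumerate(CLASS_NAMES)}
    site_xyz, site_cls, site_str = [], [], []
    pocket_manifest = []

    chain_axis = native_ca[-1] - native_ca[0]
    chain_axis /= np.linalg.norm(chain_axis)
    for pos in sorted(spec.preferences):
        k = SIDE_COUNTS[spec.template[pos].upper()]
        # anchor the recognition sites beside the first side-chain
        # pseudo-atom (CB), which every non-glycine type places
        # identically: discrimination is then class-based, not
        # reach-based
        slot = 3 if k > 0 else 1
        tip = native_conf.atom_coords(pos, slot)
        ca = native_ca[pos]
        u = tip - ca
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-9 else np.array([0.0, 0.0, 1.0])
        for entry, (cls_name, strength) in enumerate(spec._pref_list(pos)):
            for j in range(spec.sites_per_preference):
                ang = ((j - (spec.sites_per_preference - 1) / 2.0)
                       * np.deg2rad(55.0) + entry * np.deg2rad(25.0))
                direction = _rotation_about(chain_axis, ang) @ u
                p = tip + spec.pocket_distance * direction \
                    + rng.normal(0.0, spec.jitter, 3)
                site_xyz.append(p)
                site_cls.append(cls_index[cls_name])
                site_str.append(strength)
                pocket_manifest.append({"position": int(pos),
                                        "class": cls_name,
                                        "strength": float(strength),
                                        "xyz": [float(v) for v in p]})

    # binding groove: one polar site below each native residue, so the
    # full chain is rewarded for lying extended along its native
    # direction (peptides bind PDZ-like grooves in extended orientation)
    e3 = np.array([0.0, 0.0, 1.0])
    e1 = chain_axis
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    if spec.groove_strength > 0:
        for i in range(n_res):
            p = native_ca[i] - spec.groove_distance * e3 \
                + rng.normal(0.0, spec.jitter, 3)
            site_xyz.append(p)
            site_cls.append(cls_index["polar"])
            site_str.append(spec.groove_strength)

    # steric groove walls: two ridges of excluded-volume-only sites
    # (strength 0) flanking the native chain line, and a cul-de-sac wall
    # past the C-terminus, so the pocket is approachable only with the
    # chain lying along the groove
    if spec.ridge_offset > 0:
        chain_len = float(np.dot(native_ca[-1] - native_ca[0], e1))
        for t in np.arange(-spec.ridge_spacing,
                           chain_len + 2 * spec.ridge_spacing,
                           spec.ridge_spacing):
            base = native_ca[0] + t * e1
            for sign in (-1.0, 1.0):
                for height in (-0.5, 2.5):
                    p = base + sign * spec.ridge_offset * e2 \
                        + height * e3 + rng.normal(0.0, spec.jitter, 3)
                    site_xyz.append(p)
                    site_cls.append(cls_index["polar"])
                    site_str.append(0.0)
        wall_base = native_ca[-1] + spec.wall_distance * e1
        for a in (-2.2, 0.0, 2.2):
            for b in (-2.0, 0.5, 3.0):
                p = wall_base + a * e2 + b * e3 \
                    + rng.normal(0.0, spec.jitter, 3)
                site_xyz.append(p)
                site_cls.append(cls_index["polar"])
                site_str.append(0.0)

    # backbone-anchoring sites at the pocket mouth: amide-class sites at
    # hydrogen-bond distance from the C-terminal backbone (the analogue
    # of a carboxylate-binding loop), giving the pocket a sequence-
    # independent affinity component
    if spec.anchor_sites > 0:
        # direction away from the decoy surface (up) tilted off-chain
        up = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
        bb_atoms = [native_conf.atom_coords(n_res - 1, 0),
                    native_conf.atom_coords(n_res - 1, 2)]
        for j in range(spec.anchor_sites):
            base = bb_atoms[j % 2]
            p = base + spec.anchor_distance * up + rng.normal(0.0, spec.jitter, 3)
            site_xyz.append(p)
            site_cls.append(cls_index["amide"])
            site_str.append(spec.anchor_strength)
            pocket_manifest.append({"position": int(n_res - 1),
                                    "class": "amide",
                                    "strength": float(spec.anchor_strength),
                                    "role": "backbone_anchor",
                                    "xyz": [float(v) for v in p]})

    # decoy surface: a plane of mild polar sites below the peptide
    side = int(np.ceil(np.sqrt(spec.n_decoy)))
    z0 = float(np.min(native_conf.coords[:, 2])) - 4.5
    x0 = native_ca.mean(axis=0)
    count = 0
    for ix in range(side):
        for iy in range(side):
            if count >= spec.n_decoy:
                break
            p = np.array([
                x0[0] + (ix - (side - 1) / 2.0) * spec.decoy_spacing,
                x0[1] + (iy - (side - 1) / 2.0) * spec.decoy_spacing,
                z0]) + rng.normal(0.0, spec.jitter, 3)
            site_xyz.append(p)
            site_cls.append(cls_index["polar"])
            site_str.append(spec.decoy_strength)
            count += 1

    xyz = np.array(site_xyz)
    receptor = ReceptorSites(
        xyz=xyz, site_class=np.array(site_cls, dtype=np.int64),
        strength=np.array(site_str),
        radius=np.full(len(site_xyz), spec.site_radius),
        native_xyz=xyz.copy())

    binding = BindingDefinition(native_ca=native_ca,
                                rmsd_cutoff=spec.rmsd_cutoff)
    constraint = ConstraintSpec(strength=spec.constraint_strength,
                                onset=spec.constraint_onset)

    # start with alanine at the variable positions
    start_seq = native_seq.copy()
    start_seq.residues[start_seq.variable_mask] = aa_index("A")
    system = PeptideSystem(
        seq=start_seq, dofs=dofs.copy(), pose=pose.copy(),
        box=SimulationBox(spec.box_side, periodic=True),
        receptor=receptor, binding=binding, constraint=constraint)

    manifest = {
        "spec": asdict(spec),
        "seed": int(seed),
        "native_sequence": spec.template,
        "variable_positions": [int(i) for i in native_seq.variable_positions],
        "n_sites": int(receptor.n_sites),
        "pocket_sites": pocket_manifest,
        "n_decoy": int(count),
        "native_ca": [[float(v) for v in row] for row in native_ca],
        "preferences": {str(p): [{"class": c, "strength": float(s)}
                                 for c, s in spec._pref_list(p)]
                        for p in spec.preferences},
    }
    return system, manifest
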