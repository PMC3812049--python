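"""Energy models: the E(x, s) contract and two implementations.

``CoarseGrainedModel`` is the production surrogate.  Its potential is a
sum of five named physical terms — excluded-volume repulsion, local
torsional energy, backbone hydrogen bonding, side-chain contact energy,
and backbone desolvation — plus the receptor restraint and the optional
pocket constraint.  Functional forms are deliberately simple (truncated
quadratic repulsion, cosine torsions, a distance-window H-bond score, a
5x5 residue-class contact matrix, a smooth burial count); all parameters
sit in one place below.  Units are dimensionless with k_B = 1.

``ToyEnumerableModel`` is a finite catalogue of discrete peptide
"conformations" with labelled bound/unbound subsets, small enough that
partition functions can be summed exactly.  It exists to verify the
samplers and estimators against exact enumeration.
"""

from __future__ import annotations

import io
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chain import (ALPHABET, ATOMS_PER_RES, CLASS_ARR, GEOM,
                    SIDE_COUNTS_ARR)
from .system import PeptideSystem

TERM_NAMES = ("excluded_volume", "local", "hbond", "sidechain",
              "desolvation", "restraint", "constraint")

#: Default residue-class contact matrix (hydrophobic, polar, amide,
#: basic, acidic): hydrophobic-hydrophobic attraction, opposite-charge
#: attraction, like-charge repulsion, mild polar cohesion.
DEFAULT_CONTACT = np.array([
    [-1.0,  0.0,  0.0,  0.1,  0.1],
    [ 0.0, -0.2, -0.2,  0.0,  0.0],
    [ 0.0, -0.2, -0.2, -0.1, -0.1],
    [ 0.1,  0.0, -0.1,  0.6, -0.8],
    [ 0.1,  0.0, -0.1, -0.8,  0.6],
])

_EMPTY_SITES = (np.zeros((0, 3)), np.zeros(0, dtype=np.int64),
                np.zeros(0), np.zeros(0), np.zeros((0, 3)))


class EnergyModel(ABC):
    """Contract for potential energies E(x, s).

    Implementations must be finite on any legal state, independent of
    phantom angles, and report term breakdowns that sum exactly to the
    total.
    """

    name: str = "energy"

    @abstractmethod
    def total_energy(self, system) -> float:
        ...

    @abstractmethod
    def term_breakdown(self, system) -> dict:
        ...

    def energy_delta(self, system_before, system_after) -> float:
        """Energy difference of a proposed move, exact by construction
        (full recomputation; systems here are small enough that
        incremental bookkeeping buys nothing)."""
        return self.total_energy(system_after) - self.total_energy(system_before)


@dataclass
class CoarseGrainedModel(EnergyModel):
    """Five-term coarse-grained surrogate potential (see module docs).

    Parameters (dimensionless energies; distances in A)
    --------------------------------------------------
    eps_ev : soft-sphere repulsion prefactor
    w_tor, w_chi : backbone / side-chain torsion weights
    eps_hb : backbone hydrogen-bond well depth
    w_solv : backbone burial (desolvation) penalty per receptor contact
    k_restraint : harmonic restraint of receptor sites to native, per A^2
    rad_bb, rad_side : repulsion radii of backbone / side pseudo-atoms
    r_on, r_off : side-chain contact switching window
    contact : 5x5 symmetric residue-class contact matrix
    """

    eps_ev: float = 4.0
    w_tor: float = 0.3
    w_chi: float = 0.2
    eps_hb: float = 0.6
    w_solv: float = 0.15
    k_restraint: float = 5.0
    rad_bb: float = 1.5
    rad_side: float = 1.7
    r_on: float = 4.5
    r_off: float = 6.5
    contact: np.ndarray = field(default_factory=lambda: DEFAULT_CONTACT.copy())
    name: str = "coarse_grained"

    def __post_init__(self):
        self.contact = np.asarray(self.contact, dtype=float)
        if self.contact.shape != (5, 5):
            raise ValueError("contact matrix must be 5x5")
        if not np.allclose(self.contact, self.contact.T):
            raise ValueError("contact matrix must be symmetric")

    def pack_params(self, system: PeptideSystem) -> np.ndarray:
        con = system.constraint
        active = 1.0 if (con is not None and system.binding is not None) else 0.0
        k_con = con.strength if con is not None else 0.0
        d0 = con.onset if con is not None else 10.0
        return np.array([self.eps_ev, self.w_tor, self.w_chi, self.eps_hb,
                         self.w_solv, self.k_restraint, k_con, d0,
                         self.rad_bb, self.rad_side, self.r_on, self.r_off,
                         active])

    def _receptor_arrays(self, system: PeptideSystem):
        r = system.receptor
        if r is None:
            return _EMPTY_SITES
        return (r.xyz, r.site_class, r.strength, r.radius, r.native_xyz)

    def _terms(self, system: PeptideSystem) -> np.ndarray:
        seq, dofs, pose = system.seq, system.dofs, system.pose
        if len(dofs.phi) != seq.n_res:
            raise ValueError("conformation inconsistent with sequence length")
        coords = np.empty((seq.n_res * ATOMS_PER_RES, 3))
        _kernels.build_chain(seq.residues, SIDE_COUNTS_ARR, dofs.phi, dofs.psi,
                             dofs.chi, GEOM, pose.rotation, pose.translation,
                             coords)
        rec_xyz, rec_class, rec_strength, rec_radius, rec_nat = \
            self._receptor_arrays(system)
        anchor = (system.binding.anchor if system.binding is not None
                  else np.zeros(3))
        terms = np.empty(_kernels.N_TERMS)
        _kernels.chain_energy(coords, seq.residues, SIDE_COUNTS_ARR,
                              dofs.phi, dofs.psi, dofs.chi,
                              rec_xyz, rec_class, rec_strength, rec_radius,
                              rec_nat, CLASS_ARR, self.contact,
                              self.pack_params(system), anchor,
                              system.box.side_length, system.box.periodic,
                              terms)
        return terms

    def total_energy(self, system: PeptideSystem) -> float:
        return float(self._terms(system).sum())

    def term_breakdown(self, system: PeptideSystem) -> dict:
        return dict(zip(TERM_NAMES, map(float, self._terms(system))))


@dataclass
class ToyExact:
    """Exact enumeration tables of a toy model at one temperature.

    All arrays are indexed by sequence index (base ``n_alpha`` encoding
    of the variable positions)."""

    Z: np.ndarray
    Z_B: np.ndarray
    Z_U: np.ndarray
    P_B: np.ndarray
    P_U: np.ndarray
    delta_f: np.ndarray
    F_U: np.ndarray
    p_s_given_B: np.ndarray
    p_s_given_U: np.ndarray


@dataclass
class ToyEnumerableModel:
    """Finite catalogue of discrete peptide states with exact sums.

    ``e_state[c]`` is a sequence-independent state energy, ``bound[c]``
    labels the bound-like subset, and ``u_table[c, i, a]`` couples state
    c to amino acid type a at variable position i, so
    ``E(c, s) = e_state[c] + sum_i u_table[c, i, s_i]``.
    An optional reduced alphabet uses the first ``n_alpha`` letters of
    the canonical 20-letter ordering.
    """

    e_state: np.ndarray
    bound: np.ndarray
    u_table: np.ndarray
    name: str = "toy"

    def __post_init__(self):
        self.e_state = np.asarray(self.e_state, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        self.u_table = np.asarray(self.u_table, dtype=float)
        nc = len(self.e_state)
        if self.bound.shape != (nc,) or self.u_table.shape[0] != nc:
            raise ValueError("inconsistent toy-model array shapes")
        if self.n_states_total > 10 ** 7:
            raise ValueError("toy state space too large for exact sums")

    @property
    def n_states(self) -> int:
        return len(self.e_state)

    @property
    def n_var(self) -> int:
        return self.u_table.shape[1]

    @property
    def n_alpha(self) -> int:
        return self.u_table.shape[2]

    @property
    def n_seq(self) -> int:
        return self.n_alpha ** self.n_var

    @property
    def n_states_total(self) -> int:
        return self.n_states * self.n_seq

    def seq_index(self, seq_codes) -> int:
        i = 0
        for t in seq_codes:
            i = i * self.n_alpha + int(t)
        return i

    def seq_of_index(self, index: int) -> np.ndarray:
        out = np.empty(self.n_var, dtype=np.int64)
        for i in range(self.n_var - 1, -1, -1):
            out[i] = index % self.n_alpha
            index //= self.n_alpha
        return out

    def seq_string(self, index: int) -> str:
        return "".join(ALPHABET[t] for t in self.seq_of_index(index))

    def total_energy(self, state: int, seq_codes) -> float:
        e = float(self.e_state[state])
        for i, t in enumerate(seq_codes):
            e += float(self.u_table[state, i, int(t)])
        return e

    def _all_seq_energies(self) -> np.ndarray:
        """Matrix E[c, s_index] of energies over the full product space."""
        nc, nv, na = self.u_table.shape
        e = np.broadcast_to(self.e_state[:, None], (nc, 1)).astype(float)
        E = np.repeat(e, 1, axis=1)
        for i in range(nv):
            E = (E[:, :, None] + self.u_table[:, i, :][:, None, :]).reshape(nc, -1)
        return E

    def enumerate_exact(self, T: float, gamma=None) -> ToyExact:
        """Exact partition sums: per-sequence Z_s, bound/unbound split,
        binding free energies dF(s) = -T ln(Z_B/Z_U), and the conditional
        sequence distributions P(s|B), P(s|U) under the joint sampling
        weight exp(-E/T + g_s)."""
        beta = 1.0 / T
        E = self._all_seq_energies()
        w = np.exp(-beta * E)
        Z = w.sum(axis=0)
        Z_B = w[self.bound].sum(axis=0)
        Z_U = w[~self.bound].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            P_B = Z_B / Z
            P_U = Z_U / Z
            delta_f = -T * np.log(Z_B / Z_U)
            F_U = -T * np.log(Z_U)
        if gamma is None:
            g = np.zeros(self.n_seq)
        else:
            gamma = np.asarray(gamma, dtype=float)
            g = np.zeros(self.n_seq)
            for s in range(self.n_seq):
                g[s] = gamma[self.seq_of_index(s)].sum()
        wb = Z_B * np.exp(g)
        wu = Z_U * np.exp(g)
        return ToyExact(Z=Z, Z_B=Z_B, Z_U=Z_U, P_B=P_B, P_U=P_U,
                        delta_f=delta_f, F_U=F_U,
                        p_s_given_B=wb / wb.sum(),
                        p_s_given_U=wu / wu.sum())

    def exact_unbound_type_marginal(self, T: float, gamma=None) -> np.ndarray:
        """Exact P_U(a): amino acid type distribution aggregated over all
        variable positions in the unbound ensemble under ``gamma``."""
        ex = self.enumerate_exact(T, gamma)
        marg = np.zeros(self.n_alpha)
        for s in range(self.n_seq):
            for t in self.seq_of_index(s):
                marg[t] += ex.p_s_given_U[s]
        return marg / self.n_var

    # --- plain-text serialization (state id, label, coefficients) ---

    def to_text(self) -> str:
        buf = io.StringIO()
        nc, nv, na = self.u_table.shape
        buf.write(f"# toy model: {nc} states, {nv} variable positions, "
                  f"alphabet {na}\n")
        for c in range(nc):
            coeffs = "\t".join(f"{v:.10g}" for v in self.u_table[c].ravel())
            label = "B" if self.bound[c] else "U"
            buf.write(f"{c}\t{label}\t{self.e_state[c]:.10g}\t{nv}\t{na}\t{coeffs}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ToyEnumerableModel":
        e, b, u = [], [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            _, label, e_c, nv, na = parts[:5]
            nv, na = int(nv), int(na)
            e.append(float(e_c))
            b.append(label == "B")
            u.append(np.array([float(v) for v in parts[5:]]).reshape(nv, na))
        return cls(np.array(e), np.array(b), np.array(u))
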