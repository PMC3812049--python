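"""Metropolis Monte Carlo over the joint (conformation, sequence) space.

Conformational updates (pivot moves on backbone torsions, rotamer turns
on the formal chi angles, rigid-body rotations and translations, and
restrained receptor-site displacements) and mutational updates (a new
amino acid type at a random variable position, inheriting all angles)
are treated on an equal footing: every move is accepted with probability
``min(1, exp(-beta dE + dg))``, where ``dg = g_s' - g_s`` is nonzero
only for mutational moves.  With sequence weights ``g_s`` tuned so the
free-peptide sequence distribution is flat, bound-state runs generate
sequences Boltzmann-weighted by binding free energy.

One elementary MC step is one attempted move of any type.  A single
seeded generator drives each run; identical seeds give identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .chain import ALPHABET, CLASS_ARR, GEOM, N_TYPES, SIDE_COUNTS_ARR
from .analysis import ScreenResult
from .energy import CoarseGrainedModel, ToyEnumerableModel
from .system import PeptideSystem

MOVE_NAMES = ("pivot", "rotamer", "rigid_rot", "rigid_trans", "mutation",
              "receptor")


@dataclass
class ThermoState:
    """Dimensionless temperature (k_B = 1)."""

    T: float = 0.60

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / self.T


@dataclass
class MoveSchedule:
    """Relative move frequencies and amplitudes.

    Frequencies are renormalized internally; setting ``mutation = 0``
    gives an ordinary fixed-sequence canonical simulation.
    ``mutate_excl_current`` switches the mutation proposal from uniform
    over all 20 types (default; self-proposals allowed, trivially
    symmetric) to uniform over the 19 other types (also symmetric).
    """

    pivot: float = 0.25
    rotamer: float = 0.25
    rigid_rot: float = 0.10
    rigid_trans: float = 0.15
    mutation: float = 0.20
    receptor: float = 0.05
    amp_pivot: float = 0.8
    amp_rotamer: float = 1.2
    amp_rigid_rot: float = 0.35
    amp_rigid_trans: float = 0.8
    amp_receptor: float = 0.25
    mutate_excl_current: bool = False

    def frequencies(self) -> np.ndarray:
        return np.array([self.pivot, self.rotamer, self.rigid_rot,
                         self.rigid_trans, self.mutation, self.receptor])

    def cumulative(self, has_receptor: bool, has_variable: bool) -> np.ndarray:
        f = self.frequencies()
        if np.any(f < 0):
            raise ValueError("move frequencies must be nonnegative")
        if not has_receptor:
            f[5] = 0.0
        if not has_variable:
            f[4] = 0.0
        tot = f.sum()
        if tot <= 0:
            raise ValueError("all move frequencies are zero")
        return np.cumsum(f / tot)

    def amplitudes(self) -> np.ndarray:
        return np.array([self.amp_pivot, self.amp_rotamer, self.amp_rigid_rot,
                         self.amp_rigid_trans, self.amp_receptor])

    def fixed_sequence(self) -> "MoveSchedule":
        """Copy with mutational moves disabled."""
        import dataclasses
        return dataclasses.replace(self, mutation=0.0)


def metropolis_accept(delta_E: float, delta_g: float, thermo: ThermoState,
                      u: float) -> bool:
    """Metropolis criterion on the joint weight: accept iff
    ``u < min(1, exp(-beta dE + dg))``.  Conformational moves have
    ``dg = 0``."""
    arg = -thermo.beta * delta_E + delta_g
    return u < (1.0 if arg >= 0 else np.exp(arg))


def propose_mutation(seq, rng: np.random.Generator,
                     include_current: bool = True) -> tuple[int, int]:
    """Symmetric mutation proposal: a uniform variable position and a
    uniform new type (over all 20, or the 19 others)."""
    var = seq.variable_positions
    if len(var) == 0:
        raise ValueError("no variable positions")
    pos = int(var[rng.integers(len(var))])
    if include_current:
        new_t = int(rng.integers(N_TYPES))
    else:
        new_t = int(rng.integers(N_TYPES - 1))
        if new_t >= seq.residues[pos]:
            new_t += 1
    return pos, new_t


@dataclass
class ChainRunResult:
    """Trajectory statistics of one chain-system run."""

    system: PeptideSystem           # final state
    records: pd.DataFrame           # fixed-interval trajectory records
    pos_counts: np.ndarray          # (n_var, 20) unconditional, post burn-in
    bound_pos_counts: np.ndarray
    unbound_pos_counts: np.ndarray
    seq_counts_bound: np.ndarray | None
    seq_counts_unbound: np.ndarray | None
    rmsd_bin_counts: np.ndarray
    n_bound: int
    n_counted: int
    accepted: np.ndarray
    attempted: np.ndarray
    thermo: ThermoState
    angles: dict = field(default_factory=dict)

    @property
    def acceptance_rates(self) -> dict:
        with np.errstate(invalid="ignore"):
            r = self.accepted / np.maximum(self.attempted, 1)
        return dict(zip(MOVE_NAMES, r))

    @property
    def bound_flags(self) -> np.ndarray:
        """Per-step bound flags are not stored; the recorded stream is
        returned (fixed sampling interval)."""
        return self.records["bound"].to_numpy()

    def type_marginal(self) -> np.ndarray:
        """P(a) aggregated over variable positions, post burn-in."""
        tot = self.pos_counts.sum()
        if tot == 0:
            raise ValueError("no counted samples")
        return self.pos_counts.sum(axis=0) / tot

    def _seq_dict(self, counts: np.ndarray) -> dict:
        n_var = self.pos_counts.shape[0]
        out = {}
        nz = np.nonzero(counts)[0]
        for idx in nz:
            code = []
            k = idx
            for _ in range(n_var):
                code.append(k % 20)
                k //= 20
            s = "".join(ALPHABET[t] for t in reversed(code))
            out[s] = int(counts[idx])
        return out

    def to_screen_result(self, meta: dict | None = None) -> ScreenResult:
        if self.seq_counts_bound is None:
            raise ValueError("per-sequence counts not tracked for > 3 "
                             "variable positions")
        var = self.system.seq.variable_positions
        return ScreenResult(
            variable_positions=var,
            bound_counts=self._seq_dict(self.seq_counts_bound),
            unbound_counts=self._seq_dict(self.seq_counts_unbound),
            bound_pos_counts=self.bound_pos_counts.copy(),
            unbound_pos_counts=self.unbound_pos_counts.copy(),
            rmsd_bin_counts=self.rmsd_bin_counts.copy(),
            n_bound=self.n_bound, n_total=self.n_counted,
            temperature=self.thermo.T, meta=meta or {})


def run(system: PeptideSystem, model: CoarseGrainedModel, thermo: ThermoState,
        schedule: MoveSchedule | None = None, n_steps: int = 100_000,
        seed: int = 0, gamma=None, burn_in: int = 0,
        record_interval: int = 100, record_angles: bool = False) -> ChainRunResult:
    """Run the joint sampler on a chain system and collect statistics.

    ``gamma`` is the 20-entry sequence-weight table (zeros = unweighted).
    The input ``system`` is not modified; the result carries the final
    state.
    """
    schedule = schedule if schedule is not None else MoveSchedule()
    sys_ = system.copy()
    seq, dofs, pose = sys_.seq, sys_.dofs, sys_.pose
    var = seq.variable_positions
    has_receptor = sys_.receptor is not None and sys_.receptor.n_sites > 0
    move_cum = schedule.cumulative(has_receptor, len(var) > 0)

    if has_receptor:
        r = sys_.receptor
        rec = (r.xyz, r.site_class, r.strength, r.radius, r.native_xyz)
    else:
        rec = (np.zeros((0, 3)), np.zeros(0, dtype=np.int64), np.zeros(0),
               np.zeros(0), np.zeros((0, 3)))

    has_native = sys_.binding is not None
    if has_native:
        nat_ca = sys_.binding.native_ca
        anchor = sys_.binding.anchor
        cutoff = sys_.binding.rmsd_cutoff
        if nat_ca.shape[0] != seq.n_res:
            raise ValueError("native reference site count does not match "
                             "peptide length")
    else:
        nat_ca = np.zeros((seq.n_res, 3))
        anchor = np.zeros(3)
        cutoff = 6.0

    g = np.zeros(N_TYPES) if gamma is None else np.asarray(gamma, dtype=float)
    L = sys_.box.side_length
    n_bins = int(np.ceil(np.sqrt(3.0) * L)) + 1

    out = _kernels.run_chain(
        seq.residues, var, SIDE_COUNTS_ARR, CLASS_ARR, GEOM,
        dofs.phi, dofs.psi, dofs.chi, pose.rotation.copy(), pose.translation,
        *rec, model.contact, model.pack_params(sys_), nat_ca, anchor,
        has_native, L, sys_.box.periodic, g, thermo.beta,
        move_cum, schedule.amplitudes(), schedule.mutate_excl_current,
        n_steps, burn_in, record_interval, record_angles, seed,
        cutoff, n_bins)

    (pos_counts, bpc, upc, scb, scu, rbc, n_bound, n_counted, acc, att,
     rec_e, rec_rmsd, rec_bound, rec_seq, rec_phi, rec_psi, rec_chi,
     phi_f, psi_f, chi_f, rot_f, trans_f, rec_xyz_f, types_f, e_final) = out

    n_var = len(var)
    track_seq = n_var <= 3
    steps = np.arange(1, len(rec_e) + 1) * record_interval
    df = pd.DataFrame({"step": steps, "energy": rec_e, "rmsd": rec_rmsd,
                       "bound": rec_bound.astype(bool)})
    for v in range(n_var):
        df[f"pos{int(var[v])}"] = [ALPHABET[t] for t in rec_seq[:, v]]
    df["sequence"] = ["".join(ALPHABET[t] for t in row[:n_var])
                      for row in rec_seq] if n_var else ""

    sys_.seq.residues[:] = types_f
    sys_.dofs.phi[:] = phi_f
    sys_.dofs.psi[:] = psi_f
    sys_.dofs.chi[:] = chi_f
    sys_.pose.rotation = rot_f
    sys_.pose.translation[:] = trans_f
    if has_receptor:
        sys_.receptor.xyz[:] = rec_xyz_f

    angles = {}
    if record_angles:
        angles = {"phi": rec_phi, "psi": rec_psi, "chi": rec_chi}

    return ChainRunResult(
        system=sys_, records=df, pos_counts=pos_counts,
        bound_pos_counts=bpc, unbound_pos_counts=upc,
        seq_counts_bound=scb if track_seq else None,
        seq_counts_unbound=scu if track_seq else None,
        rmsd_bin_counts=rbc, n_bound=int(n_bound), n_counted=int(n_counted),
        accepted=acc, attempted=att, thermo=thermo, angles=angles)


@dataclass
class ToyRunResult:
    """Joint visit counts of a toy-model run."""

    model: ToyEnumerableModel
    counts: np.ndarray       # (n_states, n_seq)
    accepted: np.ndarray
    attempted: np.ndarray
    thermo: ThermoState

    @property
    def seq_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def seq_counts_bound(self) -> np.ndarray:
        return self.counts[self.model.bound].sum(axis=0)

    @property
    def seq_counts_unbound(self) -> np.ndarray:
        return self.counts[~self.model.bound].sum(axis=0)

    def p_seq(self) -> np.ndarray:
        c = self.seq_counts
        return c / c.sum()

    def p_seq_given_bound(self) -> np.ndarray:
        c = self.seq_counts_bound
        if c.sum() == 0:
            raise ValueError("no bound samples")
        return c / c.sum()

    def state_marginal(self) -> np.ndarray:
        c = self.counts.sum(axis=1)
        return c / c.sum()

    def type_marginal(self) -> np.ndarray:
        """P(a) aggregated over variable positions."""
        m = self.model
        marg = np.zeros(m.n_alpha)
        p = self.p_seq()
        for s in np.nonzero(p)[0]:
            for t in m.seq_of_index(s):
                marg[t] += p[s]
        return marg / m.n_var

    def p_bound_unbound_ratio(self) -> np.ndarray:
        """Estimated P_B(s)/P_U(s) per sequence (nan where undefined)."""
        b = self.seq_counts_bound.astype(float)
        u = self.seq_counts_unbound.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(u > 0, b / u, np.nan)


def run_toy(model: ToyEnumerableModel, thermo: ThermoState,
            n_steps: int = 100_000, seed: int = 0, gamma=None,
            burn_in: int = 0, restrict: str | None = None,
            p_conf: float = 0.5, init_state: int | None = None,
            init_seq=None, mutate_excl_current: bool = False) -> ToyRunResult:
    """Joint sampler on the enumerable toy catalogue.

    ``restrict`` limits conformational proposals to the bound ("B") or
    unbound ("U") subset, mirroring the restricted simulations of the
    two-step screening protocol.
    """
    if restrict is None:
        allowed = np.ones(model.n_states, dtype=np.bool_)
    elif restrict == "B":
        allowed = model.bound.copy()
    elif restrict == "U":
        allowed = ~model.bound
    else:
        raise ValueError("restrict must be None, 'B' or 'U'")
    if not allowed.any():
        raise ValueError("no states in the requested subset")
    g = np.zeros(model.n_alpha) if gamma is None \
        else np.asarray(gamma, dtype=float)
    if init_state is None:
        init_state = int(np.nonzero(allowed)[0][0])
    if not allowed[init_state]:
        raise ValueError("initial state outside the allowed subset")
    if init_seq is None:
        # alanine start at the variable positions
        init_seq = np.zeros(model.n_var, dtype=np.int64)
    init_seq = np.asarray(init_seq, dtype=np.int64)
    counts, acc, att, _, _ = _kernels.run_toy(
        model.e_state, model.u_table, allowed, g, thermo.beta, p_conf,
        init_state, init_seq, n_steps, burn_in, seed, mutate_excl_current)
    return ToyRunResult(model=model, counts=counts, accepted=acc,
                        attempted=att, thermo=thermo)
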