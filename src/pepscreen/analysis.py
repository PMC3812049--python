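"""Bound-state geometry and derived binding statistics.

Binding is monitored by the Cα root-mean-square distance (RMSD) of the
peptide to its native, receptor-anchored reference coordinates — no
superposition is applied, because the receptor is restrained to its
native frame and a superposition would erase the binding pose.  The
bound state B is defined as RMSD < 6 A (strict); everything else is U.

From bound/unbound sample counts the module derives binding free
energies ``dF = -T ln(P_B / P_U)``, screening-based relative free
energies ``dF(s) = -T ln P(s|B)`` (reported relative to the weakest
observed binder), per-position specificity profiles, their sequence
entropies, and RMSD-conditioned amino acid distributions used in
binding-site discovery mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import ALPHABET


@dataclass
class BindingDefinition:
    """Native reference geometry defining the bound state.

    Parameters
    ----------
    native_ca
        Native peptide Cα coordinates (n_sites, 3), receptor frame, A.
    rmsd_cutoff
        Bound iff RMSD < cutoff (strict); default 6 A.
    """

    native_ca: np.ndarray
    rmsd_cutoff: float = 6.0

    def __post_init__(self):
        self.native_ca = np.asarray(self.native_ca, dtype=float)
        if self.native_ca.ndim != 2 or self.native_ca.shape[0] < 1 \
                or self.native_ca.shape[1] != 3:
            raise ValueError("native_ca must be (n_sites, 3) with n_sites >= 1")
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")

    @property
    def n_sites(self) -> int:
        return self.native_ca.shape[0]

    @property
    def anchor(self) -> np.ndarray:
        """Native position of the peptide C-terminal Cα (constraint anchor)."""
        return self.native_ca[-1]


@dataclass
class ConstraintSpec:
    """Piecewise-linear pocket constraint: zero up to ``onset`` A of
    C-terminal Cα displacement from its native position, then a linear
    ramp of slope ``strength`` (dimensionless energy per A)."""

    strength: float = 1.0
    onset: float = 10.0

    def __post_init__(self):
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if self.onset <= 0:
            raise ValueError("onset must be positive")


def rmsd(model_coords, native_coords) -> float:
    """Root-mean-square distance between matched coordinate sets, in the
    shared receptor-anchored frame (no superposition)."""
    a = np.asarray(model_coords, dtype=float)
    b = np.asarray(native_coords, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate shapes differ")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def classify_bound(rmsd_value: float, binding: BindingDefinition) -> bool:
    """Bound iff RMSD strictly below the cutoff."""
    return rmsd_value < binding.rmsd_cutoff


def constraint_energy(d: float, spec: ConstraintSpec) -> float:
    """Pocket-constraint energy k * max(0, d - onset)."""
    return spec.strength * max(0.0, d - spec.onset)


def sequence_entropy(p) -> float:
    """Shannon entropy (nats) of a normalized profile, 0*ln0 = 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


@dataclass
class FreeEnergyEstimate:
    """Binding free energy of one sequence: dF = -T ln(P_B / P_U)."""

    delta_f: float
    p_bound: float
    p_unbound: float
    std_err: float = np.nan
    n_samples: int = 0


def estimate_delta_f_fixed(bound_flags, thermo) -> FreeEnergyEstimate:
    """Fixed-sequence binding free energy from a stream of bound flags.

    ``bound_flags`` may be one array or a list of arrays from independent
    runs; with several runs the standard error across per-run estimates
    is reported.
    """
    if isinstance(bound_flags, np.ndarray) and bound_flags.ndim == 1:
        runs = [bound_flags]
    else:
        runs = [np.asarray(r) for r in bound_flags]
    T = thermo.T
    estimates = []
    n_tot = 0
    nb_tot = 0
    for r in runs:
        nb = int(np.sum(r != 0))
        nu = len(r) - nb
        n_tot += len(r)
        nb_tot += nb
        if nb > 0 and nu > 0:
            estimates.append(-T * np.log(nb / nu))
    if nb_tot == 0 or nb_tot == n_tot:
        raise ValueError(
            "trajectory contains no bound/unbound transitions; binding free "
            "energy is undefined (adjust temperature or constraint)")
    pb = nb_tot / n_tot
    df = -T * np.log(pb / (1.0 - pb))
    se = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates))) \
        if len(estimates) > 1 else np.nan
    return FreeEnergyEstimate(delta_f=float(df), p_bound=pb, p_unbound=1.0 - pb,
                              std_err=se, n_samples=n_tot)


@dataclass
class ScreenResult:
    """Accumulated statistics of one bound-state screening run.

    ``bound_counts``/``unbound_counts`` map sequence strings (variable
    positions only) to sample counts; positional count matrices have
    shape (n_var, 20) in :data:`~pepscreen.chain.ALPHABET` order.
    """

    variable_positions: np.ndarray
    bound_counts: dict
    unbound_counts: dict
    bound_pos_counts: np.ndarray
    unbound_pos_counts: np.ndarray
    rmsd_bin_counts: np.ndarray  # (n_bins, n_var, 20), 1 A bins
    n_bound: int
    n_total: int
    temperature: float
    meta: dict = field(default_factory=dict)

    @property
    def p_bound(self) -> float:
        return self.n_bound / self.n_total if self.n_total else np.nan

    @property
    def p_unbound(self) -> float:
        return 1.0 - self.p_bound

    @property
    def n_var(self) -> int:
        return len(self.variable_positions)

    def position_profile(self, position: int) -> np.ndarray:
        """Conditional amino acid distribution p_i(a) among bound samples
        at variable position index ``position`` (normalized over 20)."""
        c = self.bound_pos_counts[position].astype(float)
        tot = c.sum()
        if tot == 0:
            raise ValueError("no bound samples; profile undefined")
        return c / tot

    def profiles(self) -> pd.DataFrame:
        """Position x type profile matrix (weblogo-style PWM)."""
        rows = [self.position_profile(i) for i in range(self.n_var)]
        return pd.DataFrame(rows, columns=list(ALPHABET),
                            index=[int(p) for p in self.variable_positions])

    def entropies(self) -> np.ndarray:
        """Per-position sequence entropy S_i in nats (max ln 20)."""
        return np.array([sequence_entropy(self.position_profile(i))
                         for i in range(self.n_var)])

    def p_seq_given_bound(self) -> dict:
        """Empirical conditional sequence distribution P(s|B)."""
        tot = sum(self.bound_counts.values())
        if tot == 0:
            raise ValueError("no bound samples")
        return {s: c / tot for s, c in self.bound_counts.items()}


def position_profile(result: ScreenResult, position: int) -> np.ndarray:
    return result.position_profile(position)


def estimate_delta_f_screen(result: ScreenResult, thermo,
                            min_count: int = 10) -> pd.Series:
    """Relative binding free energies from the bound-state sequence
    distribution: dF(s) = -T ln P(s|B), shifted so the weakest observed
    binder (largest dF among sequences with at least ``min_count`` bound
    samples) sits at zero.  Unobserved sequences are absent."""
    T = thermo.T
    counts = {s: c for s, c in result.bound_counts.items() if c > 0}
    if not counts:
        raise ValueError("no bound samples; screening dF undefined")
    tot = sum(counts.values())
    df = {s: -T * np.log(c / tot) for s, c in counts.items()}
    anchored = [s for s, c in counts.items() if c >= min_count]
    if not anchored:
        anchored = list(counts)
    ref = max(df[s] for s in anchored)
    ser = pd.Series({s: v - ref for s, v in df.items()}, name="delta_f")
    return ser.sort_values()


def merge_screen_results(results: list) -> ScreenResult:
    """Pool counts from independent screening runs of the same system."""
    if not results:
        raise ValueError("nothing to merge")
    first = results[0]
    for r in results[1:]:
        if not np.array_equal(r.variable_positions, first.variable_positions) \
                or r.temperature != first.temperature:
            raise ValueError("runs are not compatible")
    bound = {}
    unbound = {}
    for r in results:
        for s, c in r.bound_counts.items():
            bound[s] = bound.get(s, 0) + c
        for s, c in r.unbound_counts.items():
            unbound[s] = unbound.get(s, 0) + c
    return ScreenResult(
        variable_positions=first.variable_positions.copy(),
        bound_counts=bound, unbound_counts=unbound,
        bound_pos_counts=sum(r.bound_pos_counts for r in results),
        unbound_pos_counts=sum(r.unbound_pos_counts for r in results),
        rmsd_bin_counts=sum(r.rmsd_bin_counts for r in results),
        n_bound=sum(r.n_bound for r in results),
        n_total=sum(r.n_total for r in results),
        temperature=first.temperature,
        meta={"n_runs": len(results)})


def profile_by_rmsd(result: ScreenResult, position: int,
                    min_samples: int = 1) -> pd.DataFrame:
    """Amino acid distribution conditioned on 1 A RMSD bins,
    P(a | RMSD bin), at one variable position.  Bins with fewer than
    ``min_samples`` samples are omitted (marked absent)."""
    out = {}
    for b in range(result.rmsd_bin_counts.shape[0]):
        c = result.rmsd_bin_counts[b, position].astype(float)
        tot = c.sum()
        if tot >= min_samples and tot > 0:
            out[b] = c / tot
    frame = pd.DataFrame.from_dict(out, orient="index", columns=list(ALPHABET))
    frame.index.name = "rmsd_bin"
    return frame
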