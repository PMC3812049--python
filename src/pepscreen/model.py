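"""High-level modelling interface: build, fit, inspect.

:class:`PeptideScreeningModel` bundles a receptor-peptide system with an
energy model, a thermodynamic state and a move schedule;
:meth:`~PeptideScreeningModel.fit` executes the full two-step screening
protocol (iterative unbound-state flattening, then replicate bound-state
screening runs) and returns a :class:`ScreeningResults` carrying the
specificity profiles, per-position entropies, relative binding free
energies with replicate standard errors, and diagnostics.

Example
-------
>>> from pepscreen import PeptideScreeningModel
>>> model = PeptideScreeningModel.from_fixture(seed=1)
>>> results = model.fit(n_steps=500_000, n_runs=3, seed=7)
>>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mcmc
from .analysis import (ScreenResult, estimate_delta_f_fixed,
                       estimate_delta_f_screen, merge_screen_results,
                       profile_by_rmsd)
from .chain import ALPHABET
from .energy import CoarseGrainedModel
from .fixtures import SyntheticReceptorSpec, generate_fixture
from .mcmc import MoveSchedule, ThermoState
from .multisequence import (FlatteningDiagnostics, GammaTable, flatten_unbound,
                            screen_bound)
from .system import PeptideSystem


class PeptideScreeningModel:
    """Multisequence Monte Carlo screening of one receptor-peptide system.

    Parameters
    ----------
    system
        The receptor-peptide system (e.g. from :func:`from_fixture` or
        :func:`~pepscreen.pdbio.load_native_complex`).
    energy_model, thermo, schedule
        Energy function, temperature and move mix; defaults are the
        package's standard coarse-grained model at T = 0.60.
    """

    def __init__(self, system: PeptideSystem,
                 energy_model: CoarseGrainedModel | None = None,
                 thermo: ThermoState | None = None,
                 schedule: MoveSchedule | None = None):
        self.system = system
        self.energy_model = energy_model or CoarseGrainedModel()
        self.thermo = thermo or ThermoState()
        self.schedule = schedule or MoveSchedule()
        self.gamma_: GammaTable | None = None
        self.flatten_diagnostics_: FlatteningDiagnostics | None = None
        self.manifest: dict | None = None

    @classmethod
    def from_fixture(cls, spec: SyntheticReceptorSpec | None = None,
                     seed: int = 0, **kwargs) -> "PeptideScreeningModel":
        """Build from the synthetic receptor fixture."""
        system, manifest = generate_fixture(spec, seed=seed)
        obj = cls(system, **kwargs)
        obj.manifest = manifest
        return obj

    @classmethod
    def from_pdb(cls, path, protein_chain: str, peptide_chain: str,
                 variable: str | None = None, **kwargs) -> "PeptideScreeningModel":
        """Build from a native complex in PDB format."""
        from .pdbio import load_native_complex
        system, _ = load_native_complex(path, protein_chain, peptide_chain,
                                        variable=variable)
        return cls(system, **kwargs)

    # --- step 1: unbound-state flattening ---

    def flatten(self, tol: float = 0.10, max_iter: int = 30,
                steps_per_iter: int = 200_000, seed: int = 0,
                ) -> tuple[GammaTable, FlatteningDiagnostics]:
        """Iteratively flatten the free-peptide sequence distribution;
        caches the resulting gamma table on the model."""
        gamma, diag = flatten_unbound(
            self.system, self.energy_model, self.thermo, tol=tol,
            max_iter=max_iter, steps_per_iter=steps_per_iter, seed=seed,
            schedule=self.schedule)
        self.gamma_ = gamma
        self.flatten_diagnostics_ = diag
        return gamma, diag

    # --- step 2: bound-state screening ---

    def fit(self, n_steps: int = 1_000_000, n_runs: int = 3, seed: int = 0,
            gamma: GammaTable | None = None, unrestrained: bool = False,
            flatten_kwargs: dict | None = None) -> "ScreeningResults":
        """Run the two-step protocol and return pooled results.

        ``unrestrained = True`` removes the pocket constraint (discovery
        mode: the peptide may roam the whole box).  Replicate runs use
        seeds ``seed + 1000*k``.
        """
        if gamma is None and self.gamma_ is None:
            self.flatten(seed=seed + 500_000, **(flatten_kwargs or {}))
        gamma = gamma or self.gamma_
        system = self.system.copy()
        if unrestrained:
            system.constraint = None
        runs = []
        for k in range(n_runs):
            runs.append(screen_bound(
                system, self.energy_model, gamma, self.thermo, self.schedule,
                n_steps=n_steps, seed=seed + 1000 * k))
        pooled = merge_screen_results(runs)
        return ScreeningResults(model=self, gamma=gamma, runs=runs,
                                pooled=pooled,
                                diagnostics=self.flatten_diagnostics_)

    # --- fixed-sequence reference protocol ---

    def fixed_sequence_delta_f(self, sequence: str, n_steps: int = 500_000,
                               n_runs: int = 2, seed: int = 0,
                               burn_in_fraction: float = 0.10):
        """Binding free energy of one fixed sequence,
        dF = -T ln(P_B/P_U), from ordinary canonical runs (no
        mutational moves)."""
        system = self.system.copy()
        fixed = system.seq.copy()
        codes = [ALPHABET.index(c) for c in sequence.upper()]
        if len(codes) != fixed.n_res:
            raise ValueError("sequence length mismatch")
        fixed.residues[:] = codes
        fixed.variable_mask[:] = False
        system.seq = fixed
        flags = []
        for k in range(n_runs):
            res = mcmc.run(system, self.energy_model, self.thermo,
                           self.schedule.fixed_sequence(), n_steps=n_steps,
                           seed=seed + 1000 * k,
                           burn_in=int(burn_in_fraction * n_steps),
                           record_interval=max(n_steps // 5000, 1))
            flags.append(np.concatenate([
                np.ones(res.n_bound, dtype=bool),
                np.zeros(res.n_counted - res.n_bound, dtype=bool)]))
        return estimate_delta_f_fixed(flags, self.thermo)


@dataclass
class ScreeningResults:
    """Results of a fitted screening model (statsmodels-style).

    Attributes
    ----------
    gamma : the flattened sequence-weight table used for screening
    runs : per-replicate :class:`ScreenResult` objects
    pooled : counts pooled over replicates
    """

    model: PeptideScreeningModel
    gamma: GammaTable
    runs: list
    pooled: ScreenResult
    diagnostics: FlatteningDiagnostics | None = None

    @property
    def p_bound(self) -> float:
        return self.pooled.p_bound

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def profiles(self) -> pd.DataFrame:
        """Position x 20 specificity profile matrix P(a at i | B)."""
        return self.pooled.profiles()

    def entropies(self) -> pd.Series:
        """Per-position sequence entropies S_i (nats; ln 20 = 3.00 is a
        fully promiscuous position)."""
        return pd.Series(self.pooled.entropies(),
                         index=[int(p) for p in
                                self.pooled.variable_positions],
                         name="entropy")

    def delta_f(self, min_count: int = 10) -> pd.DataFrame:
        """Relative binding free energies -T ln P(s|B) (pooled), with
        standard errors over replicate runs where available."""
        pooled = estimate_delta_f_screen(self.pooled, self.model.thermo,
                                         min_count=min_count)
        per_run = []
        for r in self.runs:
            try:
                per_run.append(estimate_delta_f_screen(
                    r, self.model.thermo, min_count=max(min_count // 2, 1)))
            except ValueError:
                pass
        frame = pd.DataFrame({"delta_f": pooled})
        if len(per_run) > 1:
            stack = pd.concat(per_run, axis=1)
            frame["std_err"] = stack.std(axis=1, ddof=1) / np.sqrt(stack.shape[1])
        counts = pd.Series(self.pooled.bound_counts)
        frame["n_bound"] = counts.reindex(frame.index).fillna(0).astype(int)
        return frame

    def rmsd_profile(self, position: int = -1) -> pd.DataFrame:
        """P(a | RMSD bin) at one variable position (discovery mode)."""
        idx = position if position >= 0 else self.pooled.n_var + position
        return profile_by_rmsd(self.pooled, idx)

    def summary(self) -> str:
        """Human-readable report."""
        lines = []
        w = 62
        lines.append(" Multisequence Monte Carlo peptide screening ".center(w, "="))
        lines.append(f"Energy model: {self.model.energy_model.name}"
                     f"    T = {self.model.thermo.T:g} (dimensionless)")
        n_steps = self.pooled.n_total // max(self.n_runs, 1)
        lines.append(f"Replicates:   {self.n_runs} x {n_steps:,} counted steps")
        lines.append(f"P(bound) = {self.p_bound:.3f}   "
                     f"bound samples = {self.pooled.n_bound:,}")
        if self.diagnostics is not None:
            d = self.diagnostics
            state = "converged" if d.converged else "NOT converged"
            lines.append(f"Flattening:   {state} after {d.n_iterations} "
                         f"iterations, max deviation "
                         f"{d.max_rel_deviation[-1]*100:.1f}% (tol "
                         f"{d.tol*100:.0f}%)")
        lines.append("-" * w)
        lines.append("Position profiles (top 3 types) and entropy "
                     "[ln 20 = 3.00 nats]:")
        prof = self.profiles()
        ent = self.entropies()
        for pos in prof.index:
            row = prof.loc[pos].sort_values(ascending=False)
            top = "  ".join(f"{a}:{v:.2f}" for a, v in row.head(3).items())
            lines.append(f"  position {pos}:  {top}   S = {ent[pos]:.2f}")
        lines.append("-" * w)
        df = self.delta_f()
        lines.append("Strongest binders (dF relative to weakest observed):")
        for s, row in df.head(5).iterrows():
            se = (f" +/- {row['std_err']:.2f}"
                  if "std_err" in row and np.isfinite(row.get("std_err", np.nan))
                  else "")
            lines.append(f"  {s}:  dF = {row['delta_f']:.2f}{se}"
                         f"   (n_bound = {int(row['n_bound'])})")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Stacked-bar rendering of the specificity profile matrix."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * self.pooled.n_var + 2, 3))
        prof = self.profiles()
        bottom = np.zeros(len(prof))
        for a in ALPHABET:
            vals = prof[a].to_numpy()
            ax.bar(prof.index.astype(str), vals, bottom=bottom, label=a)
            bottom += vals
        ax.set_xlabel("peptide position")
        ax.set_ylabel("P(a | bound)")
        ax.set_ylim(0, 1)
        return ax
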