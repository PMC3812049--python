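"""Sequence weights g_s and the two-step screening protocol.

The joint sampling weight is ``exp(-beta E(x, s) + g_s)``.  The package
uses the linear form ``g_s = sum_i gamma(s_i)`` over the variable
positions, with one gamma parameter per amino acid type.  Choosing
``g_s = beta F_U(s)`` makes the free-peptide (unbound-state) sequence
distribution flat, and is found iteratively: simulate the free peptide,
measure the aggregated type probabilities P_U(a), and correct

    gamma'(a) = gamma(a) - ln(20 P_U(a)),

whose fixed point is the uniform distribution.  Gamma tables are
re-centered to zero mean (an additive constant cancels in sampling).
After flattening, bound-state screening runs generate sequences with
Boltzmann weights exp(-dF_bind(s)/T); any residual error delta_s in the
linear approximation shifts ln P(s|B) by exactly delta_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import mcmc
from .analysis import ScreenResult
from .chain import ALPHABET, N_TYPES, SequenceState
from .energy import CoarseGrainedModel, ToyEnumerableModel
from .mcmc import MoveSchedule, ThermoState
from .system import PeptideSystem


@dataclass
class GammaTable:
    """Per-type sequence weight parameters gamma(a), zero-mean.

    ``meta`` records the provenance (peptide template, energy model
    name, temperature) so that a table produced by flattening is only
    used for screening under matching conditions.
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros(N_TYPES))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("gamma values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gamma values must be finite")

    @property
    def n_alpha(self) -> int:
        return len(self.values)

    def centered(self) -> "GammaTable":
        return GammaTable(self.values - self.values.mean(), dict(self.meta))

    def as_dict(self) -> dict:
        return {ALPHABET[i]: float(v) for i, v in enumerate(self.values)}


def g_of_sequence(gamma: GammaTable, seq: SequenceState) -> float:
    """Linear sequence weight g_s = sum over variable positions of
    gamma(s_i)."""
    codes = seq.residues[seq.variable_mask]
    return float(np.sum(gamma.values[codes]))


def update_gamma(gamma: GammaTable, observed, pseudo: float = 1e-4) -> GammaTable:
    """One flattening correction from measured type probabilities.

    ``observed`` is P_U(a) aggregated over variable positions (it is
    renormalized defensively).  Types with zero observed probability get
    the documented pseudo-probability ``pseudo`` before the log.  The
    result is re-centered to zero mean; the uniform distribution is the
    fixed point.
    """
    obs = np.asarray(observed, dtype=float).copy()
    n = gamma.n_alpha
    if obs.shape != (n,):
        raise ValueError("observed distribution has wrong length")
    if np.any(obs < 0):
        raise ValueError("observed probabilities must be nonnegative")
    if np.any(obs == 0):
        obs = obs + pseudo
    obs = obs / obs.sum()
    new = gamma.values - np.log(n * obs)
    new -= new.mean()
    return GammaTable(new, dict(gamma.meta))


@dataclass
class FlatteningDiagnostics:
    """Per-iteration record of the unbound-state flattening.

    ``max_rel_deviation[k]`` is max_a |20 P_U(a) - 1| measured in
    iteration k; it serves as the observable proxy for the residual
    errors delta_s of the linear unbound-state model (a deviation of
    0.10 means the per-type probabilities are within 10% of uniform).
    """

    observed: list = field(default_factory=list)
    max_rel_deviation: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    tol: float = 0.10

    def record(self, p: np.ndarray):
        p = np.asarray(p, dtype=float)
        p = p / p.sum()
        self.observed.append(p)
        self.max_rel_deviation.append(float(np.max(np.abs(len(p) * p - 1.0))))
        self.n_iterations += 1


def max_relative_deviation(p) -> float:
    """max_a |n P(a) - 1| — relative deviation from the uniform 1/n."""
    p = np.asarray(p, dtype=float)
    return float(np.max(np.abs(len(p) * p / p.sum() - 1.0)))


def flatten_unbound(peptide, model, thermo: ThermoState, tol: float = 0.10,
                    max_iter: int = 30, steps_per_iter: int = 200_000,
                    seed: int = 0, schedule: MoveSchedule | None = None,
                    burn_in_fraction: float = 0.10,
                    gamma0: GammaTable | None = None,
                    ) -> tuple[GammaTable, FlatteningDiagnostics]:
    """Iteratively tune gamma until the free-peptide type distribution
    is flat.

    ``peptide`` is a :class:`PeptideSystem` (its unbound copy is
    simulated) or a :class:`ToyEnumerableModel` (its unbound subset is
    sampled).  Each iteration runs ``steps_per_iter`` MC steps, discards
    the first ``burn_in_fraction`` as burn-in, measures P_U(a) over all
    variable positions, and applies :func:`update_gamma`.  Terminates
    when the maximum relative deviation from 1/n is at most ``tol``, or
    at ``max_iter`` with a warning.
    """
    toy = isinstance(peptide, ToyEnumerableModel)
    if toy:
        toy_model = peptide
        n_alpha = toy_model.n_alpha
        meta = {"model": toy_model.name, "temperature": thermo.T,
                "template": f"toy[{toy_model.n_var}]"}
    else:
        if len(peptide.seq.variable_positions) == 0:
            raise ValueError("peptide has no variable positions")
        free = peptide.unbound()
        n_alpha = N_TYPES
        meta = {"model": model.name, "temperature": thermo.T,
                "template": _template_string(peptide.seq)}
    gamma = (gamma0.centered() if gamma0 is not None
             else GammaTable(np.zeros(n_alpha)))
    gamma.meta.update(meta)
    diag = FlatteningDiagnostics(tol=tol)
    burn = int(burn_in_fraction * steps_per_iter)
    for it in range(max_iter):
        if toy:
            res = mcmc.run_toy(toy_model, thermo, n_steps=steps_per_iter,
                               seed=seed + it, gamma=gamma.values,
                               burn_in=burn, restrict="U")
            p = res.type_marginal()
        else:
            res = mcmc.run(free, model, thermo, schedule,
                           n_steps=steps_per_iter, seed=seed + it,
                           gamma=gamma.values, burn_in=burn,
                           record_interval=max(steps_per_iter // 100, 1))
            p = res.type_marginal()
        diag.record(p)
        if diag.max_rel_deviation[-1] <= tol:
            diag.converged = True
            break
        gamma = update_gamma(gamma, p)
    if not diag.converged:
        warnings.warn(
            f"flattening did not reach tol={tol} in {max_iter} iterations "
            f"(last deviation {diag.max_rel_deviation[-1]:.3f}); returning "
            "the best gamma table", RuntimeWarning)
    return gamma, diag


def _template_string(seq: SequenceState) -> str:
    return "".join("x" if v else ALPHABET[t]
                   for t, v in zip(seq.residues, seq.variable_mask))


def check_gamma_compatible(gamma: GammaTable, seq: SequenceState,
                           model_name: str, thermo: ThermoState,
                           rtol: float = 1e-6):
    """Refuse a gamma table produced under different conditions."""
    m = gamma.meta
    if not m:
        return
    if "temperature" in m and abs(m["temperature"] - thermo.T) > rtol * thermo.T:
        raise ValueError(
            f"gamma table was produced at T={m['temperature']}, screening "
            f"requested at T={thermo.T}; flattening and screening "
            "temperatures must match")
    if "template" in m and not m["template"].startswith("toy"):
        if m["template"] != _template_string(seq):
            raise ValueError(
                f"gamma table was produced for peptide template "
                f"{m['template']!r}, not {_template_string(seq)!r}")
    if "model" in m and m["model"] != model_name:
        raise ValueError(
            f"gamma table was produced with energy model {m['model']!r}, "
            f"not {model_name!r}")


def screen_bound(system: PeptideSystem, model: CoarseGrainedModel,
                 gamma: GammaTable, thermo: ThermoState,
                 schedule: MoveSchedule | None = None,
                 n_steps: int = 1_000_000, seed: int = 0,
                 burn_in_fraction: float = 0.10,
                 record_interval: int = 100,
                 check_provenance: bool = True) -> ScreenResult:
    """Bound-state screening: a joint run of the receptor-peptide system
    with the flattened gamma table; sequences are labelled bound/unbound
    by the RMSD criterion and P(s|B) is estimated from bound samples.
    """
    if system.binding is None:
        raise ValueError("screening requires a binding definition")
    if check_provenance:
        check_gamma_compatible(gamma, system.seq, model.name, thermo)
    res = mcmc.run(system, model, thermo, schedule, n_steps=n_steps,
                   seed=seed, gamma=gamma.values,
                   burn_in=int(burn_in_fraction * n_steps),
                   record_interval=record_interval)
    sr = res.to_screen_result(meta={"gamma": gamma.as_dict(),
                                    "seed": seed, "n_steps": n_steps,
                                    "acceptance": res.acceptance_rates,
                                    "records": res.records})
    if sr.n_bound == 0:
        raise RuntimeError(
            "screening run produced zero bound-state samples; consider "
            "lowering the temperature, strengthening the pocket constraint "
            "or extending the run")
    return sr
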