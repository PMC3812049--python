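"""Run configuration and file I/O.

One YAML config drives every CLI mode; all defaults mirror the study
conditions (50 A periodic box, 6 A RMSD cutoff, 10 A constraint onset,
alanine start at variable positions).  Every output file records the
config hash and seed for provenance; gamma tables carry their peptide
template, energy model and temperature and are rejected on mismatch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .analysis import ConstraintSpec, ScreenResult
from .chain import ALPHABET
from .energy import CoarseGrainedModel
from .fixtures import SyntheticReceptorSpec, generate_fixture
from .mcmc import MoveSchedule, ThermoState
from .multisequence import GammaTable


@dataclass
class RunConfig:
    """Structured configuration for flatten / screen / fixed / discover
    runs.  ``fixture`` overrides fields of :class:`SyntheticReceptorSpec`;
    ``pdb`` selects a native complex instead
    (``{path, protein_chain, peptide_chain, variable}``)."""

    mode: str = "screen"
    temperature: float = 0.60
    n_steps: int = 1_000_000
    seed: int = 0
    record_interval: int = 200
    burn_in_fraction: float = 0.10
    constraint_strength: float = 1.0
    constraint_onset: float = 10.0
    schedule: dict = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)
    fixture: dict = field(default_factory=dict)
    pdb: dict | None = None
    sequences: list = field(default_factory=list)
    n_runs: int = 1
    gamma_file: str | None = None
    flatten_tol: float = 0.10
    flatten_max_iter: int = 30
    flatten_steps_per_iter: int = 200_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # --- builders ---

    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature)

    def energy_model(self) -> CoarseGrainedModel:
        return CoarseGrainedModel(**self.model_params)

    def move_schedule(self) -> MoveSchedule:
        return MoveSchedule(**self.schedule)

    def constraint(self) -> ConstraintSpec:
        return ConstraintSpec(self.constraint_strength, self.constraint_onset)

    def build_system(self):
        """Build the receptor-peptide system: synthetic fixture by
        default, a PDB complex when ``pdb`` is configured.  Returns
        (system, manifest-or-None)."""
        if self.pdb is not None:
            from .pdbio import load_native_complex
            system, _ = load_native_complex(
                self.pdb["path"], self.pdb["protein_chain"],
                self.pdb["peptide_chain"],
                variable=self.pdb.get("variable"),
                rmsd_cutoff=self.pdb.get("rmsd_cutoff", 6.0),
                constraint=self.constraint())
            return system, None
        spec = SyntheticReceptorSpec(**{
            "constraint_strength": self.constraint_strength,
            "constraint_onset": self.constraint_onset,
            **self.fixture})
        return generate_fixture(spec, seed=self.seed)


def _provenance(config: RunConfig | None, seed: int) -> dict:
    return {"config_hash": config.config_hash() if config else None,
            "seed": int(seed)}


def save_gamma(gamma: GammaTable, path, config: RunConfig | None = None,
               seed: int = 0):
    payload = {"gamma": gamma.as_dict() if gamma.n_alpha == 20
               else list(map(float, gamma.values)),
               "meta": gamma.meta, "provenance": _provenance(config, seed)}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_gamma(path) -> GammaTable:
    payload = json.loads(Path(path).read_text())
    g = payload["gamma"]
    if isinstance(g, dict):
        values = np.array([g[a] for a in ALPHABET])
    else:
        values = np.array(g, dtype=float)
    return GammaTable(values, payload.get("meta", {}))


def save_screen_result(result: ScreenResult, out_dir,
                       config: RunConfig | None = None, seed: int = 0,
                       delta_f=None):
    """Write profile matrix (TSV, logo-tool compatible), entropies,
    relative dF table (CSV) and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof = result.profiles()
    prof.index.name = "position"
    prof.to_csv(out / "profiles.tsv", sep="\t", float_format="%.6g")
    ent = result.entropies()
    with open(out / "entropy.tsv", "w") as fh:
        fh.write("position\tentropy_nats\n")
        for p, s in zip(result.variable_positions, ent):
            fh.write(f"{int(p)}\t{s:.6g}\n")
    if delta_f is not None:
        delta_f.rename_axis("sequence").to_csv(out / "delta_f.csv",
                                               float_format="%.6g")
    summary = {
        "p_bound": result.p_bound,
        "n_bound": result.n_bound,
        "n_total": result.n_total,
        "temperature": result.temperature,
        "variable_positions": [int(p) for p in result.variable_positions],
        "provenance": _provenance(config, seed),
        "meta": {k: v for k, v in result.meta.items()
                 if k not in ("gamma", "records")},
    }
    (out / "result.json").write_text(json.dumps(summary, indent=2))


def save_records_jsonl(records, path, config: RunConfig | None = None,
                       seed: int = 0):
    """Trajectory records as JSON-lines, one object per record."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"provenance": _provenance(config, seed)}) + "\n")
        for row in records.itertuples(index=False):
            d = row._asdict()
            for k, v in d.items():
                if isinstance(v, (np.floating, np.integer)):
                    d[k] = v.item()
                elif isinstance(v, np.bool_):
                    d[k] = bool(v)
            fh.write(json.dumps(d) + "\n")
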