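"""Flat key=value run configuration shared by the CLI commands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .energy import EnergyModel, default_pair_potential, read_pair_potential


@dataclass
class RunConfig:
    """Defaults mirror the pipeline's stated cutoffs: SRLF +-1, rvET 5,
    contacts at 6.5 A with within-chain separation >= 2, 2000 decoys."""

    energy_matrix: str | None = None
    contact_cutoff_A: float = 6.5
    min_seq_sep: int = 2
    decoy_policy: str = "composition"
    n_decoys: int = 2000
    seed: int = 0
    srlf_cutoff: float = 1.0
    rvet_cutoff: float = 5.0
    reference_fasta: str | None = None
    receptor_chains: dict[str, str] = field(default_factory=dict)  # structure id -> comma-joined chain ids

    def energy_model(self) -> EnergyModel:
        pot = (
            read_pair_potential(self.energy_matrix)
            if self.energy_matrix
            else default_pair_potential()
        )
        return EnergyModel(
            pair_potential=pot,
            contact_cutoff_A=self.contact_cutoff_A,
            min_seq_sep=self.min_seq_sep,
            decoy_policy=self.decoy_policy,
            n_decoys=self.n_decoys,
            seed=self.seed,
        )

    def digest(self) -> str:
        payload = asdict(self)
        payload["pair_potential_sha"] = hashlib.sha256(
            self.energy_model().pair_potential.tobytes()
        ).hexdigest()[:12]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


_FLOAT_KEYS = {"contact_cutoff_A", "srlf_cutoff", "rvet_cutoff"}
_INT_KEYS = {"min_seq_sep", "n_decoys", "seed"}


def load_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` file; unknown keys raise."""
    cfg = RunConfig()
    known = set(asdict(cfg))
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("receptor_chains."):
            cfg.receptor_chains[key.split(".", 1)[1]] = value
            continue
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        if key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        else:
            setattr(cfg, key, value)
    return cfg
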