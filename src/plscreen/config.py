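"""Run configuration: every tunable threshold of every stage, validated at
load time, serializable to JSON or YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # normalization
    scale: float = 1e7
    pseudocount: float = 1.0
    # hairpin enrichment calls
    fold: float = 4.0
    floor: float = 100.0
    # gene ranking
    permutations: int = 10000
    weight_exponent: float = 0.0
    reference: str = "plasmid"
    # candidate filters
    p_cut: float = 1e-4
    phi_cut: float = 0.08
    h_cut: int = 4
    min_tumors_per_hairpin: int = 1
    # library design
    pool_target_size: int = 100
    gene_blocked: bool = True
    # ATAC / motif
    promoter_radius: int = 2000
    r_small: int = 150
    r_large: int = 1500
    # DE filter
    fc_cut: float = 2.0
    fdr_cut: float = 0.1
    strict_fdr: bool = True
    # TF integration
    weight_group: str = "sh"
    top_rna: int = 12
    top_atac: int = 5
    n_combined: int = 20
    n_atac: int = 2
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.pseudocount < 0:
            raise ValueError("scale must be positive, pseudocount non-negative")
        if self.fold <= 0 or self.floor < 0:
            raise ValueError("fold must be positive, floor non-negative")
        if self.permutations < 1:
            raise ValueError("permutations must be at least 1")
        if not 0 < self.p_cut <= 1 or not 0 <= self.phi_cut < 1:
            raise ValueError("p_cut in (0,1], phi_cut in [0,1)")
        if self.h_cut < 0 or self.min_tumors_per_hairpin < 1:
            raise ValueError("invalid hairpin-support cutoffs")
        if self.pool_target_size < 1:
            raise ValueError("pool_target_size must be positive")
        if self.r_small >= self.r_large or self.r_small <= 0:
            raise ValueError("need 0 < r_small < r_large")
        if not 0 <= self.fdr_cut <= 1:
            raise ValueError("fdr_cut must lie in [0,1]")
        if self.weight_group not in ("sh", "xe"):
            raise ValueError("weight_group must be 'sh' or 'xe'")
        if min(self.top_rna, self.top_atac, self.n_combined, self.n_atac) < 0:
            raise ValueError("selection sizes must be non-negative")
        if self.reference not in ("plasmid", "pregraft"):
            raise ValueError("reference must be 'plasmid' or 'pregraft'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
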