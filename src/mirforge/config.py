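"""Run configuration holding the pipeline's tunable parameters.

Defaults are the published operating point of the method: k=14 de Bruijn
graph with a minimum k-mer abundance of 5, three tip-removal iterations,
3-fold expression-ratio arc pruning, 18-24 nt candidates, a KM>50 bar for
isolated single-node components, 15-mer overlap reclustering with edit
distance <= 2, a 16-mer exclusion filter (min count 5), 200-bp genome
windows seeded with 12-mers at edit distance <= 2 and at most 100 hits,
and kingdom-specific precursor lengths (animal 110; plant 110-300).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


_PRECURSOR_LENGTHS = {"animal": [110], "plant": [110, 150, 200, 250, 300]}


@dataclass
class RunConfig:
    # de Bruijn graph
    k: int = 14
    km_min: float = 5.0
    # graph cleaning
    tip_iterations: int = 3
    tip_km_max: float = 5.0
    fold_threshold: float = 3.0
    # component classification
    isolated_km_min: float = 50.0
    candidate_len_min: int = 18
    candidate_len_max: int = 24
    # reclustering
    overlap_k: int = 15
    recluster_max_edit: int = 2
    # other-RNA exclusion filter
    filter_k: int = 16
    filter_min_count: int = 5
    # genome mapper
    window_size: int = 200
    seed_len: int = 12
    map_max_edit: int = 2
    max_hits: int = 100
    precursor_flank: int = 15
    # hairpin validation
    kingdom: str = "animal"
    precursor_lengths: list[int] = field(default_factory=lambda: [110])
    fold_engine: str = "builtin"
    # |MFE| window in kcal/mol: accept -mfe_hi <= MFE <= -mfe_lo
    mfe_lo: float = 15.0
    mfe_hi: float = 80.0
    require_mature_on_arm: bool = True
    # misc
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.kingdom not in _PRECURSOR_LENGTHS:
            raise ValueError(f"kingdom must be one of {sorted(_PRECURSOR_LENGTHS)}")
        # kingdom drives precursor lengths unless explicitly overridden
        if self.precursor_lengths == [110] and self.kingdom == "plant":
            self.precursor_lengths = list(_PRECURSOR_LENGTHS["plant"])
        for name in ("km_min", "tip_km_max", "fold_threshold", "isolated_km_min",
                     "mfe_lo", "mfe_hi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
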