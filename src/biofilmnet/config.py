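"""Analysis configuration and deterministic random-stream derivation."""
from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np

PVALUE_METHODS = ("t_approx", "exact_perm")
ENV_MARGINS = ("per_sample", "per_variable")
FILTER_MODES = ("mean_across_samples", "overall")


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across all pipeline stages.

    Defaults are the conventional settings of this kind of co-occurrence
    study: OTUs kept above 0.01% relative abundance, edges kept when
    |rho| > 0.7 and p < 0.01 (both strict), a network called modular when
    Q > 0.4, and "major" modules holding more than 15 nodes.
    """

    abundance_threshold: float = 1e-4
    rho_threshold: float = 0.7
    p_threshold: float = 0.01
    major_module_min_nodes: int = 16  # "more than 15 nodes"
    modular_structure_q: float = 0.4
    n_permutations: int = 999
    rng_seed: int = 0
    pvalue_method: str = "t_approx"
    env_normalize_margin: str = "per_sample"
    filter_mode: str = "mean_across_samples"
    apply_bh_correction: bool = False

    def __post_init__(self) -> None:
        for name in ("abundance_threshold", "rho_threshold", "p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.major_module_min_nodes < 1:
            raise ValueError("major_module_min_nodes must be >= 1")
        if self.pvalue_method not in PVALUE_METHODS:
            raise ValueError(f"pvalue_method must be one of {PVALUE_METHODS}")
        if self.env_normalize_margin not in ENV_MARGINS:
            raise ValueError(f"env_normalize_margin must be one of {ENV_MARGINS}")
        if self.filter_mode not in FILTER_MODES:
            raise ValueError(f"filter_mode must be one of {FILTER_MODES}")

    def substream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the single run seed.

        Stage names are hashed (CRC32) into a spawn key so every stage sees
        an independent stream and the whole run is reproducible from
        ``rng_seed`` alone.
        """
        key = zlib.crc32(stage.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence(self.rng_seed, spawn_key=(key,)))

    def substream_seed(self, stage: str) -> int:
        """A plain integer seed (< 2**31) for APIs that take one."""
        return int(self.substream(stage).integers(0, 2**31 - 1))

    def to_dict(self) -> dict:
        return asdict(self)
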