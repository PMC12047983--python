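"""Pipeline configuration: every gate and threshold in one place.

Defaults follow the analysis contract: gene-level significance at
P < 2.5e-6 (0.05 over ~20,000 genes), strategy-level significance at
2.5e-6 / m for an m-mask strategy, burdens recomputed at MAF sub-bins
0.5 / 0.01 / 0.001, tests with cumulative minor-allele count <= 10 removed,
masks with mean genomic inflation lambda > 1.2 removed, composite damaging
vote cut 0.67, and LD clumping at p < 1e-4, r^2 >= 0.5, 250 kb windows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    alpha0: float = 2.5e-6
    lambda_max: float = 1.2
    cmac_min: int = 10            # tests with cMAC <= cmac_min are removed
    aaf_bins: tuple[float, ...] = (0.5, 0.01, 0.001)
    composite_threshold: float = 0.67
    clump_p1: float = 1e-4
    clump_r2: float = 0.5
    clump_window_kb: int = 250
    lambda_min_tests: int = 50     # min tests per trait before lambda can exclude
    variance_target: float = 0.90  # PCA variance retained for mask clustering
    elbow_drop: float = 0.05       # relative k-means cost drop ending the elbow
    kmeans_restarts: int = 10
    k_max: int = 15
    m_max: int | None = None       # greedy search cap; None -> number of masks
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "aaf_bins" in kwargs:
            kwargs["aaf_bins"] = tuple(kwargs["aaf_bins"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: maps a frequency class to the MAF sub-bin whose p-value defines it
FREQ_CLASS_BIN = {"total": 0.5, "low-frequency": 0.01, "rare": 0.001}
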