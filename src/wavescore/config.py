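"""Resolved run configuration shared by the pipeline and the CLI.

Precedence when assembling a RunConfig: CLI flag > config file > default.
The resolved object is serialized into every output file's provenance
header so a run can be reproduced from its results alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Literal


@dataclass
class RunConfig:
    # inputs
    geno: str = ""
    geno_format: Literal["auto", "vcf", "tsv"] = "auto"
    pheno: str = ""
    annot: str = ""
    trait: str = ""
    covariates: list[str] = field(default_factory=list)
    binary_trait: bool = False
    # windowing / filtering
    window_mode: Literal["fixed", "gene"] = "fixed"
    window_size: int = 8
    nonsyn_only: bool = True
    # stratification adjustment
    pca_k: int | Literal["auto"] = "auto"
    pca_ratio_threshold: float = 2.0
    pca_max_components: int = 10
    # wavelet shrinkage
    wavelet_family: str = "haar"
    wavelet_prior_scale: float = 0.5
    wavelet_level_dependent: bool = True
    wavelet_scope: Literal["chromosome", "window"] = "chromosome"
    residual_method: Literal["ols", "logistic"] = "ols"
    # testing
    permutations: int = 60000
    correction: Literal["bonferroni", "maxstat", "both"] = "bonferroni"
    two_sided: bool = True
    seed: int = 0
    out: str = "results.tsv"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance_lines(self, version: str) -> list[str]:
        return [
            f"wavescore {version}",
            f"config_hash {self.config_hash()}",
            f"seed {self.seed}",
        ] + [f"{k} {v}" for k, v in sorted(asdict(self).items())]


def parse_config_file(path: str) -> dict[str, str]:
    """Flat key=value (or key: value) config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, val = line.split(sep, 1)
                    out[key.strip()] = val.strip()
                    break
            else:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
    return out
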