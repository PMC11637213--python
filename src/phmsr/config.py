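"""Run configuration with the method's published defaults.

Every numeric knob of the pipeline lives here so a run is reproducible
from its manifest. Defaults resolve exactly to the published settings:
gamma_max 20 deg (small) / 25 deg (large), r = 0.1 / 0.3 mm, p = 0.5,
mu = 10, n2 = 2, ns = 3, ICP 100 iterations / 0.1 mm tolerance.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config"]

_METHODS = ("phmsr", "sicp", "icp", "cpd")


@dataclass
class RunConfig:
    method: str = "phmsr"
    deviation_preset: str = "small"
    seed: int = 0

    # PHFM / mapping surfaces (None = resolved from the preset)
    gamma_max_small_deg: float = 20.0
    gamma_max_large_deg: float = 25.0
    r_small_mm: float = 0.1
    r_large_mm: float = 0.3
    d_sample_mm: float | None = None  # None -> median target spacing
    k_y: int = 8
    k_c: int = 24
    n_horns: int = 4

    # sparse ICP / ADMM
    p: float = 0.5
    mu: float = 10.0
    n2: int = 2
    ns: int = 3

    # classic ICP
    icp_max_iter: int = 100
    icp_tol_mm: float = 0.1

    # CPD
    cpd_outlier_weight: float = 0.1
    cpd_max_iter: int = 100
    cpd_tol: float = 1e-6

    # adaptive SCM (C=None -> 0.02 * max intensity)
    scm_C: float | None = None
    scm_a: float = 0.2
    scm_n_iter: int = 40

    # io
    input_paths: dict = field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.deviation_preset not in ("small", "large"):
            raise ValueError("deviation_preset must be 'small' or 'large'")

    @property
    def gamma_max_deg(self) -> float:
        return (self.gamma_max_small_deg if self.deviation_preset == "small"
                else self.gamma_max_large_deg)

    @property
    def r_mm(self) -> float:
        return self.r_small_mm if self.deviation_preset == "small" else self.r_large_mm

    def manifest(self) -> dict:
        import phmsr
        d = dataclasses.asdict(self)
        d["package_version"] = phmsr.__version__
        return d

    def write_manifest(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.manifest(), indent=2))


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus keyword overrides.

    Flags (overrides) win over the file; unknown keys raise before any
    computation starts.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
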