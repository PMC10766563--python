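"""Run configuration: a flat, typed key-value record that round-trips losslessly
through a plain-text file.  Unknown keys are rejected so config typos fail loudly."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # reference preparation
    m_states: int = 50
    n_signature_genes: int = 500
    min_gene_fraction: float = 0.10
    bandwidth: float | None = None  # None = auto (median weight 0.5)
    # REML
    theta_min: float = 0.0
    theta_max: float = 0.95
    theta_step: float = 0.05
    # smoothing / rescaling
    smoothing_method: str = "loess"  # loess | knn | none
    smoothing_span: float = 0.35
    knn_q: int = 0  # 0 = auto max(3, m_states/10)
    normalize: bool = True
    gene_scaling: str = "mean"  # mean | none (per-gene GLS weighting)
    # group test
    group_test_degree: int = 2
    n_perm: int = 1000
    # csd-eQTL
    maf_min: float = 0.05
    cis_window: int = 1_000_000
    fdr_threshold: float = 0.05
    n_expression_pcs: int = 15
    # simulation
    noise_sd: float = 0.2
    # randomness
    seed: int = 0

    def theta_grid(self) -> np.ndarray:
        return np.arange(self.theta_min, self.theta_max + self.theta_step / 2, self.theta_step)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {'none' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            kwargs[key] = _parse(raw, known[key].type)
        return cls(**kwargs)


def _parse(raw: str, annotation: str):
    if raw.lower() in {"none", "auto"}:
        return None
    ann = str(annotation)
    if "bool" in ann:
        if raw.lower() in {"true", "1", "yes"}:
            return True
        if raw.lower() in {"false", "0", "no"}:
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if "int" in ann and "float" not in ann:
        return int(raw)
    if "float" in ann:
        return float(raw)
    return raw
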