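"""Pipeline configuration: validated, YAML-round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from comorbnet.treecut import CutParams


@dataclass
class PipelineConfig:
    """Everything a full run needs; a serialised copy is written next to outputs."""

    records_path: str = "records.csv"
    output_dir: str = "out"
    years: list[int] | None = None  # None: all years found in the records
    code_map_path: str | None = None
    on_unmapped: str = "keep"
    apply_code_filter: bool = True
    tau_policy: str = "reference"  # reference | per-year | fixed
    tau: float | None = None
    reference_year: int | None = None
    tau_grid_start: float = 0.005
    tau_grid_stop: float = 0.10
    tau_grid_step: float = 0.005
    r2_target: float = 0.80
    adjacency_mode: str = "magnitude"  # magnitude | literal
    min_module_size: int = 20
    cut_gap_frac: float = 0.10
    cut_straggler_size: int = 2
    cut_refine_beta: float = 3.0
    cut_refine_member_frac: float = 0.4
    cut_refine_iters: int = 2
    smoothing_span: float = 0.5
    seed: int = 0
    write_plots: bool = True

    def validate(self) -> None:
        if self.tau_policy not in {"reference", "per-year", "fixed"}:
            raise ValueError(f"unknown tau_policy {self.tau_policy!r}")
        if self.tau_policy == "fixed" and self.tau is None:
            raise ValueError("tau_policy 'fixed' requires tau")
        if self.adjacency_mode not in {"magnitude", "literal"}:
            raise ValueError(f"unknown adjacency_mode {self.adjacency_mode!r}")
        if self.on_unmapped not in {"keep", "drop", "error"}:
            raise ValueError(f"unknown on_unmapped {self.on_unmapped!r}")
        if not (0 < self.tau_grid_start <= self.tau_grid_stop < 1):
            raise ValueError("tau grid must lie in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")

    def tau_grid(self) -> tuple[float, ...]:
        import numpy as np

        return tuple(
            np.round(
                np.arange(self.tau_grid_start, self.tau_grid_stop + 1e-9, self.tau_grid_step), 6
            )
        )

    def cut_params(self) -> CutParams:
        return CutParams(
            gap_frac=self.cut_gap_frac,
            straggler_size=self.cut_straggler_size,
            refine_beta=self.cut_refine_beta,
            refine_member_frac=self.cut_refine_member_frac,
            refine_iters=self.cut_refine_iters,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
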