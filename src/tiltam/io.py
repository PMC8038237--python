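"""Data loading and run configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .additive import TermSpec
from .kernels import KernelSpec

__all__ = ["RunConfig", "load_table", "load_config"]

log = logging.getLogger("tiltam")


def load_table(path, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a CSV table and enforce complete cases on the modelled columns.

    Rows missing any value in `required` are dropped with a logged count;
    unmodelled extra columns pass through untouched.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    if df.shape[0] == 0:
        raise ValueError(f"input file has a header but no rows: {path}")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"required column {missing[0]!r} missing from {path}")
        before = len(df)
        df = df.dropna(subset=list(required)).reset_index(drop=True)
        dropped = before - len(df)
        if dropped:
            log.info("dropped %d rows with missing modelled values (%d retained)", dropped, len(df))
    return df


@dataclass
class RunConfig:
    """Configuration for a full analysis run."""

    data: Optional[str] = None
    outcome: str = "AOV"
    terms: list = field(default_factory=list)          # list[TermSpec]
    kernel: KernelSpec = field(default_factory=KernelSpec)
    tol: float = 1e-6
    max_iter: int = 100
    tilt_grid_size: int = 50
    comparator_factor: float = 1.2
    n_boot: int = 200
    level: float = 0.95
    seed: Optional[int] = None
    output_dir: str = "tiltam_out"
    prefer_simple_on_borderline: bool = True
    borderline_window: tuple = (0.04, 0.05)

    def validate(self, df: pd.DataFrame) -> None:
        if self.outcome not in df.columns:
            raise ValueError(f"outcome column {self.outcome!r} not in data")
        for t in self.terms:
            if t.name not in df.columns:
                raise ValueError(f"term column {t.name!r} not in data")
        if self.seed is None:
            raise ValueError("a seed is mandatory when bootstrap or simulation is requested")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    terms = [
        TermSpec(
            name=t["name"],
            kind=t.get("kind", "smooth"),
            bandwidth=t.get("bandwidth", "auto"),
            tilt=bool(t.get("tilt", True)),
        )
        for t in raw.get("terms", [])
    ]
    kraw = raw.get("kernel", {}) or {}
    kernel = KernelSpec(kraw.get("family", "gaussian"), kraw.get("taper", 0.5))
    boot = raw.get("bootstrap", {}) or {}
    return RunConfig(
        data=raw.get("data"),
        outcome=raw.get("outcome", "AOV"),
        terms=terms,
        kernel=kernel,
        tol=float(raw.get("tol", 1e-6)),
        max_iter=int(raw.get("max_iter", 100)),
        tilt_grid_size=int(raw.get("tilt_grid_size", 50)),
        comparator_factor=float(raw.get("comparator_factor", 1.2)),
        n_boot=int(boot.get("n_boot", 200)),
        level=float(boot.get("level", 0.95)),
        seed=raw.get("seed"),
        output_dir=raw.get("output_dir", "tiltam_out"),
        prefer_simple_on_borderline=bool(raw.get("prefer_simple_on_borderline", True)),
        borderline_window=tuple(raw.get("borderline_window", (0.04, 0.05))),
    )
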