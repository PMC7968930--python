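"""Run configuration: one object holding every tunable the pipeline uses.

Defaults are the analysis constants the quantifications were designed
around: a 30 nt enrichment window stepping by 15 nt over a 3000 nt
background, a ring-intensity filter at 100, a 10 x 20 px ring ROI, a 5 px
reslice line width, three multi-Otsu classes, a 0.95 Spearman gate and the
2x acid-quench dilution.  Overrides are recorded so a run report can echo
exactly what was changed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    # chip
    window: int = 30
    step: int = 15
    background: int = 3000
    rho_threshold: float = 0.95
    tail: str = "upper"
    # zring
    min_intensity: float = 100.0
    n_classes: int = 3
    roi_shape: tuple[int, int] = (10, 20)
    line_width: int = 5
    # kinetics
    range_mode: str = "auto"
    dilution: float = 2.0

    def overrides(self) -> dict:
        """Fields that differ from the defaults, for report echoing."""
        defaults = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(defaults, f.name)
        }

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_shape"] = list(self.roi_shape)
        return d


def load_config(path: str | Path | None = None, **cli_overrides) -> RunConfig:
    """Build a RunConfig from an optional JSON file plus explicit overrides.

    Explicit (CLI) values win over the file; unknown keys are rejected so
    typos fail loudly rather than silently running with defaults.
    """
    values: dict = {}
    if path is not None:
        values.update(json.loads(Path(path).read_text()))
    values.update({k: v for k, v in cli_overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "roi_shape" in values:
        values["roi_shape"] = tuple(values["roi_shape"])
    return RunConfig(**values)
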