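"""File-format readers and writers shared across the pipeline.

Text formats throughout: depth tracks as the three-column tab-separated
dialect of ``samtools depth`` (1-based positions, zero-depth rows omitted),
enrichment as bedgraph (0-based half-open), tabular results as CSV with
headers, image stacks as multi-frame TIFF with a JSON metadata sidecar.
Every writer here has a matching reader that restores an identical
in-memory object (round-trip closure), which the test suite enforces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from sephkit.chip import (  # noqa: F401  (re-exported as the canonical IO surface)
    DepthTrack,
    read_bedgraph,
    read_depth,
    write_bedgraph,
    write_depth,
)

__all__ = [
    "read_depth",
    "write_depth",
    "read_bedgraph",
    "write_bedgraph",
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
    "write_report",
]


def write_stack(stack: np.ndarray, path, metadata: dict | None = None) -> None:
    """Write an image stack as multi-frame TIFF with a JSON sidecar.

    ``metadata`` (pixel size, frame interval, planted truth, ...) goes to
    ``<path>.json`` so the TIFF stays plain.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True)
        )


def read_stack(path) -> tuple[np.ndarray, dict | None]:
    """Read a multi-frame TIFF and its JSON sidecar if present."""
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return np.asarray(stack), meta


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with header, no index — the one tabular dialect used throughout."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report: dict, path) -> None:
    """Machine-readable JSON run report (parameters, seeds, outputs)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
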