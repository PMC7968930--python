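"""Sliding-window ChIP-seq enrichment from per-base depth tracks.

The statistic: for each 30 nt window advancing in 15 nt steps along the
contig, local enrichment is the mean depth in the window divided by the mean
depth in a 3000 nt background window centred on the same midpoint (truncated
at contig ends, no wrap — the chromosome is linear).  This yields one ratio
per 15 nt.  Replicates are gated on pairwise Spearman correlation (> 0.95 by
default), averaged, and the control-strain enrichment is subtracted; the
significance of the control-subtracted values is computed by z-scoring
against their own mean and SD under a normal model, upper tail by default.

Windows whose background mean is zero carry no evidence and yield a missing
(NaN) ratio; missing values are excluded from correlation and significance
and are omitted from bedgraph output.

The whole pipeline is invariant to uniform depth scaling: multiplying all
depths by k > 0 leaves every ratio unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DepthTrack",
    "EnrichmentTrack",
    "DiffTrack",
    "SignificanceTrack",
    "read_depth",
    "write_depth",
    "window_enrichment",
    "replicate_gate",
    "mean_and_subtract",
    "significance",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass
class DepthTrack:
    """Per-base read depth along one contig (index 0 = base 1)."""

    contig: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        return self.contig == other.contig and np.array_equal(
            self.depths, other.depths
        )


@dataclass
class EnrichmentTrack:
    """Windowed enrichment ratios on a fixed step grid.

    ``positions`` are window midpoints (bp, 0-based: start + window//2),
    strictly increasing with constant spacing ``step``.  ``ratios`` may
    contain NaN where the background mean was zero.
    """

    contig: str
    positions: np.ndarray
    ratios: np.ndarray
    window: int = 30
    step: int = 15
    background: int = 3000

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.positions.shape != self.ratios.shape:
            raise ValueError("positions and ratios must have equal length")
        if len(self.positions) > 1:
            steps = np.diff(self.positions)
            if not np.all(steps == self.step):
                raise ValueError("positions must advance by exactly `step`")
        with np.errstate(invalid="ignore"):
            if np.any(self.ratios[np.isfinite(self.ratios)] < 0):
                raise ValueError("defined ratios must be non-negative")

    @property
    def starts(self) -> np.ndarray:
        return self.positions - self.window // 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnrichmentTrack):
            return NotImplemented
        return (
            self.contig == other.contig
            and self.window == other.window
            and self.step == other.step
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ratios, other.ratios, equal_nan=True)
        )


@dataclass
class DiffTrack:
    """Control-subtracted enrichment on the shared window grid (may be < 0)."""

    contig: str
    positions: np.ndarray
    diff: np.ndarray
    window: int = 30
    step: int = 15
    background: int = 3000

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.diff = np.asarray(self.diff, dtype=float)
        if self.positions.shape != self.diff.shape:
            raise ValueError("positions and diff must have equal length")


@dataclass
class SignificanceTrack:
    """Control-subtracted enrichment with normal-theory scores.

    ``z`` standardises ``diff`` against its own (track-wide) mean and SD;
    ``p`` is the corresponding tail probability; ``q`` holds
    Benjamini–Hochberg adjusted values when requested, else NaN.
    """

    contig: str
    positions: np.ndarray
    diff: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None


def read_depth(path, contig_length: int, contig: str | None = None) -> DepthTrack:
    """Parse a three-column contig / position (1-based) / depth table.

    The dialect produced by ``samtools depth``: tab-separated, positions
    absent from the file get depth 0.  Positions outside
    ``[1, contig_length]`` and malformed lines raise ``ValueError``.
    """
    depths = np.zeros(contig_length, dtype=np.int64)
    name = contig
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            c, pos_s, depth_s = fields
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            if name is None:
                name = c
            elif c != name:
                raise ValueError(f"{path}:{lineno}: multiple contigs ({name!r}, {c!r})")
            if not 1 <= pos <= contig_length:
                raise ValueError(
                    f"{path}:{lineno}: position {pos} outside [1, {contig_length}]"
                )
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            depths[pos - 1] = depth
    return DepthTrack(name if name is not None else "contig", depths)


def write_depth(track: DepthTrack, path) -> None:
    """Write a depth track in the three-column 1-based dialect.

    Zero-depth positions are omitted, as ``samtools depth`` does by default;
    :func:`read_depth` restores them.
    """
    with open(path, "w") as fh:
        for idx in np.nonzero(track.depths)[0]:
            fh.write(f"{track.contig}\t{idx + 1}\t{track.depths[idx]}\n")


def window_enrichment(
    track: DepthTrack, window: int = 30, step: int = 15, background: int = 3000
) -> EnrichmentTrack:
    """Local enrichment ratio for every window position along the contig.

    For each window start 0, step, 2*step, ... with start + window <= length:
    ratio = mean depth in [start, start+window) divided by the mean depth in
    the ``background``-wide interval centred on the window midpoint,
    truncated to the contig.  Zero background mean gives NaN.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window >= background:
        raise ValueError("background must exceed window")
    n = len(track)
    if n < window:
        raise ValueError("contig shorter than one window")
    depths = track.depths.astype(float)
    csum = np.concatenate([[0.0], np.cumsum(depths)])

    starts = np.arange(0, n - window + 1, step)
    win_sum = csum[starts + window] - csum[starts]
    centers = starts + window // 2

    bg_lo = np.clip(centers - background // 2, 0, n)
    bg_hi = np.clip(centers + (background - background // 2), 0, n)
    bg_sum = csum[bg_hi] - csum[bg_lo]
    bg_len = bg_hi - bg_lo

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (win_sum / window) / (bg_sum / bg_len)
    ratio = np.where(bg_sum > 0, ratio, np.nan)
    return EnrichmentTrack(track.contig, centers, ratio, window, step, background)


def replicate_gate(
    tracks: Sequence[EnrichmentTrack], threshold: float = 0.95
) -> tuple[np.ndarray, bool]:
    """Pairwise Spearman correlation between replicate enrichment tracks.

    Computed over positions where both members of a pair are defined.
    Returns the full rho matrix and a flag that is True iff every pairwise
    rho exceeds ``threshold``.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two replicate tracks")
    _check_aligned(tracks)
    k = len(tracks)
    rho = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = tracks[i].ratios, tracks[j].ratios
            ok = np.isfinite(a) & np.isfinite(b)
            if not np.any(ok):
                raise ValueError("no jointly defined positions")
            r = stats.spearmanr(a[ok], b[ok]).statistic
            rho[i, j] = rho[j, i] = r
    iu = np.triu_indices(k, 1)
    return rho, bool(np.all(rho[iu] > threshold))


def _check_aligned(tracks: Sequence[EnrichmentTrack]) -> None:
    first = tracks[0]
    for t in tracks[1:]:
        if t.contig != first.contig or not np.array_equal(
            t.positions, first.positions
        ):
            raise ValueError("tracks are not on the same position grid")


def mean_and_subtract(
    chip_tracks: Sequence[EnrichmentTrack], control_track: EnrichmentTrack
) -> DiffTrack:
    """Replicate-mean enrichment minus control enrichment, per position.

    A position missing in any replicate or in the control stays missing.
    The result can be negative (control exceeding ChIP), so it is returned
    as a :class:`DiffTrack` rather than a ratio track.
    """
    _check_aligned(list(chip_tracks) + [control_track])
    stacked = np.vstack([t.ratios for t in chip_tracks])
    diff = stacked.mean(axis=0) - control_track.ratios
    return DiffTrack(
        control_track.contig,
        control_track.positions.copy(),
        diff,
        control_track.window,
        control_track.step,
        control_track.background,
    )


def significance(
    diff_track: DiffTrack,
    tail: str = "upper",
    fdr: bool = False,
) -> SignificanceTrack:
    """Normal-theory significance of control-subtracted enrichment.

    z-scores each defined difference against the track-wide mean and SD;
    ``tail='upper'`` tests for enrichment only, ``'two-sided'`` for either
    direction.  With ``fdr=True`` Benjamini–Hochberg adjusted q-values are
    attached (NaN at missing positions).
    """
    d = diff_track.diff
    ok = np.isfinite(d)
    if ok.sum() < 2:
        raise ValueError("need at least two defined values")
    mean, sd = d[ok].mean(), d[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in control-subtracted enrichment")
    z = np.full_like(d, np.nan)
    z[ok] = (d[ok] - mean) / sd
    if tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "two-sided":
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError("tail must be 'upper' or 'two-sided'")
    q = None
    if fdr:
        from statsmodels.stats.multitest import multipletests

        q = np.full_like(d, np.nan)
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return SignificanceTrack(
        diff_track.contig, diff_track.positions.copy(), d.copy(), z, p, q
    )


def write_bedgraph(track: EnrichmentTrack | DiffTrack, path) -> None:
    """Write defined windows as bedgraph: contig, 0-based start, start+window, value.

    Accepts ratio tracks and control-subtracted difference tracks.  Adjacent
    intervals overlap by ``window - step`` bp when the step is smaller than
    the window; that is inherent to the overlapping-window statistic and
    genome viewers handle it.
    """
    values = track.ratios if isinstance(track, EnrichmentTrack) else track.diff
    starts = track.positions - track.window // 2
    order = np.argsort(starts)
    with open(path, "w") as fh:
        for i in order:
            r = values[i]
            if not np.isfinite(r):
                continue
            fh.write(
                f"{track.contig}\t{starts[i]}\t{starts[i] + track.window}\t{r:.17g}\n"
            )


def read_bedgraph(
    path, step: int = 15, background: int = 3000, kind: str = "ratio"
) -> EnrichmentTrack | DiffTrack:
    """Read a bedgraph produced by :func:`write_bedgraph`.

    The window size is taken from the interval lengths; interior windows
    absent from the file (written as missing) are restored as NaN on the
    reconstructed step grid.  Leading/trailing missing windows are not
    recoverable from the file.  ``kind='ratio'`` returns an
    :class:`EnrichmentTrack` (values must be >= 0); ``kind='diff'`` returns
    a :class:`DiffTrack` for control-subtracted values of either sign.
    """
    if kind not in ("ratio", "diff"):
        raise ValueError("kind must be 'ratio' or 'diff'")
    contigs, starts, vals, widths = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            contigs.append(fields[0])
            starts.append(int(fields[1]))
            widths.append(int(fields[2]) - int(fields[1]))
            vals.append(float(fields[3]))
    if not starts:
        raise ValueError(f"{path}: empty bedgraph")
    if len(set(contigs)) != 1:
        raise ValueError(f"{path}: multiple contigs")
    if len(set(widths)) != 1:
        raise ValueError(f"{path}: inconsistent window widths")
    window = widths[0]
    starts_arr = np.array(starts)
    order = np.argsort(starts_arr)
    starts_arr = starts_arr[order]
    vals_arr = np.array(vals)[order]
    grid = np.arange(starts_arr[0], starts_arr[-1] + 1, step)
    ratios = np.full(grid.shape, np.nan)
    idx = (starts_arr - starts_arr[0]) // step
    if np.any(starts_arr != grid[idx]):
        raise ValueError(f"{path}: starts not on a {step} bp grid")
    ratios[idx] = vals_arr
    cls = EnrichmentTrack if kind == "ratio" else DiffTrack
    return cls(contigs[0], grid + window // 2, ratios, window, step, background)
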