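"""Region calling, punctate peak boundary refinement, stalling scores, CNV mode.

Windows whose enrichment posterior exceeds a threshold (default 0.95) are
pooled across offset grids and merged into enriched regions (adjacent or
overlapping by default; within 5 kb in the broad setting).  Inside each
region, the base-pair read-overlap profile is scanned for local maxima, and
punctate peak boundaries are placed on each side of a maximum at the
position maximizing the R^2 of a line anchored at the summit.  A stalling
score contrasts punctate against broad signal, and CNV mode reruns the
mixture on input-control counts in 10-kb windows without covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import WindowTable
from .genomic_windows import (
    FragmentLength,
    ReadSet,
    build_window_grid,
    count_in_windows,
    extend_and_center,
)
from .zinb_mixture import MixtureFit, fit_mixture

logger = logging.getLogger(__name__)


@dataclass
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    max_posterior: float
    source_offsets: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RefinedPeak:
    chrom: str
    start: int
    end: int
    summit: int
    summit_height: float
    max_posterior: float = 1.0

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie within the peak")


@dataclass(frozen=True)
class StallingInput:
    """Punctate-vs-broad geometry of one enriched region: the punctate peak's
    length and maximum height against the broad region's length and median
    height (median excludes the punctate peak)."""

    length_punctate: float
    length_broad: float
    height_punctate_max: float
    height_broad_median: float

    def __post_init__(self) -> None:
        if self.length_punctate <= 0 or self.length_broad <= 0:
            raise ValueError("region lengths must be positive")
        if self.length_punctate > self.length_broad:
            raise ValueError("punctate length cannot exceed broad length")
        if min(self.height_punctate_max, self.height_broad_median) < 0:
            raise ValueError("heights must be non-negative")


def call_regions(
    windows: pd.DataFrame, threshold: float = 0.95, merge_gap: int = 0
) -> list[EnrichedRegion]:
    """Merge above-threshold windows (pooled across offset grids) into regions.

    ``windows`` needs columns chrom, start, end, tau2 and optionally offset.
    Windows within ``merge_gap`` bp of each other are unioned (0 = merge only
    overlapping or book-ended windows); broad mode uses merge_gap=5000.
    """
    if not 0.5 <= threshold < 1:
        raise ValueError("posterior threshold must lie in [0.5, 1)")
    sel = windows[windows["tau2"] > threshold]
    regions: list[EnrichedRegion] = []
    has_offset = "offset" in sel.columns
    for chrom, sub in sel.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        taus = sub["tau2"].to_numpy()
        offs = sub["offset"].to_numpy() if has_offset else np.zeros(len(sub), dtype=int)
        cur = None
        for s, e, t, o in zip(starts, ends, taus, offs):
            if cur is None:
                cur = [s, e, t, {int(o)}]
            elif s <= cur[1] + merge_gap:
                cur[1] = max(cur[1], e)
                cur[2] = max(cur[2], t)
                cur[3].add(int(o))
            else:
                regions.append(
                    EnrichedRegion(str(chrom), int(cur[0]), int(cur[1]), float(cur[2]),
                                   frozenset(cur[3]))
                )
                cur = [s, e, t, {int(o)}]
        if cur is not None:
            regions.append(
                EnrichedRegion(str(chrom), int(cur[0]), int(cur[1]), float(cur[2]),
                               frozenset(cur[3]))
            )
    return regions


def coverage_profile(
    reads: ReadSet, frag: FragmentLength | int, chrom: str, start: int, end: int
) -> np.ndarray:
    """Number of overlapping extended reads at each base of [start, end)."""
    if isinstance(frag, int):
        frag = FragmentLength(frag)
    f = frag.value
    sub = reads.for_chrom(chrom)
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    plus = (sub["strand"] == "+").to_numpy()
    ext_s = np.where(plus, s, e - f)
    ext_e = ext_s + f
    lo = np.clip(ext_s, start, end) - start
    hi = np.clip(ext_e, start, end) - start
    keep = hi > lo
    diff = np.zeros(end - start + 1, dtype=np.int64)
    np.add.at(diff, lo[keep], 1)
    np.add.at(diff, hi[keep], -1)
    return np.cumsum(diff[:-1])


def find_local_maxima(
    profile: np.ndarray, quantile: float = 0.9, span: int = 50
) -> list[int]:
    """Summit positions: strict maxima of the profile within +-span whose
    height exceeds the given quantile of the profile's positive values.
    A flat plateau reports its midpoint."""
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ValueError("empty coverage profile")
    positive = profile[profile > 0]
    if positive.size == 0:
        return []
    thr = float(np.quantile(positive, quantile))

    # run-length encode plateaus
    change = np.flatnonzero(np.diff(profile)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(profile)]])  # half-open runs
    summits = []
    for i, j in zip(starts, ends):
        h = profile[i]
        if h <= 0 or h <= thr:
            continue
        left = profile[max(0, i - span) : i]
        right = profile[j : j + span]
        if left.size and left.max() >= h:
            continue
        if right.size and right.max() >= h:
            continue
        summits.append(int((i + j - 1) // 2))
    return summits


def _anchored_side_scan(profile: np.ndarray, summit: int, right: bool, min_side: int) -> int:
    """Endpoint on one side of a summit maximizing the R^2 of a line through
    the summit.  Ties (within 1e-9) resolve to the farthest endpoint."""
    L = len(profile)
    h = float(profile[summit])
    if right:
        lo, hi = min(summit + min_side, L - 1), L - 1
        seg = profile[summit : hi + 1].astype(np.float64)
    else:
        lo, hi = max(summit - min_side, 0), 0
        seg = profile[summit::-1][: summit + 1].astype(np.float64)
    m = len(seg)
    if m < 2:
        return summit
    dx = np.arange(m, dtype=np.float64)
    dy = seg - h
    c_dx2 = np.cumsum(dx * dx)
    c_dxdy = np.cumsum(dx * dy)
    c_y = np.cumsum(seg)
    c_y2 = np.cumsum(seg * seg)
    k = np.arange(m)  # endpoint offset from summit
    with np.errstate(invalid="ignore", divide="ignore"):
        # SSE of the anchored fit: sum dy^2 - (sum dx dy)^2 / sum dx^2
        sum_dy2 = c_y2 - 2 * h * c_y + (k + 1) * h * h
        sse = sum_dy2 - np.where(c_dx2 > 0, c_dxdy**2 / np.maximum(c_dx2, 1e-300), 0.0)
        mean = c_y / (k + 1)
        sst = c_y2 - (k + 1) * mean**2
        r2 = np.where(sst > 1e-12, 1.0 - sse / np.maximum(sst, 1e-300), 0.0)
    off_lo = abs(lo - summit)
    cand = r2[off_lo:]
    if cand.size == 0:
        return hi
    best_r2 = np.max(cand)
    far = int(np.flatnonzero(cand >= best_r2 - 1e-9)[-1]) + off_lo
    return summit + far if right else summit - far


def refine_boundaries(
    profile: np.ndarray,
    summits,
    merge_within: int = 100,
    min_side: int = 25,
    region_start: int = 0,
    chrom: str = ".",
    max_posterior: float = 1.0,
) -> list[RefinedPeak]:
    """Place punctate peak boundaries around each summit by the anchored
    best-line scan, then merge summits within ``merge_within`` bp of each
    other or with overlapping boundaries (the taller summit is kept).

    Coordinates in the returned peaks are absolute when ``region_start`` is
    the genomic start of the profile.
    """
    profile = np.asarray(profile)
    raw = []
    for s in sorted(summits):
        left = _anchored_side_scan(profile, s, right=False, min_side=min_side)
        right = _anchored_side_scan(profile, s, right=True, min_side=min_side)
        raw.append((left, right, s, float(profile[s])))

    merged: list[list] = []
    for left, right, s, h in raw:
        if merged and (s - merged[-1][2] < merge_within or left <= merged[-1][1]):
            prev = merged[-1]
            prev[0] = min(prev[0], left)
            prev[1] = max(prev[1], right)
            if h > prev[3]:
                prev[2], prev[3] = s, h
        else:
            merged.append([left, right, s, h])
    return [
        RefinedPeak(
            chrom,
            region_start + left,
            region_start + right + 1,
            region_start + s,
            h,
            max_posterior,
        )
        for left, right, s, h in merged
    ]


def refine_region(
    reads: ReadSet,
    frag: FragmentLength | int,
    region: EnrichedRegion,
    quantile: float = 0.9,
    span: int = 50,
    merge_within: int = 100,
    min_side: int = 25,
) -> list[RefinedPeak]:
    """Full refinement of one enriched region from the read-overlap profile."""
    profile = coverage_profile(reads, frag, region.chrom, region.start, region.end)
    if not profile.any():
        return []
    summits = find_local_maxima(profile, quantile, span)
    return refine_boundaries(
        profile,
        summits,
        merge_within,
        min_side,
        region_start=region.start,
        chrom=region.chrom,
        max_posterior=region.max_posterior,
    )


def stalling_score(inp: StallingInput) -> float:
    """Punctate-vs-broad stalling index.

    score = [(MAX(H_punctate) + 1) / (Median(H_broad) + 1)]
            * (L_punctate / L_broad)

    High values indicate a punctate 5' peak towering over a quiet gene body
    (stalled polymerase); low values indicate broad high-amplitude signal.
    The pseudocount of 1 in the height ratio avoids division by zero.
    """
    if inp.length_punctate <= 0 or inp.length_broad <= 0:
        raise ValueError("lengths must be positive")
    height_ratio = (inp.height_punctate_max + 1.0) / (inp.height_broad_median + 1.0)
    return height_ratio * (inp.length_punctate / inp.length_broad)


def cnv_mode(
    input_reads: ReadSet,
    chrom_sizes: dict[str, int],
    window_size: int = 10_000,
    frag: FragmentLength | int = 200,
    threshold: float = 0.95,
) -> tuple[list[EnrichedRegion], MixtureFit]:
    """Detect candidate copy-number amplifications from the input control.

    The mixture model is run on input-sample counts in large windows
    (default 10 kb, single grid, no covariates in any component); regions
    enriched at the posterior threshold are candidate amplifications.
    """
    if len(input_reads) == 0:
        raise ValueError("CNV mode requires input-control reads")
    if isinstance(frag, int):
        frag = FragmentLength(frag)
    centers = extend_and_center(input_reads, frag, chrom_sizes)
    grids = build_window_grid(chrom_sizes, window_size, offsets=(0,))
    frames = []
    for grid in grids:
        c = centers.get(grid.chrom, np.zeros(0, dtype=np.int64))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": grid.chrom,
                    "start": grid.starts,
                    "end": grid.ends,
                    "offset": 0,
                    "count": count_in_windows(c, grid),
                }
            )
        )
    table_df = pd.concat(frames, ignore_index=True)
    y = table_df["count"].to_numpy()
    n = len(y)
    table = WindowTable(y, np.ones((n, 1)), np.ones((n, 1)), np.ones((n, 1)))
    fit = fit_mixture(table)
    table_df["tau2"] = fit.posteriors.tau2
    return call_regions(table_df, threshold=threshold), fit


def regions_to_bed(regions: list[EnrichedRegion]) -> pd.DataFrame:
    """BED6-style frame for merged enriched regions."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [f"region_{i + 1}" for i in range(len(regions))],
            "score": [min(int(round(1000 * r.max_posterior)), 1000) for r in regions],
            "strand": ".",
        }
    )


def peaks_to_bed(peaks: list[RefinedPeak]) -> pd.DataFrame:
    """BED6+3 frame for refined punctate peaks (summit, height, refined flag)."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [f"peak_{i + 1}" for i in range(len(peaks))],
            "score": [min(int(round(1000 * p.max_posterior)), 1000) for p in peaks],
            "strand": ".",
            "summit": [p.summit for p in peaks],
            "summit_height": [p.summit_height for p in peaks],
            "refined": 1,
        }
    )
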