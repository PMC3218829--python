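"""Per-window covariate scoring and design-matrix assembly.

Covariates scored for every analysis window:

* ``gc``    — proportion of G/C among non-N bases in the window,
* ``map``   — mappability score: proportion of window bases that are
  alignable after shifting the per-base uniqueness calls by plus and minus
  half the fragment length (mirroring how fragment centers are assigned),
* ``bg``    — local background: reads per mappable base in sliding 100-kb
  windows (stepped every 2.5 kb), change-point filtered to exclude windows
  straddling copy-number boundaries, rescaled to the analysis window length,
* ``input`` — read counts from a matched input-control sample, tabulated
  exactly as the experimental sample.

Selected covariates are standardized (mean 0, variance 1) before entering
the component design matrices; interaction columns are products of the
standardized main effects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_windows import FragmentLength, WindowGrid

logger = logging.getLogger(__name__)


@dataclass
class CovariateTrack:
    """A real-valued vector aligned to one WindowGrid."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"covariate {self.name!r} contains non-finite values")


@dataclass(frozen=True)
class ChangePointSet:
    """Ordered boundaries of a piecewise-constant fit to a background-rate series.

    ``boundaries`` are indices into the rate series: a boundary k splits
    segments [.., k) and [k, ..).  ``positions_bp`` (when set) are the
    corresponding genomic coordinates.
    """

    boundaries: tuple[int, ...]
    positions_bp: tuple[int, ...] = ()


@dataclass
class WindowTable:
    """Counts plus per-component design matrices for the mixture regression.

    X0 / X1 / X2 are the designs for the zero-inflated, background, and
    enrichment components; each starts with an intercept column of ones.
    """

    y: np.ndarray
    X0: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    colnames0: tuple[str, ...] = ("intercept",)
    colnames1: tuple[str, ...] = ("intercept",)
    colnames2: tuple[str, ...] = ("intercept",)
    meta: pd.DataFrame | None = None  # optional chrom/start/end/offset per row

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        n = len(self.y)
        for X in (self.X0, self.X1, self.X2):
            if X.shape[0] != n:
                raise ValueError("design matrix row count does not match y")
            if not np.all(np.isfinite(X)):
                raise ValueError("design matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.y)


def gc_fraction(sequence: str, grid: WindowGrid) -> CovariateTrack:
    """G/C proportion among non-N bases per window (all-N windows score 0)."""
    if len(sequence) < grid.chrom_length:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than chromosome length {grid.chrom_length}"
        )
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_n = ~((seq == ord("A")) | (seq == ord("T")) | is_gc)
    cgc = np.concatenate([[0], np.cumsum(is_gc)])
    cn = np.concatenate([[0], np.cumsum(is_n)])
    s, e = grid.starts, grid.ends
    gc = (cgc[e] - cgc[s]).astype(np.float64)
    non_n = (e - s) - (cn[e] - cn[s])
    all_n = non_n == 0
    if all_n.any():
        logger.info("%d all-N window(s) on %s assigned gc=0", int(all_n.sum()), grid.chrom)
    vals = np.where(all_n, 0.0, gc / np.maximum(non_n, 1))
    return CovariateTrack("gc", vals)


def binarize_uniqueness(uniqueness: np.ndarray, criterion: int = 1) -> np.ndarray:
    """Per-base alignability call: 1 if 0 < k-mer occurrence count <= criterion.

    A count of 0 marks bases where uniqueness was not assessed (e.g. within a
    k-mer length of the chromosome end) and is treated as unmappable.
    """
    if criterion < 1:
        raise ValueError("uniqueness criterion must be >= 1")
    u = np.asarray(uniqueness)
    return ((u > 0) & (u <= criterion)).astype(np.float64)


def mappability_score(
    uniqueness: np.ndarray,
    criterion: int,
    frag: FragmentLength | int,
    grid: WindowGrid,
) -> CovariateTrack:
    """Window mappability score in [0, 1].

    Per-base uniqueness counts are binarized against ``criterion``, then each
    base receives the sum of the binary calls at +- half the fragment length
    (0, 1 or 2, matching the fragment-center shift applied to reads), and the
    per-base scores are summed within each window and divided by twice the
    window size.
    """
    if isinstance(frag, int):
        frag = FragmentLength(frag)
    if len(uniqueness) < grid.chrom_length:
        raise ValueError("uniqueness track shorter than the chromosome")
    binary = binarize_uniqueness(uniqueness, criterion)
    h = frag.value // 2
    L = grid.chrom_length
    shifted = np.zeros(L)
    # score[p] = binary[p - h] + binary[p + h], out-of-range terms 0
    shifted[h:L] += binary[: L - h]
    shifted[: L - h] += binary[h:L]
    csum = np.concatenate([[0.0], np.cumsum(shifted)])
    s, e = grid.starts, grid.ends
    vals = (csum[e] - csum[s]) / (2.0 * grid.window_size)
    return CovariateTrack("map", vals)


def detect_changepoints(rates: np.ndarray, penalty: float | None = None) -> ChangePointSet:
    """Change points of a piecewise-constant mean fit by binary segmentation.

    Splits are accepted greedily while the within-segment squared-error
    reduction exceeds ``penalty``.  The default penalty is 2 * sigma^2 * log(n)
    with sigma estimated from the median absolute deviation of the first
    differences (robust to the level shifts being sought).
    """
    x = np.asarray(rates, dtype=np.float64)
    n = len(x)
    if n < 2:
        return ChangePointSet(())
    if penalty is None:
        diffs = np.diff(x)
        mad = np.median(np.abs(diffs - np.median(diffs)))
        sigma = 1.4826 * mad / np.sqrt(2.0)
        if sigma == 0:
            sigma = max(np.std(x), 1e-12)
        penalty = 2.0 * sigma**2 * np.log(n)

    def best_split(lo: int, hi: int) -> tuple[int, float]:
        """Best single split of x[lo:hi]; returns (index, SSE gain)."""
        seg = x[lo:hi]
        m = len(seg)
        if m < 4:
            return -1, 0.0
        c1 = np.cumsum(seg)
        c2 = np.cumsum(seg**2)
        total = c2[-1] - c1[-1] ** 2 / m
        k = np.arange(1, m)  # split into [0:k) and [k:m)
        left = c2[k - 1] - c1[k - 1] ** 2 / k
        rs1 = c1[-1] - c1[k - 1]
        rs2 = c2[-1] - c2[k - 1]
        right = rs2 - rs1**2 / (m - k)
        gains = total - (left + right)
        j = int(np.argmax(gains))
        return lo + int(k[j]), float(gains[j])

    boundaries: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        k, gain = best_split(lo, hi)
        if k >= 0 and gain > penalty:
            boundaries.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return ChangePointSet(tuple(sorted(boundaries)))


def local_background(
    centers: np.ndarray,
    map_track: np.ndarray,
    chrom_length: int,
    grid: WindowGrid,
    big_window: int = 100_000,
    step: int = 2_500,
    changepoint_penalty: float | None = None,
) -> CovariateTrack:
    """Local background estimate per analysis window.

    Reads per mappable base are computed in ``big_window``-bp sliding windows
    stepped every ``step`` bp.  Big windows straddling change-point boundaries
    (candidate CNV edges) are removed, and each analysis window receives the
    mean surviving rate over all overlapping big windows, multiplied by the
    analysis window size.

    ``map_track`` is the per-base binary alignability vector (all ones for a
    fully mappable toy genome).
    """
    if big_window < grid.window_size:
        raise ValueError("big_window must be at least the analysis window size")
    centers = np.sort(np.asarray(centers))
    mappable = np.asarray(map_track, dtype=np.float64)
    if len(mappable) < chrom_length:
        raise ValueError("per-base mappability track shorter than the chromosome")

    if chrom_length <= big_window:
        logger.info("chromosome shorter than %d bp: single background window", big_window)
        big_starts = np.array([0])
        big_ends = np.array([chrom_length])
    else:
        big_starts = np.arange(0, chrom_length - big_window + 1, step, dtype=np.int64)
        big_ends = big_starts + big_window

    cmap = np.concatenate([[0.0], np.cumsum(mappable[:chrom_length])])
    n_map = cmap[big_ends] - cmap[big_starts]
    n_reads = np.searchsorted(centers, big_ends) - np.searchsorted(centers, big_starts)
    rates = np.where(n_map > 0, n_reads / np.maximum(n_map, 1.0), 0.0)

    cps = detect_changepoints(rates, changepoint_penalty)
    keep = np.ones(len(rates), dtype=bool)
    positions = []
    for k in cps.boundaries:
        bp = int(big_starts[min(k, len(big_starts) - 1)] + big_window // 2)
        positions.append(bp)
        keep &= ~((big_starts < bp) & (big_ends > bp))
    if cps.boundaries:
        logger.info(
            "removed %d big window(s) straddling %d change point(s)",
            int((~keep).sum()),
            len(cps.boundaries),
        )

    kept_rates = np.where(keep, rates, 0.0)
    crate = np.concatenate([[0.0], np.cumsum(kept_rates)])
    ckeep = np.concatenate([[0], np.cumsum(keep.astype(np.int64))])

    s, e = grid.starts, grid.ends
    # big window i overlaps analysis window [s, e) iff big_starts[i] in (s - big_window, e)
    lo = np.searchsorted(big_starts, s - big_window, side="right")
    hi = np.searchsorted(big_starts, e, side="left")
    n_keep = ckeep[hi] - ckeep[lo]
    rate_sum = crate[hi] - crate[lo]
    # windows whose every overlapping big window was filtered fall back to all
    call = np.concatenate([[0.0], np.cumsum(rates)])
    n_all = np.maximum(hi - lo, 1)
    mean_rate = np.where(
        n_keep > 0, rate_sum / np.maximum(n_keep, 1), (call[hi] - call[lo]) / n_all
    )
    return CovariateTrack("bg", mean_rate * grid.window_size)


def kmer_uniqueness(sequence: str, k: int = 36) -> np.ndarray:
    """Brute-force per-base k-mer occurrence counts for a toy genome (< 1 Mb).

    For each base, the number of times the k-mer starting there occurs in the
    sequence.  Bases within k of the end get 0 (not assessed), matching the
    convention of genome-scale uniqueness tracks.
    """
    if len(sequence) > 1_000_000:
        raise ValueError("brute-force uniqueness is restricted to toy genomes (< 1 Mb)")
    seq = sequence.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    out = np.zeros(len(seq), dtype=np.int64)
    for i in range(len(seq) - k + 1):
        out[i] = counts[seq[i : i + k]]
    return out


def standardize(values: np.ndarray, name: str = "covariate") -> np.ndarray:
    """Center and scale to mean 0, variance 1; errors on constant input."""
    v = np.asarray(values, dtype=np.float64)
    sd = v.std()
    if sd == 0:
        raise ValueError(f"covariate {name!r} has zero variance and cannot be standardized")
    return (v - v.mean()) / sd


def _build_design(
    terms, standardized: dict[str, np.ndarray], n: int
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in terms:
        parts = term.split(":")
        for p in parts:
            if p not in standardized:
                raise KeyError(f"term {term!r} references unknown covariate {p!r}")
        col = standardized[parts[0]].copy()
        for p in parts[1:]:
            col = col * standardized[p]
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), tuple(names)


def assemble_design(
    y: np.ndarray,
    tracks: dict[str, np.ndarray],
    formulation: dict[str, list[str]],
    meta: pd.DataFrame | None = None,
) -> WindowTable:
    """Build the per-component design matrices for a covariate formulation.

    ``formulation`` maps component keys ``zi`` / ``bg`` / ``enr`` to lists of
    terms; a term is a covariate name or a ':'-joined interaction
    (e.g. ``"gc:map"``).  Main effects are standardized over the analyzed
    windows; interaction columns are elementwise products of standardized
    main-effect columns; the intercept is prepended.
    """
    y = np.asarray(y)
    n = len(y)
    used = set()
    for comp in ("zi", "bg", "enr"):
        for term in formulation.get(comp, []):
            used.update(term.split(":"))
    standardized = {name: standardize(tracks[name], name) for name in sorted(used)}

    X0, names0 = _build_design(formulation.get("zi", []), standardized, n)
    X1, names1 = _build_design(formulation.get("bg", []), standardized, n)
    X2, names2 = _build_design(formulation.get("enr", []), standardized, n)
    return WindowTable(y, X0, X1, X2, names0, names1, names2, meta=meta)


def read_bedgraph_track(path, chrom: str, chrom_length: int) -> np.ndarray:
    """Expand a bedGraph interval track into a per-base vector for one chromosome."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    df = df[df["chrom"] == chrom]
    out = np.zeros(chrom_length)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        out[max(0, int(s)) : min(chrom_length, int(e))] = v
    return out
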