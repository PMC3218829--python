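"""End-to-end orchestration of the three pipeline steps.

Stages write plain-text TSV/JSON intermediates into a run directory so every
stage can be re-run independently from the previous stage's files:

    counts.tsv       chrom, start, end, offset, count [, input]
    covariates.tsv   counts plus one column per scored covariate
    best_model.json  winning formulation and its BIC (+ models_ranked.tsv)
    fit.json         fitted coefficients and the log-likelihood trace
    posteriors.tsv   per-window tau0 / tau1 / tau2
    regions.bed      merged enriched regions
    peaks.bed        refined punctate peaks (when refinement is requested)
    manifest.json    parameters and sha256 checksums per stage
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import genomic_windows as gw
from .covariates import WindowTable, assemble_design
from .model_selection import Formulation, select_best_model
from .peaks import call_regions, peaks_to_bed, refine_region, regions_to_bed
from .zinb_mixture import fit_mixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reads: str
    chrom_sizes: str
    out_dir: str
    input_reads: str | None = None
    fasta: str | None = None
    uniqueness: str | None = None  # bedGraph of per-base k-mer occurrence counts
    map_criterion: int = 1
    window_size: int = 250
    offsets: tuple[int, ...] = (0, 125)
    frag: int | str = 200  # bp, or "auto" for cross-correlation estimation
    starting: tuple[str, ...] = ("gc",)
    threshold: float = 0.95
    broad: bool = False
    refine: bool = False
    selection_chroms: tuple[str, ...] | None = None
    heuristic: bool = True
    interactions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.threshold < 1:
            raise ValueError("posterior threshold must lie in [0.5, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_reads_and_frag(cfg: RunConfig) -> tuple[gw.ReadSet, gw.FragmentLength]:
    reads = gw.read_alignments(cfg.reads)
    if cfg.frag == "auto":
        frag = gw.estimate_fragment_length(reads)
        logger.info("estimated fragment length: %d bp", frag.value)
    else:
        frag = gw.FragmentLength(int(cfg.frag))
    return reads, frag


def stage_count(cfg: RunConfig, out: Path) -> Path:
    reads, frag = _load_reads_and_frag(cfg)
    sizes = gw.read_chrom_sizes(cfg.chrom_sizes)
    counts = gw.window_counts(reads, sizes, cfg.window_size, cfg.offsets, frag)
    if cfg.input_reads:
        inp = gw.read_alignments(cfg.input_reads)
        icounts = gw.window_counts(inp, sizes, cfg.window_size, cfg.offsets, frag)
        counts["input"] = icounts["count"]
    path = out / "counts.tsv"
    counts.to_csv(path, sep="\t", index=False)
    logger.info("count stage: %d windows across %d chromosome(s)", len(counts), len(sizes))
    return path


def stage_covariates(cfg: RunConfig, out: Path) -> Path:
    counts = pd.read_csv(out / "counts.tsv", sep="\t")
    sizes = gw.read_chrom_sizes(cfg.chrom_sizes)
    reads, frag = _load_reads_and_frag(cfg)
    centers = gw.extend_and_center(reads, frag, sizes)

    fasta = None
    if cfg.fasta:
        from pyfaidx import Fasta

        fasta = Fasta(cfg.fasta)
    need_gc = "gc" in cfg.starting
    if need_gc and fasta is None:
        raise FileNotFoundError("G/C covariate requested but no FASTA supplied")
    need_map = "map" in cfg.starting
    if need_map and cfg.uniqueness is None:
        raise FileNotFoundError("mappability covariate requested but no uniqueness track supplied")

    pieces = []
    for (chrom, offset), sub in counts.groupby(["chrom", "offset"], sort=False):
        grid = gw.WindowGrid(str(chrom), sizes[str(chrom)], cfg.window_size, int(offset))
        cols: dict[str, np.ndarray] = {}
        binary_map = np.ones(grid.chrom_length)
        if need_map:
            uniq = cov.read_bedgraph_track(cfg.uniqueness, str(chrom), grid.chrom_length)
            cols["map"] = cov.mappability_score(uniq, cfg.map_criterion, frag, grid).values
            binary_map = cov.binarize_uniqueness(uniq, cfg.map_criterion)
        if need_gc:
            seq = str(fasta[str(chrom)][: grid.chrom_length])
            cols["gc"] = cov.gc_fraction(seq, grid).values
        if "bg" in cfg.starting:
            c = centers.get(str(chrom), np.zeros(0, dtype=np.int64))
            cols["bg"] = cov.local_background(c, binary_map, grid.chrom_length, grid).values
        piece = sub.reset_index(drop=True)
        for name, vals in cols.items():
            piece[name] = vals
        pieces.append(piece)
    table = pd.concat(pieces, ignore_index=True)
    path = out / "covariates.tsv"
    table.to_csv(path, sep="\t", index=False)
    return path


def _tracks_from_table(table: pd.DataFrame, starting) -> dict[str, np.ndarray]:
    tracks = {}
    for name in starting:
        if name not in table.columns:
            raise KeyError(f"covariate {name!r} missing from covariates.tsv")
        tracks[name] = table[name].to_numpy(dtype=np.float64)
    return tracks


def stage_select(cfg: RunConfig, out: Path) -> Path:
    table = pd.read_csv(out / "covariates.tsv", sep="\t")
    tracks = _tracks_from_table(table, cfg.starting)
    best, ranked = select_best_model(
        table["count"].to_numpy(),
        tracks,
        cfg.starting,
        window_chroms=table["chrom"].to_numpy(),
        chroms=list(cfg.selection_chroms) if cfg.selection_chroms else None,
        heuristic=cfg.heuristic,
        interactions=cfg.interactions,
    )
    ranked.to_csv(out / "models_ranked.tsv", sep="\t", index=False)
    path = out / "best_model.json"
    path.write_text(
        json.dumps(
            {
                "formulation": best.formulation.as_dict(),
                "bic": best.bic,
                "loglik": best.fit.loglik,
            },
            indent=2,
        )
    )
    logger.info("selected formulation: %s (BIC %.2f)", best.formulation.as_dict(), best.bic)
    return path


def stage_fit(cfg: RunConfig, out: Path) -> Path:
    table = pd.read_csv(out / "covariates.tsv", sep="\t")
    model_path = out / "best_model.json"
    if model_path.exists():
        formulation = json.loads(model_path.read_text())["formulation"]
    else:
        formulation = {"zi": [], "bg": list(cfg.starting), "enr": []}
        logger.info("no selection output; fitting default formulation %s", formulation)
    used = sorted({p for terms in formulation.values() for t in terms for p in t.split(":")})
    tracks = _tracks_from_table(table, used)
    wt = assemble_design(table["count"].to_numpy(), tracks, formulation)
    fit = fit_mixture(wt)
    (out / "fit.json").write_text(
        json.dumps(
            {
                "formulation": formulation,
                "gamma": fit.params.gamma.tolist(),
                "beta1": fit.params.beta1.tolist(),
                "beta2": fit.params.beta2.tolist(),
                "theta1": fit.params.theta1,
                "theta2": fit.params.theta2,
                "pi1": fit.params.pi1,
                "pi2": fit.params.pi2,
                "loglik_trace": fit.loglik_trace.tolist(),
                "converged": fit.converged,
                "n_iter": fit.n_iter,
                "init_fraction": fit.init_fraction,
            },
            indent=2,
        )
    )
    post = table[["chrom", "start", "end", "offset", "count"]].copy()
    post["tau0"] = fit.posteriors.tau0
    post["tau1"] = fit.posteriors.tau1
    post["tau2"] = fit.posteriors.tau2
    path = out / "posteriors.tsv"
    post.to_csv(path, sep="\t", index=False, float_format="%.10g")
    logger.info(
        "fit: %d EM iterations, init fraction %.3f, loglik %.2f",
        fit.n_iter,
        fit.init_fraction,
        fit.loglik,
    )
    return path


def stage_call(cfg: RunConfig, out: Path) -> Path:
    post = pd.read_csv(out / "posteriors.tsv", sep="\t")
    merge_gap = 5000 if cfg.broad else 0
    regions = call_regions(post, threshold=cfg.threshold, merge_gap=merge_gap)
    regions_to_bed(regions).to_csv(out / "regions.bed", sep="\t", index=False, header=False)
    logger.info("called %d enriched region(s)", len(regions))
    path = out / "regions.bed"
    if cfg.refine:
        reads, frag = _load_reads_and_frag(cfg)
        peaks = []
        for region in regions:
            peaks.extend(refine_region(reads, frag, region))
        peaks_to_bed(peaks).to_csv(out / "peaks.bed", sep="\t", index=False, header=False)
        logger.info("refined %d punctate peak(s)", len(peaks))
        path = out / "peaks.bed"
    return path


STAGES = {
    "count": stage_count,
    "covariates": stage_covariates,
    "select": stage_select,
    "fit": stage_fit,
    "call": stage_call,
}


def run_pipeline(cfg: RunConfig, stages=("count", "covariates", "select", "fit", "call")) -> Path:
    """Execute the requested stages in order, writing a run manifest.

    Any stage failure raises with the stage name attached; completed stages
    leave their intermediates in place so the run can resume.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: list(v) if isinstance(v, tuple) else v
                                 for k, v in asdict(cfg).items()},
                      "stages": {}}
    for name in stages:
        try:
            result = STAGES[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "output": result.name,
            "sha256": _sha256(result),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
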