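"""Synthetic window-count generator with ground-truth component labels.

Counts are generated by a two-step procedure.  Step 1 draws per-window
covariates, computes the background mean mu_B = exp(X_B . beta_B*) and the
zero-inflation probability pi_z = sigmoid(X_z . gamma*) from pre-specified
coefficient vectors, samples background counts from NB(mu_B, theta_B), and
zeroes each window independently with probability pi_z.  Step 2 selects a
random subset of the remaining background windows as enriched and replaces
their counts with draws from NB(b * GC_i + a, theta_E): the enrichment mean
is linear in the raw G/C fraction, so the sign of b sets whether enrichment
signal rises or falls with G/C and (b, a) together tune the signal-to-noise
ratio.

The covariate generator emulates genomic windows (G/C from a beta
distribution with mean 0.41 and sd 0.07; mappability as a spike near 1 with
a uniform tail); real per-window covariates can be supplied instead via
``covariate_values``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .covariates import WindowTable, assemble_design

LABEL_ZERO_INFLATED = 0
LABEL_BACKGROUND = 1
LABEL_ENRICHED = 2

# beta distribution matching genomic-window G/C (mean 0.41, sd 0.07)
_GC_BETA_A = 19.83
_GC_BETA_B = 28.53


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic dataset.

    ``gamma_star`` / ``beta_b_star`` map covariate names (plus "intercept")
    to true coefficients on the standardized-covariate scale; ``a`` and ``b``
    set the enrichment mean b * GC + a on the raw G/C scale.
    """

    n_windows: int = 20_000
    enr_fraction: float = 0.01
    a: float = 30.0
    b: float = -30.0
    theta_b: float = 2.0
    theta_e: float = 10.0
    gamma_star: dict = field(
        default_factory=lambda: {"intercept": -1.5, "gc": 0.5}
    )
    beta_b_star: dict = field(
        default_factory=lambda: {"intercept": 1.1, "gc": 0.5}
    )
    covariates: tuple[str, ...] = ("gc",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.enr_fraction < 0.5:
            raise ValueError("enrichment fraction must lie in (0, 0.5)")
        if self.a <= 0:
            raise ValueError("enrichment intercept a must be positive")
        if self.theta_b <= 0 or self.theta_e <= 0:
            raise ValueError("dispersions must be positive")


@dataclass
class SimTruth:
    """Latent per-window component labels (0 = zero-inflated, 1 = background,
    2 = enriched) and generating means."""

    label: np.ndarray
    mu_true: np.ndarray


@dataclass
class SimData:
    y: np.ndarray
    tracks: dict[str, np.ndarray]
    truth: SimTruth
    config: SimConfig


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = config.n_windows
    tracks: dict[str, np.ndarray] = {}
    for name in config.covariates:
        if name == "gc":
            tracks["gc"] = rng.beta(_GC_BETA_A, _GC_BETA_B, size=n)
        elif name == "map":
            spike = rng.random(n) < 0.85
            tracks["map"] = np.where(
                spike, rng.uniform(0.95, 1.0, size=n), rng.uniform(0.0, 0.95, size=n)
            )
        else:
            raise ValueError(f"no generator for covariate {name!r}")
    return tracks


def _linear_predictor(coeffs: dict, tracks_std: dict[str, np.ndarray], n: int) -> np.ndarray:
    eta = np.full(n, float(coeffs.get("intercept", 0.0)))
    for name, val in coeffs.items():
        if name == "intercept":
            continue
        eta += val * tracks_std[name]
    return eta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    return rng.negative_binomial(theta, theta / (theta + mu))


def simulate_dataset(
    config: SimConfig, covariate_values: dict[str, np.ndarray] | None = None
) -> SimData:
    """Generate one dataset (fully reproducible from ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_windows
    tracks = (
        {k: np.asarray(v, dtype=np.float64) for k, v in covariate_values.items()}
        if covariate_values is not None
        else _draw_covariates(config, rng)
    )
    tracks_std = {k: (v - v.mean()) / v.std() for k, v in tracks.items()}

    mu_b = np.exp(_linear_predictor(config.beta_b_star, tracks_std, n))
    pi_z = expit(_linear_predictor(config.gamma_star, tracks_std, n))

    if "gc" in tracks:
        mu_e_all = config.b * tracks["gc"] + config.a
    else:
        mu_e_all = np.full(n, config.a)
    if np.any(mu_e_all <= 0):
        raise ValueError(
            "enrichment mean b * GC + a is non-positive for some window; "
            "adjust a and b before sampling"
        )

    y = _nb_draw(rng, mu_b, config.theta_b)
    mu_true = mu_b.copy()
    label = np.full(n, LABEL_BACKGROUND, dtype=np.int8)

    zi = rng.random(n) < pi_z
    y[zi] = 0
    mu_true[zi] = 0.0
    label[zi] = LABEL_ZERO_INFLATED

    background_idx = np.flatnonzero(~zi)
    n_enr = int(round(config.enr_fraction * n))
    n_enr = min(n_enr, len(background_idx))
    enr_idx = rng.choice(background_idx, size=n_enr, replace=False)
    y[enr_idx] = _nb_draw(rng, mu_e_all[enr_idx], config.theta_e)
    mu_true[enr_idx] = mu_e_all[enr_idx]
    label[enr_idx] = LABEL_ENRICHED

    return SimData(y.astype(np.int64), tracks, SimTruth(label, mu_true), config)


# ---------------------------------------------------------------------------
# benchmark scenario builders

SCENARIOS = {
    # (enrichment fraction, enrichment intercept a): high / moderate / low SNR
    "tfbs": (0.01, 30.0),
    "faire": (0.05, 20.0),
    "histone": (0.10, 10.0),
}
GC_EFFECTS = ("neg", "zero", "pos")


def benchmark_scenarios(seed: int = 0, n_windows: int = 100_000) -> dict[tuple[str, str], SimConfig]:
    """Nine benchmark configs: {TFBS 1%, FAIRE 5%, histone 10%} enrichment
    crossed with a negative / neutral / positive G/C effect on enrichment.
    G/C is positively tied to both the background mean and the
    zero-inflation probability in every config."""
    out = {}
    i = 0
    for scen, (frac, a) in SCENARIOS.items():
        for effect in GC_EFFECTS:
            b = {"neg": -a, "zero": 0.0, "pos": a}[effect]
            out[(scen, effect)] = SimConfig(
                n_windows=n_windows,
                enr_fraction=frac,
                a=a,
                b=b,
                seed=seed * 100 + i,
            )
            i += 1
    return out


def selection_benchmark_config(seed: int = 0, n_windows: int = 20_000) -> SimConfig:
    """Strong-G/C-effect config for covariate-selection benchmarks: G/C drives
    the background mean (+0.5 per sd), zero-inflation (+0.5 per sd) and the
    enrichment mean (steep negative slope)."""
    return SimConfig(
        n_windows=n_windows,
        enr_fraction=0.05,
        a=30.0,
        b=-35.0,
        seed=seed,
    )


MODEL_FORMULATIONS = {
    # covariate usage per component for the three benchmark model variants
    1: {"zi": [], "bg": [], "enr": []},
    2: {"zi": ["gc"], "bg": ["gc"], "enr": []},
    3: {"zi": ["gc"], "bg": ["gc"], "enr": ["gc"]},
}


def model_design(sim: SimData, model: int) -> WindowTable:
    """Design matrices for benchmark model 1 (no covariates), model 2 (G/C in
    the zero-inflated and background components) or model 3 (G/C in all
    three components)."""
    return assemble_design(sim.y, sim.tracks, MODEL_FORMULATIONS[model])


# ---------------------------------------------------------------------------
# read-level simulation (for local-background / CNV / pipeline experiments)


def simulate_reads(
    chrom_length: int,
    base_rate: float = 0.012,
    read_length: int = 36,
    frag: int = 200,
    amplicon: tuple[int, int, float] | None = None,
    spikes=(),
    spike_width: int = 500,
    chrom: str = "chr1",
    seed: int = 0,
):
    """Simulate single-end reads on one chromosome.

    Fragment centers arrive as a Poisson process at ``base_rate`` reads/bp,
    multiplied by ``fold`` inside an optional ``amplicon`` (start, end, fold)
    to emulate a copy-number gain.  Each entry of ``spikes`` is
    ``(position, n_reads)``: an enrichment site whose fragment centers fall
    uniformly within ``spike_width`` bp of the position.  Read strand is
    uniform, and read coordinates are placed so that 3'-extension to ``frag``
    bp recovers the fragment center exactly.
    """
    from .genomic_windows import ReadSet

    rng = np.random.default_rng(seed)
    n_bg = rng.poisson(base_rate * chrom_length)
    centers = [rng.integers(0, chrom_length, size=n_bg)]
    if amplicon is not None:
        a_start, a_end, fold = amplicon
        n_amp = rng.poisson(base_rate * (a_end - a_start) * (fold - 1.0))
        centers.append(rng.integers(a_start, a_end, size=n_amp))
    for pos, n_reads in spikes:
        lo = max(pos - spike_width // 2, 0)
        hi = min(pos + spike_width // 2, chrom_length)
        centers.append(rng.integers(lo, hi, size=n_reads))
    c = np.concatenate(centers)
    plus = rng.random(len(c)) < 0.5
    start = np.where(plus, c - frag // 2, c + (frag + 1) // 2 - read_length)
    end = start + read_length
    shift = np.maximum(-start, 0)  # keep reads on-chromosome
    start += shift
    end += shift
    shift = np.maximum(end - chrom_length, 0)
    start -= shift
    end -= shift
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "strand": np.where(plus, "+", "-"),
        }
    ).sort_values(["start", "end"], ignore_index=True)
    return ReadSet(df)


def write_tagalign(reads, path) -> None:
    """Write a ReadSet as a tagAlign (BED6) file."""
    df = reads.df.copy()
    df["name"] = "N"
    df["score"] = 1000
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def random_genome(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Random nucleotide sequence with the given expected G/C fraction."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("AGCT"), size=length, p=probs))


@dataclass
class ClassificationResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate_classification(truth: SimTruth, tau2: np.ndarray) -> ClassificationResult:
    """ROC of the enrichment posterior against the latent enriched-vs-rest
    labels, with the area under the curve by trapezoid."""
    is_enr = truth.label == LABEL_ENRICHED
    if not is_enr.any():
        raise ValueError("truth contains no enriched windows")
    fpr, tpr, _ = roc_curve(is_enr.astype(int), np.asarray(tau2))
    return ClassificationResult(fpr, tpr, float(_trapezoid_auc(fpr, tpr)))
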