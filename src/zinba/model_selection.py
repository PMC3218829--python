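"""BIC-driven covariate formulation search for the mixture regression.

For a set of starting covariates, all strong-heredity term sets (main
effects, pairwise and three-way interactions) are enumerated per component,
the mixture is fit under each candidate formulation on a restricted window
set, and the formulation minimizing the BIC is selected.  A search heuristic
keeps the zero-inflated component intercept-only while the background and
enrichment formulations vary (for three starting covariates this gives
19 x 19 = 361 candidates); after the search, mappability is offered to the
zero-inflated component and kept if it lowers the BIC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import assemble_design
from .zinb_mixture import DEFAULT_INIT_FRACTIONS, MixtureFit, fit_mixture

logger = logging.getLogger(__name__)

MAX_COVARIATES = 4


@dataclass(frozen=True)
class Formulation:
    """Per-component term lists (strong heredity holds within each component)."""

    terms0: tuple[str, ...] = ()  # zero-inflated
    terms1: tuple[str, ...] = ()  # background
    terms2: tuple[str, ...] = ()  # enrichment

    def as_dict(self) -> dict[str, list[str]]:
        return {"zi": list(self.terms0), "bg": list(self.terms1), "enr": list(self.terms2)}


@dataclass
class ScoredModel:
    formulation: Formulation
    bic: float
    fit: MixtureFit


def hierarchical_term_sets(covariates, interactions: bool = True) -> list[tuple[str, ...]]:
    """All term sets over the covariates obeying strong heredity.

    A pairwise interaction requires both main effects; a three-way interaction
    requires all three mains and all three pairwise interactions.
    """
    covs = list(covariates)
    out: list[tuple[str, ...]] = []
    for r in range(len(covs) + 1):
        for mains in itertools.combinations(covs, r):
            if not interactions:
                out.append(tuple(mains))
                continue
            pairs = list(itertools.combinations(mains, 2))
            for pr in range(len(pairs) + 1):
                for psub in itertools.combinations(pairs, pr):
                    base = tuple(mains) + tuple(":".join(p) for p in psub)
                    eligible = [
                        trip
                        for trip in itertools.combinations(mains, 3)
                        if set(itertools.combinations(trip, 2)) <= set(psub)
                    ]
                    for tr in range(len(eligible) + 1):
                        for tsub in itertools.combinations(eligible, tr):
                            out.append(base + tuple(":".join(t) for t in tsub))
    return out


def enumerate_formulations(
    covariates, components=("bg", "enr"), interactions: bool = True
) -> list[Formulation]:
    """Cartesian product of strong-heredity term sets over the selected
    components; unselected components stay intercept-only."""
    covs = list(covariates)
    if interactions and len(covs) > MAX_COVARIATES:
        raise ValueError(
            f"{len(covs)} covariates with interactions is combinatorially infeasible; "
            "use the bg/enr-only heuristic or drop covariates"
        )
    per_comp = hierarchical_term_sets(covs, interactions)
    pools = {
        comp: per_comp if comp in components else [()] for comp in ("zi", "bg", "enr")
    }
    return [
        Formulation(t0, t1, t2)
        for t0 in pools["zi"]
        for t1 in pools["bg"]
        for t2 in pools["enr"]
    ]


def n_parameters(fit: MixtureFit) -> int:
    """gamma + beta1 + beta2 coefficients, two dispersions, one free mixture
    proportion."""
    p = fit.params
    return len(p.gamma) + len(p.beta1) + len(p.beta2) + 2 + 1


def bic_score(fit: MixtureFit, n: int) -> float:
    """BIC = -2 * loglik + p * ln(n); lower is better."""
    return -2.0 * fit.loglik + n_parameters(fit) * np.log(n)


def select_best_model(
    y: np.ndarray,
    tracks: dict[str, np.ndarray],
    starting,
    window_chroms: np.ndarray | None = None,
    chroms=None,
    heuristic: bool = True,
    interactions: bool = True,
    full_search: bool = False,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[ScoredModel, pd.DataFrame]:
    """Fit every enumerated formulation on the restricted windows and return
    the BIC argmin plus a ranked table of all candidates.

    ``window_chroms`` assigns each window to a chromosome; the restriction
    set defaults to the single largest supplied chromosome (``chroms``
    overrides it).  Unless ``full_search`` is set, each candidate reuses the
    winning initialization fraction of an intercept-only pre-fit instead of
    re-running all five starting partitions.
    """
    y = np.asarray(y)
    starting = list(starting)
    if window_chroms is not None:
        window_chroms = np.asarray(window_chroms)
        if chroms is None:
            uniq, counts = np.unique(window_chroms, return_counts=True)
            chroms = [uniq[np.argmax(counts)]]
            logger.info("BIC restriction set defaulting to largest chromosome: %s", chroms[0])
        mask = np.isin(window_chroms, list(chroms))
        if not mask.any():
            raise ValueError(f"restriction set {chroms} matches no windows")
    else:
        mask = np.ones(len(y), dtype=bool)
    y_r = y[mask]
    tracks_r = {k: np.asarray(v)[mask] for k, v in tracks.items()}
    n = len(y_r)

    components = ("bg", "enr") if heuristic else ("zi", "bg", "enr")
    candidates = enumerate_formulations(starting, components, interactions)
    logger.info("evaluating %d candidate formulations on %d windows", len(candidates), n)

    if full_search:
        init_fracs = DEFAULT_INIT_FRACTIONS
    else:
        # short screening fit: only the winning init fraction is reused
        pre = fit_mixture(
            assemble_design(y_r, tracks_r, Formulation().as_dict()),
            tol=tol,
            max_iter=min(50, max_iter),
        )
        init_fracs = (pre.init_fraction,)
        logger.info("intercept-only pre-fit selected init fraction %.3f", pre.init_fraction)

    rows = []
    scored: list[ScoredModel] = []
    failures = []
    for form in candidates:
        try:
            fit = fit_mixture(
                assemble_design(y_r, tracks_r, form.as_dict()),
                tol=tol,
                max_iter=max_iter,
                init_fractions=init_fracs,
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            failures.append((form, str(exc)))
            continue
        b = bic_score(fit, n)
        scored.append(ScoredModel(form, b, fit))
        rows.append(
            {
                "zi": "+".join(form.terms0) or "1",
                "bg": "+".join(form.terms1) or "1",
                "enr": "+".join(form.terms2) or "1",
                "bic": b,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    if not scored:
        raise RuntimeError(f"all {len(candidates)} candidate fits failed: {failures[:3]}")

    best = min(scored, key=lambda s: s.bic)

    if heuristic and "map" in tracks_r:
        zi_form = Formulation(("map",), best.formulation.terms1, best.formulation.terms2)
        try:
            fit_zi = fit_mixture(
                assemble_design(y_r, tracks_r, zi_form.as_dict()),
                tol=tol,
                max_iter=max_iter,
                init_fractions=init_fracs,
            )
            b_zi = bic_score(fit_zi, n)
            rows.append(
                {
                    "zi": "map",
                    "bg": "+".join(zi_form.terms1) or "1",
                    "enr": "+".join(zi_form.terms2) or "1",
                    "bic": b_zi,
                    "loglik": fit_zi.loglik,
                    "converged": fit_zi.converged,
                }
            )
            if b_zi < best.bic:
                logger.info("mappability retained in the zero-inflated component")
                best = ScoredModel(zi_form, b_zi, fit_zi)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("zero-inflated mappability refit failed: %s", exc)

    ranked = pd.DataFrame(rows).sort_values("bic", ignore_index=True)
    return best, ranked
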