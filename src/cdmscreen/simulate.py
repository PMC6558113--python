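"""Synthetic study generator emulating the instrument-development design.

Generates every input the pipeline consumes: a Q-matrix over K = 10 binary
symptom criteria with 1–4 criteria per item, correlated latent symptom
profiles (thresholded equicorrelated Gaussian), item parameters drawn per
response-model family, dichotomous responses, two demographic grouping
factors, and optional contamination with low-discrimination, misfitting and
DIF items. Defaults mirror the development-study scale: N = 1181
respondents, an 89-item pool, a 591/590 calibration/validation split, and a
criteria-per-item distribution with mean 1.67.

Everything is deterministic given (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import ItemParameters, link_fn, inv_link_fn, LINKS
from .taxonomy import CriterionTaxonomy, QMatrix, default_taxonomy

__all__ = [
    "SimulationDesign",
    "SimulatedStudy",
    "sample_qmatrix",
    "sample_profiles",
    "sample_item_parameters",
    "sample_responses",
    "simulate_study",
    "simulate_responses_from_items",
]


class DesignError(ValueError):
    """Infeasible simulation design."""


@dataclass
class SimulationDesign:
    """Knobs of the synthetic study.

    Defaults are the study conditions: pool scale, criteria-per-item
    distribution with mean 1.67, a response-model mixture matching the
    relative frequencies the calibrated instrument reports, symptom
    prevalence 0.4 (the recruited sample was ~41% depressive patients) with
    equicorrelation 0.5, and guessing/slip in [0.05, 0.2] so clean items
    discriminate in the 0.6–0.9 range.
    """

    n_respondents: int = 1181
    n_items: int = 89
    n_criteria: int = 10
    criteria_per_item_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.36, 3: 0.11, 4: 0.03}
    )
    model_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "ACDM": 0.45,
            "GDINA": 0.35,
            "RRUM": 0.10,
            "DINA": 0.04,
            "DINO": 0.03,
            "LLM": 0.03,
        }
    )
    prevalence: float = 0.4
    latent_correlation: float = 0.5
    guessing_range: tuple[float, float] = (0.05, 0.2)
    slip_range: tuple[float, float] = (0.05, 0.2)
    low_disc_range: tuple[float, float] = (0.15, 0.35)
    dif_shift: float = 0.25
    n_low_disc: int = 0
    n_dif: int = 0
    n_misfit: int = 0
    split_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_respondents, self.n_items, self.n_criteria) < 1:
            raise DesignError("N, J and K must be positive")
        if not 0 <= self.latent_correlation < 1:
            raise DesignError("latent correlation must be in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise DesignError("prevalence must be in (0, 1)")
        g_hi, s_hi = self.guessing_range[1], self.slip_range[1]
        if g_hi + s_hi >= 1:
            raise DesignError("guessing + slip ranges must leave headroom")
        n_bad = self.n_low_disc + self.n_dif + self.n_misfit
        if n_bad > self.n_items:
            raise DesignError("more contaminated items than items")


@dataclass
class SimulatedStudy:
    """Outputs of one simulated study, with generating truth for scoring."""

    design: SimulationDesign
    q: QMatrix
    taxonomy: CriterionTaxonomy
    responses: pd.DataFrame  # N x J, values 0/1
    groups: pd.DataFrame  # N x 2 factors, values 0/1
    profiles: np.ndarray  # N x K true latent profiles
    items: list[ItemParameters]  # generating parameters (declared Q rows)
    contamination: dict[str, list[str]]  # low_disc / dif / misfit item ids

    @property
    def bad_items(self) -> list[str]:
        return sorted(set(sum(self.contamination.values(), [])))


def sample_qmatrix(
    design: SimulationDesign, rng: np.random.Generator
) -> QMatrix:
    """Draw a Q-matrix with the design's criteria-per-item distribution.

    Rows are resampled until every criterion is measured at least once;
    structurally infeasible designs raise a design error.
    """
    counts = np.array(
        [c for c in sorted(design.criteria_per_item_probs) if c <= design.n_criteria]
    )
    if counts.size == 0:
        raise DesignError("criteria-per-item distribution has no feasible support")
    probs = np.array([design.criteria_per_item_probs[c] for c in counts], float)
    probs /= probs.sum()
    if counts.max() * design.n_items < design.n_criteria:
        raise DesignError("too few items to cover every criterion")
    J, K = design.n_items, design.n_criteria
    for _ in range(1000):
        entries = np.zeros((J, K), dtype=int)
        row_counts = rng.choice(counts, size=J, p=probs)
        for j in range(J):
            entries[j, rng.choice(K, size=row_counts[j], replace=False)] = 1
        if (entries.sum(axis=0) > 0).all():
            item_ids = tuple(f"item{j+1:02d}" for j in range(J))
            crit = tuple(f"C{k+1}" for k in range(K))
            return QMatrix(entries, item_ids, crit)
    raise DesignError("could not cover every criterion; design likely infeasible")


def sample_profiles(
    design: SimulationDesign, rng: np.random.Generator
) -> np.ndarray:
    """Latent profiles from a thresholded equicorrelated Gaussian.

    alpha_ik = 1 iff Z_ik > Phi^{-1}(1 - prevalence), with
    corr(Z_k, Z_k') = rho via a single shared factor.
    """
    rho = design.latent_correlation
    n, K = design.n_respondents, design.n_criteria
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, K))
    Z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * unique
    return (Z > norm.ppf(1 - design.prevalence)).astype(np.int8)


def _interior_probs(
    tag: str, k_star: int, p_null: float, p_full: float, rng: np.random.Generator
) -> np.ndarray:
    """Sub-profile probability vector with the given null/full anchors."""
    n_cells = 2**k_star
    alpha = ((np.arange(n_cells)[:, None] >> np.arange(k_star)) & 1).astype(float)
    if tag == "DINA":
        p = np.full(n_cells, p_null)
        p[-1] = p_full
        return p
    if tag == "DINO":
        p = np.full(n_cells, p_full)
        p[0] = p_null
        return p
    w = rng.dirichlet(np.full(k_star, 2.0))
    frac = alpha @ w
    link = LINKS[tag] if tag != "GDINA" else "identity"
    lo, hi = link_fn(link, np.array([p_null, p_full]))
    p = inv_link_fn(link, lo + (hi - lo) * frac)
    if tag == "GDINA" and k_star > 1:
        jitter = rng.uniform(-0.05, 0.05, n_cells) * (p_full - p_null)
        p = np.clip(p + jitter, min(p_null, p_full), max(p_null, p_full))
        p[0], p[-1] = p_null, p_full
    return np.clip(p, 1e-4, 1 - 1e-4)


def sample_item_parameters(
    design: SimulationDesign,
    q: QMatrix,
    rng: np.random.Generator,
    low_disc_items: list[str] | None = None,
) -> list[ItemParameters]:
    """Generating parameters per item.

    Clean items: P(null) ~ U(guessing range), P(full) = 1 - slip. Items in
    `low_disc_items` instead get a discrimination drawn from
    ``low_disc_range`` (below the 0.4 deletion threshold).
    """
    low = set(low_disc_items or [])
    tags = list(design.model_mixture)
    tag_p = np.array([design.model_mixture[t] for t in tags], float)
    tag_p /= tag_p.sum()
    items = []
    for j, item_id in enumerate(q.item_ids):
        k_star = int(q.entries[j].sum())
        tag = str(rng.choice(tags, p=tag_p)) if k_star > 1 else "GDINA"
        if item_id in low:
            disc = rng.uniform(*design.low_disc_range)
            p_null = rng.uniform(0.2, min(0.6, 1 - disc - 0.05))
            p_full = p_null + disc
        else:
            p_null = rng.uniform(*design.guessing_range)
            p_full = 1.0 - rng.uniform(*design.slip_range)
        p = _interior_probs(tag, k_star, p_null, p_full, rng)
        items.append(ItemParameters.from_probs(item_id, tag, k_star, p))
    return items


def _item_prob_matrix(
    items: list[ItemParameters], q: QMatrix, profiles: np.ndarray
) -> np.ndarray:
    """(N, J) endorsement probability of each respondent on each item."""
    P = np.empty((profiles.shape[0], q.n_items))
    for j, params in enumerate(items):
        req = q.required(j)
        idx = profiles[:, req].astype(np.int64) @ (1 << np.arange(req.size))
        P[:, j] = params.probs()[idx]
    return P


def sample_responses(
    profiles: np.ndarray,
    items: list[ItemParameters],
    q: QMatrix,
    design: SimulationDesign,
    rng: np.random.Generator,
    dif_items: list[str] | None = None,
    misfit_rows: dict[str, np.ndarray] | None = None,
    focal: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bernoulli responses given profiles and item parameters.

    DIF items have every sub-profile probability shifted by ``dif_shift``
    (clipped) for the focal group; misfit items are generated from a
    substitute Q-row (``misfit_rows``) outside the fitted model family.
    """
    P = _item_prob_matrix(items, q, profiles)
    item_index = {i: j for j, i in enumerate(q.item_ids)}
    if dif_items:
        if focal is None:
            raise DesignError("DIF items require a focal-group indicator")
        for item_id in dif_items:
            j = item_index[item_id]
            P[focal.astype(bool), j] = np.clip(
                P[focal.astype(bool), j] + design.dif_shift, 0.02, 0.98
            )
    if misfit_rows:
        for item_id, row in misfit_rows.items():
            j = item_index[item_id]
            req = np.flatnonzero(row)
            # conjunctive dependence on criteria absent from the declared row
            hold_all = profiles[:, req].all(axis=1)
            P[:, j] = np.where(hold_all, 0.9, 0.1)
    X = (rng.random(P.shape) < P).astype(np.int8)
    return pd.DataFrame(X, columns=list(q.item_ids))


def simulate_responses_from_items(
    items: list[ItemParameters],
    q: QMatrix,
    profiles: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Plain response matrix from given parameters (no contamination)."""
    P = _item_prob_matrix(items, q, profiles)
    return (rng.random(P.shape) < P).astype(np.int8)


def simulate_study(design: SimulationDesign | None = None) -> SimulatedStudy:
    """End-to-end generation of one synthetic study from a single seed."""
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)
    q = sample_qmatrix(design, rng)
    taxonomy = default_taxonomy()
    if design.n_criteria != 10:
        crit = tuple(f"C{k+1}" for k in range(design.n_criteria))
        n_typ = min(3, max(1, design.n_criteria - 1))
        taxonomy = CriterionTaxonomy(crit, crit[:n_typ], crit[n_typ:])
    profiles = sample_profiles(design, rng)

    ids = list(q.item_ids)
    n_bad = design.n_low_disc + design.n_dif + design.n_misfit
    bad = rng.choice(ids, size=n_bad, replace=False) if n_bad else np.array([])
    low_disc = list(bad[: design.n_low_disc])
    dif = list(bad[design.n_low_disc : design.n_low_disc + design.n_dif])
    misfit = list(bad[design.n_low_disc + design.n_dif :])

    items = sample_item_parameters(design, q, rng, low_disc_items=low_disc)
    misfit_rows = {}
    for item_id in misfit:
        j = ids.index(item_id)
        declared = set(np.flatnonzero(q.entries[j]).tolist())
        others = [k for k in range(design.n_criteria) if k not in declared]
        pick = rng.choice(others, size=min(2, len(others)), replace=False)
        row = np.zeros(design.n_criteria, dtype=int)
        row[pick] = 1
        misfit_rows[item_id] = row

    groups = pd.DataFrame(
        {
            "group1": rng.integers(0, 2, design.n_respondents),
            "group2": rng.integers(0, 2, design.n_respondents),
        }
    )
    responses = sample_responses(
        profiles,
        items,
        q,
        design,
        rng,
        dif_items=dif,
        misfit_rows=misfit_rows,
        focal=groups["group1"].to_numpy(),
    )
    return SimulatedStudy(
        design=design,
        q=q,
        taxonomy=taxonomy,
        responses=responses,
        groups=groups,
        profiles=profiles,
        items=items,
        contamination={"low_disc": low_disc, "dif": dif, "misfit": misfit},
    )
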