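"""Item-level Wald comparison of reduced models against the saturated G-DINA.

For every item measuring two or more criteria, each candidate reduced model
(DINA, DINO, A-CDM, LLM, RRUM) imposes linear restrictions on the saturated
parameter vector — on the identity link for DINA/DINO/A-CDM, on the logit or
log link for LLM/RRUM (delta method). A non-significant Wald statistic means
the reduced model can replace the saturated one without measurable loss of
fit; among non-rejected candidates the one with the largest p-value is
selected, falling back to the saturated G-DINA when all are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.stats import chi2

from .config import PipelineConfig
from .estimation import FitResult
from .models import (
    LINKS,
    ModelConfigError,
    design_matrix,
    link_fn,
    n_free_parameters,
)

__all__ = [
    "ModelSelectionRecord",
    "wald_statistic",
    "build_restrictions",
    "select_item_model",
    "select_models",
]

#: Fixed precedence for p-value ties (fewest parameters first is applied
#: before this order).
CANDIDATE_ORDER = ("DINA", "DINO", "ACDM", "LLM", "RRUM")


@dataclass
class ModelSelectionRecord:
    item_id: str
    tests: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    selected_tag: str = "GDINA"
    selection_reason: str = ""


def wald_statistic(
    saturated_coeffs: np.ndarray,
    covariance: np.ndarray,
    restriction_matrix: np.ndarray,
) -> tuple[float, int, float]:
    """W = (R phi)' (R Sigma R')^{-1} (R phi), chi-square with df = rank(R)."""
    phi = np.asarray(saturated_coeffs, dtype=float)
    R = np.atleast_2d(np.asarray(restriction_matrix, dtype=float))
    Sigma = np.asarray(covariance, dtype=float)
    r = R @ phi
    mid = R @ Sigma @ R.T
    df = int(np.linalg.matrix_rank(R))
    try:
        sol = np.linalg.solve(mid, r)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular restricted covariance; using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        sol = np.linalg.pinv(mid) @ r
    W = float(r @ sol)
    return W, df, float(chi2.sf(W, df))


def build_restrictions(model_tag: str, k_star: int) -> np.ndarray:
    """Restriction matrix over saturated link-scale coefficients.

    Rows span the orthogonal complement of the reduced model's design space:
    a saturated coefficient vector phi (on the candidate's link scale)
    satisfies the reduced model iff R phi = 0. Row count equals
    2^K* - (free parameters of the candidate).
    """
    if k_star < 2:
        raise ModelConfigError("restrictions require an item with K* >= 2")
    A = design_matrix(model_tag, k_star)
    if model_tag == "GDINA":
        raise ModelConfigError("the saturated model imposes no restrictions")
    M = design_matrix("GDINA", k_star)
    B = null_space(A.T)  # orthonormal basis, (2^K*, df)
    return B.T @ M


def _saturated_on_link(
    fit: FitResult, item_id: str, link: str
) -> tuple[np.ndarray, np.ndarray]:
    """Saturated cell vector and covariance transported to a link scale.

    The saturated item is parameterized by identity-link coefficients phi;
    cell probabilities are p = M phi. For logit/log candidates the Wald test
    acts on zeta = h(p) with covariance via the delta method.
    """
    j = list(fit.q.item_ids).index(item_id)
    params = fit.items[j]
    if params.model_tag != "GDINA":
        raise ModelConfigError(
            f"item {item_id} must be fitted saturated for model selection"
        )
    M = design_matrix("GDINA", params.k_star)
    cov_phi = fit.item_covariances[item_id]
    p = params.probs()
    cov_p = M @ cov_phi @ M.T
    if link == "identity":
        return p, cov_p
    zeta = link_fn(link, p)
    p_c = np.clip(p, 1e-6, 1 - 1e-6)
    d = 1.0 / (p_c * (1.0 - p_c)) if link == "logit" else 1.0 / p_c
    return zeta, (d[:, None] * cov_p) * d[None, :]


def select_item_model(
    fit: FitResult,
    item_id: str,
    candidates: tuple[str, ...] = CANDIDATE_ORDER,
    alpha: float = 0.05,
) -> ModelSelectionRecord:
    """Wald-test each reduced candidate against the saturated fit of one item.

    Single-criterion items are returned untested (all candidate models are
    equivalent when K* = 1).
    """
    j = list(fit.q.item_ids).index(item_id)
    params = fit.items[j]
    rec = ModelSelectionRecord(item_id=item_id)
    if params.k_star < 2:
        rec.selected_tag = "GDINA"
        rec.selection_reason = "single-criterion item; all models equivalent"
        return rec
    for tag in candidates:
        zeta, cov_zeta = _saturated_on_link(fit, item_id, LINKS[tag])
        A = design_matrix(tag, params.k_star)
        B = null_space(A.T)
        W, df, p = wald_statistic(zeta, cov_zeta, B.T)
        rec.tests[tag] = (W, df, p)
    kept = {t: v for t, v in rec.tests.items() if v[2] > alpha}
    if not kept:
        rec.selected_tag = "GDINA"
        rec.selection_reason = "all reduced candidates rejected"
        return rec
    best_p = max(v[2] for v in kept.values())
    tied = [t for t, v in kept.items() if v[2] == best_p]
    tied.sort(
        key=lambda t: (
            n_free_parameters(t, params.k_star),
            CANDIDATE_ORDER.index(t),
        )
    )
    rec.selected_tag = tied[0]
    rec.selection_reason = f"largest non-rejected p-value ({best_p:.4f})"
    return rec


def select_models(
    fit: FitResult, config: PipelineConfig | None = None
) -> list[ModelSelectionRecord]:
    """Run the per-item Wald selection over a saturated fit."""
    cfg = config or PipelineConfig()
    return [
        select_item_model(fit, item_id, alpha=cfg.wald_alpha)
        for item_id in fit.q.item_ids
    ]
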