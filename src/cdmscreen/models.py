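"""Item response functions for the G-DINA model family.

Each item measuring K* criteria has 2^K* latent sub-profiles and an
endorsement probability for each. The saturated G-DINA model writes that
probability, on the identity link, as an intercept plus main effects of the
present criteria plus all their interactions:

    P(alpha) = phi_0 + sum_k phi_k alpha_k + sum_{k<k'} phi_kk' alpha_k alpha_k' + ...

Reduced models constrain this structure: DINA (conjunctive — probability
jumps only when every required criterion is present), DINO (disjunctive —
any one suffices), and three additive models without interactions, on the
identity (A-CDM), logit (LLM) and log (RRUM) link scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "MODEL_TAGS",
    "ItemParameters",
    "design_matrix",
    "endorsement_probability",
    "constrain_to_model",
    "n_free_parameters",
]

MODEL_TAGS = ("GDINA", "DINA", "DINO", "ACDM", "LLM", "RRUM")

#: Link scale each model's additive structure lives on.
LINKS = {
    "GDINA": "identity",
    "DINA": "identity",
    "DINO": "identity",
    "ACDM": "identity",
    "LLM": "logit",
    "RRUM": "log",
}

_PCLIP = 1e-6  # probability clip for link transforms


class ModelConfigError(ValueError):
    """Unknown model tag or malformed design request."""


class ParameterValidityError(ValueError):
    """Coefficients imply endorsement probabilities outside [0, 1]."""


def link_fn(link: str, p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    if link == "identity":
        return np.asarray(p, dtype=float)
    if link == "logit":
        return logit(p)
    if link == "log":
        return np.log(p)
    raise ModelConfigError(f"unknown link {link!r}")


def inv_link_fn(link: str, eta: np.ndarray) -> np.ndarray:
    if link == "identity":
        return np.asarray(eta, dtype=float)
    if link == "logit":
        return expit(eta)
    if link == "log":
        return np.exp(eta)
    raise ModelConfigError(f"unknown link {link!r}")


def coefficient_subsets(model_tag: str, k_star: int) -> list[tuple[int, ...]]:
    """Criterion subsets indexing a model's coefficients, in design-column order.

    GDINA: all subsets ordered by (size, lexicographic) — intercept, mains,
    then interactions. Additive models: intercept plus singletons. DINA/DINO:
    intercept plus the full set (the single effect coefficient).
    """
    if model_tag == "GDINA":
        subs: list[tuple[int, ...]] = []
        for size in range(k_star + 1):
            subs.extend(combinations(range(k_star), size))
        return subs
    if model_tag in ("ACDM", "LLM", "RRUM"):
        return [()] + [(k,) for k in range(k_star)]
    if model_tag in ("DINA", "DINO"):
        return [(), tuple(range(k_star))]
    raise ModelConfigError(f"unknown model tag {model_tag!r}")


def design_matrix(model_tag: str, k_star: int) -> np.ndarray:
    """Map coefficients to sub-profile linear predictors on the link scale.

    Rows follow the reduced-profile binary-counting order; the matrix has
    shape (2^K*, m) with m = 2^K* (GDINA), K*+1 (additive), or 2 (DINA/DINO).
    """
    if k_star < 1:
        raise ModelConfigError("k_star must be >= 1")
    if model_tag not in MODEL_TAGS:
        raise ModelConfigError(f"unknown model tag {model_tag!r}")
    n_rows = 2**k_star
    alpha = ((np.arange(n_rows)[:, None] >> np.arange(k_star)) & 1).astype(float)
    if model_tag == "GDINA":
        cols = [
            alpha[:, list(s)].prod(axis=1) if s else np.ones(n_rows)
            for s in coefficient_subsets("GDINA", k_star)
        ]
        return np.column_stack(cols)
    if model_tag in ("ACDM", "LLM", "RRUM"):
        return np.column_stack([np.ones(n_rows), alpha])
    if model_tag == "DINA":
        return np.column_stack([np.ones(n_rows), alpha.prod(axis=1)])
    # DINO: effect fires if any required criterion is present
    return np.column_stack([np.ones(n_rows), (alpha.sum(axis=1) > 0).astype(float)])


def n_free_parameters(model_tag: str, k_star: int) -> int:
    return design_matrix(model_tag, k_star).shape[1]


@dataclass
class ItemParameters:
    """Coefficients of one item's response function.

    Attributes
    ----------
    item_id
        Item label.
    model_tag
        One of :data:`MODEL_TAGS`.
    k_star
        Number of criteria the item measures.
    coefs
        Coefficient vector on the model's link scale, ordered as
        :func:`coefficient_subsets`.
    """

    item_id: str
    model_tag: str
    k_star: int
    coefs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.model_tag not in MODEL_TAGS:
            raise ModelConfigError(f"unknown model tag {self.model_tag!r}")
        self.coefs = np.asarray(self.coefs, dtype=float)
        expected = n_free_parameters(self.model_tag, self.k_star)
        if self.coefs.shape != (expected,):
            raise ParameterValidityError(
                f"{self.item_id}: {self.model_tag} with K*={self.k_star} needs "
                f"{expected} coefficients, got {self.coefs.shape}"
            )
        self.probs()  # validate range eagerly

    @property
    def link(self) -> str:
        return LINKS[self.model_tag]

    def probs(self) -> np.ndarray:
        """Endorsement probability for each of the 2^K* reduced sub-profiles."""
        eta = design_matrix(self.model_tag, self.k_star) @ self.coefs
        p = inv_link_fn(self.link, eta)
        if (p < -1e-9).any() or (p > 1 + 1e-9).any():
            raise ParameterValidityError(
                f"{self.item_id}: implied probabilities outside [0,1]: {p}"
            )
        return np.clip(p, 0.0, 1.0)

    @classmethod
    def from_probs(
        cls, item_id: str, model_tag: str, k_star: int, probs: np.ndarray
    ) -> "ItemParameters":
        """Build coefficients whose implied probabilities match `probs`.

        For GDINA the saturated design is square and the fit is exact; for
        reduced models this is the link-scale least-squares representation
        (exact when `probs` already satisfies the model's structure).
        """
        probs = np.asarray(probs, dtype=float)
        design = design_matrix(model_tag, k_star)
        eta = link_fn(LINKS[model_tag], probs)
        coefs, *_ = np.linalg.lstsq(design, eta, rcond=None)
        return cls(item_id, model_tag, k_star, coefs)

    def coefficient_map(self, criterion_labels: list[str] | None = None) -> dict:
        """Coefficients keyed by the criterion subset each one multiplies."""
        subs = coefficient_subsets(self.model_tag, self.k_star)
        labels = criterion_labels or [str(k + 1) for k in range(self.k_star)]
        return {
            ",".join(labels[k] for k in s): float(c)
            for s, c in zip(subs, self.coefs)
        }


def endorsement_probability(
    params: ItemParameters, sub_profile: np.ndarray
) -> float:
    """P(endorse | sub-profile) for one item.

    `sub_profile` is the binary vector of the item's required criteria only
    (length K*).
    """
    sub = np.asarray(sub_profile, dtype=int)
    if sub.shape != (params.k_star,):
        raise ValueError(
            f"sub-profile length {sub.shape} does not match K*={params.k_star}"
        )
    idx = int(sub @ (1 << np.arange(params.k_star)))
    return float(params.probs()[idx])


def default_reduced_params(
    item_id: str, model_tag: str, k_star: int, p_lo: float = 0.25, p_hi: float = 0.75
) -> ItemParameters:
    """A valid-by-construction parameter set for any tag (EM warm start)."""
    lo, hi = link_fn(LINKS[model_tag], np.array([p_lo, p_hi]))
    if model_tag in ("DINA", "DINO"):
        coefs = np.array([p_lo, p_hi - p_lo])
    elif model_tag == "GDINA":
        probs = p_lo + (p_hi - p_lo) * design_matrix("ACDM", k_star)[:, 1:].mean(1)
        return ItemParameters.from_probs(item_id, "GDINA", k_star, probs)
    else:
        coefs = np.concatenate([[lo], np.full(k_star, (hi - lo) / k_star)])
    return ItemParameters(item_id, model_tag, k_star, coefs)


def constrain_to_model(saturated: ItemParameters, target_tag: str) -> ItemParameters:
    """Project a saturated item onto a reduced model's design space.

    Least-squares projection of the probability vector on the target model's
    link scale. Used for initialisation; final reduced-model estimates come
    from EM, not from this projection.
    """
    if target_tag not in MODEL_TAGS:
        raise ModelConfigError(f"unknown model tag {target_tag!r}")
    p = saturated.probs()
    out = ItemParameters.from_probs(saturated.item_id, target_tag, saturated.k_star, p)
    out.probs()  # raises ParameterValidityError if projection leaves [0,1]
    return out
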