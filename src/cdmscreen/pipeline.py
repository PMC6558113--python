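"""Iterative item selection with a calibration/validation split.

The instrument-building procedure: split the sample in half; on the
calibration half, repeatedly (1) delete misfitting items (S-X² p below
threshold), (2) delete DIF items, (3) delete low-discrimination items,
refitting and re-running the Wald model selection after every batch of
deletions, until a full pass deletes nothing; then re-run the three screens
once on the validation half and drop any newly failing items. Deleting an
item may never strip a symptom criterion of all its items — that aborts
with a structural error naming the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .estimation import FitResult, em_fit
from .models import constrain_to_model
from .quality import ItemQualityRecord, quality_screen
from .selection import select_models
from .taxonomy import InvalidQMatrixError, QMatrix

__all__ = [
    "SelectionLog",
    "StructuralSelectionError",
    "split_sample",
    "run_selection",
    "validate_selection",
]


class StructuralSelectionError(RuntimeError):
    """Deletion would leave a criterion unmeasured, or the pool got too small."""


@dataclass
class SelectionLog:
    """Per-iteration record of the deletion procedure."""

    phase: str  # "calibration" or "validation"
    records: list[dict] = field(default_factory=list)
    final_item_set: list[str] = field(default_factory=list)
    final_model_tags: dict[str, str] = field(default_factory=dict)
    final_fit: FitResult | None = None
    quality: list[ItemQualityRecord] = field(default_factory=list)

    def deleted_items(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            out.extend(rec["items_deleted"])
        return out


def split_sample(
    responses: np.ndarray | pd.DataFrame, ratio: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split into calibration/validation indices.

    The calibration half receives ``ceil(N * ratio)`` respondents (so
    N = 1181 at ratio 0.5 splits 591/590), deterministically under `seed`.
    """
    n = len(responses)
    if n < 2:
        raise ValueError("need at least 2 respondents to split")
    n_cal = int(np.ceil(n * ratio))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])


def _subset_q(q: QMatrix, keep: list[str]) -> QMatrix:
    try:
        return q.subset(keep)
    except InvalidQMatrixError as err:
        raise StructuralSelectionError(str(err)) from err


def _fit_with_selection(
    X: np.ndarray,
    q: QMatrix,
    config: PipelineConfig,
    warm_sat: FitResult | None = None,
) -> tuple[FitResult, FitResult]:
    """Saturated fit -> Wald model selection -> refit under the chosen tags.

    Returns (working fit, saturated fit); the saturated fit warm-starts the
    next refit after a deletion (surviving items keep their parameters).
    """
    init_items = init_pi = None
    if warm_sat is not None:
        init_items = [warm_sat.item(i) for i in q.item_ids]
        init_pi = warm_sat.structural.pi
    sat = em_fit(X, q, "GDINA", config, init_items=init_items, init_pi=init_pi)
    tags = [rec.selected_tag for rec in select_models(sat, config)]
    if all(t == "GDINA" for t in tags):
        return sat, sat
    start = [
        p if t == "GDINA" else _safe_constrain(p, t)
        for p, t in zip(sat.items, tags)
    ]
    fit = em_fit(X, q, tags, config, init_items=start, init_pi=sat.structural.pi)
    return fit, sat


def _safe_constrain(params, tag: str):
    """Projection init for a reduced tag, with a neutral fallback."""
    from .models import ParameterValidityError, default_reduced_params

    try:
        return constrain_to_model(params, tag)
    except ParameterValidityError:
        return default_reduced_params(params.item_id, tag, params.k_star)


_STEPS = (
    ("itemfit", "misfit"),
    ("dif", "dif"),
    ("disc", "low_disc"),
)


def run_selection(
    responses: np.ndarray | pd.DataFrame,
    q: QMatrix,
    groups: pd.DataFrame | None,
    config: PipelineConfig | None = None,
) -> SelectionLog:
    """Run the three-step deletion loop on a calibration sample.

    Within each step every currently failing item is deleted in one batch,
    the model is refit (with model re-selection), and the next step runs on
    the reduced pool. The loop ends when a full pass deletes nothing.
    """
    cfg = config or PipelineConfig()
    resp_df = (
        responses
        if isinstance(responses, pd.DataFrame)
        else pd.DataFrame(np.asarray(responses, dtype=float), columns=q.item_ids)
    )
    X = _as_matrix(resp_df, q)
    log = SelectionLog(phase="calibration")
    item_ids = list(q.item_ids)
    fit, sat = _fit_with_selection(X, q, cfg)
    iteration = 0
    while True:
        iteration += 1
        deleted_this_pass = 0
        for step, flag in _STEPS:
            records = quality_screen(
                fit,
                groups if step == "dif" else None,
                cfg,
                screens=(step,),
            )
            if step == "itemfit":
                bad = [r.item_id for r in records if "misfit" in r.flags]
            elif step == "dif":
                bad = [r.item_id for r in records if "dif" in r.flags]
            else:
                bad = [r.item_id for r in records if "low_disc" in r.flags]
            log.records.append(
                {
                    "iteration": iteration,
                    "step": step,
                    "items_deleted": bad,
                    "items_remaining": len(item_ids) - len(bad),
                }
            )
            if not bad:
                continue
            deleted_this_pass += len(bad)
            item_ids = [i for i in item_ids if i not in bad]
            if len(item_ids) < cfg.min_items:
                raise StructuralSelectionError(
                    f"fewer than min_items={cfg.min_items} items remain"
                )
            q = _subset_q(q, item_ids)
            X = _as_matrix(resp_df, q)
            fit, sat = _fit_with_selection(X, q, cfg, warm_sat=sat)
        if deleted_this_pass == 0:
            break
    log.final_item_set = item_ids
    log.final_model_tags = dict(zip(item_ids, fit.model_tags))
    log.final_fit = fit
    log.quality = quality_screen(fit, groups, cfg)
    return log


def validate_selection(
    selected_items: list[str],
    responses: np.ndarray | pd.DataFrame,
    q: QMatrix,
    groups: pd.DataFrame | None,
    config: PipelineConfig | None = None,
) -> SelectionLog:
    """One validation pass of the three screens on held-out data.

    Items failing any screen on the validation sample are removed; the
    returned log carries the final instrument fit on the validation data.
    """
    cfg = config or PipelineConfig()
    if len(responses) == 0:
        raise ValueError("validation sample is empty")
    resp_df = (
        responses
        if isinstance(responses, pd.DataFrame)
        else pd.DataFrame(np.asarray(responses, dtype=float), columns=q.item_ids)
    )
    q_sel = _subset_q(q, list(selected_items))
    X = _as_matrix(resp_df, q_sel)
    log = SelectionLog(phase="validation")
    fit, sat = _fit_with_selection(X, q_sel, cfg)
    records = quality_screen(fit, groups, cfg)
    bad = [r.item_id for r in records if r.flags]
    log.records.append(
        {
            "iteration": 1,
            "step": "validation",
            "items_deleted": bad,
            "items_remaining": len(selected_items) - len(bad),
        }
    )
    item_ids = [i for i in selected_items if i not in bad]
    if bad:
        if len(item_ids) < cfg.min_items:
            raise StructuralSelectionError(
                f"fewer than min_items={cfg.min_items} items remain"
            )
        q_sel = _subset_q(q, item_ids)
        X = _as_matrix(resp_df, q_sel)
        fit, _ = _fit_with_selection(X, q_sel, cfg, warm_sat=sat)
        records = quality_screen(fit, groups, cfg)
    log.final_item_set = item_ids
    log.final_model_tags = dict(zip(item_ids, fit.model_tags))
    log.final_fit = fit
    log.quality = records
    return log


def _as_matrix(responses: np.ndarray | pd.DataFrame, q: QMatrix) -> np.ndarray:
    """Align a response table to the Q-matrix item order."""
    if isinstance(responses, pd.DataFrame):
        missing = [i for i in q.item_ids if i not in responses.columns]
        if missing:
            raise ValueError(f"response table lacks items: {missing}")
        return responses.loc[:, list(q.item_ids)].to_numpy(dtype=float)
    X = np.asarray(responses, dtype=float)
    if X.shape[1] < q.n_items:
        raise ValueError("response matrix has fewer columns than Q-matrix items")
    return X
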