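"""Readers and writers for the pipeline's plain-text artifacts.

All tabular formats are delimited text with headers; structured artifacts
are JSON with a schema-version field. Floats are serialized to 12
significant digits, so write-then-read round-trips are identity at that
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, StructuralParameters
from .models import ItemParameters, coefficient_subsets
from .taxonomy import CriterionTaxonomy, QMatrix

SCHEMA_VERSION = 1


class SchemaVersionError(ValueError):
    pass


def _check_version(payload: dict, what: str) -> None:
    v = payload.get("schema_version")
    if v != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{what}: schema version {v!r} not supported (expected {SCHEMA_VERSION})"
        )


# -- responses --------------------------------------------------------------


def read_responses(path: str | Path) -> pd.DataFrame:
    """Responses CSV: header = item ids, rows = respondents, cells 0/1/NA."""
    df = pd.read_csv(path, index_col=0)
    bad = df.stack().dropna()
    if not bad.isin((0, 1)).all():
        raise ValueError(f"{path}: responses must be 0/1/NA")
    return df.astype(float)


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, na_rep="NA")


# -- Q-matrix / taxonomy ----------------------------------------------------


def read_qmatrix(path: str | Path) -> QMatrix:
    """Q-matrix CSV: first column item id, remaining columns criteria."""
    df = pd.read_csv(path, index_col=0)
    return QMatrix(
        df.to_numpy(dtype=int),
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
    )


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    q.to_frame().to_csv(path, index_label="item")


def read_taxonomy(path: str | Path) -> CriterionTaxonomy:
    payload = json.loads(Path(path).read_text())
    return CriterionTaxonomy(
        criteria=tuple(payload["typical"] + payload["common"])
        if "criteria" not in payload
        else tuple(payload["criteria"]),
        typical=tuple(payload["typical"]),
        common=tuple(payload["common"]),
        domains=payload.get("domains", {}),
    )


def write_taxonomy(t: CriterionTaxonomy, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "criteria": list(t.criteria),
                "typical": list(t.typical),
                "common": list(t.common),
                "domains": t.domains,
            },
            indent=2,
        )
    )


# -- fitted instruments -----------------------------------------------------


def _round(x: float) -> float:
    return float(f"{x:.12g}")


def write_fit(fit: FitResult, path: str | Path) -> None:
    """FitResult bundle (item coefficients + structural weights) as JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "criteria": list(fit.q.criteria),
        "loglik": _round(fit.loglik),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "pi": [_round(x) for x in fit.structural.pi],
        "items": [
            {
                "item_id": p.item_id,
                "model_tag": p.model_tag,
                "k_star": p.k_star,
                "q_row": fit.q.entries[j].tolist(),
                "coefficients": {
                    key: _round(val)
                    for key, val in p.coefficient_map(
                        [fit.q.criteria[k] for k in fit.q.required(j)]
                    ).items()
                },
            }
            for j, p in enumerate(fit.items)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit(path: str | Path) -> tuple[QMatrix, list[ItemParameters], StructuralParameters]:
    """Read a fit bundle back into (QMatrix, items, structural)."""
    payload = json.loads(Path(path).read_text())
    _check_version(payload, str(path))
    criteria = tuple(payload["criteria"])
    entries, item_ids, items = [], [], []
    for rec in payload["items"]:
        entries.append(rec["q_row"])
        item_ids.append(rec["item_id"])
        subs = coefficient_subsets(rec["model_tag"], rec["k_star"])
        req = [k for k, v in enumerate(rec["q_row"]) if v]
        labels = [criteria[k] for k in req]
        coefs = np.array(
            [
                rec["coefficients"][",".join(labels[k] for k in s)]
                for s in subs
            ]
        )
        items.append(
            ItemParameters(rec["item_id"], rec["model_tag"], rec["k_star"], coefs)
        )
    q = QMatrix(np.array(entries, dtype=int), tuple(item_ids), criteria)
    pi = np.array(payload["pi"], dtype=float)
    return q, items, StructuralParameters(pi / pi.sum())


def write_posterior(fit: FitResult, path: str | Path) -> None:
    pd.DataFrame(fit.posterior).to_csv(path, index_label="respondent")


# -- selection log / reports ------------------------------------------------


def write_selection_log(log, path: str | Path) -> None:
    """JSON-lines deletion log, one record per step, plus a summary line."""
    lines = [json.dumps({"schema_version": SCHEMA_VERSION, "phase": log.phase})]
    lines += [json.dumps(rec) for rec in log.records]
    lines.append(json.dumps({"final_item_set": log.final_item_set}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports(reports: list, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "reports": [r.to_dict() for r in reports],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
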