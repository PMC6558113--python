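"""Attribute-level classification consistency and accuracy indices.

Both indices are computed from the marginal criterion posteriors
p_ik = P(alpha_k = 1 | X_i):

* consistency Pc_k — probability that two independent administrations
  classify a respondent identically on criterion k, estimated as the mean
  of p_ik^2 + (1 - p_ik)^2;
* accuracy Pa_k — probability that the classification matches the true
  latent status, the mean of alphahat_ik * p_ik + (1 - alphahat_ik)(1 - p_ik).

The accuracy estimator is exact under a correctly specified model (the
posterior is the true conditional of the latent status); the consistency
estimator is the standard posterior-based approximation, validated here by
simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "classification_consistency",
    "classification_accuracy",
    "reliability_frame",
    "point_biserial",
]


def classification_consistency(marginals: np.ndarray) -> np.ndarray:
    """Pc_k = mean_i [p_ik^2 + (1 - p_ik)^2], one value per criterion."""
    p = np.atleast_2d(np.asarray(marginals, dtype=float))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("marginal posteriors must lie in [0, 1]")
    return (p**2 + (1.0 - p) ** 2).mean(axis=0)


def classification_accuracy(
    marginals: np.ndarray, classifications: np.ndarray
) -> np.ndarray:
    """Pa_k = mean_i [ahat_ik p_ik + (1 - ahat_ik)(1 - p_ik)] per criterion."""
    p = np.atleast_2d(np.asarray(marginals, dtype=float))
    a = np.atleast_2d(np.asarray(classifications, dtype=float))
    if p.shape != a.shape:
        raise ValueError("marginals and classifications must align")
    return (a * p + (1.0 - a) * (1.0 - p)).mean(axis=0)


def reliability_frame(
    marginals: np.ndarray,
    classifications: np.ndarray,
    criteria: list[str],
) -> pd.DataFrame:
    """Report table: rows C1..CK, columns consistency/accuracy."""
    pc = classification_consistency(marginals)
    pa = classification_accuracy(marginals, classifications)
    return pd.DataFrame(
        {"consistency": pc, "accuracy": pa}, index=list(criteria)
    )


def point_biserial(score: np.ndarray, external: np.ndarray) -> float:
    """Generic Pearson correlation utility for external-criterion validity.

    Provided for convenience when an external instrument is available; the
    package ships no external data.
    """
    s = np.asarray(score, dtype=float)
    e = np.asarray(external, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(e))
    return float(np.corrcoef(s[ok], e[ok])[0, 1])
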