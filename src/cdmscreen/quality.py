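"""Per-item quality screens: discrimination, S-X² fit, and DIF Wald tests.

Three screens decide whether an item stays in the instrument:

* the discrimination index ``Disc`` — endorsement-probability gap between
  respondents holding all versus none of the item's required criteria;
* the S-X² statistic — an Orlando–Thissen-type comparison of observed and
  model-expected endorsement proportions across raw-score groups, with the
  expected proportions obtained by mixing, over latent profiles, the
  Poisson-binomial rest-score distribution of the remaining items;
* a two-group Wald test of differential item functioning (DIF), with all
  other items serving as DIF-free anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .config import PipelineConfig
from .estimation import FitResult, _log_pq, _update_item
from .models import ItemParameters, design_matrix, inv_link_fn, n_free_parameters
from .taxonomy import profile_reduction_map

__all__ = [
    "ItemQualityRecord",
    "discrimination_index",
    "sx2_item_fit",
    "dif_wald",
    "quality_screen",
]


@dataclass
class TestOutcome:
    statistic: float
    df: int
    p: float
    tested: bool = True
    note: str = ""


@dataclass
class ItemQualityRecord:
    item_id: str
    disc: float
    sx2: TestOutcome
    dif: dict[str, TestOutcome] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)


def discrimination_index(params: ItemParameters) -> float:
    """Disc = P(all required criteria present) - P(none present)."""
    p = params.probs()
    return float(p[-1] - p[0])


# ---------------------------------------------------------------------------
# S-X2 item fit


def _score_distributions(p_full: np.ndarray) -> np.ndarray:
    """Poisson-binomial total-score pmf per latent profile.

    Returns an array F of shape (2^K, J+1): F[w, s] is the probability that
    a respondent with profile w obtains raw score s over all J items.
    """
    n_items = p_full.shape[0]
    F = np.zeros((p_full.shape[1], n_items + 1))
    F[:, 0] = 1.0
    for j in range(n_items):
        pj = p_full[j][:, None]
        F[:, 1 : j + 2] = F[:, 1 : j + 2] * (1.0 - pj) + F[:, : j + 1] * pj
        F[:, 0] *= 1.0 - p_full[j]
    return F


def _rest_score_distribution(F: np.ndarray, pj: np.ndarray) -> np.ndarray:
    """Deconvolve item j out of the total-score pmf, per latent profile.

    Runs the forward recurrence where pj < 0.5 and the backward recurrence
    otherwise, which keeps the divisor away from zero; tiny negatives from
    cancellation are clipped.
    """
    n_prof, ns = F.shape
    S = ns - 2  # rest score support 0..J-1
    G = np.zeros((n_prof, S + 1))
    fwd = pj < 0.5
    if fwd.any():
        q = 1.0 - pj[fwd]
        G[fwd, 0] = F[fwd, 0] / q
        for s in range(1, S + 1):
            G[fwd, s] = (F[fwd, s] - pj[fwd] * G[fwd, s - 1]) / q
    bwd = ~fwd
    if bwd.any():
        G[bwd, S] = F[bwd, S + 1] / pj[bwd]
        for s in range(S - 1, -1, -1):
            G[bwd, s] = (F[bwd, s + 1] - (1.0 - pj[bwd]) * G[bwd, s + 1]) / pj[bwd]
    return np.clip(G, 0.0, 1.0)


def _collapse_groups(
    n_s: np.ndarray, obs1: np.ndarray, exp1: np.ndarray, min_cell: float
) -> list[tuple[float, float, float]]:
    """Merge adjacent raw-score groups until expected cell counts clear min_cell.

    Greedy left-to-right accumulation; a deficient final group is folded back
    into its predecessor. Returns (count, observed endorsements, expected
    endorsements) per surviving group.
    """
    groups: list[list[float]] = []
    acc = [0.0, 0.0, 0.0]
    for s in range(len(n_s)):
        acc[0] += n_s[s]
        acc[1] += obs1[s]
        acc[2] += exp1[s]
        if acc[0] > 0 and acc[2] >= min_cell and (acc[0] - acc[2]) >= min_cell:
            groups.append(acc)
            acc = [0.0, 0.0, 0.0]
    if acc[0] > 0 or acc[2] > 0:
        if groups:
            groups[-1] = [a + b for a, b in zip(groups[-1], acc)]
        else:
            groups.append(acc)
    return [tuple(g) for g in groups]


def sx2_item_fit(
    fit: FitResult,
    item_id: str,
    config: PipelineConfig | None = None,
) -> TestOutcome:
    """S-X² item fit statistic for one item.

    Respondents are grouped by raw sum score (complete cases only); the
    model-expected endorsement proportion in score group s is

        E_js = sum_w pi_w P_j(w) f_{-j,w}(s-1) / sum_w pi_w f_w(s),

    with f the Poisson-binomial score pmf given profile w. Adjacent groups
    collapse until expected counts reach ``sx2_min_cell``; df equals the
    surviving group count minus the item's free parameters, and df <= 0
    marks the item untestable rather than misfitting.
    """
    cfg = config or PipelineConfig()
    X = fit.responses
    if X is None:
        raise ValueError("fit carries no responses")
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    if Xc.shape[0] < 2:
        return TestOutcome(np.nan, 0, np.nan, tested=False, note="too few complete cases")
    j = list(fit.q.item_ids).index(item_id)
    p_full = fit.item_probs_full()
    pi = fit.structural.pi
    n_items = p_full.shape[0]

    F = _score_distributions(p_full)
    G = _rest_score_distribution(F, p_full[j])
    scores = Xc.sum(axis=1).astype(int)
    n_s = np.bincount(scores, minlength=n_items + 1).astype(float)
    obs1 = np.bincount(scores, weights=Xc[:, j], minlength=n_items + 1)

    den = F.T @ pi  # marginal score pmf
    num = G.T @ (pi * p_full[j])  # joint pmf of (rest score, endorse)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.zeros(n_items + 1)
        # score s pairs with rest score s-1 for an endorsed item
        E[1:] = np.where(den[1:] > 0, num[: n_items] / den[1:], 0.0)
    exp1 = n_s * E

    groups = _collapse_groups(n_s, obs1, exp1, cfg.sx2_min_cell)
    df = len(groups) - n_free_parameters(
        fit.items[j].model_tag, fit.items[j].k_star
    )
    if df <= 0:
        return TestOutcome(np.nan, df, np.nan, tested=False, note="df <= 0")
    stat = 0.0
    for n_g, o_g, e_g in groups:
        Eg = min(max(e_g / n_g, 1e-10), 1 - 1e-10)
        Og = o_g / n_g
        stat += n_g * (Og - Eg) ** 2 / (Eg * (1.0 - Eg))
    return TestOutcome(float(stat), df, float(chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# DIF Wald


def _two_level(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = pd.unique(pd.Series(labels).dropna())
    if len(levels) != 2:
        raise ValueError(f"grouping factor must have exactly 2 levels, got {levels}")
    lab = np.asarray(labels)
    return lab == levels[0], lab == levels[1]


def dif_wald(
    fit: FitResult,
    group_labels: np.ndarray,
    item_id: str,
    config: PipelineConfig | None = None,
    exclude_anchors: list[str] | None = None,
) -> TestOutcome:
    """Two-group Wald DIF test for one studied item.

    All other items are treated as DIF-free anchors with their parameters
    frozen at the pooled fit; the studied item's coefficients and the
    structural weights are re-estimated per group by EM. The statistic is

        W = (b_A - b_B)' (Sigma_A + Sigma_B)^{-1} (b_A - b_B).

    The p-value comes from a label-permutation reference distribution of W
    by default (``dif_permutations`` draws, early-stopped when clearly
    non-significant); with ``dif_permutations = 0`` the chi-square
    reference with df = the item's free coefficient count is used instead.
    ``exclude_anchors`` drops suspected-DIF items from the anchor set
    (purification).

    Two-step formulation: respondent profile weights are fixed at the
    pooled fit's leave-one-item-out posteriors (the studied item is
    excluded so its own responses cannot tilt the weights), and only the
    studied item's coefficients are re-estimated per group. Group ability
    differences are carried by each respondent's own posterior, so impact
    does not masquerade as DIF, while no per-group structural estimation
    is attempted — re-estimating 2^K class weights from a few hundred
    respondents measurably inflates the test's far-tail rejection rate.
    """
    cfg = config or PipelineConfig()
    X = fit.responses
    if X is None:
        raise ValueError("fit carries no responses")
    in_a, in_b = _two_level(group_labels)
    if in_a.sum() < cfg.min_group_size or in_b.sum() < cfg.min_group_size:
        warnings.warn(
            f"group smaller than {cfg.min_group_size}; DIF test for "
            f"{item_id} skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return TestOutcome(np.nan, 0, np.nan, tested=False, note="group too small")

    j = list(fit.q.item_ids).index(item_id)
    K = fit.n_criteria
    pmap = profile_reduction_map(fit.q.entries[j], K)
    n_cells = 2 ** fit.items[j].k_star
    onehot = np.equal(pmap[:, None], np.arange(n_cells)).astype(float)

    p_full = fit.item_probs_full()
    logP, logQ = _log_pq(p_full)
    obs = ~np.isnan(X)
    A1 = np.where(obs, X, 0.0)
    A0 = np.where(obs, 1.0 - X, 0.0)
    # anchor log-likelihood = total minus the studied item's contribution;
    # the total is cached on the fit so per-item DIF calls stay cheap
    total_ll = getattr(fit, "_total_ll_cache", None)
    if total_ll is None:
        total_ll = A1 @ logP + A0 @ logQ
        fit._total_ll_cache = total_ll
    base_ll = total_ll - (A1[:, [j]] * logP[j] + A0[:, [j]] * logQ[j])
    for other in exclude_anchors or ():
        k = list(fit.q.item_ids).index(other)
        if k == j:
            continue
        base_ll = base_ll - (A1[:, [k]] * logP[k] + A0[:, [k]] * logQ[k])

    # leave-one-item-out pooled posterior -> fixed profile weights
    ll = base_ll + np.log(np.clip(fit.structural.pi, 1e-300, None))
    m = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - m)
    T_all = (w / w.sum(axis=1, keepdims=True)) @ onehot

    x_all = X[:, j]
    obs_all = ~np.isnan(x_all)
    xv_all = np.where(obs_all, x_all, 0.0)
    a1_all = A1[:, j]
    a0_all = A0[:, j]
    base_params = fit.items[j]
    design = design_matrix(base_params.model_tag, base_params.k_star)

    def group_estimate(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        params = base_params
        T = T_all[mask]
        r = T.T @ a1_all[mask]
        n = r + T.T @ a0_all[mask]
        for _ in range(25):
            new = _update_item(params, r, n, monotone=cfg.monotone)
            if np.allclose(new.coefs, params.coefs, atol=1e-8):
                params = new
                break
            params = new
        eta = design @ params.coefs
        mu = np.clip(inv_link_fn(params.link, eta), 1e-4, 1.0 - 1e-4)
        if params.link == "identity":
            gprime = np.ones_like(mu)
        elif params.link == "logit":
            gprime = mu * (1.0 - mu)
        else:
            gprime = mu
        C = (
            (xv_all[mask, None] - mu[None, :])
            / (mu * (1.0 - mu))[None, :]
            * gprime[None, :]
        )
        C[~obs_all[mask]] = 0.0
        S = (T * C) @ design
        info = S.T @ S
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        return params.coefs.copy(), cov

    def wald_between(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
        ba, cov_a = group_estimate(mask_a)
        bb, cov_b = group_estimate(mask_b)
        d = ba - bb
        mid = cov_a + cov_b
        try:
            sol = np.linalg.solve(mid, d)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(mid) @ d
        return float(d @ sol)

    W = wald_between(in_a, in_b)
    df = n_free_parameters(base_params.model_tag, base_params.k_star)
    if cfg.dif_permutations <= 0:
        return TestOutcome(W, df, float(chi2.sf(W, df)))

    # permutation reference: group labels are exchangeable under the null,
    # so the permuted Wald statistics give an exact conditional reference
    # distribution (the chi-square reference neglects anchor-estimation
    # uncertainty and over-rejects in the far tail). Early stop once the
    # p-value is clearly above the screening threshold.
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.dif_permutation_seed, j])
    )
    labels_pool = np.where(in_a, 0, np.where(in_b, 1, -1))
    usable = labels_pool >= 0
    base_labels = labels_pool[usable]
    exceed = 0
    done = 0
    block = 50
    while done < cfg.dif_permutations:
        for _ in range(min(block, cfg.dif_permutations - done)):
            perm = rng.permutation(base_labels)
            pa = np.zeros_like(in_a)
            pb = np.zeros_like(in_b)
            pa[usable] = perm == 0
            pb[usable] = perm == 1
            if wald_between(pa, pb) >= W:
                exceed += 1
            done += 1
        if exceed >= 10:  # p-value is far above any screening alpha
            break
    p = (1.0 + exceed) / (1.0 + done)
    return TestOutcome(W, df, p, note=f"permutation ({done})")


def dif_screen(
    fit: FitResult,
    groups: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict[str, dict[str, TestOutcome]]:
    """DIF Wald tests for every item and factor, with anchor purification.

    Stage 1 tests each item with all other items as anchors. Items flagged
    at ``dif_alpha`` are then re-tested with every stage-1 flagged item
    removed from the anchor set, so one genuinely DIF item cannot induce
    spurious flags on clean items through a contaminated anchor scale.
    Purification can be disabled via ``dif_purify``.
    """
    cfg = config or PipelineConfig()
    out: dict[str, dict[str, TestOutcome]] = {i: {} for i in fit.q.item_ids}
    for col in groups.columns:
        labels = groups[col].to_numpy()
        stage1 = {
            item_id: dif_wald(fit, labels, item_id, cfg)
            for item_id in fit.q.item_ids
        }
        flagged = [
            i for i, t in stage1.items() if t.tested and t.p < cfg.dif_alpha
        ]
        final = dict(stage1)
        if cfg.dif_purify and 0 < len(flagged) < fit.q.n_items:
            for item_id in flagged:
                final[item_id] = dif_wald(
                    fit, labels, item_id, cfg,
                    exclude_anchors=[i for i in flagged if i != item_id],
                )
        for item_id, t in final.items():
            out[item_id][col] = t
    return out


def quality_screen(
    fit: FitResult,
    groups: pd.DataFrame | None,
    config: PipelineConfig | None = None,
    screens: tuple[str, ...] = ("disc", "itemfit", "dif"),
) -> list[ItemQualityRecord]:
    """Quality screens for every item, with threshold flags.

    ``groups`` holds one column per two-level demographic factor (or None to
    skip DIF). ``screens`` restricts which statistics are computed (the
    selection loop runs one screen per step). Flags: ``low_disc`` (Disc
    below ``disc_min``), ``misfit`` (S-X² p below ``itemfit_alpha``;
    untestable items are never flagged), ``dif`` (any factor's Wald p below
    ``dif_alpha``).
    """
    cfg = config or PipelineConfig()
    dif_results = (
        dif_screen(fit, groups, cfg)
        if groups is not None and "dif" in screens
        else None
    )
    records = []
    for item_id in fit.q.item_ids:
        disc = discrimination_index(fit.item(item_id))
        sx2 = (
            sx2_item_fit(fit, item_id, cfg)
            if "itemfit" in screens
            else TestOutcome(np.nan, 0, np.nan, tested=False, note="not run")
        )
        rec = ItemQualityRecord(item_id=item_id, disc=disc, sx2=sx2)
        if dif_results is not None:
            rec.dif = dif_results[item_id]
        if "disc" in screens and disc < cfg.disc_min:
            rec.flags.add("low_disc")
        if sx2.tested and sx2.p < cfg.itemfit_alpha:
            rec.flags.add("misfit")
        if any(t.tested and t.p < cfg.dif_alpha for t in rec.dif.values()):
            rec.flags.add("dif")
        records.append(rec)
    return records


def quality_frame(records: list[ItemQualityRecord]) -> pd.DataFrame:
    """Quality report in the instrument-table shape (one row per item)."""
    rows = []
    for r in records:
        row = {
            "item": r.item_id,
            "disc": r.disc,
            "sx2": r.sx2.statistic,
            "sx2_df": r.sx2.df,
            "sx2_p": r.sx2.p,
        }
        for i, (factor, t) in enumerate(r.dif.items(), start=1):
            row[f"dif{i}_factor"] = factor
            row[f"dif{i}_wald"] = t.statistic
            row[f"dif{i}_p"] = t.p
        row["flags"] = ",".join(sorted(r.flags))
        rows.append(row)
    return pd.DataFrame(rows)
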