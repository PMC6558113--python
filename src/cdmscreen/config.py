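"""Pipeline configuration with the screening thresholds used throughout."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    """Thresholds and numeric controls for calibration and item selection.

    Attributes
    ----------
    disc_min
        Minimum acceptable discrimination index; items below are deleted.
    itemfit_alpha
        S-X² significance level for deleting misfitting items.
    dif_alpha
        Deletion threshold for each differential-item-functioning Wald
        test, per grouping factor. The default matches `itemfit_alpha`:
        with two factors, repeated passes and a validation re-screen, a
        5%-per-factor rule would delete ~25-30% of clean items by multiple
        testing alone, far above the deletion profile instrument
        developers report.
    wald_alpha
        Significance level for the item-level model-comparison Wald test.
    em_tol, em_max_iter
        EM stopping rule: absolute log-likelihood change below `em_tol`, or
        `em_max_iter` iterations.
    split_ratio, split_seed
        Calibration/validation split fraction and its RNG seed.
    sx2_min_cell
        Minimum expected cell count before adjacent score groups collapse.
    classification_rule
        "EAP" (marginal posterior >= 0.5) or "MAP" (modal profile).
    suicidality_threshold
        Marginal posterior on the self-harm criterion above which a report
        raises a flag.
    min_group_size
        Smallest group size for which a DIF test is attempted.
    max_missing_fraction
        Respondents missing more than this fraction of items are dropped.
    min_items
        Item selection aborts if the pool shrinks below this.
    """

    disc_min: float = 0.4
    itemfit_alpha: float = 0.01
    dif_alpha: float = 0.01
    wald_alpha: float = 0.05
    em_tol: float = 1e-6
    em_max_iter: int = 2000
    split_ratio: float = 0.5
    split_seed: int = 0
    sx2_min_cell: float = 1.0
    classification_rule: str = "EAP"
    suicidality_threshold: float = 0.5
    min_group_size: int = 50
    max_missing_fraction: float = 0.2
    min_items: int = 10
    monotone: bool = False
    smoothing: float = 1e-6
    dif_purify: bool = True
    #: permutation draws for the DIF reference distribution (0 = chi-square)
    dif_permutations: int = 0
    dif_permutation_seed: int = 1729

    def __post_init__(self) -> None:
        for name in ("itemfit_alpha", "dif_alpha", "wald_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 <= self.disc_min <= 1:
            raise ValueError("disc_min must be in [0,1]")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")
        if self.classification_rule not in ("EAP", "MAP"):
            raise ValueError("classification_rule must be 'EAP' or 'MAP'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
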