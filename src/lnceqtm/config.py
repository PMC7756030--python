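"""Shared threshold and option containers for the lnc-eQTM pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Thresholds:
    """Cut-offs used across the pipeline stages.

    Attributes
    ----------
    fdr_alpha : float
        Benjamini–Hochberg q-value cut-off for differential methylation
        (records kept when ``q < fdr_alpha``, strict).
    delta_beta : float
        Minimum absolute difference in mean beta value between cohorts
        (records kept when ``|delta| > delta_beta``, strict).
    delta_pcc : float
        Minimum absolute difference of the two per-condition Pearson
        coefficients for an edge to enter a cancer-specific network
        (``|pcc_tumor - pcc_normal| > delta_pcc``, strict).
    survival_alpha : float
        Log-rank significance level for flagging a prognostic lncRNA model.
    min_pairs : int
        Minimum number of complete (both non-missing) observation pairs
        required to compute a Pearson coefficient.
    """

    fdr_alpha: float = 0.05
    delta_beta: float = 0.3
    delta_pcc: float = 0.3
    survival_alpha: float = 0.05
    min_pairs: int = 10

    def validate(self) -> None:
        for name in ("fdr_alpha", "delta_beta", "delta_pcc", "survival_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if self.min_pairs < 3:
            raise ValueError(f"min_pairs must be >= 3, got {self.min_pairs!r}")

    def as_dict(self) -> dict:
        return asdict(self)


#: valid edge sign-class conventions (see network.sign_class)
SIGN_MODES = ("tumor", "normal", "stronger")

#: valid two-sample t-test variants
TTEST_MODES = ("student", "welch")


@dataclass
class PipelineOptions:
    """Behavioural switches whose defaults follow the published procedure."""

    sign_mode: str = "tumor"
    ttest_mode: str = "student"
    risk_covariate: str = "methylation"  # or "expression"
    probe_flank: int = 0  # bp added to each gene span when mapping probes

    def validate(self) -> None:
        if self.sign_mode not in SIGN_MODES:
            raise ValueError(f"sign_mode must be one of {SIGN_MODES}")
        if self.ttest_mode not in TTEST_MODES:
            raise ValueError(f"ttest_mode must be one of {TTEST_MODES}")
        if self.risk_covariate not in ("methylation", "expression"):
            raise ValueError("risk_covariate must be 'methylation' or 'expression'")
        if self.probe_flank < 0:
            raise ValueError("probe_flank must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)
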