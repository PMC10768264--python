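"""The published diagnostic model and the printed cohort summary tables.

The study's original cohort (98 ground-glass nodules: 39 precursor
glandular lesions + minimally invasive adenocarcinoma, 59 invasive
adenocarcinoma) is not publicly deposited; what is printed are its summary
tables and the fitted logistic model.  Those printed values are inputs here:
the model coefficients drive the published predictive-probability equation,
and the per-group feature means/SDs parameterise the synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "PublishedModel",
    "PUBLISHED_MODEL",
    "published_probability",
    "GROUP_NEGATIVE",
    "GROUP_POSITIVE",
    "GROUP_SIZES",
    "TABLE1_SEX",
    "TABLE1_LOBE",
    "LOBE_LEVELS",
    "TABLE1_AGE",
    "TABLE2_STATS",
    "PUBLISHED_CUTOFFS",
]

#: Group labels: the positive class is invasive adenocarcinoma.
GROUP_NEGATIVE = "PGL_MIA"
GROUP_POSITIVE = "IAC"
GROUP_SIZES = {GROUP_NEGATIVE: 39, GROUP_POSITIVE: 59}

#: Sex counts per group (men, women).
TABLE1_SEX = {GROUP_NEGATIVE: (13, 26), GROUP_POSITIVE: (24, 35)}

LOBE_LEVELS = (
    "right_upper",
    "right_middle",
    "right_lower",
    "left_upper",
    "left_lower",
)
#: Nodule location counts per group, ordered as LOBE_LEVELS.
TABLE1_LOBE = {
    GROUP_NEGATIVE: (17, 4, 4, 8, 6),
    GROUP_POSITIVE: (25, 4, 8, 17, 5),
}

#: Age mean +/- SD per group (years).
TABLE1_AGE = {GROUP_NEGATIVE: (54.4, 12.1), GROUP_POSITIVE: (60.4, 9.4)}

#: Feature (mean, SD) per group: the quantitative comparison table.
TABLE2_STATS = {
    "MA_mm2": {GROUP_NEGATIVE: (97.029, 110.315), GROUP_POSITIVE: (224.752, 154.947)},
    "LD_mm": {GROUP_NEGATIVE: (11.818, 4.742), GROUP_POSITIVE: (19.488, 6.060)},
    "BiA_deg": {GROUP_NEGATIVE: (80.315, 6.763), GROUP_POSITIVE: (74.617, 12.477)},
    "LD_PD": {GROUP_NEGATIVE: (1.247, 0.161), GROUP_POSITIVE: (1.491, 0.568)},
    "BiA_SmA": {GROUP_NEGATIVE: (1.055, 0.042), GROUP_POSITIVE: (1.136, 0.080)},
}

#: Reported decision thresholds: classify as invasive when either holds.
PUBLISHED_CUTOFFS = {"BiA_SmA": 1.068, "LD_mm": 11.56}


@dataclass(frozen=True)
class PublishedModel:
    """The printed binary logistic model for P(invasive adenocarcinoma).

    logit P = intercept + beta_ratio * (BiA/SmA) + beta_ld * LD[mm].
    The coefficient exponentials reproduce the printed odds ratios
    (exp(0.27) = 1.310 per mm of LD).
    """

    intercept: float = -34.571
    beta_ratio: float = 28.443
    beta_ld: float = 0.27

    def logit(self, bia_sma, ld_mm):
        return self.intercept + self.beta_ratio * np.asarray(
            bia_sma, dtype=float
        ) + self.beta_ld * np.asarray(ld_mm, dtype=float)

    def predict_proba(self, bia_sma, ld_mm):
        """Predictive probability of the invasive class."""
        return expit(self.logit(bia_sma, ld_mm))

    @property
    def odds_ratios(self) -> dict:
        return {
            "BiA_SmA": float(np.exp(self.beta_ratio)),
            "LD_mm": float(np.exp(self.beta_ld)),
        }


PUBLISHED_MODEL = PublishedModel()


def published_probability(
    x1: float, x2: float, model: PublishedModel = PUBLISHED_MODEL
):
    """Predictive probability at BiA/SmA ratio ``x1`` and LD ``x2`` (mm).

    Strictly increasing in both arguments; the P = 0.5 level set is the line
    beta_ratio * x1 + beta_ld * x2 = -intercept.
    """
    x1a, x2a = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if np.any(x1a < 1.0):
        raise ValueError("BiA/SmA ratio must be >= 1")
    if np.any(x2a <= 0.0):
        raise ValueError("LD must be positive (mm)")
    p = model.predict_proba(x1a, x2a)
    return float(p) if p.ndim == 0 else p
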