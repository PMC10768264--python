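"""Assemble the full cohort analysis into one JSON-serialisable report.

Sections mirror a standard diagnostic-study write-up: demographic
contingency tests, per-descriptor group comparisons (mean +/- SD with
parametric and nonparametric p-values), the fitted logistic model with odds
ratios, per-descriptor and combined-score ROC analyses with Youden
cut-offs, and per-lesion predicted probabilities from the published
coefficient vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import compare_groups, pearson_chi_square
from .model import DEFAULT_FEATURES, NoduleDiagnosisModel, combined_score_roc
from .published import GROUP_POSITIVE, PUBLISHED_MODEL
from .roc import RocResult

__all__ = ["analyze_cohort", "roc_to_dict"]

CONTINUOUS_DEFAULT = ("MA_mm2", "LD_mm", "BiA_deg", "LD_PD", "BiA_SmA")
CATEGORICAL_DEFAULT = ("sex", "lobe")


def roc_to_dict(r: RocResult) -> dict:
    return {
        "auc": r.auc,
        "auc_se": r.auc_se,
        "auc_ci_95": list(r.auc_ci_95),
        "youden_cutoff": r.youden_cutoff,
        "youden_j": r.youden_j,
        "sens_at_cutoff": r.sens_at_cutoff,
        "spec_at_cutoff": r.spec_at_cutoff,
        "thresholds": r.thresholds.tolist(),
        "sensitivities": r.sensitivities.tolist(),
        "specificities": r.specificities.tolist(),
    }


def analyze_cohort(
    cohort: pd.DataFrame,
    features=DEFAULT_FEATURES,
    continuous=None,
    categorical=None,
    group_col: str = "group",
    positive: str = GROUP_POSITIVE,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict:
    """Run the full statistical pipeline on a cohort table."""
    if continuous is None:
        continuous = [c for c in CONTINUOUS_DEFAULT if c in cohort.columns]
    if categorical is None:
        categorical = [c for c in CATEGORICAL_DEFAULT if c in cohort.columns]
    levels = sorted(cohort[group_col].unique())
    if len(levels) != 2:
        raise ValueError("cohort must contain exactly two groups")
    groups = tuple(x for x in levels if x != positive) + (positive,)

    report: dict = {
        "n_per_group": {g: int((cohort[group_col] == g).sum()) for g in groups},
        "positive_class": positive,
    }

    cat_tests = {}
    for col in categorical:
        tab = pd.crosstab(cohort[group_col], cohort[col])
        try:
            res = pearson_chi_square(tab.to_numpy())
            cat_tests[col] = {
                "statistic": res.statistic,
                "df": res.df,
                "p": res.pvalue,
                "levels": list(map(str, tab.columns)),
            }
        except ValueError as exc:
            cat_tests[col] = {"error": str(exc)}
    report["categorical_tests"] = cat_tests

    report["group_comparisons"] = {
        f: compare_groups(cohort, f, group_col=group_col, groups=groups).as_record()
        for f in continuous
    }

    model = NoduleDiagnosisModel(
        cohort, features=features, group_col=group_col, positive=positive
    )
    fit = model.fit(ci_method=ci_method, n_boot=n_boot, seed=seed)
    report["logistic"] = {
        "terms": list(fit.params.index),
        "coef": fit.params.tolist(),
        "se": fit.bse.tolist(),
        "odds_ratio": fit.odds_ratios.tolist(),
        "or_ci_95": fit.or_conf_int.to_numpy().tolist(),
        "converged": fit.converged,
        "separation": fit.separation,
        "log_likelihood": fit.llf,
    }
    report["roc"] = {f: roc_to_dict(r) for f, r in fit.feature_rocs.items()}
    report["roc"]["combined_fitted"] = roc_to_dict(fit.combined_roc)
    report["roc"]["combined_published"] = roc_to_dict(
        combined_score_roc(
            cohort,
            model=PUBLISHED_MODEL,
            group_col=group_col,
            positive=positive,
            ci_method=ci_method,
            n_boot=n_boot,
            seed=seed,
        )
    )
    report["published_predictions"] = {
        "lesion_id": cohort.get(
            "lesion_id", pd.Series(np.arange(len(cohort)).astype(str))
        ).tolist(),
        "probability": PUBLISHED_MODEL.predict_proba(
            cohort["BiA_SmA"].to_numpy(float), cohort["LD_mm"].to_numpy(float)
        ).tolist(),
    }
    return report
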