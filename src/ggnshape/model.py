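"""Diagnostic logistic model for invasive-versus-preinvasive classification.

``NoduleDiagnosisModel`` follows the statsmodels idiom: the model object is
built from a cohort DataFrame (one lesion per row), ``fit()`` runs the
maximum-likelihood binary logistic regression of group on the shape
descriptors and returns a ``NoduleDiagnosisResults`` carrying coefficients,
odds ratios with Wald 95% CIs, per-feature ROC analyses, the combined-score
ROC (predicted probability as discriminator) and Youden cut-offs, plus a
``summary()`` table.

The published coefficient vector can be scored on any cohort through
``combined_score_roc(cohort, model=PUBLISHED_MODEL)`` without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .published import GROUP_POSITIVE, PUBLISHED_MODEL, PublishedModel
from .roc import RocResult, empirical_roc

__all__ = [
    "NoduleDiagnosisModel",
    "NoduleDiagnosisResults",
    "fit_logistic",
    "combined_score_roc",
]

DEFAULT_FEATURES = ("BiA_SmA", "LD_mm")


@dataclass
class NoduleDiagnosisResults:
    """Fitted diagnostic model: estimates, uncertainty and discrimination."""

    model: "NoduleDiagnosisModel"
    params: pd.Series
    bse: pd.Series
    odds_ratios: pd.Series
    or_conf_int: pd.DataFrame
    converged: bool
    separation: bool
    llf: float
    feature_rocs: dict[str, RocResult] = field(default_factory=dict)
    combined_roc: RocResult | None = None

    @property
    def youden_cutoffs(self) -> dict[str, dict]:
        out = {
            f: {
                "cutoff": r.youden_cutoff,
                "sens": r.sens_at_cutoff,
                "spec": r.spec_at_cutoff,
                "youden_j": r.youden_j,
            }
            for f, r in self.feature_rocs.items()
        }
        if self.combined_roc is not None:
            r = self.combined_roc
            out["combined"] = {
                "cutoff": r.youden_cutoff,
                "sens": r.sens_at_cutoff,
                "spec": r.spec_at_cutoff,
                "youden_j": r.youden_j,
            }
        return out

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted probability of the positive (invasive) class."""
        if data is None:
            data = self.model.data
        x = sm.add_constant(
            data[list(self.model.features)].to_numpy(float), has_constant="add"
        )
        return np.asarray(
            1.0 / (1.0 + np.exp(-(x @ self.params.to_numpy()))), dtype=float
        )

    def summary(self) -> str:
        lines = [
            "Nodule diagnosis logistic model",
            f"  positive class: {self.model.positive}"
            f"   n = {len(self.model.data)}   log-likelihood = {self.llf:.3f}",
            f"  converged: {self.converged}   separation flagged: {self.separation}",
            "",
            f"  {'term':>10} {'coef':>10} {'se':>9} {'OR':>12} {'OR 95% CI':>24}",
        ]
        for term in self.params.index:
            orr = self.odds_ratios[term]
            lo, hi = self.or_conf_int.loc[term]
            lines.append(
                f"  {term:>10} {self.params[term]:>10.4f} {self.bse[term]:>9.4f}"
                f" {orr:>12.4g} {f'[{lo:.4g}, {hi:.4g}]':>24}"
            )
        lines.append("")
        for name, r in {**self.feature_rocs, "combined": self.combined_roc}.items():
            if r is None:
                continue
            lines.append(
                f"  ROC {name:>10}: AUC = {r.auc:.4f} "
                f"(95% CI {r.auc_ci_95[0]:.4f}-{r.auc_ci_95[1]:.4f}), "
                f"cut-off {r.youden_cutoff:.4g} "
                f"(sens {r.sens_at_cutoff:.2%}, spec {r.spec_at_cutoff:.2%})"
            )
        return "\n".join(lines)


class NoduleDiagnosisModel:
    """Binary logistic model of pathology group on shape descriptors.

    Parameters
    ----------
    data : DataFrame with one row per lesion, a binary group column and the
        feature columns (no missing values in analysed rows).
    features : descriptor columns used as predictors
        (default BiA/SmA ratio and LD in mm).
    group_col, positive : the group label column and which level counts as
        the positive (invasive) class.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: Sequence[str] = DEFAULT_FEATURES,
        group_col: str = "group",
        positive: str = GROUP_POSITIVE,
    ):
        missing = [c for c in (*features, group_col) if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        data = data.dropna(subset=[*features, group_col]).reset_index(drop=True)
        levels = set(data[group_col].unique())
        if len(levels) != 2 or positive not in levels:
            raise ValueError(
                "group column must be binary and contain the positive level"
            )
        self.data = data
        self.features = tuple(features)
        self.group_col = group_col
        self.positive = positive
        self.endog = (data[group_col] == positive).to_numpy(int)
        if self.endog.sum() < 2 or (1 - self.endog).sum() < 2:
            raise ValueError("need at least 2 lesions per class")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "NoduleDiagnosisModel":
        return cls(data, **kwargs)

    def fit(
        self,
        ci_method: str = "delong",
        n_boot: int = 2000,
        seed: int | None = None,
        maxiter: int = 100,
        tol: float = 1e-8,
    ) -> NoduleDiagnosisResults:
        """Maximum-likelihood fit (Newton/IRLS, unregularised).

        Perfect separation does not silently pass: it is surfaced through
        the ``separation`` flag on the results.
        """
        exog = sm.add_constant(
            self.data[list(self.features)].to_numpy(float), has_constant="add"
        )
        names = ["const", *self.features]
        separation = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(self.endog, exog).fit(
                    disp=False, maxiter=maxiter, tol=tol
                )
            except Exception as exc:
                # Newton dies on separable data (diverging coefficients make
                # the Hessian singular); fall back to a gradient method so a
                # flagged result can still be reported.
                hit_separation = "separation" in str(exc).lower() or any(
                    issubclass(w.category, PerfectSeparationWarning) for w in caught
                )
                if not hit_separation:
                    raise
                separation = True
                res = sm.Logit(self.endog, exog).fit(
                    disp=False, maxiter=5 * maxiter, method="bfgs"
                )
            separation = separation or any(
                issubclass(w.category, PerfectSeparationWarning) for w in caught
            )
        if separation:
            warnings.warn(
                "perfect separation detected: coefficients diverge and Wald "
                "intervals are unreliable",
                stacklevel=2,
            )
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        ci = pd.DataFrame(
            np.exp(res.conf_int()), index=names, columns=["or_lo", "or_hi"]
        )
        results = NoduleDiagnosisResults(
            model=self,
            params=params,
            bse=bse,
            odds_ratios=np.exp(params),
            or_conf_int=ci,
            converged=bool(res.mle_retvals.get("converged", True)),
            separation=separation,
            llf=float(res.llf),
        )
        for f in self.features:
            results.feature_rocs[f] = empirical_roc(
                self.data[f].to_numpy(float),
                self.endog,
                ci_method=ci_method,
                n_boot=n_boot,
                seed=seed,
            )
        results.combined_roc = empirical_roc(
            results.predict(),
            self.endog,
            ci_method=ci_method,
            n_boot=n_boot,
            seed=seed,
        )
        return results


def fit_logistic(
    cohort: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    group_col: str = "group",
    positive: str = GROUP_POSITIVE,
    **fit_kwargs,
) -> NoduleDiagnosisResults:
    """Functional shorthand for ``NoduleDiagnosisModel(...).fit(...)``."""
    return NoduleDiagnosisModel(
        cohort, features=features, group_col=group_col, positive=positive
    ).fit(**fit_kwargs)


def combined_score_roc(
    cohort: pd.DataFrame,
    model: NoduleDiagnosisResults | PublishedModel = PUBLISHED_MODEL,
    group_col: str = "group",
    positive: str = GROUP_POSITIVE,
    ratio_col: str = "BiA_SmA",
    ld_col: str = "LD_mm",
    **roc_kwargs,
) -> RocResult:
    """ROC of a model's predicted probability used as the score.

    ``model`` is either a fitted ``NoduleDiagnosisResults`` or a
    ``PublishedModel`` with fixed printed coefficients.
    """
    labels = (cohort[group_col] == positive).to_numpy(int)
    if isinstance(model, PublishedModel):
        scores = model.predict_proba(
            cohort[ratio_col].to_numpy(float), cohort[ld_col].to_numpy(float)
        )
    else:
        scores = model.predict(cohort)
    return empirical_roc(scores, labels, **roc_kwargs)
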