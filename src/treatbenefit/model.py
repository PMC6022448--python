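"""The all-interactions treatment-benefit model.

A logistic regression of a binary trial outcome on treatment, all marker
dummies and every marker-by-treatment interaction.  Applied twice per
patient — once with the treatment indicator (and its interactions)
forced to 0 and once to 1 — it yields counterfactual risks whose
difference is the predicted individual treatment benefit.  Because the
full interaction model overfits small trials, coefficients may be
multiplicatively shrunk toward zero by a bootstrap-estimated calibration
slope, with the intercept re-estimated so the mean predicted risk equals
the observed event rate (calibration-in-the-large).

The API follows the Model/Results convention: build a
:class:`TreatmentBenefitModel` from a :class:`~treatbenefit.data.TrialDataset`
(or a raw DataFrame via :meth:`~TreatmentBenefitModel.from_dataframe`),
call :meth:`~TreatmentBenefitModel.fit`, and work with the returned
:class:`TreatmentBenefitResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from . import __version__ as _version
from .data import (
    MarkerSpec,
    TrialDataset,
    coefficient_names,
    design_matrix,
    profile_to_markers,
)
from .exceptions import DesignError, FitError, ShrinkageError

__all__ = [
    "TreatmentBenefitModel",
    "TreatmentBenefitResults",
    "BenefitPrediction",
    "fit_interaction_model",
    "estimate_shrinkage_factor",
    "apply_shrinkage",
]

# Coefficients beyond this magnitude on the log-odds scale are taken as
# evidence of separation rather than a genuine effect.
_SEPARATION_BOUND = 15.0
_MAXITER = 100
_TOL = 1e-8


@dataclass(frozen=True)
class BenefitPrediction:
    """Counterfactual risks and treatment benefit for one profile.

    ``multimarker_positive`` requires the net benefit to be strictly
    positive: a patient whose predicted benefit exactly equals the
    treatment threshold is classified negative, because treatment is
    only justified when its effect exceeds the threshold.
    """

    risk_untreated: float
    risk_treated: float
    benefit: float
    net_benefit: float
    multimarker_positive: bool


def _fit_logistic(y: np.ndarray, X: np.ndarray,
                  allow_separation: bool = False):
    """GLM-binomial fit with convergence and separation guards.

    Returns (params, bse).  Raises FitError on failure.  Bootstrap
    refits pass ``allow_separation=True``: a resample with an empty or
    pure marker cell still yields a usable linear predictor (the
    affected risks saturate at 0/1), so only genuine numerical failure
    counts against it.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=_MAXITER, tol=_TOL)
        except Exception as exc:  # numerical failure inside IRLS
            raise FitError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        raise FitError("logistic fit produced non-finite coefficients")
    if not res.converged and not allow_separation:
        raise FitError(f"logistic fit did not converge in "
                       f"{_MAXITER} iterations")
    if not allow_separation and np.any(np.abs(params) > _SEPARATION_BOUND):
        diverging = np.flatnonzero(np.abs(params) > _SEPARATION_BOUND)
        raise FitError("apparent separation: diverging coefficient(s) at "
                       f"position(s) {diverging.tolist()}")
    return params, np.asarray(res.bse)


class TreatmentBenefitModel:
    """Full marker-by-treatment interaction logistic model for a trial.

    Parameters
    ----------
    dataset : TrialDataset
        A validated, complete-case trial extract.
    threshold : float, default 0.0
        Treatment threshold delta on the risk-difference scale: the
        minimum benefit at which treatment is worthwhile.  Zero means
        any benefit justifies treatment.
    """

    def __init__(self, dataset: TrialDataset, threshold: float = 0.0):
        if not -1.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [-1, 1], got {threshold}")
        self.dataset = dataset
        self.threshold = float(threshold)
        self.coefficient_names = coefficient_names(dataset.marker_specs)
        self._X = design_matrix(dataset.markers, dataset.treatment,
                                dataset.marker_specs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, treatment_col: str,
                       outcome_col: str,
                       marker_specs: Sequence[MarkerSpec],
                       threshold: float = 0.0) -> "TreatmentBenefitModel":
        specs = tuple(marker_specs)
        markers = df[[s.name for s in specs]].astype(str)
        ds = TrialDataset(df[treatment_col].to_numpy(),
                          df[outcome_col].to_numpy(), markers, specs)
        return cls(ds, threshold=threshold)

    @property
    def n_model_params(self) -> int:
        """Non-intercept parameter count (treatment + dummies + interactions)."""
        return len(self.coefficient_names) - 1

    def _check_rank(self) -> None:
        X = self._X.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            constant = [c for c in self._X.columns[1:]
                        if self._X[c].nunique() == 1]
            detail = (f"; constant column(s): {constant}" if constant else "")
            raise DesignError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{X.shape[1]} columns){detail}")

    def fit(self, shrinkage: float | str | None = None, n_boot: int = 200,
            seed: int | None = None) -> "TreatmentBenefitResults":
        """Maximum-likelihood fit, optionally followed by shrinkage.

        Parameters
        ----------
        shrinkage : None, "bootstrap", or float
            ``None`` returns the plain ML fit.  ``"bootstrap"`` estimates
            the shrinkage factor as the average calibration slope over
            ``n_boot`` bootstrap refits and applies it.  A float in
            (0, 1] is applied directly.
        n_boot : int
            Bootstrap resamples for shrinkage estimation (only with
            ``shrinkage="bootstrap"``).
        seed : int, optional
            Seed for the bootstrap resampling stream.
        """
        self._check_rank()
        y = self.dataset.outcome.astype(float)
        params, bse = _fit_logistic(y, self._X.to_numpy())
        res = TreatmentBenefitResults(
            model=self,
            coefficient_names=list(self.coefficient_names),
            params=pd.Series(params, index=self.coefficient_names),
            bse=pd.Series(bse, index=self.coefficient_names),
            shrinkage_factor=1.0,
            is_shrunken=False,
            marker_specs=self.dataset.marker_specs,
            threshold=self.threshold,
            nobs=self.dataset.n)
        if shrinkage is None:
            return res
        if shrinkage == "bootstrap":
            factor = estimate_shrinkage_factor(self.dataset, n_boot=n_boot,
                                               seed=seed)
        else:
            factor = float(shrinkage)
        return apply_shrinkage(res, factor, self.dataset)


@dataclass
class TreatmentBenefitResults:
    """Fitted treatment-benefit model.

    Carries the coefficient estimates (possibly shrunken), the standard
    errors of the unshrunken maximum-likelihood fit, the shrinkage
    factor, and the marker coding metadata needed to rebuild the design
    from raw marker values — so a results object restored from JSON can
    predict without the original data.
    """

    coefficient_names: list[str]
    params: pd.Series
    bse: pd.Series
    shrinkage_factor: float
    is_shrunken: bool
    marker_specs: tuple[MarkerSpec, ...]
    threshold: float
    nobs: int | None = None
    model: TreatmentBenefitModel | None = None

    def __post_init__(self):
        if not (len(self.coefficient_names) == len(self.params)
                == len(self.bse)):
            raise ValueError("names, coefficients and standard errors must "
                             "have equal length")
        if not 0.0 < self.shrinkage_factor <= 1.0:
            raise ValueError(f"shrinkage_factor must be in (0, 1], got "
                             f"{self.shrinkage_factor}")

    # -- inference ---------------------------------------------------------

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratios with Wald confidence intervals, one row per
        non-intercept term.

        The interval is centred at the (possibly shrunken) coefficient
        and uses the unshrunken standard error, so it is log-symmetric
        about the reported estimate.
        """
        z = norm.ppf(0.5 + level / 2.0)
        rows = []
        for term in self.coefficient_names:
            if term == "intercept":
                continue
            beta = float(self.params[term])
            se = float(self.bse[term])
            rows.append({"term": term, "beta": beta,
                         "odds_ratio": float(np.exp(beta)),
                         "ci_low": float(np.exp(beta - z * se)),
                         "ci_high": float(np.exp(beta + z * se))})
        return pd.DataFrame(rows)

    # -- prediction --------------------------------------------------------

    def _counterfactual_risks(self, markers: pd.DataFrame
                              ) -> tuple[np.ndarray, np.ndarray]:
        beta = self.params.to_numpy()
        n = len(markers)
        X0 = design_matrix(markers, np.zeros(n), self.marker_specs)
        X1 = design_matrix(markers, np.ones(n), self.marker_specs)
        return (expit(X0.to_numpy() @ beta), expit(X1.to_numpy() @ beta))

    def predict_risks(self, profile: Mapping[str, object]
                      ) -> tuple[float, float]:
        """Counterfactual (risk_untreated, risk_treated) for one profile."""
        markers = profile_to_markers(profile, self.marker_specs)
        p0, p1 = self._counterfactual_risks(markers)
        return float(p0[0]), float(p1[0])

    def predict_benefit(self, profile: Mapping[str, object],
                        threshold: float | None = None) -> BenefitPrediction:
        """Predicted benefit and multimarker class for one profile."""
        thr = self.threshold if threshold is None else float(threshold)
        if not -1.0 <= thr <= 1.0:
            raise ValueError(f"threshold must be in [-1, 1], got {thr}")
        p0, p1 = self.predict_risks(profile)
        benefit = p0 - p1
        net = benefit - thr
        return BenefitPrediction(risk_untreated=p0, risk_treated=p1,
                                 benefit=benefit, net_benefit=net,
                                 multimarker_positive=net > 0)

    def predict_benefit_frame(self, markers: pd.DataFrame,
                              threshold: float | None = None
                              ) -> pd.DataFrame:
        """Vectorised benefit predictions, one row per patient.

        Columns: risk_untreated, risk_treated, benefit, net_benefit,
        multimarker_positive.  Row order matches the input.
        """
        thr = self.threshold if threshold is None else float(threshold)
        p0, p1 = self._counterfactual_risks(markers)
        benefit = p0 - p1
        net = benefit - thr
        return pd.DataFrame({
            "risk_untreated": p0, "risk_treated": p1, "benefit": benefit,
            "net_benefit": net, "multimarker_positive": net > 0})

    def linear_predictor(self, markers: pd.DataFrame,
                         treatment) -> np.ndarray:
        X = design_matrix(markers, treatment, self.marker_specs)
        return X.to_numpy() @ self.params.to_numpy()

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Human-readable coefficient and odds-ratio table."""
        lines = ["Treatment-benefit interaction logistic model",
                 "=" * 60]
        if self.nobs is not None:
            lines.append(f"n = {self.nobs}")
        lines.append(f"treatment threshold = {self.threshold:g}")
        if self.is_shrunken:
            lines.append(f"coefficients shrunken by factor "
                         f"{self.shrinkage_factor:.4f} "
                         f"(intercept re-estimated)")
        else:
            lines.append("coefficients: unshrunken maximum likelihood")
        lines.append("-" * 60)
        lines.append(f"{'term':<36}{'beta':>8}{'OR':>8}  95% CI")
        lines.append(f"{'intercept':<36}{self.params['intercept']:>8.3f}")
        for _, r in self.odds_ratios().iterrows():
            lines.append(
                f"{r['term']:<36}{r['beta']:>8.3f}{r['odds_ratio']:>8.3f}"
                f"  ({r['ci_low']:.2f}-{r['ci_high']:.2f})")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "treatbenefit-model",
            "tool_version": _version,
            "coefficient_names": list(self.coefficient_names),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "shrinkage_factor": float(self.shrinkage_factor),
            "is_shrunken": bool(self.is_shrunken),
            "threshold": float(self.threshold),
            "nobs": self.nobs,
            "markers": [s.to_dict() for s in self.marker_specs],
        }

    def save(self, path) -> None:
        from .jsonio import dump_json
        dump_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreatmentBenefitResults":
        names = list(d["coefficient_names"])
        return cls(
            coefficient_names=names,
            params=pd.Series({k: d["coefficients"][k] for k in names}),
            bse=pd.Series({k: d["standard_errors"][k] for k in names}),
            shrinkage_factor=d["shrinkage_factor"],
            is_shrunken=d["is_shrunken"],
            marker_specs=tuple(MarkerSpec.from_dict(m)
                               for m in d["markers"]),
            threshold=d["threshold"],
            nobs=d.get("nobs"))

    @classmethod
    def load(cls, path) -> "TreatmentBenefitResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Functional layer
# ---------------------------------------------------------------------------

def fit_interaction_model(ds: TrialDataset,
                          threshold: float = 0.0) -> TreatmentBenefitResults:
    """Unshrunken maximum-likelihood fit of the full interaction model."""
    return TreatmentBenefitModel(ds, threshold=threshold).fit()


def _fit_unchecked(ds: TrialDataset,
                   threshold: float = 0.0) -> TreatmentBenefitResults:
    """ML fit without rank/separation guards, for bootstrap resamples.

    A resample with an empty or pure marker cell still yields usable
    predictions (saturated risks classify deterministically), so the
    performance bootstrap keeps such refits rather than discarding
    them.
    """
    model = TreatmentBenefitModel(ds, threshold=threshold)
    params, bse = _fit_logistic(ds.outcome.astype(float),
                                model._X.to_numpy(), allow_separation=True)
    return TreatmentBenefitResults(
        model=model,
        coefficient_names=list(model.coefficient_names),
        params=pd.Series(params, index=model.coefficient_names),
        bse=pd.Series(bse, index=model.coefficient_names),
        shrinkage_factor=1.0,
        is_shrunken=False,
        marker_specs=ds.marker_specs,
        threshold=model.threshold,
        nobs=ds.n)


def estimate_shrinkage_factor(ds: TrialDataset, n_boot: int = 200,
                              seed: int | None = None) -> float:
    """Bootstrap estimate of the uniform shrinkage factor.

    For each of ``n_boot`` patient-level resamples with replacement, the
    full interaction model is refitted on the resample and its linear
    predictor evaluated on the *original* data; the calibration slope is
    the coefficient of a one-covariate logistic regression of the
    original outcomes on that linear predictor.  The shrinkage factor is
    the average slope over resamples that converged — below 1 in
    overfitted models because bootstrap-fitted predictions are too
    extreme for the original data.

    Raises :class:`ShrinkageError` if more than 20% of resamples fail.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be at least 1, got {n_boot}")
    model = TreatmentBenefitModel(ds)
    model._check_rank()
    X = model._X.to_numpy()
    y = ds.outcome.astype(float)
    n = ds.n
    rng = np.random.default_rng(seed)
    slopes = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            params_b, _ = _fit_logistic(y[idx], X[idx],
                                        allow_separation=True)
            lp = X @ params_b
            slope_params, _ = _fit_logistic(
                y, np.column_stack([np.ones(n), lp]))
        except FitError:
            failures += 1
            continue
        slopes.append(slope_params[1])
    if failures > 0.2 * n_boot:
        raise ShrinkageError(
            f"{failures}/{n_boot} bootstrap resamples failed to fit "
            f"({failures / n_boot:.0%}); the model is too unstable for "
            f"bootstrap shrinkage estimation")
    return float(np.mean(slopes))


def apply_shrinkage(results: TreatmentBenefitResults, factor: float,
                    ds: TrialDataset) -> TreatmentBenefitResults:
    """Shrink all non-intercept coefficients and recalibrate the intercept.

    Non-intercept coefficients are multiplied by ``factor``; the
    intercept is then re-estimated by a one-parameter logistic fit on
    ``ds`` with the shrunken non-intercept linear predictor as a fixed
    offset.  The score equation of that refit forces the mean predicted
    risk to equal the observed event rate (calibration-in-the-large).
    Standard errors are carried over from the unshrunken fit.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"shrinkage factor must be in (0, 1], got {factor}")
    if results.is_shrunken:
        raise ValueError("model is already shrunken")
    new_params = results.params.copy()
    non_int = [c for c in results.coefficient_names if c != "intercept"]
    new_params[non_int] = new_params[non_int] * factor
    X = design_matrix(ds.markers, ds.treatment, ds.marker_specs)
    offset = X[non_int].to_numpy() @ new_params[non_int].to_numpy()
    y = ds.outcome.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refit = sm.GLM(y, np.ones((ds.n, 1)),
                       family=sm.families.Binomial(),
                       offset=offset).fit(maxiter=_MAXITER, tol=_TOL)
    if not refit.converged:
        raise FitError("intercept recalibration did not converge")
    new_params["intercept"] = float(refit.params[0])
    return TreatmentBenefitResults(
        model=results.model,
        coefficient_names=list(results.coefficient_names),
        params=new_params,
        bse=results.bse.copy(),
        shrinkage_factor=float(factor),
        is_shrunken=True,
        marker_specs=results.marker_specs,
        threshold=results.threshold,
        nobs=results.nobs)
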