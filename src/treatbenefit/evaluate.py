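"""Treatment-selection performance of a fitted benefit model.

Quantifies how a model changes treatment decisions and outcomes on a
trial: the distribution and calibration of predicted benefit, the
multimarker positivity rate, the observed (arm-contrast) benefit within
the recommended subgroups, and the population impact of a model-based
treatment policy against a treat-none or treat-all default — each with
percentile bootstrap confidence intervals.  External validation applies
a frozen model to an independent trial.

Observed benefits are empirical event-rate differences between the
randomised arms within a subgroup, never model output, so calibration
compares the model against design-unbiased estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import TrialDataset
from .exceptions import (
    CIError,
    SchemaError,
    UndefinedEstimateError,
)
from .model import (
    TreatmentBenefitResults,
    _fit_unchecked,
    apply_shrinkage,
)

__all__ = [
    "Estimate",
    "PerformanceSummary",
    "CalibrationTable",
    "benefit_distribution",
    "multimarker_positivity_rate",
    "observed_subgroup_benefit",
    "population_impact",
    "calibration_table",
    "bootstrap_performance",
    "external_validate",
]

_HIST_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional percentile bootstrap CI."""

    value: float
    ci_low: float = math.nan
    ci_high: float = math.nan

    def to_dict(self) -> dict:
        return {"value": self.value, "ci_low": self.ci_low,
                "ci_high": self.ci_high}


@dataclass
class PerformanceSummary:
    """Step-6 style treatment-selection measures for one trial.

    Under a treat-none default the population impact is exactly
    positivity_rate x avg_benefit_positives and the baseline risk is the
    control-arm event rate; under treat-all it is
    negativity_rate x avg_benefit_no_treatment_negatives against the
    treated-arm rate.  residual_risk = baseline_risk - population_impact.
    """

    default_strategy: str
    positivity_rate: Estimate
    avg_benefit_positives: Estimate
    avg_benefit_no_treatment_negatives: Estimate
    population_impact: Estimate
    baseline_risk: float
    residual_risk: float
    n: int
    flags: list[str] = field(default_factory=list)

    @property
    def negativity_rate(self) -> float:
        return 1.0 - self.positivity_rate.value

    @classmethod
    def from_components(cls, default_strategy: str, positivity_rate: float,
                        avg_benefit_positives: float,
                        avg_benefit_no_treatment_negatives: float,
                        baseline_risk: float,
                        n: int = 0) -> "PerformanceSummary":
        """Assemble a summary from its components via the impact identities.

        Useful for reproducing published arithmetic: the population
        impact is computed as rate x subgroup benefit and the residual
        risk as baseline minus impact, exactly as the point-estimate
        path does.
        """
        if default_strategy == "treat_none":
            impact = positivity_rate * avg_benefit_positives
        elif default_strategy == "treat_all":
            impact = ((1.0 - positivity_rate)
                      * avg_benefit_no_treatment_negatives)
        else:
            raise ValueError(f"unknown default strategy "
                             f"{default_strategy!r}")
        return cls(
            default_strategy=default_strategy,
            positivity_rate=Estimate(positivity_rate),
            avg_benefit_positives=Estimate(avg_benefit_positives),
            avg_benefit_no_treatment_negatives=Estimate(
                avg_benefit_no_treatment_negatives),
            population_impact=Estimate(impact),
            baseline_risk=baseline_risk,
            residual_risk=baseline_risk - impact,
            n=n)

    def to_dict(self) -> dict:
        return {
            "default_strategy": self.default_strategy,
            "n": self.n,
            "positivity_rate": self.positivity_rate.to_dict(),
            "negativity_rate": self.negativity_rate,
            "avg_benefit_positives": self.avg_benefit_positives.to_dict(),
            "avg_benefit_no_treatment_negatives":
                self.avg_benefit_no_treatment_negatives.to_dict(),
            "population_impact": self.population_impact.to_dict(),
            "baseline_risk": self.baseline_risk,
            "residual_risk": self.residual_risk,
            "flags": list(self.flags),
        }

    def __str__(self) -> str:
        def fmt(e: Estimate) -> str:
            s = f"{e.value:.4f}" if not math.isnan(e.value) else "undefined"
            if not math.isnan(e.ci_low):
                s += f"  (95% CI {e.ci_low:.4f} to {e.ci_high:.4f})"
            return s

        lines = [
            "Treatment-selection performance",
            "=" * 60,
            f"n = {self.n}, default strategy = {self.default_strategy}",
            f"multimarker positivity rate        {fmt(self.positivity_rate)}",
            f"avg benefit of treatment, positives {fmt(self.avg_benefit_positives)}",
            f"avg benefit of no treatment, negatives "
            f"{fmt(self.avg_benefit_no_treatment_negatives)}",
            f"population impact                  {fmt(self.population_impact)}",
            f"baseline risk ({'control' if self.default_strategy == 'treat_none' else 'treated'} arm)      "
            f"{self.baseline_risk:.4f}",
            f"residual risk under model policy   {self.residual_risk:.4f}",
        ]
        lines += [f"flag: {f}" for f in self.flags]
        return "\n".join(lines)


@dataclass
class CalibrationTable:
    """Observed vs predicted benefit in evenly sized benefit groups.

    ``frame`` has one row per group, ordered by increasing mean
    predicted benefit, with columns group, size, mean_predicted_benefit,
    observed_benefit, n_control, n_treated.  observed_benefit is NaN
    (and flagged) for groups with an empty arm.
    """

    frame: pd.DataFrame
    n_groups: int
    warnings: list[str] = field(default_factory=list)

    def slope(self) -> float:
        """Least-squares slope of observed on predicted group benefits."""
        ok = self.frame["observed_benefit"].notna()
        if ok.sum() < 2:
            raise UndefinedEstimateError(
                "fewer than 2 groups with a defined observed benefit")
        x = self.frame.loc[ok, "mean_predicted_benefit"].to_numpy()
        y = self.frame.loc[ok, "observed_benefit"].to_numpy()
        return float(np.polyfit(x, y, 1)[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _check_markers_compatible(results: TreatmentBenefitResults,
                              ds: TrialDataset) -> None:
    ds_specs = {s.name: s for s in ds.marker_specs}
    problems = []
    for spec in results.marker_specs:
        other = ds_specs.get(spec.name)
        if other is None:
            problems.append(f"marker {spec.name!r} absent from dataset")
        elif set(other.levels) != set(spec.levels):
            problems.append(
                f"marker {spec.name!r}: model levels {spec.levels} vs "
                f"dataset levels {other.levels}")
    if problems:
        raise SchemaError("model/dataset marker mismatch: "
                          + "; ".join(problems))


def benefit_distribution(ds: TrialDataset, results: TreatmentBenefitResults,
                         threshold: float | None = None
                         ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-patient benefit predictions plus histogram bin counts.

    Returns ``(predictions, bin_edges, counts)``.  Bins are fixed-width
    (0.05) on a grid anchored at zero, clipped to the observed benefit
    range.
    """
    _check_markers_compatible(results, ds)
    preds = results.predict_benefit_frame(ds.markers, threshold=threshold)
    b = preds["benefit"].to_numpy()
    lo = math.floor(b.min() / _HIST_BIN_WIDTH) * _HIST_BIN_WIDTH
    hi = math.ceil(b.max() / _HIST_BIN_WIDTH) * _HIST_BIN_WIDTH
    if hi <= lo:
        hi = lo + _HIST_BIN_WIDTH
    lo, hi = max(lo, -1.0), min(max(hi, lo + _HIST_BIN_WIDTH), 1.0)
    n_bins = int(round((hi - lo) / _HIST_BIN_WIDTH))
    edges = lo + _HIST_BIN_WIDTH * np.arange(n_bins + 1)
    counts, _ = np.histogram(b, bins=edges)
    return preds, edges, counts


def multimarker_positivity_rate(predictions) -> float:
    """Fraction of patients classified as benefiting from treatment."""
    if isinstance(predictions, pd.DataFrame):
        flags = predictions["multimarker_positive"].to_numpy()
    else:
        flags = np.array([p.multimarker_positive for p in predictions])
    if flags.size == 0:
        raise ValueError("empty prediction list")
    return float(flags.mean())


def observed_subgroup_benefit(ds: TrialDataset, subgroup_mask,
                              direction: str = "benefit_of_treatment"
                              ) -> float:
    """Observed arm-contrast of event rates within a subgroup.

    ``benefit_of_treatment`` is control-arm rate minus treated-arm rate
    (positive when treatment reduces events); ``benefit_of_no_treatment``
    is the negative of that.
    """
    if direction not in ("benefit_of_treatment", "benefit_of_no_treatment"):
        raise ValueError(f"unknown direction {direction!r}")
    mask = np.asarray(subgroup_mask, bool)
    sub_t = ds.treatment[mask]
    sub_y = ds.outcome[mask]
    for arm, label in ((0, "control"), (1, "treated")):
        if not np.any(sub_t == arm):
            raise UndefinedEstimateError(
                f"subgroup contains no patients in the {label} arm")
    rate0 = float(sub_y[sub_t == 0].mean())
    rate1 = float(sub_y[sub_t == 1].mean())
    diff = rate0 - rate1
    return diff if direction == "benefit_of_treatment" else -diff


def _point_summary(ds: TrialDataset, positive: np.ndarray,
                   default_strategy: str) -> PerformanceSummary:
    """Point estimates of all performance measures by direct counting."""
    if default_strategy not in ("treat_none", "treat_all"):
        raise ValueError(f"unknown default strategy {default_strategy!r}")
    n = ds.n
    rate_pos = float(positive.mean())
    flags: list[str] = []

    def subgroup(mask, direction):
        if not mask.any():
            return math.nan
        return observed_subgroup_benefit(ds, mask, direction)

    ben_pos = subgroup(positive, "benefit_of_treatment")
    ben_neg = subgroup(~positive, "benefit_of_no_treatment")
    if math.isnan(ben_pos):
        flags.append("no multimarker-positive patients; their subgroup "
                     "benefit is undefined")
    if math.isnan(ben_neg):
        flags.append("no multimarker-negative patients; their subgroup "
                     "benefit is undefined")
    if default_strategy == "treat_none":
        baseline = ds.event_rate(arm=0)
        # no positives -> no recommendation changes -> zero impact
        impact = 0.0 if rate_pos == 0 else rate_pos * ben_pos
    else:
        baseline = ds.event_rate(arm=1)
        impact = 0.0 if rate_pos == 1 else (1.0 - rate_pos) * ben_neg
    return PerformanceSummary(
        default_strategy=default_strategy,
        positivity_rate=Estimate(rate_pos),
        avg_benefit_positives=Estimate(ben_pos),
        avg_benefit_no_treatment_negatives=Estimate(ben_neg),
        population_impact=Estimate(impact),
        baseline_risk=baseline,
        residual_risk=baseline - impact,
        n=n,
        flags=flags)


def population_impact(ds: TrialDataset, results: TreatmentBenefitResults,
                      threshold: float | None = None,
                      default_strategy: str = "treat_none"
                      ) -> PerformanceSummary:
    """Point estimates of positivity, subgroup benefits and impact.

    The impact identity holds exactly: under treat_none it is the
    positivity rate times the observed benefit of treatment in
    positives; under treat_all, the negativity rate times the observed
    benefit of no treatment in negatives.
    """
    _check_markers_compatible(results, ds)
    preds = results.predict_benefit_frame(ds.markers, threshold=threshold)
    positive = preds["multimarker_positive"].to_numpy()
    return _point_summary(ds, positive, default_strategy)


def calibration_table(ds: TrialDataset, results: TreatmentBenefitResults,
                      threshold: float | None = None,
                      n_groups: int = 10) -> CalibrationTable:
    """Observed vs predicted benefit in evenly sized groups.

    Patients are ranked by predicted benefit (stable sort, input order
    breaking ties) and split into ``n_groups`` contiguous groups whose
    sizes differ by at most one; remainder patients go one-per-group
    from the lowest-benefit group upward.  The observed benefit of a
    group is its control-arm event rate minus its treated-arm event
    rate; groups with an empty arm are flagged and left NaN.
    """
    if n_groups < 2:
        raise ValueError(f"n_groups must be at least 2, got {n_groups}")
    if ds.n < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} patients for "
                         f"{n_groups} groups, have {ds.n}")
    _check_markers_compatible(results, ds)
    preds = results.predict_benefit_frame(ds.markers, threshold=threshold)
    benefit = preds["benefit"].to_numpy()
    order = np.argsort(benefit, kind="stable")
    base, rem = divmod(ds.n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    rows = []
    warnings: list[str] = []
    start = 0
    for g, size in enumerate(sizes):
        idx = order[start:start + size]
        start += size
        t = ds.treatment[idx]
        y = ds.outcome[idx]
        n_c, n_t = int((t == 0).sum()), int((t == 1).sum())
        if n_c == 0 or n_t == 0:
            observed = math.nan
            warnings.append(f"group {g + 1}: observed benefit undefined "
                            f"(n_control={n_c}, n_treated={n_t})")
        else:
            observed = float(y[t == 0].mean() - y[t == 1].mean())
        rows.append({"group": g + 1, "size": size,
                     "mean_predicted_benefit": float(benefit[idx].mean()),
                     "observed_benefit": observed,
                     "n_control": n_c, "n_treated": n_t})
    return CalibrationTable(pd.DataFrame(rows), n_groups, warnings)


def _stratified_indices(ds: TrialDataset,
                        rng: np.random.Generator) -> np.ndarray:
    """Bootstrap indices resampled within each arm, preserving arm sizes."""
    parts = []
    for arm in (0, 1):
        arm_idx = np.flatnonzero(ds.treatment == arm)
        parts.append(rng.choice(arm_idx, size=arm_idx.size, replace=True))
    return np.concatenate(parts)


def bootstrap_performance(ds: TrialDataset,
                          results: TreatmentBenefitResults,
                          threshold: float | None = None,
                          default_strategy: str = "treat_none",
                          n_boot: int = 500,
                          seed: int | None = None,
                          refit: bool = True) -> PerformanceSummary:
    """Performance summary with percentile bootstrap confidence intervals.

    Patients are resampled with replacement within each treatment arm.
    With ``refit=True`` the interaction model is refitted on every
    resample with the original shrinkage factor held fixed, so the CIs
    reflect model-fitting variability; with ``refit=False`` the
    coefficients stay frozen (the external-validation setting).  Point
    estimates always come from the original data.

    Raises :class:`CIError` if any measure is inestimable in more than
    20% of resamples.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    point = population_impact(ds, results, threshold, default_strategy)
    thr = results.threshold if threshold is None else float(threshold)
    rng = np.random.default_rng(seed)
    measures = {"positivity_rate": [], "avg_benefit_positives": [],
                "avg_benefit_no_treatment_negatives": [],
                "population_impact": []}
    for _ in range(n_boot):
        idx = _stratified_indices(ds, rng)
        bs = ds.subset(idx)
        try:
            if refit:
                bres = _fit_unchecked(bs, threshold=thr)
                if results.is_shrunken:
                    bres = apply_shrinkage(bres, results.shrinkage_factor, bs)
            else:
                bres = results
            summ = population_impact(bs, bres, thr, default_strategy)
        except Exception:
            summ = None
        for key in measures:
            if summ is None:
                measures[key].append(math.nan)
            else:
                measures[key].append(getattr(summ, key).value)
    cis = {}
    for key, vals in measures.items():
        vals = np.asarray(vals, float)
        n_bad = int(np.isnan(vals).sum())
        if n_bad > 0.2 * n_boot:
            raise CIError(
                f"measure {key!r} inestimable in {n_bad}/{n_boot} "
                f"resamples; cannot form a percentile interval")
        lo, hi = np.nanpercentile(vals, [2.5, 97.5])
        cis[key] = (float(lo), float(hi))

    def with_ci(est: Estimate, key: str) -> Estimate:
        return Estimate(est.value, *cis[key])

    return replace(
        point,
        positivity_rate=with_ci(point.positivity_rate, "positivity_rate"),
        avg_benefit_positives=with_ci(point.avg_benefit_positives,
                                      "avg_benefit_positives"),
        avg_benefit_no_treatment_negatives=with_ci(
            point.avg_benefit_no_treatment_negatives,
            "avg_benefit_no_treatment_negatives"),
        population_impact=with_ci(point.population_impact,
                                  "population_impact"))


def external_validate(results: TreatmentBenefitResults,
                      ds_new: TrialDataset,
                      threshold: float | None = None,
                      default_strategy: str = "treat_none",
                      n_groups: int = 10,
                      n_boot: int | None = 500,
                      seed: int | None = None
                      ) -> tuple[PerformanceSummary, CalibrationTable]:
    """Evaluate a frozen model on an independent trial.

    All predictions use the development model's coefficients as-is — no
    refitting, no re-shrinkage — and bootstrap CIs (when ``n_boot`` is
    given) keep the model frozen across resamples.
    """
    _check_markers_compatible(results, ds_new)
    if n_boot is None:
        summary = population_impact(ds_new, results, threshold,
                                    default_strategy)
    else:
        summary = bootstrap_performance(ds_new, results, threshold,
                                        default_strategy, n_boot=n_boot,
                                        seed=seed, refit=False)
    table = calibration_table(ds_new, results, threshold, n_groups)
    return summary, table
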