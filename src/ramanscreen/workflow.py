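"""High-level orchestration: screen -> factorial models -> desirability
optimization -> profile simulation -> report.

These functions tie the library together the way the command-line interface
(and the test-bench scripts) drive it; each is reusable on saved artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import (
    ANNSearchRegressor,
    PLSCalibrator,
    fit_pca_scores,
    split_calibration,
)
from .dataset import PARAMETERS, SpectralDataset
from .doe import (
    DesirabilityResult,
    DesirabilitySpec,
    MetricModel,
    code_design,
    compare_individual_vs_overall,
    fit_metric_model,
    optimize_combination,
)
from .filters import FilterCombination, FilterParams, make_pipeline
from .metrics import relative_errors
from .screen import ScreenTable

__all__ = [
    "MAE_IMPORTANCE",
    "SD_AE_IMPORTANCE",
    "FittedPreprocessor",
    "fit_preprocessor",
    "fit_metric_models",
    "optimize_screen",
    "OptimizationBundle",
    "ProfileSimulation",
    "simulate_profiles",
    "report",
]

MAE_IMPORTANCE = 5
SD_AE_IMPORTANCE = 4


class FittedPreprocessor:
    """A filter combination fitted on calibration spectra, applicable to any
    spectra on the same axis (carries the calibration-fitted MSC state)."""

    def __init__(self, combo: FilterCombination, params: FilterParams,
                 axis_values: np.ndarray):
        self.combo = combo
        self.params = params
        self.axis_values = axis_values
        self._stages = None

    def fit(self, X_cal: np.ndarray) -> "FittedPreprocessor":
        stages = make_pipeline(self.combo, self.params, self.axis_values)
        Xc = X_cal
        for _, tr in stages:
            tr.fit(Xc)
            Xc = tr.transform(Xc)
        self._stages = stages
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._stages is None:
            raise RuntimeError("preprocessor not fitted")
        for _, tr in self._stages:
            X = tr.transform(X)
        return X


def fit_preprocessor(dataset: SpectralDataset, combo: FilterCombination,
                     params: FilterParams, cal_mask: np.ndarray) -> FittedPreprocessor:
    return FittedPreprocessor(combo, params, dataset.axis.values).fit(
        dataset.intensities[cal_mask]
    )


def fit_metric_models(screen: ScreenTable, parameters=None, alpha: float = 0.05,
                      transform: str = "auto"):
    """Fit the factorial MAE and SD_AE models for each parameter.

    Returns ``(models, specs)`` keyed by ``"<param>:<metric>"``; the
    desirability bounds are the observed response min/max over the screen.
    """
    parameters = parameters or screen.parameters()
    models, specs = {}, {}
    for p in parameters:
        for metric, importance in (("MAE", MAE_IMPORTANCE),
                                   ("SD_AE", SD_AE_IMPORTANCE)):
            combos, y = code_design(screen, p, metric)
            if len(combos) == 0:
                continue
            key = f"{p}:{metric}"
            models[key] = fit_metric_model(combos, y, response_name=key,
                                           alpha=alpha, transform=transform)
            lo, hi = float(np.min(y)), float(np.max(y))
            if hi <= lo:
                hi = lo + max(abs(lo), 1.0) * 1e-6
            specs[key] = DesirabilitySpec(name=key, lower=lo, upper=hi,
                                          importance=importance)
    return models, specs


@dataclass
class OptimizationBundle:
    individual: dict[str, DesirabilityResult]
    overall: DesirabilityResult
    models: dict[str, MetricModel]
    specs: dict[str, DesirabilitySpec]
    comparison: pd.DataFrame | None = None


def optimize_screen(screen: ScreenTable, parameters=None, alpha: float = 0.05,
                    transform: str = "auto",
                    compare: bool = True) -> OptimizationBundle:
    """Individual (per parameter) and overall desirability optimization of a
    screen, with the individual-vs-overall t-test comparison."""
    parameters = parameters or screen.parameters()
    models, specs = fit_metric_models(screen, parameters, alpha, transform)
    individual = {}
    for p in parameters:
        keys = [k for k in models if k.startswith(f"{p}:")]
        individual[p] = optimize_combination(
            {k: models[k] for k in keys}, {k: specs[k] for k in keys},
            mode="individual")
    overall = optimize_combination(models, specs, mode="overall")
    comparison = (
        compare_individual_vs_overall(individual, overall, screen, alpha)
        if compare else None
    )
    return OptimizationBundle(individual=individual, overall=overall,
                              models=models, specs=specs, comparison=comparison)


@dataclass
class ProfileSimulation:
    """Hourly predicted trajectories for one run, with provenance."""

    run_id: str
    frame: pd.DataFrame  # time_h + one column per parameter
    combination: str
    technique: str
    seed: int

    def relative_errors_vs(self, truth: pd.DataFrame, parameter: str) -> np.ndarray:
        merged = self.frame.merge(truth, on="time_h", suffixes=("_pred", "_true"))
        return relative_errors(merged[f"{parameter}_true"],
                               merged[f"{parameter}_pred"])


def simulate_profiles(
    dataset: SpectralDataset,
    references: pd.DataFrame,
    hourly: SpectralDataset,
    combo: FilterCombination,
    params: FilterParams = FilterParams(),
    parameters=None,
    technique: str = "pls",
    seed: int = 0,
    cal_fraction: float = 0.8,
    max_lv: int = 10,
    cv_groups: int = 7,
    clamp_nonnegative: bool = False,
    ann_kwargs: dict | None = None,
) -> ProfileSimulation:
    """Refit the chosen combination's calibration models and predict the
    hourly spectral stream (data never used in calibration).

    Preprocessing state (MSC reference) is fitted on the calibration rows
    and reused for the hourly spectra.
    """
    if hourly.axis != dataset.axis:
        raise ValueError("hourly spectra must share the calibration axis")
    parameters = parameters or PARAMETERS
    cal_ids, _ = split_calibration(dataset, cal_fraction, seed)
    cal_mask = np.isin(dataset.sample_ids, cal_ids)
    pre = fit_preprocessor(dataset, combo, params, cal_mask)
    X_all = pre.transform(dataset.intensities)
    X_hour = pre.transform(hourly.intensities)
    cal_idx = np.flatnonzero(cal_mask)
    out = {"time_h": hourly.sample_times}
    for p in parameters:
        y = references[p].reindex(dataset.sample_ids).to_numpy(dtype=float)
        ok = cal_idx[np.isfinite(y[cal_idx])]
        if technique == "pls":
            model = PLSCalibrator(max_lv=max_lv, cv_groups=cv_groups,
                                  random_state=seed).fit(X_all[ok], y[ok])
            pred = model.predict(X_hour)
        else:
            basis = fit_pca_scores(X_all[ok])
            model = ANNSearchRegressor(random_state=seed,
                                       **(ann_kwargs or {})).fit(
                basis.transform(X_all[ok]), y[ok])
            pred = model.predict(basis.transform(X_hour))
        if clamp_nonnegative:
            pred = np.maximum(pred, 0.0)
        out[p] = pred
    run_id = hourly.run_ids[0] if hourly.run_ids else "run"
    return ProfileSimulation(run_id=run_id, frame=pd.DataFrame(out),
                             combination=combo.label(), technique=technique,
                             seed=seed)


def report(screen: ScreenTable | None, bundle: OptimizationBundle | None) -> str:
    """Human-readable summary: per parameter and mode, the chosen filters,
    model size and MAE +/- SD_AE."""
    lines = []
    if screen is None or not screen.records:
        return "No screening results available.\n"
    lines.append(f"Screen: technique={screen.technique}, seed={screen.seed}, "
                 f"{len(screen.records)} metric rows")
    lines.append(f"Calibration n={len(screen.cal_ids)}, "
                 f"validation n={len(screen.val_ids)}")
    if bundle is None:
        return "\n".join(lines) + "\n"
    lines.append("")
    header = (f"{'parameter':<8} {'mode':<10} {'combination':<72} "
              f"{'size':>4} {'MAE':>10} {'SD_AE':>10}")
    lines.append(header)
    lines.append("-" * len(header))

    def best_row(param, result, mode):
        label = result.best.label()
        try:
            rec = screen.lookup(param, label)
            m, s, size = rec.mae, rec.sd_ae, rec.model_size
        except KeyError:
            m = s = float("nan")
            size = 0
        lines.append(f"{param:<8} {mode:<10} {label:<72} {size:>4} "
                     f"{m:>10.4g} {s:>10.4g}")

    for param, res in bundle.individual.items():
        best_row(param, res, "individual")
        best_row(param, bundle.overall, "overall")
    lines.append("")
    lines.append(f"Overall optimum: {bundle.overall.best.label()} "
                 f"(D = {bundle.overall.D:.4f})")
    if bundle.comparison is not None and len(bundle.comparison):
        flagged = bundle.comparison[bundle.comparison["individual_better"]]
        if len(flagged):
            lines.append("Individually-optimized MAE significantly lower for: "
                         + ", ".join(flagged["parameter"]))
        else:
            lines.append("No parameter shows a significant individual-vs-"
                         "overall difference (paired one-tailed t-test).")
    return "\n".join(lines) + "\n"
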