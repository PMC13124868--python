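"""The exhaustive preprocessing screen.

Every one of the 480 filter combinations — plus 10 replicate fits of the
raw (all-None) treatment that estimate pure error for the factorial stage —
is applied to the calibration spectra and scored by a calibration model per
bioprocess parameter.  One calibration/validation split, drawn once per
seed and stratified by run, is reused across all rows so that metric
differences reflect preprocessing alone.

Preprocessing cost is kept linear in the number of *stage outputs* rather
than combinations: the four-stage pipeline is walked as a tree (6 smoothing
-> 30 smoothing x baseline -> 120 x normalization -> 480 full
combinations), computing each stage matrix once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import (
    ANNSearchRegressor,
    DegenerateTargetError,
    PLSCalibrator,
    fit_pca_scores,
    split_calibration,
)
from .dataset import PARAMETERS, SpectralDataset
from .filters import (
    BASELINE_LEVELS,
    NORMALIZATION_LEVELS,
    OTHER_LEVELS,
    SMOOTHING_LEVELS,
    DegenerateSpectrumError,
    FilterCombination,
    FilterParams,
    _stage_transformer,
    all_combinations,
)
from .metrics import MetricRecord, absolute_errors, mae, relative_errors, sd_ae

__all__ = ["enumerate_screen", "ScreenTable", "run_screen"]

N_RAW_REPETITIONS = 10


def enumerate_screen() -> list[tuple[FilterCombination, int]]:
    """All 480 combinations (repetition 1) in deterministic order, followed
    by 10 replicate entries (repetitions 2..11) of the raw treatment —
    490 entries total."""
    entries = [(c, 1) for c in all_combinations()]
    raw = FilterCombination.raw()
    entries += [(raw, rep) for rep in range(2, N_RAW_REPETITIONS + 2)]
    return entries


@dataclass
class ScreenTable:
    """All metric records of one screen plus its provenance."""

    technique: str
    records: list[MetricRecord]
    seed: int
    cal_ids: list[str]
    val_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.records])

    def lookup(self, parameter: str, combination: str,
               repetition: int = 1) -> MetricRecord:
        for r in self.records:
            if (r.parameter == parameter and r.combination == combination
                    and r.repetition == repetition):
                return r
        raise KeyError((parameter, combination, repetition))

    def parameters(self) -> list[str]:
        return list(dict.fromkeys(r.parameter for r in self.records))


def _iter_preprocessed(X, axis_values, cal_mask, params):
    """Depth-first walk of the staged pipeline, yielding
    ``(combo, X_processed or exception)`` for all 480 combinations."""

    def _apply(level_cat, level, X_in):
        tr = _stage_transformer(level_cat, level, params, axis_values)
        if tr is None:
            return X_in
        tr.fit(X_in[cal_mask])
        return tr.transform(X_in)

    for s in SMOOTHING_LEVELS:
        Xs = _apply("smoothing", s, X)
        for b in BASELINE_LEVELS:
            Xb = _apply("baseline", b, Xs)
            for n in NORMALIZATION_LEVELS:
                try:
                    Xn = _apply("normalization", n, Xb)
                except DegenerateSpectrumError as err:
                    for o in OTHER_LEVELS:
                        yield FilterCombination(s, b, n, o), err
                    continue
                for o in OTHER_LEVELS:
                    try:
                        Xo = _apply("other", o, Xn)
                    except DegenerateSpectrumError as err:
                        yield FilterCombination(s, b, n, o), err
                        continue
                    yield FilterCombination(s, b, n, o), Xo


def _fit_and_score(technique, Xp, y_all, cal_idx, val_idx, seed, *,
                   max_lv, cv_groups, q2_gain_threshold, variance_target,
                   n_pc_max, ann_kwargs):
    """Fit one model on the calibration rows with a non-missing target and
    score it on the validation rows; returns (mae, sd_ae, ae, re, size)."""
    ok_cal = cal_idx[np.isfinite(y_all[cal_idx])]
    ok_val = val_idx[np.isfinite(y_all[val_idx])]
    if ok_cal.size < cv_groups + 1 or ok_val.size == 0:
        raise DegenerateTargetError("too few non-missing reference values")
    y_cal, y_val = y_all[ok_cal], y_all[ok_val]
    if technique == "pls":
        model = PLSCalibrator(max_lv=max_lv, cv_groups=cv_groups,
                              q2_gain_threshold=q2_gain_threshold,
                              random_state=seed).fit(Xp[ok_cal], y_cal)
        pred = model.predict(Xp[ok_val])
        size = model.n_lv_
    elif technique == "ann":
        basis = fit_pca_scores(Xp[ok_cal], variance_target, n_pc_max)
        model = ANNSearchRegressor(random_state=seed, **ann_kwargs).fit(
            basis.transform(Xp[ok_cal]), y_cal)
        pred = model.predict(basis.transform(Xp[ok_val]))
        size = model.n_hidden_
    else:
        raise ValueError(f"unknown technique {technique!r}")
    ae = absolute_errors(y_val, pred)
    with np.errstate(divide="ignore"):
        re = relative_errors(y_val, pred)
    return mae(ae), sd_ae(ae), ae, re, size


def run_screen(
    dataset: SpectralDataset,
    references: pd.DataFrame,
    technique: str = "pls",
    parameters: list[str] | None = None,
    params: FilterParams = FilterParams(),
    seed: int = 0,
    cal_fraction: float = 0.8,
    max_lv: int = 10,
    cv_groups: int = 7,
    q2_gain_threshold: float = 0.01,
    variance_target: float = 0.99,
    n_pc_max: int = 30,
    ann_kwargs: dict | None = None,
    progress=None,
) -> ScreenTable:
    """Run the exhaustive screen for one technique over the requested
    parameters (default: all seven).

    A combination whose preprocessing degenerates is recorded as a failure
    row with missing metrics; the screen never aborts.
    """
    parameters = parameters or PARAMETERS
    ann_kwargs = ann_kwargs or {}
    cal_ids, val_ids = split_calibration(dataset, cal_fraction, seed)
    id_pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    cal_idx = np.array([id_pos[s] for s in cal_ids])
    val_idx = np.array([id_pos[s] for s in val_ids])
    cal_mask = np.zeros(dataset.n_samples, dtype=bool)
    cal_mask[cal_idx] = True

    # Reference values aligned to dataset row order by sample_id.
    y_cols = {}
    for p in parameters:
        col = references[p].reindex(dataset.sample_ids)
        y_cols[p] = col.to_numpy(dtype=float)

    records: list[MetricRecord] = []

    def score_combo(combo, Xp_or_err, repetition, fit_seed):
        label = combo.label()
        for p in parameters:
            if isinstance(Xp_or_err, Exception):
                records.append(MetricRecord(
                    parameter=p, technique=technique, combination=label,
                    repetition=repetition, failed=True,
                    failure_reason=str(Xp_or_err)))
                continue
            try:
                m, s, ae, re, size = _fit_and_score(
                    technique, Xp_or_err, y_cols[p], cal_idx, val_idx,
                    fit_seed, max_lv=max_lv, cv_groups=cv_groups,
                    q2_gain_threshold=q2_gain_threshold,
                    variance_target=variance_target, n_pc_max=n_pc_max,
                    ann_kwargs=ann_kwargs)
                records.append(MetricRecord(
                    parameter=p, technique=technique, combination=label,
                    repetition=repetition, mae=m, sd_ae=s, n_val=len(ae),
                    ae=ae, re=re, model_size=size))
            except (DegenerateTargetError, RuntimeError) as err:
                records.append(MetricRecord(
                    parameter=p, technique=technique, combination=label,
                    repetition=repetition, failed=True,
                    failure_reason=str(err)))

    X_raw_processed = None
    for i, (combo, result) in enumerate(_iter_preprocessed(
            dataset.intensities, dataset.axis.values, cal_mask, params)):
        score_combo(combo, result, 1, seed)
        if combo.is_raw and not isinstance(result, Exception):
            X_raw_processed = result
        if progress is not None:
            progress(i, combo)

    # Replicate fits of the raw treatment: identical data, fit seed varies.
    raw = FilterCombination.raw()
    if X_raw_processed is None:
        X_raw_processed = dataset.intensities
    for rep in range(2, N_RAW_REPETITIONS + 2):
        score_combo(raw, X_raw_processed, rep, seed + rep)

    return ScreenTable(technique=technique, records=records, seed=seed,
                       cal_ids=cal_ids, val_ids=val_ids)
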