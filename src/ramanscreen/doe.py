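"""Factorial modelling of the screen metrics and desirability optimization.

The 480-cell filter grid is a complete 6 x 5 x 4 x 4 factorial in four
categorical factors.  MAE and SD_AE are modelled by OLS on sum-to-zero
coded main effects and two-factor interactions, reduced by backward
elimination of whole factor terms (grouped partial F-tests) with a
Bonferroni-style family-wise correction at the stated significance level —
so a spurious factor survives the whole reduction with probability at most
alpha.  The best combination is then the grid cell maximising the Derringer
desirability of the model-predicted responses (MAE importance 5, SD_AE
importance 4, both minimised).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filters import CATEGORY_LEVELS, FilterCombination, all_combinations
from .metrics import paired_t_test_one_tailed

__all__ = [
    "FACTOR_ORDER",
    "main_effect_terms",
    "two_factor_terms",
    "build_design",
    "code_design",
    "MetricModel",
    "fit_metric_model",
    "DesirabilitySpec",
    "desirability",
    "DesirabilityResult",
    "optimize_combination",
    "compare_individual_vs_overall",
]

FACTOR_ORDER = ("smoothing", "baseline", "normalization", "other")

Term = tuple[str, ...]


def main_effect_terms() -> list[Term]:
    return [(f,) for f in FACTOR_ORDER]


def two_factor_terms() -> list[Term]:
    return [tuple(p) for p in itertools.combinations(FACTOR_ORDER, 2)]


def _level_contrast(factor: str, level: str) -> np.ndarray:
    """Sum-to-zero contrast row for one level: L-1 columns; level i < L-1 is
    the i-th unit vector, the last level is all -1."""
    levels = CATEGORY_LEVELS[factor]
    L = len(levels)
    i = levels.index(level)
    row = np.zeros(L - 1)
    if i < L - 1:
        row[i] = 1.0
    else:
        row[:] = -1.0
    return row


def _factor_matrix(factor: str, combos: list[FilterCombination]) -> np.ndarray:
    """[n_rows x (L-1)] sum-to-zero contrast columns for one factor."""
    levels = CATEGORY_LEVELS[factor]
    C = np.vstack([_level_contrast(factor, lv) for lv in levels])
    idx = [levels.index(getattr(c, factor)) for c in combos]
    return C[idx]


def _term_blocks(combos: list[FilterCombination],
                 terms: list[Term]) -> dict[Term, np.ndarray]:
    mains = {f: _factor_matrix(f, combos) for f in FACTOR_ORDER}
    blocks = {}
    for t in terms:
        if len(t) == 1:
            blocks[t] = mains[t[0]]
        else:
            a, b = mains[t[0]], mains[t[1]]
            blocks[t] = np.einsum("ni,nj->nij", a, b).reshape(len(combos), -1)
    return blocks


def _assemble(blocks: dict[Term, np.ndarray], terms: list[Term]):
    n = next(iter(blocks.values())).shape[0] if blocks else 0
    slices = {}
    start = 1
    mats = [np.ones((n, 1))]
    for t in terms:
        w = blocks[t].shape[1]
        slices[t] = slice(start, start + w)
        mats.append(blocks[t])
        start += w
    return np.hstack(mats), slices


def build_design(combos: list[FilterCombination], terms: list[Term]):
    """Design matrix (with leading intercept column) and the column slice of
    each term."""
    return _assemble(_term_blocks(combos, terms), terms)


def code_design(screen, parameter: str, response: str = "MAE"):
    """Extract (combinations, response vector) for one parameter from a
    screen table, dropping failed rows.  Replicate raw rows share the raw
    cell's coding."""
    combos, ys = [], []
    for r in screen.records:
        if r.parameter != parameter or r.failed:
            continue
        combos.append(FilterCombination.from_label(r.combination))
        ys.append(getattr(r, response.lower() if response != "SD_AE" else "sd_ae"))
    return combos, np.asarray(ys, dtype=float)


def _boxcox_profile(y: np.ndarray, X: np.ndarray, lams: np.ndarray):
    """Profile log-likelihood of the Box-Cox parameter for a regression
    model: llf(lam) = -n/2 log(SSE(lam)/n) + (lam - 1) * sum(log y)."""
    n = y.size
    logy = np.log(y)
    slog = logy.sum()
    llf = np.empty(lams.size)
    for i, lam in enumerate(lams):
        z = logy if abs(lam) < 1e-9 else (y**lam - 1.0) / lam
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        sse = float(np.sum((z - X @ beta) ** 2))
        llf[i] = -0.5 * n * np.log(max(sse, 1e-300) / n) + (lam - 1.0) * slog
    return llf


def _choose_transform(y: np.ndarray, X: np.ndarray):
    """Pick none / log / Box-Cox by the regression profile likelihood of the
    Box-Cox parameter: keep the identity if its 95% interval contains 1,
    else the log if it contains 0, else the MLE."""
    if np.any(y <= 0):
        return "none", 1.0
    lams = np.linspace(-2.0, 3.0, 101)
    llf = _boxcox_profile(y, X, lams)
    best = llf.max()
    ci = lams[llf >= best - stats.chi2.ppf(0.95, 1) / 2.0]
    if ci.min() <= 1.0 <= ci.max():
        return "none", 1.0
    if ci.min() <= 0.0 <= ci.max():
        return "log", 0.0
    return "boxcox", float(lams[np.argmax(llf)])


def _forward_transform(y, transform, lam):
    if transform == "none":
        return y
    if transform == "log":
        return np.log(y)
    return (y**lam - 1.0) / lam


def _inverse_transform(z, transform, lam):
    if transform == "none":
        return z
    if transform == "log":
        return np.exp(z)
    return np.power(np.maximum(lam * z + 1.0, 1e-12), 1.0 / lam)


@dataclass
class MetricModel:
    """A reduced factorial OLS model of one screen metric."""

    response: str
    transform: str
    lam: float
    terms: list[Term]
    term_pvalues: dict[Term, float]
    coef: np.ndarray
    slices: dict[Term, slice]
    residual_df: int
    r2: float

    def predict(self, combos: list[FilterCombination]) -> np.ndarray:
        """Model-predicted response (back on the original scale)."""
        X, _ = build_design(combos, self.terms)
        return _inverse_transform(X @ self.coef, self.transform, self.lam)


def _fit_ols(X, z):
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    sse = float(np.sum((z - X @ beta) ** 2))
    return beta, sse


def fit_metric_model(
    combos: list[FilterCombination],
    response: np.ndarray,
    response_name: str = "MAE",
    alpha: float = 0.05,
    transform: str = "auto",
) -> MetricModel:
    """OLS of a screen metric on main effects + two-factor interactions with
    hierarchical backward elimination of whole factor terms.

    A term is dropped while its grouped partial-F p-value exceeds the
    family-wise adjusted threshold ``alpha / n_candidate_terms``; a main
    effect is never dropped while an interaction containing it is retained.
    """
    y = np.asarray(response, dtype=float)
    all_terms = main_effect_terms() + two_factor_terms()
    X_full, _ = build_design(combos, all_terms)
    if transform == "auto":
        transform, lam = _choose_transform(y, X_full)
    else:
        lam = {"none": 1.0, "log": 0.0}.get(transform, 1.0)
        if transform in ("log", "boxcox") and np.any(y <= 0):
            raise ValueError(f"{transform} transform needs a positive response")
    z = _forward_transform(y, transform, lam)

    blocks = _term_blocks(combos, all_terms)

    def term_pvals(terms, which):
        X, slices = _assemble(blocks, terms)
        df_resid = X.shape[0] - X.shape[1]
        if df_resid <= 0:
            raise ValueError("design is saturated; cannot test terms")
        _, sse = _fit_ols(X, z)
        out = {}
        for t in which:
            Xr, _ = _assemble(blocks, [u for u in terms if u != t])
            _, sse_r = _fit_ols(Xr, z)
            df_t = slices[t].stop - slices[t].start
            f = ((sse_r - sse) / df_t) / (sse / df_resid)
            out[t] = float(stats.f.sf(max(f, 0.0), df_t, df_resid))
        return out

    terms = list(all_terms)
    alpha_adj = alpha / len(all_terms)
    while terms:
        droppable = [
            t for t in terms
            if len(t) == 2
            or not any(len(u) == 2 and t[0] in u for u in terms)
        ]
        pvals = term_pvals(terms, droppable)
        worst_t = max(pvals, key=pvals.get) if pvals else None
        if worst_t is not None and pvals[worst_t] > alpha_adj:
            terms.remove(worst_t)
            continue
        break

    X, slices = _assemble(blocks, terms)
    beta, sse = _fit_ols(X, z)
    df_resid = X.shape[0] - X.shape[1]
    sst = float(np.sum((z - z.mean()) ** 2))
    term_pvalues = term_pvals(terms, terms) if terms else {}
    return MetricModel(
        response=response_name, transform=transform, lam=lam, terms=terms,
        term_pvalues=term_pvalues, coef=beta, slices=slices,
        residual_df=df_resid, r2=1.0 - sse / sst if sst > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# Desirability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesirabilitySpec:
    """Minimisation goal for one response: Derringer ramp from the observed
    maximum (d = 0) down to the observed minimum (d = 1)."""

    name: str
    lower: float
    upper: float
    weight: float = 1.0
    importance: int = 5

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("need lower < upper desirability bounds")
        if not 1 <= self.importance <= 5:
            raise ValueError("importance must lie in 1..5")

    def d(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        ramp = (self.upper - y) / (self.upper - self.lower)
        return np.clip(ramp, 0.0, 1.0) ** self.weight


def desirability(values: dict[str, float], specs: dict[str, "DesirabilitySpec"]):
    """Per-response desirabilities and their importance-weighted geometric
    mean D = (prod d_i^r_i)^(1 / sum r_i)."""
    ds = {name: float(spec.d(values[name])) for name, spec in specs.items()}
    r = np.array([specs[name].importance for name in specs], dtype=float)
    dv = np.array([ds[name] for name in specs])
    if np.any(dv == 0):
        return ds, 0.0
    D = float(np.exp(np.sum(r * np.log(dv)) / r.sum()))
    return ds, D


@dataclass
class DesirabilityResult:
    """Outcome of a desirability optimization over the 480-cell grid."""

    best: FilterCombination
    D: float
    predictions: dict[str, float]  # per response at the best cell
    per_response_d: dict[str, float]
    D_all: np.ndarray  # D at every grid cell, enumeration order
    mode: str = "individual"

    def ramp_frame(self, specs: dict[str, DesirabilitySpec]) -> pd.DataFrame:
        rows = [
            {
                "response": name,
                "lower": specs[name].lower,
                "upper": specs[name].upper,
                "importance": specs[name].importance,
                "predicted": self.predictions[name],
                "d": self.per_response_d[name],
            }
            for name in specs
        ]
        return pd.DataFrame(rows)


def optimize_combination(
    models: dict[str, MetricModel],
    specs: dict[str, DesirabilitySpec],
    mode: str = "individual",
) -> DesirabilityResult:
    """Evaluate the fitted metric models at every one of the 480 grid cells
    and return the cell maximising overall desirability.

    ``models`` and ``specs`` are keyed by response name (e.g. ``Gluc:MAE``);
    individual mode passes one parameter's two responses, overall mode pools
    every parameter's MAE (importance 5) and SD_AE (importance 4).
    """
    if set(models) != set(specs):
        raise ValueError("models and specs must cover the same responses")
    cells = all_combinations()
    preds = {name: m.predict(cells) for name, m in models.items()}
    names = list(specs)
    r = np.array([specs[n].importance for n in names], dtype=float)
    dmat = np.vstack([specs[n].d(preds[n]) for n in names])  # resp x cells
    with np.errstate(divide="ignore"):
        logd = np.where(dmat > 0, np.log(np.maximum(dmat, 1e-300)), -np.inf)
    D_all = np.where(
        np.any(dmat == 0, axis=0), 0.0, np.exp((r @ logd) / r.sum())
    )
    if np.all(D_all == 0):
        warnings.warn("desirability is zero everywhere; optimization degenerate")
    best_i = int(np.argmax(D_all))
    best = cells[best_i]
    predictions = {n: float(preds[n][best_i]) for n in names}
    ds, D = desirability(predictions, specs)
    return DesirabilityResult(best=best, D=D, predictions=predictions,
                              per_response_d=ds, D_all=D_all, mode=mode)


def compare_individual_vs_overall(
    individual: dict[str, DesirabilityResult],
    overall: DesirabilityResult,
    screen,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per parameter, a paired one-tailed t-test of whether the overall
    optimum's absolute errors exceed the individually-optimal combination's
    (i.e. whether individual optimization is significantly better)."""
    rows = []
    for param, res in individual.items():
        ind_label = res.best.label()
        ovl_label = overall.best.label()
        row = {
            "parameter": param,
            "individual_combination": ind_label,
            "overall_combination": ovl_label,
            "individual_better": False,
            "t": np.nan,
            "p": np.nan,
        }
        if ind_label != ovl_label:
            try:
                ae_ind = screen.lookup(param, ind_label).ae
                ae_ovl = screen.lookup(param, ovl_label).ae
            except KeyError:
                ae_ind = ae_ovl = None
            if ae_ind is not None and ae_ovl is not None:
                t = paired_t_test_one_tailed(ae_ovl, ae_ind, alpha)
                row.update(individual_better=bool(t.reject), t=t.t, p=t.p)
        rows.append(row)
    return pd.DataFrame(rows)
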