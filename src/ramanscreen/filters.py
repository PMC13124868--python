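"""The spectral filter library and its four-stage composition.

Nineteen operators in four categories — smoothing (Savitzky-Golay, symmetric
EWMA, wavelet denoising, moving median, AsLS curve, none), baseline
correction (row-centre, offset, linear detrend, AsLS subtraction, none),
normalization (SNV, peak height, peak area, none) and "other" (MSC,
first/second Savitzky-Golay derivative, none).  A
:class:`FilterCombination` picks one level per category; enumerating all
levels yields the 6 x 5 x 4 x 4 = 480 member grid that the screening stage
evaluates exhaustively.

All operators are scikit-learn transformers acting row-wise on an
``[n_samples, n_wavenumbers]`` matrix.  MSC is the only operator with
cross-sample state: its reference spectrum is the mean of the *calibration*
rows it was fitted on and is reused unchanged for validation spectra.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DegenerateSpectrumError",
    "FilterParams",
    "FilterCombination",
    "SMOOTHING_LEVELS",
    "BASELINE_LEVELS",
    "NORMALIZATION_LEVELS",
    "OTHER_LEVELS",
    "asls_fit",
    "SavitzkyGolaySmoother",
    "EWMASmoother",
    "WaveletDenoiser",
    "MovingMedianSmoother",
    "AsLSSmoother",
    "RowCenter",
    "OffsetBaseline",
    "LinearBaseline",
    "AsLSBaseline",
    "SNV",
    "PeakHeightNormalizer",
    "PeakAreaNormalizer",
    "MSC",
    "SavitzkyGolayDerivative",
    "all_combinations",
    "make_pipeline",
    "apply_combination",
]


class DegenerateSpectrumError(ValueError):
    """A spectrum is degenerate for the requested operator (e.g. SNV of a
    constant spectrum, peak normalization of a non-positive spectrum)."""


# Category level names, in presentation order (None last).
SMOOTHING_LEVELS = ("SG", "EWMA", "WDS", "MW", "AsLS", "none")
BASELINE_LEVELS = ("rowcenter", "offset", "linear", "asls", "none")
NORMALIZATION_LEVELS = ("snv", "peakheight", "peakarea", "none")
OTHER_LEVELS = ("msc", "d1q", "d2c", "none")

CATEGORY_LEVELS = {
    "smoothing": SMOOTHING_LEVELS,
    "baseline": BASELINE_LEVELS,
    "normalization": NORMALIZATION_LEVELS,
    "other": OTHER_LEVELS,
}


@dataclass(frozen=True)
class FilterParams:
    """Operator parameters with the published screening defaults.

    sg_window/sg_polyorder: Savitzky-Golay smoothing (15 points, quadratic).
    mw_window: moving-median window (15 points).
    asls_lambda/asls_p: AsLS smoothness and asymmetry (1e4, 0.001).
    wds_wavelet: Daubechies order-4 wavelet, mean-detrend before transform.
    ewma_alpha: EWMA smoothing constant (symmetric two-pass).
    deriv_window: window for the derivative operators.
    """

    sg_window: int = 15
    sg_polyorder: int = 2
    mw_window: int = 15
    asls_lambda: float = 1.0e4
    asls_p: float = 1.0e-3
    asls_max_iter: int = 50
    asls_tol: float = 1.0e-6
    wds_wavelet: str = "db4"
    ewma_alpha: float = 0.3
    deriv_window: int = 15

    def __post_init__(self) -> None:
        for name in ("sg_window", "mw_window", "deriv_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be > 0")
        if not 0 < self.asls_p < 1:
            raise ValueError("asls_p must lie in (0, 1)")
        if not 0 < self.ewma_alpha <= 1:
            raise ValueError("ewma_alpha must lie in (0, 1]")


@dataclass(frozen=True)
class FilterCombination:
    """One preprocessing treatment: a level from each of the four categories."""

    smoothing: str = "none"
    baseline: str = "none"
    normalization: str = "none"
    other: str = "none"

    def __post_init__(self) -> None:
        for cat, levels in CATEGORY_LEVELS.items():
            val = getattr(self, cat)
            if val not in levels:
                raise ValueError(f"{cat} must be one of {levels}, got {val!r}")

    @property
    def is_raw(self) -> bool:
        return all(
            getattr(self, c) == "none" for c in ("smoothing", "baseline",
                                                 "normalization", "other")
        )

    def label(self) -> str:
        return (
            f"smoothing={self.smoothing},baseline={self.baseline},"
            f"norm={self.normalization},other={self.other}"
        )

    @classmethod
    def from_label(cls, label: str) -> "FilterCombination":
        parts = dict(p.split("=", 1) for p in label.split(","))
        return cls(
            smoothing=parts["smoothing"],
            baseline=parts["baseline"],
            normalization=parts["norm"],
            other=parts["other"],
        )

    @classmethod
    def raw(cls) -> "FilterCombination":
        return cls()


def all_combinations() -> list[FilterCombination]:
    """The full 480-member filter grid in deterministic lexicographic order
    (category order smoothing, baseline, normalization, other; levels in
    presentation order with 'none' last — so the raw treatment is the final
    element)."""
    return [
        FilterCombination(s, b, n, o)
        for s, b, n, o in itertools.product(
            SMOOTHING_LEVELS, BASELINE_LEVELS, NORMALIZATION_LEVELS, OTHER_LEVELS
        )
    ]


# ---------------------------------------------------------------------------
# AsLS (Whittaker smoother with asymmetric weights)
# ---------------------------------------------------------------------------

def asls_fit(
    y: np.ndarray,
    lam: float = 1.0e4,
    p: float = 1.0e-3,
    max_iter: int = 50,
    tol: float = 1.0e-6,
) -> np.ndarray:
    """Asymmetric-least-squares smooth curve through ``y``.

    Minimises ``sum w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` with weights
    ``p`` above the curve and ``1 - p`` below, iterated to convergence.  The
    banded normal equations are solved by Cholesky factorisation.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        return y.copy()
    # Upper-banded form of lam * D2'D2 (pentadiagonal, bandwidth 2):
    # diag [1,5,6,...,6,5,1], first off-diag [-2,-4,...,-4,-2], second 1.
    ab = np.zeros((3, n))
    ab[0, 2:] = lam
    ab[1, 1:] = -4.0 * lam
    ab[1, 1] = ab[1, -1] = -2.0 * lam
    ab[2, :] = 6.0 * lam
    ab[2, 0] = ab[2, -1] = lam
    ab[2, 1] = ab[2, -2] = 5.0 * lam
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        a = ab.copy()
        a[2, :] += w
        z_new = solveh_banded(a, w * y, lower=False)
        w_new = np.where(y > z_new, p, 1.0 - p)
        delta = np.max(np.abs(z_new - z)) / max(np.max(np.abs(y)), 1e-12)
        z = z_new
        if np.array_equal(w_new, w) or delta < tol:
            w = w_new
            break
        w = w_new
    else:
        warnings.warn("AsLS weights did not converge; returning last iterate")
    return z


class _RowwiseTransformer(TransformerMixin, BaseEstimator):
    """Base for stateless per-spectrum operators."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return self._transform_matrix(X[None, :])[0]
        return self._transform_matrix(X)

    def _transform_matrix(self, X):  # pragma: no cover - abstract
        raise NotImplementedError


class SavitzkyGolaySmoother(_RowwiseTransformer):
    """Savitzky-Golay smoothing: local quadratic least squares, 15 points,
    polynomial extrapolation at the edges."""

    def __init__(self, window: int = 15, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def _transform_matrix(self, X):
        if X.shape[1] < self.window:
            raise ValueError("window longer than spectrum")
        return savgol_filter(X, self.window, self.polyorder, axis=1, mode="interp")


class EWMASmoother(_RowwiseTransformer):
    """Symmetric exponentially weighted moving average: the mean of a
    forward and a backward recursive pass, cancelling directional lag."""

    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha

    def _transform_matrix(self, X):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        fwd = self._one_pass(X)
        bwd = self._one_pass(X[:, ::-1])[:, ::-1]
        return 0.5 * (fwd + bwd)

    def _one_pass(self, X):
        a = self.alpha
        out = np.empty_like(X)
        out[:, 0] = X[:, 0]
        for j in range(1, X.shape[1]):
            out[:, j] = a * X[:, j] + (1.0 - a) * out[:, j - 1]
        return out


class WaveletDenoiser(_RowwiseTransformer):
    """Wavelet denoising: mean-detrend, Daubechies-4 decomposition to the
    maximum feasible level, soft universal threshold (sigma from the MAD of
    the finest detail band), reconstruct, restore the mean."""

    def __init__(self, wavelet: str = "db4", level: int | None = None):
        self.wavelet = wavelet
        self.level = level

    def _transform_matrix(self, X):
        wav = pywt.Wavelet(self.wavelet)
        n = X.shape[1]
        if n < wav.dec_len:
            raise ValueError("spectrum shorter than the wavelet filter")
        level = self.level or pywt.dwt_max_level(n, wav.dec_len)
        means = X.mean(axis=1, keepdims=True)
        Xc = X - means
        coeffs = pywt.wavedec(Xc, wav, level=level, axis=1)
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest), axis=1, keepdims=True) / 0.6745
        thresh = sigma * np.sqrt(2.0 * np.log(n))
        den = [coeffs[0]] + [
            np.sign(c) * np.maximum(np.abs(c) - thresh, 0.0)
            for c in coeffs[1:]
        ]
        rec = pywt.waverec(den, wav, axis=1)[:, :n]
        return rec + means


class MovingMedianSmoother(_RowwiseTransformer):
    """Centred running median (window 15); the window shrinks symmetrically
    at the spectrum edges so output length equals input length."""

    def __init__(self, window: int = 15):
        self.window = window

    def _transform_matrix(self, X):
        n = X.shape[1]
        w = min(self.window, n if n % 2 else n - 1)
        half = w // 2
        out = np.empty_like(X)
        if n >= w:
            view = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)
            out[:, half : n - half] = np.median(view, axis=2)
        for j in range(min(half, n)):
            k = j  # symmetric shrinking window of size 2j+1
            out[:, j] = np.median(X[:, : 2 * k + 1], axis=1)
            out[:, n - 1 - j] = np.median(X[:, n - 1 - 2 * k :], axis=1)
        return out


class AsLSSmoother(_RowwiseTransformer):
    """AsLS used as a smoother: returns the fitted smooth curve itself."""

    def __init__(self, lam: float = 1.0e4, p: float = 1.0e-3,
                 max_iter: int = 50, tol: float = 1.0e-6):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def _transform_matrix(self, X):
        return np.vstack(
            [asls_fit(row, self.lam, self.p, self.max_iter, self.tol) for row in X]
        )


class RowCenter(_RowwiseTransformer):
    """Subtract each spectrum's mean intensity."""

    def _transform_matrix(self, X):
        return X - X.mean(axis=1, keepdims=True)


class OffsetBaseline(_RowwiseTransformer):
    """Subtract each spectrum's minimum (lowest-point offset correction)."""

    def _transform_matrix(self, X):
        return X - X.min(axis=1, keepdims=True)


class LinearBaseline(_RowwiseTransformer):
    """Subtract the least-squares straight line of intensity on wavenumber."""

    def __init__(self, axis_values: np.ndarray | None = None):
        self.axis_values = axis_values

    def _transform_matrix(self, X):
        n = X.shape[1]
        nu = (
            np.arange(n, dtype=float)
            if self.axis_values is None
            else np.asarray(self.axis_values, dtype=float)
        )
        nu_c = nu - nu.mean()
        slope = (X - X.mean(axis=1, keepdims=True)) @ nu_c / (nu_c @ nu_c)
        return X - X.mean(axis=1, keepdims=True) - slope[:, None] * nu_c[None, :]


class AsLSBaseline(_RowwiseTransformer):
    """Subtract the AsLS curve: classic asymmetric baseline removal."""

    def __init__(self, lam: float = 1.0e4, p: float = 1.0e-3,
                 max_iter: int = 50, tol: float = 1.0e-6):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def _transform_matrix(self, X):
        base = np.vstack(
            [asls_fit(row, self.lam, self.p, self.max_iter, self.tol) for row in X]
        )
        return X - base


class SNV(_RowwiseTransformer):
    """Standard normal variate: per-spectrum centring to mean 0 and scaling
    to unit (n-1) standard deviation."""

    def _transform_matrix(self, X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateSpectrumError("SNV undefined for a constant spectrum")
        return (X - mu) / sd


class PeakHeightNormalizer(_RowwiseTransformer):
    """Divide by the maximum intensity (optionally within a wavenumber
    sub-range)."""

    def __init__(self, axis_values=None, window: tuple[float, float] | None = None):
        self.axis_values = axis_values
        self.window = window

    def _transform_matrix(self, X):
        sub = X
        if self.window is not None and self.axis_values is not None:
            lo, hi = self.window
            mask = (self.axis_values >= lo) & (self.axis_values <= hi)
            sub = X[:, mask]
        peak = sub.max(axis=1, keepdims=True)
        if np.any(peak <= 0):
            raise DegenerateSpectrumError("peak-height normalization needs a positive peak")
        return X / peak


class PeakAreaNormalizer(_RowwiseTransformer):
    """Divide by the trapezoid-rule area of |intensity| over the axis."""

    def __init__(self, axis_values: np.ndarray | None = None):
        self.axis_values = axis_values

    def _transform_matrix(self, X):
        nu = (
            np.arange(X.shape[1], dtype=float)
            if self.axis_values is None
            else np.asarray(self.axis_values, dtype=float)
        )
        area = np.trapezoid(np.abs(X), nu, axis=1)[:, None]
        if np.any(area == 0):
            raise DegenerateSpectrumError("zero-area spectrum cannot be normalized")
        return X / area


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against the calibration mean.

    ``fit`` stores the mean of the calibration spectra as the reference;
    ``transform`` regresses each spectrum on the reference (y = a + b*ref)
    and returns ``(y - a) / b``.  A non-positive gain leaves the spectrum
    uncorrected with a warning.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ref = self.reference_
        ref_c = ref - ref.mean()
        denom = ref_c @ ref_c
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        a = X.mean(axis=1) - b * ref.mean()
        out = np.empty_like(X)
        bad = b <= 0
        if np.any(bad):
            warnings.warn("MSC gain <= 0 for some spectra; left uncorrected")
        good = ~bad
        out[good] = (X[good] - a[good, None]) / b[good, None]
        out[bad] = X[bad]
        return out


class SavitzkyGolayDerivative(_RowwiseTransformer):
    """Savitzky-Golay derivative scaled by the axis step: first derivative
    with a local quadratic, or second derivative with a local cubic."""

    def __init__(self, deriv: int = 1, window: int = 15, delta: float = 1.0):
        self.deriv = deriv
        self.window = window
        self.delta = delta

    def _transform_matrix(self, X):
        polyorder = 2 if self.deriv == 1 else 3
        return savgol_filter(
            X, self.window, polyorder, deriv=self.deriv, delta=self.delta,
            axis=1, mode="interp",
        )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _stage_transformer(category: str, level: str, params: FilterParams,
                       axis_values: np.ndarray | None):
    if level == "none":
        return None
    if category == "smoothing":
        return {
            "SG": lambda: SavitzkyGolaySmoother(params.sg_window, params.sg_polyorder),
            "EWMA": lambda: EWMASmoother(params.ewma_alpha),
            "WDS": lambda: WaveletDenoiser(params.wds_wavelet),
            "MW": lambda: MovingMedianSmoother(params.mw_window),
            "AsLS": lambda: AsLSSmoother(params.asls_lambda, params.asls_p,
                                         params.asls_max_iter, params.asls_tol),
        }[level]()
    if category == "baseline":
        return {
            "rowcenter": lambda: RowCenter(),
            "offset": lambda: OffsetBaseline(),
            "linear": lambda: LinearBaseline(axis_values),
            "asls": lambda: AsLSBaseline(params.asls_lambda, params.asls_p,
                                         params.asls_max_iter, params.asls_tol),
        }[level]()
    if category == "normalization":
        return {
            "snv": lambda: SNV(),
            "peakheight": lambda: PeakHeightNormalizer(axis_values),
            "peakarea": lambda: PeakAreaNormalizer(axis_values),
        }[level]()
    if category == "other":
        step = 1.0
        if axis_values is not None and len(axis_values) > 1:
            step = float(axis_values[1] - axis_values[0])
        return {
            "msc": lambda: MSC(),
            "d1q": lambda: SavitzkyGolayDerivative(1, params.deriv_window, step),
            "d2c": lambda: SavitzkyGolayDerivative(2, params.deriv_window, step),
        }[level]()
    raise ValueError(category)


def make_pipeline(combo: FilterCombination, params: FilterParams = FilterParams(),
                  axis_values: np.ndarray | None = None):
    """Ordered list of (category, transformer) stages for a combination;
    'none' stages are omitted.  Categories apply smoothing -> baseline ->
    normalization -> other."""
    stages = []
    for cat in ("smoothing", "baseline", "normalization", "other"):
        tr = _stage_transformer(cat, getattr(combo, cat), params, axis_values)
        if tr is not None:
            stages.append((cat, tr))
    return stages


def apply_combination(dataset, combo: FilterCombination,
                      params: FilterParams = FilterParams(),
                      cal_mask: np.ndarray | None = None):
    """Apply a filter combination to a whole dataset.

    ``cal_mask`` marks the calibration rows used to fit cross-sample state
    (the MSC reference); all other operators are strictly per-spectrum.
    Returns a new dataset of identical shape.
    """
    X = dataset.intensities
    if cal_mask is None:
        cal_mask = np.ones(X.shape[0], dtype=bool)
    for cat, tr in make_pipeline(combo, params, dataset.axis.values):
        try:
            tr.fit(X[cal_mask])
            X = tr.transform(X)
        except DegenerateSpectrumError as err:
            raise DegenerateSpectrumError(
                f"{combo.label()} failed at {cat}: {err}"
            ) from err
    return dataset.with_intensities(X)
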