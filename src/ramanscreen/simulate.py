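"""Synthetic insect-cell bioprocess study generator.

Emulates the monitoring campaign the screening workflow is designed for:
five batch bioreactor runs (uninfected growth, two single baculovirus
infections, a pre-infected inoculum, and a co-infection), each followed for
~120 h with inline Raman spectra and periodic offline sampling.  Simulated
spectra are a linear mix of analyte component spectra (Gaussian peak
groups) on top of a slowly varying run-specific fluorescence background,
with heteroscedastic detector noise; each calibration spectrum is the mean
of six consecutively acquired sub-spectra, mirroring inline practice.

The generator's defaults define the study conditions every end-to-end test
runs under; they are configuration, not claims about any real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    PARAMETERS,
    AveragingWindow,
    SpectralDataset,
    WavenumberAxis,
)
from .filters import FilterCombination, CATEGORY_LEVELS
from .metrics import MetricRecord
from .screen import N_RAW_REPETITIONS, ScreenTable, all_combinations

__all__ = [
    "KineticParams",
    "RunConfig",
    "ComponentSpectrum",
    "NoiseModel",
    "StudyConfig",
    "StudyData",
    "default_runs",
    "default_components",
    "simulate_kinetics",
    "render_spectrum",
    "generate_study",
    "planted_screen",
]


@dataclass(frozen=True)
class KineticParams:
    """Batch-culture rate constants (per hour unless noted).

    Growth is logistic in viable cell density Xv (1e5 cells/mL); infected
    scenarios switch to lytic arrest (growth stops, first-order death) one
    lag after the time of infection.  Nutrient uptake is Monod-limited and
    proportional to Xv; by-products follow fixed yields on the consumed
    nutrient.
    """

    mu: float = 0.045  # max specific growth rate
    capacity: float = 70.0  # logistic carrying capacity (1e5 cells/mL)
    lysis_lag_h: float = 12.0  # infection -> growth-arrest delay
    death_rate: float = 0.02  # post-arrest decline of Xv
    viability_decline: float = 0.035  # post-arrest CV decay rate
    viability_floor: float = 30.0  # % viability asymptote after lysis
    q_gluc: float = 1.45e-3  # g/L glucose per (1e5 cells/mL) per h
    q_gln: float = 2.9e-4
    ks: float = 0.25  # Monod half-saturation (g/L)
    y_lac: float = 4.0e-3  # g lactate per g glucose consumed
    y_glu: float = 0.25  # g glutamate per g glutamine consumed
    y_nh4: float = 2.0e-2  # g ammonium per g glutamine consumed
    gluc0: float = 9.0
    gln0: float = 1.4
    lac0: float = 0.010
    glu0: float = 0.15
    nh40: float = 0.005
    cv0: float = 96.0


@dataclass(frozen=True)
class RunConfig:
    run_id: str
    n_samples: int
    scenario: str = "uninfected"  # or single-infection / coinfection /
    #                               pre-infected-inoculum
    xv0: float = 5.0  # initial viable cell density (1e5 cells/mL)
    toi_h: float | None = None  # time of infection
    duration_h: float = 120.0
    kinetics: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a run needs at least 2 samples")


def default_runs() -> list[RunConfig]:
    """The five-run study design: 12/12/13/13/15 samples over ~120 h."""
    return [
        RunConfig("run1", 12, "uninfected", xv0=5.0),
        RunConfig("run2", 12, "single-infection", xv0=7.4, toi_h=24.0),
        RunConfig("run3", 13, "single-infection", xv0=7.2, toi_h=36.0),
        RunConfig("run4", 13, "pre-infected-inoculum", xv0=6.0, toi_h=0.0),
        RunConfig("run5", 15, "coinfection", xv0=5.0, toi_h=24.0),
    ]


def simulate_kinetics(run: RunConfig, dt: float = 0.25) -> pd.DataFrame:
    """Integrate the batch kinetics and return hourly trajectories of the
    seven monitored parameters on a 0..duration grid."""
    k = run.kinetics
    infected = run.scenario != "uninfected"
    arrest_t = (run.toi_h + k.lysis_lag_h) if infected else np.inf
    n_steps = int(round(run.duration_h / dt))
    t = 0.0
    xv, cv = run.xv0, k.cv0
    gluc, gln = k.gluc0, k.gln0
    lac, glu, nh4 = k.lac0, k.glu0, k.nh40
    rows = [(0.0, xv, cv, gluc, lac, gln, glu, nh4)]
    next_hour = 1.0
    for _ in range(n_steps):
        growing = t < arrest_t
        dxv = k.mu * xv * (1.0 - xv / k.capacity) if growing else -k.death_rate * xv
        d_gluc = -k.q_gluc * xv * gluc / (gluc + k.ks)
        d_gln = -k.q_gln * xv * gln / (gln + k.ks)
        d_cv = 0.0 if growing else -k.viability_decline * (cv - k.viability_floor)
        xv = max(xv + dt * dxv, 0.0)
        cv = min(max(cv + dt * d_cv, 0.0), 100.0)
        lac += k.y_lac * (-dt * d_gluc)
        glu += k.y_glu * (-dt * d_gln)
        nh4 += k.y_nh4 * (-dt * d_gln)
        gluc = max(gluc + dt * d_gluc, 0.0)
        gln = max(gln + dt * d_gln, 0.0)
        t += dt
        if t >= next_hour - 1e-9:
            rows.append((round(t), xv, cv, gluc, lac, gln, glu, nh4))
            next_hour += 1.0
    df = pd.DataFrame(rows, columns=["time_h", *PARAMETERS])
    return df


@dataclass(frozen=True)
class ComponentSpectrum:
    """One analyte's contribution: Gaussian peaks scaled by a response
    coefficient (intensity counts per concentration unit)."""

    name: str
    peaks: tuple  # of (center cm^-1, width cm^-1, relative amplitude)
    response: float

    def profile(self, axis: np.ndarray) -> np.ndarray:
        out = np.zeros_like(axis)
        for c, w, a in self.peaks:
            out += a * np.exp(-0.5 * ((axis - c) / w) ** 2)
        return out


def default_components() -> list[ComponentSpectrum]:
    """Component spectra for the monitored species.

    Peak positions are loosely inspired by known Raman bands (glucose near
    1125 cm^-1, phenylalanine ring mode near 1004 cm^-1, CH stretch near
    2935 cm^-1); responses are scaled so every analyte's spectral footprint
    is comparable over its realistic concentration range.
    """
    return [
        ComponentSpectrum("Gluc", ((1125, 12, 1.0), (911, 10, 0.6), (1060, 10, 0.5)), 4.5),
        ComponentSpectrum("Lac", ((830, 10, 1.0), (1045, 9, 0.7)), 1300.0),
        ComponentSpectrum("Gln", ((1090, 11, 1.0), (1620, 14, 0.5)), 28.0),
        ComponentSpectrum("Glu", ((860, 10, 1.0), (1350, 12, 0.6)), 100.0),
        ComponentSpectrum("NH4", ((1450, 18, 0.6), (3200, 40, 1.0)), 1500.0),
        # biomass tracks viable cells; debris tracks dead cell material
        ComponentSpectrum("Xv", ((1004, 8, 1.0), (1660, 16, 0.8), (2935, 25, 0.9)), 0.55),
        ComponentSpectrum("debris", ((1250, 20, 1.0), (1740, 14, 0.6)), 0.9),
    ]


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise and fluorescence background.

    Additive shot-like noise (counts), multiplicative intensity jitter, and
    a fluorescence baseline: a degree-3 polynomial plus broad humps, with
    coefficients, hump positions and an overall gain that differ per run
    (fluorescence interference from the culture medium) and drift slowly
    over a run.  The humps keep the run-to-run background variation outside
    any fixed low-dimensional subspace, as with real fluorescence.
    """

    additive_sd: float = 1.2
    multiplicative_sd: float = 0.005
    baseline_mean: tuple = (300.0, -200.0, 120.0, -40.0)
    baseline_jitter: float = 0.4  # relative run-to-run coefficient spread
    baseline_drift: float = 0.25  # relative slow gain drift over a run
    baseline_run_span: float = 1.0  # deterministic gain spread across runs
    baseline_humps: int = 2  # broad fluorescence humps per run
    baseline_hump_amp: float = 120.0  # counts, before jitter and gain
    spike_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def run_baseline(self, axis: np.ndarray, rng: np.random.Generator,
                     gain: float = 1.0) -> np.ndarray:
        """One run's fluorescence curve: jittered polynomial coefficients
        scaled by a per-run gain (media lot / probe fouling differences)."""
        x = (axis - axis[0]) / (axis[-1] - axis[0])
        coefs = np.array(self.baseline_mean) * (
            1.0 + self.baseline_jitter * rng.standard_normal(4)
        )
        base = sum(c * x**i for i, c in enumerate(coefs))
        span = axis[-1] - axis[0]
        for _ in range(self.baseline_humps):
            amp = self.baseline_hump_amp * (
                1.0 + self.baseline_jitter * rng.standard_normal())
            centre = rng.uniform(axis[0], axis[-1])
            width = rng.uniform(0.10, 0.25) * span
            base = base + amp * np.exp(-0.5 * ((axis - centre) / width) ** 2)
        return gain * base

    def run_gains(self, n_runs: int) -> np.ndarray:
        """Deterministic per-run baseline gains spanning baseline_run_span,
        guaranteeing the background differs across runs."""
        if n_runs == 1:
            return np.ones(1)
        return np.linspace(1.0 - self.baseline_run_span / 2,
                           1.0 + self.baseline_run_span / 2, n_runs)


def render_spectrum(
    concentrations: dict[str, float],
    components: list[ComponentSpectrum],
    noise: NoiseModel,
    axis: np.ndarray,
    rng: np.random.Generator,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Linear concentration -> intensity mixing plus baseline and noise."""
    signal = np.zeros_like(axis)
    for comp in components:
        c = concentrations.get(comp.name, 0.0)
        if c:
            signal += c * comp.response * comp.profile(axis)
    if baseline is not None:
        signal = signal + baseline
    if noise.multiplicative_sd > 0:
        signal = signal * (1.0 + noise.multiplicative_sd * rng.standard_normal(axis.size))
    if noise.additive_sd > 0:
        signal = signal + noise.additive_sd * rng.standard_normal(axis.size)
    if noise.spike_rate > 0:
        n_spikes = rng.poisson(noise.spike_rate)
        if n_spikes:
            pos = rng.integers(0, axis.size, n_spikes)
            signal[pos] += rng.uniform(50, 500, n_spikes)
    return signal


@dataclass(frozen=True)
class StudyConfig:
    axis: WavenumberAxis = field(default_factory=WavenumberAxis.default)
    runs: tuple = field(default_factory=lambda: tuple(default_runs()))
    components: tuple = field(default_factory=lambda: tuple(default_components()))
    noise: NoiseModel = field(default_factory=NoiseModel)
    window: AveragingWindow = field(default_factory=AveragingWindow)
    assay_cv: float = 0.02  # relative noise of the offline reference assays


@dataclass
class StudyData:
    """Everything :func:`generate_study` produces."""

    dataset: SpectralDataset  # 65 averaged calibration spectra
    references: pd.DataFrame  # offline measurements, indexed by sample_id
    hourly: dict  # run_id -> SpectralDataset of hourly single spectra
    truth: dict  # run_id -> hourly true concentration DataFrame
    sub_spectra: dict  # sample_id -> [window x n_wavenumbers] raw spectra
    config: StudyConfig
    master_seed: int


def _mixing_concentrations(row: pd.Series) -> dict[str, float]:
    conc = {p: float(row[p]) for p in PARAMETERS if p != "CV"}
    conc["debris"] = float(row["Xv"]) * (100.0 - float(row["CV"])) / 100.0
    # viable biomass signal scales with live cells only
    conc["Xv"] = float(row["Xv"]) * float(row["CV"]) / 100.0
    return conc


def _sampling_times(run: RunConfig) -> np.ndarray:
    """Up-to-three-a-day offline sampling: near-evenly spaced hourly grid
    points between 6 h and duration - 2 h."""
    t = np.linspace(6.0, run.duration_h - 2.0, run.n_samples)
    return np.round(t)


def generate_study(config: StudyConfig | None = None, master_seed: int = 0) -> StudyData:
    """Generate the full synthetic study.

    The default configuration yields 5 runs with 12/12/13/13/15 offline
    samples (65 calibration spectra, each the mean of 6 rendered
    sub-spectra) plus hourly single spectra per run for profile validation.
    Reference values carry multiplicative assay noise.
    """
    cfg = config or StudyConfig()
    ss = np.random.SeedSequence(master_seed)
    run_seeds = ss.spawn(len(cfg.runs))
    axis = cfg.axis.values

    all_spectra, all_ids, all_runs, all_times = [], [], [], []
    ref_rows = []
    hourly, truth, subs = {}, {}, {}
    gains = cfg.noise.run_gains(len(cfg.runs))
    for run, rseed, gain in zip(cfg.runs, run_seeds, gains):
        rng = np.random.default_rng(rseed)
        base = cfg.noise.run_baseline(axis, rng, gain)
        kin = simulate_kinetics(run)
        truth[run.run_id] = kin
        # hourly single spectra (profile-validation stream)
        drift = 1.0 + cfg.noise.baseline_drift * (
            kin["time_h"].to_numpy() / run.duration_h
        )
        rows = []
        for i, (_, krow) in enumerate(kin.iterrows()):
            rows.append(render_spectrum(
                _mixing_concentrations(krow), list(cfg.components), cfg.noise,
                axis, rng, baseline=base * drift[i]))
        hourly[run.run_id] = SpectralDataset(
            axis=cfg.axis, intensities=np.asarray(rows),
            sample_ids=[f"{run.run_id}_h{int(h)}" for h in kin["time_h"]],
            run_ids=[run.run_id] * len(rows),
            sample_times=kin["time_h"].to_numpy(dtype=float),
        )
        # calibration samples: mean of 6 sub-spectra at the sampling moment
        times = _sampling_times(run)
        kin_idx = kin.set_index("time_h")
        for j, ts in enumerate(times):
            sid = f"{run.run_id}_s{j:02d}"
            krow = kin_idx.loc[float(ts)]
            conc = _mixing_concentrations(krow)
            dscale = 1.0 + cfg.noise.baseline_drift * ts / run.duration_h
            sub = np.asarray([
                render_spectrum(conc, list(cfg.components), cfg.noise, axis,
                                rng, baseline=base * dscale)
                for _ in range(cfg.window.n_spectra)
            ])
            subs[sid] = sub
            all_spectra.append(sub.mean(axis=0))
            all_ids.append(sid)
            all_runs.append(run.run_id)
            all_times.append(float(ts))
            meas = {}
            for p in PARAMETERS:
                v = float(krow[p]) * (1.0 + cfg.assay_cv * rng.standard_normal())
                if p == "CV":
                    v = min(max(v, 0.0), 100.0)
                meas[p] = max(v, 0.0)
            ref_rows.append({"sample_id": sid, "run_id": run.run_id,
                             "time_h": float(ts), **meas})

    dataset = SpectralDataset(
        axis=cfg.axis, intensities=np.asarray(all_spectra),
        sample_ids=all_ids, run_ids=all_runs,
        sample_times=np.asarray(all_times),
    )
    references = pd.DataFrame(ref_rows).set_index("sample_id")
    return StudyData(dataset=dataset, references=references, hourly=hourly,
                     truth=truth, sub_spectra=subs, config=cfg,
                     master_seed=master_seed)


# ---------------------------------------------------------------------------
# Planted screens (oracle fixtures for the optimizer)
# ---------------------------------------------------------------------------

def planted_screen(
    winner: FilterCombination,
    seed: int = 0,
    parameters: list[str] | None = None,
    technique: str = "pls",
    noise_sd: float = 0.03,
    effect_low: float = 0.25,
    effect_high: float = 1.0,
    n_val: int = 13,
) -> ScreenTable:
    """Synthesize a screen table in which ``winner`` has strictly minimal
    MAE and SD_AE for every parameter.

    Responses are built additively from per-factor level effects — the
    winner's level carries effect 0 in every factor, all other levels at
    least ``effect_low`` — plus seeded Gaussian noise, so a main-effects
    factorial model recovers the construction and any optimizer must return
    the planted cell.
    """
    parameters = parameters or PARAMETERS
    rng = np.random.default_rng(seed)
    effects = {}
    for metric in ("MAE", "SD_AE"):
        for p in parameters:
            for factor, levels in CATEGORY_LEVELS.items():
                for level in levels:
                    e = 0.0 if level == getattr(winner, factor) else rng.uniform(
                        effect_low, effect_high)
                    effects[(metric, p, factor, level)] = e

    records = []
    entries = [(c, 1) for c in all_combinations()]
    entries += [(FilterCombination.raw(), rep)
                for rep in range(2, N_RAW_REPETITIONS + 2)]
    for combo, rep in entries:
        for p in parameters:
            vals = {}
            for metric, base in (("MAE", 1.0), ("SD_AE", 0.8)):
                v = base + sum(
                    effects[(metric, p, f, getattr(combo, f))]
                    for f in CATEGORY_LEVELS
                )
                v += noise_sd * rng.standard_normal()
                vals[metric] = max(v, 1e-6)
            ae = rng.gamma(shape=4.0, scale=vals["MAE"] / 4.0, size=n_val)
            records.append(MetricRecord(
                parameter=p, technique=technique, combination=combo.label(),
                repetition=rep, mae=vals["MAE"], sd_ae=vals["SD_AE"],
                n_val=n_val, ae=ae))
    return ScreenTable(technique=technique, records=records, seed=seed,
                       cal_ids=[], val_ids=[])
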