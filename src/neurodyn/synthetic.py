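"""Synthetic multi-country cohort and ROI-level EEG generator.

The generator emulates the study conditions of a multi-centre eyes-closed
resting-state EEG cohort: 512 Hz sampling, 5-minute recordings, 10 merged
source-space ROIs, an aperiodic (Lorentzian, 1/f-like) spectral background
with offset/knee/exponent, oscillatory alpha and beta peaks at a
subject-specific alpha frequency, inter-ROI coupling, and a configurable
fraction of artifact epochs drawn from the four data-quality failure modes
(amplitude bursts, flatlines, high-frequency noise, decorrelated channels).

Country-level structural income inequality enters through the Gini
coefficient, computed from the Lorenz curve by trapezoid evaluation:

    G = 100 * (1 - sum_i (x_i - x_{i-1}) * (y_i + y_{i-1}))

where (x_i, y_i) are cumulative population and income shares.  Effects of
Gini (and of age, sex, education, cognition) on the EEG are planted as
deterministic shifts of each subject's generating signal parameters, so
every downstream estimate can be checked against recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Recording, CohortFeatureTable, log_stage

__all__ = [
    "gini_coefficient", "gini_from_incomes", "SignalSpec", "EffectSpec",
    "CountrySpec", "simulate_recording", "simulate_cohort", "default_countries",
]


# ---------------------------------------------------------------------------
# Gini coefficient
# ---------------------------------------------------------------------------

def gini_coefficient(x: Sequence[float], y: Sequence[float], percent: bool = True) -> float:
    """Gini coefficient from Lorenz-curve coordinates by trapezoid evaluation.

    Parameters
    ----------
    x, y : sequences
        Lorenz coordinates with ``x_0 = y_0 = 0`` and ``x_N = y_N = 1``;
        `x` strictly increasing (cumulative population share), `y`
        non-decreasing (cumulative income share).
    percent : bool
        Return on the 0-100 percent scale (default) or the 0-1 scale.

    Returns
    -------
    float
        ``100 * (1 - sum (x_i - x_{i-1}) (y_i + y_{i-1}))`` — twice the area
        between the diagonal of perfect equality and the Lorenz curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays, length >= 2")
    if not (x[0] == 0 and y[0] == 0 and np.isclose(x[-1], 1) and np.isclose(y[-1], 1)):
        raise ValueError("Lorenz curve must run from (0,0) to (1,1)")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if np.any(np.diff(y) < -1e-12):
        raise ValueError("y must be non-decreasing")
    g = 1.0 - float(np.sum(np.diff(x) * (y[1:] + y[:-1])))
    return 100.0 * g if percent else g


def gini_from_incomes(incomes: Sequence[float], percent: bool = True) -> float:
    """Build the Lorenz curve from raw incomes (N equal population segments)
    and evaluate the Gini coefficient.
    """
    inc = np.sort(np.asarray(incomes, dtype=float))
    if inc.ndim != 1 or len(inc) == 0:
        raise ValueError("incomes must be a non-empty 1-D array")
    if np.any(inc < 0):
        raise ValueError("negative incomes are not admissible")
    total = inc.sum()
    if total == 0:
        raise ValueError("all-zero incomes: Lorenz curve undefined")
    n = len(inc)
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(inc) / total])
    return gini_coefficient(x, y, percent=percent)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SignalSpec:
    """Generating parameters of one subject's ROI-level EEG.

    The spectrum is, in log10-power units,

        log10 PSD(F) = b - log10(k + F**chi) + sum_p h_p exp(-(F-c_p)^2/(2 w_p^2))

    i.e. a Lorentzian aperiodic background (offset `b`, knee `k`, exponent
    `chi`; the reported slope is a = -chi) plus Gaussian oscillatory peaks
    ``(centre Hz, height log10-units, width Hz)``.  `noise_mix` in [0, 1]
    mixes in spectrally white noise (raises complexity, flattens the
    estimated spectrum); `roi_coupling` is the gain g of the
    nearest-neighbour ring mixing across ROIs (neighbour correlation about
    2g / (1 + 2g^2)), which drives the conditional-information network.
    """

    fs: float = 512.0
    duration: float = 300.0
    offset: float = 0.0
    knee: float = 5.0
    exponent: float = 1.5
    peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(10.0, 0.8, 1.2), (20.0, 0.3, 2.5)]
    )
    noise_mix: float = 0.1
    roi_coupling: float = 0.35
    artifact_epoch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent must be > 0")
        if self.knee < 0:
            raise ValueError("knee must be >= 0")
        if not 0 <= self.artifact_epoch_fraction <= 1:
            raise ValueError("artifact_epoch_fraction must lie in [0, 1]")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class EffectSpec:
    """Planted standardized effects of predictors on generating parameters.

    Each ``gini_*`` field is the shift, per SD of Gini, applied on the scale
    of the named outcome family: ``gini_slope``/``gini_offset`` act on the
    aperiodic slope a = -chi and offset b; ``gini_alpha_power`` and
    ``gini_beta_power`` on the log10 peak heights; ``gini_complexity`` on
    the white-noise mixture (less mix = more regular signal);
    ``gini_coupling`` on the shared-source correlation (drives conditional
    mutual information global efficiency).  The default directions follow
    the inequality findings: higher Gini gives lower complexity, lower
    slope/offset, lower alpha/beta power and higher network integration.
    """

    gini_complexity: float = -0.04
    gini_slope: float = -0.35
    gini_offset: float = -0.25
    gini_alpha_power: float = -0.25
    gini_beta_power: float = -0.12
    gini_coupling: float = 0.10
    age_slope: float = -0.10
    age_alpha_power: float = -0.06
    age_coupling: float = -0.03
    mmse_complexity: float = 0.01
    sex_alpha_power: float = 0.03
    education_complexity: float = 0.005
    gini_x_age_slope: float = 0.0
    param_noise_scale: float = 1.0

    @classmethod
    def null(cls) -> "EffectSpec":
        """All effects zero (parameter jitter retained)."""
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__ if f != "param_noise_scale"})


@dataclass
class CountrySpec:
    """Sampling distributions of one country's subsample."""

    name: str
    n_subjects: int
    gini: float | None = None
    income_sample: Sequence[float] | None = None
    gdp: float = 20_000.0
    age_mean: float = 50.0
    age_sd: float = 15.0
    p_female: float = 0.5
    education_mean: float = 13.0
    education_sd: float = 4.0
    mmse_mean: float = 28.5
    mmse_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.gini is None:
            if self.income_sample is None:
                raise ValueError("either gini or income_sample is required")
            self.gini = gini_from_incomes(self.income_sample)
        if not 0 <= self.gini <= 100:
            raise ValueError("gini must lie in [0, 100]")


def default_countries(subjects_scale: float = 1.0) -> list[CountrySpec]:
    """Ten countries spanning the global south and north, with sample sizes,
    Gini, GDP per capita and demographic distributions of the emulated
    multi-centre cohort (1394 subjects at scale 1).
    """
    rows = [
        # name, n, gini, gdp per capita (USD), age_mean, age_sd, edu_mean
        ("argentina", 41, 41.0, 13_000, 66.6, 8.3, 16.6),
        ("chile", 80, 44.5, 15_000, 58.5, 17.5, 15.2),
        ("brazil", 93, 53.0, 9_000, 60.6, 16.5, 12.5),
        ("colombia", 133, 51.0, 6_500, 48.5, 14.4, 12.5),
        ("cuba", 202, 38.0, 8_800, 31.7, 9.5, 13.1),
        ("italy", 21, 35.0, 32_000, 61.6, 8.1, 15.3),
        ("greece", 24, 34.0, 20_000, 68.8, 5.4, 13.0),
        ("uk", 53, 35.0, 43_000, 55.8, 18.7, 15.0),
        ("ireland", 85, 32.0, 80_000, 67.7, 5.5, 15.2),
        ("turkey", 590, 42.0, 11_000, 41.7, 22.0, 13.7),
    ]
    return [
        CountrySpec(
            name=name, n_subjects=max(1, int(round(n * subjects_scale))),
            gini=g, gdp=gdp, age_mean=am, age_sd=asd, education_mean=em,
        )
        for name, n, g, gdp, am, asd, em in rows
    ]


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _log10_psd(spec: SignalSpec, freqs: np.ndarray) -> np.ndarray:
    """Target log10 PSD on `freqs` (> 0); flat below 0.5 Hz to keep the
    ultra-slow drift bounded (the analysis band starts at 0.5 Hz)."""
    f = np.maximum(freqs, 0.5)
    lp = spec.offset - np.log10(spec.knee + f ** spec.exponent)
    for centre, height, width in spec.peaks:
        lp = lp + height * np.exp(-((f - centre) ** 2) / (2.0 * width ** 2))
    return lp


def _shaped_noise(spec: SignalSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """One realisation of Gaussian noise whose one-sided PSD follows the
    spec's spectral model (exact in expectation)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    psd = 10.0 ** _log10_psd(spec, freqs)
    psd[0] = 0.0
    amp = np.sqrt(psd * spec.fs * n / 2.0)
    z = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2.0)
    return np.fft.irfft(amp * z, n=n)


def _inject_artifacts(data: np.ndarray, spec: SignalSpec, rng: np.random.Generator) -> list[int]:
    """Overwrite randomly chosen 1-s epochs with one of the four failure
    modes; returns the bad-epoch indices."""
    n_rois, n = data.shape
    spe = int(round(spec.fs))  # samples per 1-s epoch
    n_epochs = n // spe
    n_bad = int(round(spec.artifact_epoch_fraction * n_epochs))
    if n_bad == 0:
        return []
    bad = sorted(rng.choice(n_epochs, size=n_bad, replace=False).tolist())
    sd = data.std(axis=1, keepdims=True)
    for e in bad:
        sl = slice(e * spe, (e + 1) * spe)
        mode = rng.integers(4)
        if mode == 0:  # large-amplitude burst
            burst = rng.standard_normal((n_rois, 1)) * 10.0 * sd
            data[:, sl] += burst * np.hanning(spe)[None, :]
        elif mode == 1:  # flatline
            data[:, sl] = data[:, sl].mean(axis=1, keepdims=True)
        elif mode == 2:  # high-frequency noise
            t = np.arange(spe) / spec.fs
            f_hf = rng.uniform(28.0, 38.0, size=n_rois)
            phase = rng.uniform(0, 2 * np.pi, size=n_rois)
            tone = np.sin(2 * np.pi * f_hf[:, None] * t[None, :] + phase[:, None])
            data[:, sl] = 0.3 * data[:, sl] + 3.0 * sd * tone
        else:  # decorrelated channels
            data[:, sl] = rng.standard_normal((n_rois, spe)) * sd
    return bad


def simulate_recording(spec: SignalSpec, n_rois: int = 10, seed: int | None = None,
                       labels: Sequence[str] | None = None,
                       centre_id: str = "synthetic") -> Recording:
    """Generate one ROI-level recording from a :class:`SignalSpec`.

    All ROIs share the spectral model; inter-ROI dependence comes from
    nearest-neighbour ring mixing with gain ``spec.roi_coupling``.
    `noise_mix` mixes in white noise after spectral shaping.  Artifact
    epochs (if requested) overwrite whole 1-s segments.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    g = spec.roi_coupling
    sources = np.stack([_shaped_noise(spec, n, rng) for _ in range(n_rois)])
    if n_rois >= 2 and g > 0:
        # nearest-neighbour ring mixing: direct links survive conditioning
        # on the remaining ROIs, so conditional-MI metrics respond to g
        left = np.roll(sources, 1, axis=0)
        right = np.roll(sources, -1, axis=0)
        rows = (sources + g * (left + right)) / np.sqrt(1.0 + 2.0 * g ** 2)
    else:
        rows = sources
    if spec.noise_mix > 0:
        white = rng.standard_normal(rows.shape) * rows.std(axis=1, keepdims=True)
        rows = np.sqrt(1.0 - spec.noise_mix) * rows + np.sqrt(spec.noise_mix) * white
    bad = _inject_artifacts(rows, spec, rng)
    if labels is None:
        labels = [f"roi_{i}" for i in range(n_rois)]
    log_stage("simulate_recording", n_rois=n_rois, n_samples=n, fs=spec.fs, seed=seed)
    return Recording(
        data=rows, fs=spec.fs, labels=list(labels), centre_id=centre_id,
        meta={"signal_spec": spec, "bad_epochs_true": bad, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

def _subject_spec(base: SignalSpec, effects: EffectSpec, z: dict[str, float],
                  rng: np.random.Generator) -> SignalSpec:
    """Deterministic parameter shifts per standardized predictors, plus
    between-subject jitter."""
    e = effects
    gz, az, sx, ez, mz = z["gini"], z["age"], z["sex"], z["education"], z["mmse"]
    jit = e.param_noise_scale
    # slope a = -chi: a negative planted slope effect raises the exponent
    chi = base.exponent - (e.gini_slope + e.gini_x_age_slope * az) * gz \
        - e.age_slope * az + jit * 0.12 * rng.standard_normal()
    chi = float(np.clip(chi, 0.3, 4.0))
    b = base.offset + e.gini_offset * gz + jit * 0.10 * rng.standard_normal()
    alpha_c, alpha_h, alpha_w = base.peaks[0]
    beta_c, beta_h, beta_w = base.peaks[1] if len(base.peaks) > 1 else (20.0, 0.3, 2.5)
    iaf = float(np.clip(alpha_c + 0.8 * rng.standard_normal(), 8.0, 12.0))
    a_h = alpha_h + (e.gini_alpha_power * gz + e.age_alpha_power * az
                     + e.sex_alpha_power * sx) + jit * 0.08 * rng.standard_normal()
    b_h = beta_h + e.gini_beta_power * gz + jit * 0.05 * rng.standard_normal()
    # complexity rises with the white-noise mixture, so a negative planted
    # complexity effect lowers the mixture weight
    mix = base.noise_mix + (e.gini_complexity * gz + e.mmse_complexity * mz
                            + e.education_complexity * ez) \
        + jit * 0.02 * rng.standard_normal()
    coup = base.roi_coupling + e.gini_coupling * gz + e.age_coupling * az \
        + jit * 0.04 * rng.standard_normal()
    return replace(
        base,
        exponent=chi, offset=b,
        peaks=[(iaf, max(a_h, 0.0), alpha_w), (beta_c, max(b_h, 0.0), beta_w)],
        noise_mix=float(np.clip(mix, 0.0, 0.6)),
        roi_coupling=float(np.clip(coup, 0.02, 0.6)),
    )


def simulate_cohort(countries: Sequence[CountrySpec], effects: EffectSpec,
                    seed: int, base: SignalSpec | None = None, n_rois: int = 10,
                    make_recordings: bool = True,
                    ) -> tuple[list[Recording | None], CohortFeatureTable]:
    """Generate a multi-country cohort.

    Each subject's generating signal parameters are deterministic functions
    of their standardized predictors (gini, age, sex, education, mmse) under
    `effects`, plus Gaussian jitter.  The returned table records the true
    parameters (``*_true`` columns) for recovery tests.  With
    ``make_recordings=False`` only the table is built (fast path for
    inference-layer calibration).
    """
    if len(countries) == 0:
        raise ValueError("empty country list")
    rng = np.random.default_rng(seed)
    base = base or SignalSpec()

    rows = []
    for ci, country in enumerate(countries):
        for j in range(country.n_subjects):
            age = float(np.clip(rng.normal(country.age_mean, country.age_sd), 17, 91))
            sex = "female" if rng.random() < country.p_female else "male"
            edu = float(np.clip(rng.normal(country.education_mean, country.education_sd), 0, 28))
            mmse = float(np.clip(np.round(rng.normal(country.mmse_mean, country.mmse_sd)), 0, 30))
            rows.append({
                "subject_id": f"{country.name}_{j:04d}", "country": country.name,
                "gini": country.gini, "gdp": country.gdp, "age": age,
                "sex": sex, "education": edu, "mmse": mmse,
            })
    df = pd.DataFrame(rows).set_index("subject_id")

    def _z(col: np.ndarray) -> np.ndarray:
        sd = col.std()
        return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    zg = _z(df["gini"].to_numpy())
    za = _z(df["age"].to_numpy())
    zs = (df["sex"] == "female").to_numpy(dtype=float)
    zs = zs - zs.mean()
    ze = _z(df["education"].to_numpy())
    zm = _z(df["mmse"].to_numpy())

    recordings: list[Recording | None] = []
    truth_rows = []
    for i, (sid, row) in enumerate(df.iterrows()):
        z = {"gini": zg[i], "age": za[i], "sex": zs[i], "education": ze[i], "mmse": zm[i]}
        spec = _subject_spec(base, effects, z, rng)
        truth_rows.append({
            "exponent_true": spec.exponent, "offset_true": spec.offset,
            "alpha_height_true": spec.peaks[0][1], "iaf_true": spec.peaks[0][0],
            "beta_height_true": spec.peaks[1][1], "noise_mix_true": spec.noise_mix,
            "coupling_true": spec.roi_coupling,
        })
        if make_recordings:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            recordings.append(simulate_recording(spec, n_rois=n_rois, seed=sub_seed,
                                                 centre_id=row["country"]))
        else:
            recordings.append(None)
    truth = pd.DataFrame(truth_rows, index=df.index)
    table = CohortFeatureTable(pd.concat([df, truth], axis=1))
    log_stage("simulate_cohort", n_subjects=len(df), n_countries=len(countries),
              seed=seed, make_recordings=make_recordings)
    return recordings, table
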