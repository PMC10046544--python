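"""Synthetic longitudinal two-arm cohorts and synthetic resting EEG.

The study's registry data are private, so every stage of the pipeline is
exercised against a generator whose ground truth is known.  Two fidelity
levels are provided:

* ``feature`` — each subject-visit emits the alpha feature directly,
  ``f(true BBA) + subject effect + visit noise``, cheap enough for large
  Monte-Carlo recovery runs;
* ``signal`` — each subject-visit emits a full 19-channel recording whose
  alpha oscillation sits at ``f(true BBA)``, on a 1/f background with line
  noise and injected artifacts, exercising the filtering/spectral chain.

The alpha–age mapping is ``f(bba) = anchor + slope·(bba − 16)`` with default
anchor 10.8 Hz and slope −0.03 Hz/y, keeping the feature inside the 7–13 Hz
analysis band over the whole 16–100 y span.

Baseline brain-age gaps (BBA − CA) come from one of two models:

* ``normal`` — a single Normal(gap_mean, gap_sd), range-clipped so true BBA
  stays inside [16, 100];
* ``stratified`` — a two-component truncated-normal mixture: a fraction
  ``older_fraction`` of subjects has a positive gap (older brain phenotype),
  the rest a negative one, with component dispersions configured separately
  and a common location shift solved numerically so the realized arm mean
  equals ``baseline_gap_mean`` exactly despite the range truncation.

The intervention acts on the true BBA with stratum-specific mean changes
(older vs younger baseline phenotype), since the observed effects of such
interventions differ strongly by baseline stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.legendre import leggauss
from scipy import optimize
from scipy import signal as sps
from scipy import stats as st

from .brainage import ALPHA_BAND, POSTERIOR_ELECTRODES
from .errors import ConfigurationError
from .io import STANDARD_1020, Recording

CA_BOUNDS = (25.0, 77.0)  # study inclusion span, years
BBA_BOUNDS = (16.0, 100.0)  # meaningful brain-age range, years
FOLLOWUP_BOUNDS = (6.0, 18.0)  # months

FRONTAL_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")
TEMPORAL_CHANNELS = ("T3", "T4", "T5", "T6")


@dataclass
class EEGConfig:
    """Synthetic EEG block: signal composition and feature-noise model.

    ``feature_noise_sd_hz`` is the per-visit noise of the extracted alpha
    feature; ``within_subject_corr`` is the pre/post correlation of that
    noise (a stable subject-level offset), reflecting the high test–retest
    reliability of the individual alpha frequency.
    """

    duration_s: float = 360.0
    n_channels: int = 19
    fs_hz: float = 256.0
    alpha_age_slope: float = -0.03  # Hz per year of brain age
    alpha_anchor_hz: float = 10.8  # feature at BBA = 16 y
    alpha_amp_uv: float = 20.0
    pink_noise_exponent: float = 1.0
    pink_noise_amp_uv: float = 4.0  # background sd
    line_noise_amp_uv: float = 2.0
    artifact_rate_per_min: float = 2.0
    feature_noise_sd_hz: float = 0.05
    within_subject_corr: float = 0.8

    def validate(self, segment_s: float = 2.0):
        if self.fs_hz <= 0:
            raise ConfigurationError("eeg.fs_hz must be positive")
        if self.duration_s <= segment_s:
            raise ConfigurationError("eeg.duration_s must exceed the segment length")
        if self.alpha_age_slope > 0:
            raise ConfigurationError("eeg.alpha_age_slope must be <= 0 (alpha slows with age)")
        if not 0 <= self.within_subject_corr <= 1:
            raise ConfigurationError("eeg.within_subject_corr must be in [0, 1]")
        if self.feature_noise_sd_hz < 0:
            raise ConfigurationError("eeg.feature_noise_sd_hz must be >= 0")
        if self.artifact_rate_per_min < 0:
            raise ConfigurationError("eeg.artifact_rate_per_min must be >= 0")
        for bba in BBA_BOUNDS:
            f = self.alpha_anchor_hz + self.alpha_age_slope * (bba - BBA_BOUNDS[0])
            if not (ALPHA_BAND[0] < f < ALPHA_BAND[1]):
                raise ConfigurationError(
                    f"eeg.alpha_anchor_hz/alpha_age_slope map BBA={bba} to {f:.2f} Hz, "
                    f"outside the open analysis band {ALPHA_BAND}"
                )


@dataclass
class ArmConfig:
    """One intervention arm: demographics, baseline gaps, true effects.

    Effects are post−pre changes of the true BBA in years (negative =
    rejuvenation), specified separately for the older-brain (baseline
    BBA > CA) and younger-brain stratum.
    """

    name: str
    n_subjects: int
    ca_mean: float
    ca_sd: float
    female_fraction: float
    baseline_gap_mean: float
    baseline_gap_sd: float
    effect_mean_older_stratum: float
    effect_mean_younger_stratum: float
    effect_sd: float
    followup_mean_months: float
    followup_sd_months: float
    gap_model: str = "normal"  # "normal" | "stratified"
    older_fraction: float | None = None  # stratified model: P(baseline gap > 0)
    gap_anchor_older: float = 9.2  # years; stratified component anchors
    gap_anchor_younger: float = -15.4
    gap_sd_older: float = 7.73
    gap_sd_younger: float = 9.24
    symptom_rate_pre: float = 0.0
    symptom_rate_post: float = 0.0

    def validate(self):
        if self.n_subjects < 1:
            raise ConfigurationError(f"arm '{self.name}': n_subjects must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigurationError(f"arm '{self.name}': female_fraction must be in [0, 1]")
        if self.ca_sd < 0:
            raise ConfigurationError(f"arm '{self.name}': ca_sd must be >= 0")
        if not CA_BOUNDS[0] <= self.ca_mean <= CA_BOUNDS[1]:
            raise ConfigurationError(
                f"arm '{self.name}': ca_mean outside the study span {CA_BOUNDS}"
            )
        if self.baseline_gap_sd < 0:
            raise ConfigurationError(f"arm '{self.name}': baseline_gap_sd must be >= 0")
        if self.effect_sd < 0:
            raise ConfigurationError(f"arm '{self.name}': effect_sd must be >= 0")
        if self.followup_sd_months < 0:
            raise ConfigurationError(f"arm '{self.name}': followup_sd_months must be >= 0")
        if self.gap_model not in ("normal", "stratified"):
            raise ConfigurationError(f"arm '{self.name}': unknown gap_model {self.gap_model!r}")
        if self.gap_model == "stratified":
            if self.older_fraction is None or not 0 < self.older_fraction < 1:
                raise ConfigurationError(
                    f"arm '{self.name}': stratified gap model needs older_fraction in (0, 1)"
                )
            if self.gap_sd_older <= 0 or self.gap_sd_younger <= 0:
                raise ConfigurationError(
                    f"arm '{self.name}': stratified gap SDs must be positive"
                )
        for fld in ("symptom_rate_pre", "symptom_rate_post"):
            if not 0 <= getattr(self, fld) <= 1:
                raise ConfigurationError(f"arm '{self.name}': {fld} must be in [0, 1]")


@dataclass
class GeneratorConfig:
    """Full cohort generator configuration: arms, EEG block, seed, fidelity."""

    arms: tuple
    eeg: EEGConfig = field(default_factory=EEGConfig)
    seed: int = 0
    fidelity: str = "feature"  # "feature" | "signal"

    def validate(self):
        if not self.arms:
            raise ConfigurationError("arms must be non-empty")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ConfigurationError("arm names must be unique")
        for arm in self.arms:
            arm.validate()
        if self.fidelity not in ("feature", "signal"):
            raise ConfigurationError(f"unknown fidelity {self.fidelity!r}")
        self.eeg.validate()


def alpha_frequency(true_bba, eeg: EEGConfig):
    """Map true brain age (years) to the alpha feature (Hz); band-checked."""
    f = eeg.alpha_anchor_hz + eeg.alpha_age_slope * (np.asarray(true_bba, float) - BBA_BOUNDS[0])
    if np.any(f <= ALPHA_BAND[0]) or np.any(f >= ALPHA_BAND[1]):
        raise ConfigurationError(
            "alpha_anchor_hz/alpha_age_slope map the requested brain age outside "
            f"the open analysis band {ALPHA_BAND}"
        )
    return f if f.shape else float(f)


# ---------------------------------------------------------------------------
# baseline gap models


def _truncnorm_mean(mu, sd, lo, hi):
    """Mean of N(mu, sd) truncated to [lo, hi] (vectorized, numerically safe)."""
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    num = st.norm.pdf(a) - st.norm.pdf(b)
    den = st.norm.cdf(b) - st.norm.cdf(a)
    den = np.where(den <= 0, np.nan, den)
    return mu + sd * num / den


def _ca_quadrature(arm: ArmConfig, n_nodes: int = 64):
    """Nodes and normalized weights for expectations over the CA distribution."""
    if arm.ca_sd == 0:
        return np.array([arm.ca_mean]), np.array([1.0])
    x, w = leggauss(n_nodes)
    lo, hi = CA_BOUNDS
    nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    weights = w * st.norm.pdf(nodes, arm.ca_mean, arm.ca_sd)
    return nodes, weights / weights.sum()


def _stratified_shift(arm: ArmConfig) -> float:
    """Common location shift of the stratified gap components.

    Solved so that the realized mean gap — a mixture of the older component
    truncated to (0, 100−CA] and the younger component truncated to
    [16−CA, 0], integrated over the CA distribution — equals
    ``baseline_gap_mean``.
    """
    nodes, weights = _ca_quadrature(arm)
    lo_b, hi_b = BBA_BOUNDS
    p = arm.older_fraction

    def realized_mean(delta):
        m_old = _truncnorm_mean(arm.gap_anchor_older + delta, arm.gap_sd_older, 0.0, hi_b - nodes)
        m_young = _truncnorm_mean(
            arm.gap_anchor_younger + delta, arm.gap_sd_younger, lo_b - nodes, 0.0
        )
        return float(np.sum(weights * (p * m_old + (1 - p) * m_young)))

    try:
        return optimize.brentq(
            lambda d: realized_mean(d) - arm.baseline_gap_mean, -40.0, 40.0, xtol=1e-10
        )
    except ValueError as exc:
        raise ConfigurationError(
            f"arm '{arm.name}': baseline_gap_mean {arm.baseline_gap_mean} not attainable "
            "with the configured stratified gap components"
        ) from exc


def _truncnorm_ppf(u, mu, sd, lo, hi):
    a = (np.asarray(lo) - mu) / sd
    b = (np.asarray(hi) - mu) / sd
    return st.truncnorm.ppf(u, a, b, loc=mu, scale=sd)


def _draw_gaps(arm: ArmConfig, ca: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Baseline gaps consistent with true BBA ∈ [16, 100]."""
    n = len(ca)
    lo = BBA_BOUNDS[0] - ca
    hi = BBA_BOUNDS[1] - ca
    if arm.gap_model == "normal":
        g = arm.baseline_gap_mean + arm.baseline_gap_sd * rng.standard_normal(n)
        clipped = np.clip(g, lo, hi)
        n_clip = int(np.sum(clipped != g))
        if n_clip > 0.01 * n:
            warnings.warn(
                f"arm '{arm.name}': {n_clip}/{n} baseline gaps clipped to keep "
                "true BBA in [16, 100]; the realized mean gap is shifted — "
                "consider the 'stratified' gap model"
            )
        return clipped
    delta = _stratified_shift(arm)
    older = rng.random(n) < arm.older_fraction
    u = rng.random(n)
    g = np.empty(n)
    g[older] = _truncnorm_ppf(
        u[older], arm.gap_anchor_older + delta, arm.gap_sd_older, 0.0, hi[older]
    )
    g[~older] = _truncnorm_ppf(
        u[~older], arm.gap_anchor_younger + delta, arm.gap_sd_younger, lo[~older], 0.0
    )
    return g


def expected_arm_effect(arm: ArmConfig) -> float:
    """Configured population-mean true BBA change for an arm (mixture over strata)."""
    if arm.gap_model == "stratified":
        p = arm.older_fraction
    else:
        if arm.baseline_gap_sd == 0:
            p = 1.0 if arm.baseline_gap_mean > 0 else 0.0
        else:
            p = float(st.norm.cdf(arm.baseline_gap_mean / arm.baseline_gap_sd))
    return p * arm.effect_mean_older_stratum + (1 - p) * arm.effect_mean_younger_stratum


def expected_followup_months(arm: ArmConfig) -> float:
    if arm.followup_sd_months == 0:
        return arm.followup_mean_months
    return float(
        _truncnorm_mean(arm.followup_mean_months, arm.followup_sd_months, *FOLLOWUP_BOUNDS)
    )


# ---------------------------------------------------------------------------
# cohort generation


def draw_subject_effect(eeg: EEGConfig, rng: np.random.Generator, size=None):
    """Stable per-subject feature offset (Hz), variance ρ·σ²."""
    return rng.normal(0.0, np.sqrt(eeg.within_subject_corr) * eeg.feature_noise_sd_hz, size)


def sample_feature(true_bba, eeg: EEGConfig, subject_effect: float = 0.0, rng=None):
    """Feature-fidelity observation: ``f(true_bba) + subject_effect + ε``.

    ε is the per-visit noise, N(0, √(1−ρ)·σ) with σ = ``feature_noise_sd_hz``
    and ρ = ``within_subject_corr``, so that the marginal per-visit noise
    (subject effect + ε) has sd σ and pre/post correlation ρ.
    """
    rng = np.random.default_rng() if rng is None else rng
    f = alpha_frequency(true_bba, eeg)
    eps_sd = np.sqrt(1.0 - eeg.within_subject_corr) * eeg.feature_noise_sd_hz
    return f + subject_effect + rng.normal(0.0, eps_sd, size=np.shape(true_bba) or None)


def generate_cohort(config: GeneratorConfig, seed: int | None = None):
    """Generate a two-visit cohort and its ground truth.

    Returns ``(cohort, truth)`` as long-format DataFrames with one row per
    subject-visit.  The cohort table holds the observables (CA, sex, arm,
    follow-up, symptom indicator and — at feature fidelity — the alpha
    feature); the truth table holds true BBA, true feature and stratum for
    recovery testing.  Deterministic given config + seed.
    """
    config.validate()
    entropy = config.seed if seed is None else seed
    if not isinstance(entropy, np.random.SeedSequence):
        entropy = np.random.SeedSequence(entropy)
    rng = np.random.default_rng(entropy)
    cohort_rows, truth_rows = [], []
    for arm in config.arms:
        n = arm.n_subjects
        n_female = int(round(arm.female_fraction * n))
        sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
        rng.shuffle(sex)
        if arm.ca_sd == 0:
            ca_pre = np.full(n, float(arm.ca_mean))
        else:
            ca_pre = _truncnorm_ppf(rng.random(n), arm.ca_mean, arm.ca_sd, *CA_BOUNDS)
        gap = _draw_gaps(arm, ca_pre, rng)
        stratum = np.where(gap > 0, "older", "younger")
        bba_pre = ca_pre + gap
        eff_mean = np.where(
            stratum == "older", arm.effect_mean_older_stratum, arm.effect_mean_younger_stratum
        )
        change = eff_mean + arm.effect_sd * rng.standard_normal(n)
        bba_post = np.clip(bba_pre + change, *BBA_BOUNDS)
        if arm.followup_sd_months == 0:
            followup = np.full(n, float(arm.followup_mean_months))
        else:
            followup = _truncnorm_ppf(
                rng.random(n), arm.followup_mean_months, arm.followup_sd_months, *FOLLOWUP_BOUNDS
            )
        ca_post = ca_pre + followup / 12.0

        u_subj = draw_subject_effect(config.eeg, rng, n)
        eps_sd = np.sqrt(1.0 - config.eeg.within_subject_corr) * config.eeg.feature_noise_sd_hz
        feat = {
            "pre": alpha_frequency(bba_pre, config.eeg) + u_subj + rng.normal(0, eps_sd, n),
            "post": alpha_frequency(bba_post, config.eeg) + u_subj + rng.normal(0, eps_sd, n),
        }
        symptom = {
            "pre": rng.random(n) < arm.symptom_rate_pre,
            "post": rng.random(n) < arm.symptom_rate_post,
        }
        bba = {"pre": bba_pre, "post": bba_post}
        ca = {"pre": ca_pre, "post": ca_post}
        for i in range(n):
            sid = f"{arm.name}-{i + 1:03d}"
            for visit in ("pre", "post"):
                row = {
                    "subject_id": sid,
                    "arm": arm.name,
                    "sex": sex[i],
                    "visit": visit,
                    "ca_years": ca[visit][i],
                    "followup_months": followup[i],
                    "symptom": bool(symptom[visit][i]),
                }
                if config.fidelity == "feature":
                    row["feature_hz"] = feat[visit][i]
                cohort_rows.append(row)
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "arm": arm.name,
                        "sex": sex[i],
                        "visit": visit,
                        "ca_years": ca[visit][i],
                        "true_bba": bba[visit][i],
                        "true_feature": alpha_frequency(bba[visit][i], config.eeg),
                        "followup_months": followup[i],
                        "stratum": stratum[i],
                    }
                )
    return pd.DataFrame(cohort_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# signal fidelity


def inject_artifacts(
    data: np.ndarray,
    fs_hz: float,
    channel_labels,
    rate_per_min: float,
    rng: np.random.Generator,
):
    """Add blink- and muscle-like transients at Poisson times.

    Blinks: 1–2 Hz half-sine deflections of 150–300 µV on frontal channels.
    Muscle bursts: 20–28 Hz band-limited noise, 50 µV sd, on temporal
    channels, Hann-tapered.  Returns ``(data_with_events, events)`` where
    events are ``(onset_s, duration_s, kind)``; the input array is not
    modified.
    """
    data = np.array(data, dtype=float)
    n_samples = data.shape[1]
    duration_s = n_samples / fs_hz
    labels = [l.lower() for l in channel_labels]
    if rate_per_min <= 0:
        return data, []
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    events = []
    frontal = [i for i, l in enumerate(labels) if l in {c.lower() for c in FRONTAL_CHANNELS}]
    temporal = [i for i, l in enumerate(labels) if l in {c.lower() for c in TEMPORAL_CHANNELS}]
    for _ in range(n_events):
        kind = "blink" if rng.random() < 0.5 else "muscle"
        if kind == "blink":
            f0 = rng.uniform(1.0, 2.0)
            dur = 1.0 / (2.0 * f0)
            amp = rng.uniform(150.0, 300.0)
        else:
            dur = rng.uniform(0.2, 0.5)
            amp = 50.0
        onset = rng.uniform(0.0, max(duration_s - dur, 0.0))
        i0 = int(round(onset * fs_hz))
        L = max(int(round(dur * fs_hz)), 2)
        i1 = min(i0 + L, n_samples)
        L = i1 - i0
        t = np.arange(L) / fs_hz
        if kind == "blink":
            wave = amp * np.sin(np.pi * t / dur)
            rows, gains = frontal, [1.0 if labels[i].startswith("fp") else 0.6 for i in frontal]
        else:
            white = rng.standard_normal(L + 64)
            sos = sps.butter(4, [20.0, 28.0], btype="bandpass", fs=fs_hz, output="sos")
            band = sps.sosfiltfilt(sos, white)[32 : 32 + L]
            band = band / max(band.std(), 1e-12) * amp
            wave = band * np.hanning(L)
            rows, gains = temporal, [1.0] * len(temporal)
        for r, g in zip(rows, gains):
            data[r, i0:i1] += g * wave
        events.append((float(onset), float(dur), kind))
    events.sort(key=lambda e: e[0])
    return data, events


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_recording(
    true_bba: float,
    eeg: EEGConfig,
    rng=None,
    subject_id: str = "",
    visit: str = "",
) -> Recording:
    """Signal-fidelity recording whose alpha rhythm encodes ``true_bba``.

    Per channel: an alpha oscillation at ``f(true_bba)`` with slow random
    amplitude modulation (posterior channels twice the anterior amplitude),
    plus a 1/f^β background, a 50 Hz line component and injected artifacts.
    Injected artifact events are stored in ``Recording.annotations`` as
    ``(onset_s, duration_s, "artifact/<kind>")`` for truth-based testing.
    """
    rng = np.random.default_rng() if rng is None else rng
    eeg.validate()
    if eeg.n_channels != len(STANDARD_1020):
        raise ConfigurationError("eeg.n_channels must be 19 (the study montage)")
    f0 = alpha_frequency(float(true_bba), eeg)
    fs = eeg.fs_hz
    n = int(round(eeg.duration_s * fs))
    t = np.arange(n) / fs
    posterior = {c.lower() for c in POSTERIOR_ELECTRODES}
    sos_slow = sps.butter(2, 0.2, btype="lowpass", fs=fs, output="sos")
    data = np.empty((len(STANDARD_1020), n))
    for i, lab in enumerate(STANDARD_1020):
        gain = 1.0 if lab.lower() in posterior else 0.4
        mod = sps.sosfiltfilt(sos_slow, rng.standard_normal(n))
        sd = mod.std()
        mod = mod / sd if sd > 0 else mod
        am = np.clip(1.0 + 0.3 * mod, 0.1, None)
        phase = rng.uniform(0, 2 * np.pi)
        x = eeg.alpha_amp_uv * gain * am * np.sin(2 * np.pi * f0 * t + phase)
        if eeg.pink_noise_amp_uv > 0:
            x = x + eeg.pink_noise_amp_uv * _pink_noise(n, eeg.pink_noise_exponent, rng)
        if eeg.line_noise_amp_uv > 0:
            x = x + eeg.line_noise_amp_uv * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        data[i] = x
    data, events = inject_artifacts(data, fs, STANDARD_1020, eeg.artifact_rate_per_min, rng)
    return Recording(
        data=data,
        channel_labels=STANDARD_1020,
        fs_hz=fs,
        subject_id=subject_id,
        visit=visit,
        annotations=[(on, du, f"artifact/{kind}") for on, du, kind in events],
    )


# ---------------------------------------------------------------------------
# shipped profiles


def _arm_from_dict(d: dict) -> ArmConfig:
    return ArmConfig(**d)


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a plain dict (YAML/JSON layout)."""
    arms = tuple(_arm_from_dict(a) for a in d["arms"])
    eeg = EEGConfig(**d.get("eeg", {}))
    cfg = GeneratorConfig(
        arms=arms,
        eeg=eeg,
        seed=int(d.get("seed", 0)),
        fidelity=d.get("fidelity", "feature"),
    )
    cfg.validate()
    return cfg


def load_profile(name_or_path) -> GeneratorConfig:
    """Load a generator profile: a shipped name (``"study"``) or a YAML path."""
    ref = resources.files("neuroage").joinpath(f"profiles/{name_or_path}.yaml")
    if ref.is_file():
        text = ref.read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return config_from_dict(yaml.safe_load(text))


def study_profile(seed: int = 0, fidelity: str = "feature") -> GeneratorConfig:
    """The shipped study profile (both arms, printed demographics and effects)."""
    cfg = load_profile("study")
    return replace(cfg, seed=seed, fidelity=fidelity)


def zero_effect_profile(seed: int = 0) -> GeneratorConfig:
    """The study profile with all true intervention effects set to zero."""
    cfg = study_profile(seed=seed)
    arms = tuple(
        replace(a, effect_mean_older_stratum=0.0, effect_mean_younger_stratum=0.0)
        for a in cfg.arms
    )
    return replace(cfg, arms=arms)
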