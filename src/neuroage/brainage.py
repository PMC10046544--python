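"""Alpha-band age feature, linear brain-age calibration, and brain resources.

The age-dependent qEEG feature is the alpha-band (7–13 Hz) center-of-gravity
frequency — a robust estimator of the individual alpha frequency that slows
with age — averaged over a posterior electrode set.  A linear regression of
chronological age (CA) on this feature, fitted on a reference cohort, turns a
feature value into a brain biological age (BBA).  Derived scores:

* brain-age gap  = BBA − CA (negative ⇒ younger/decelerated brain),
* brain resources BR = 100·(CA − BBA)/(100 − 16), a percentage of the
  meaningful adult age span (16 y ≈ EEG maturation, 100 y ≈ practical
  maximum); positive BR means a younger brain phenotype.

The calibration model is exposed as a scikit-learn compatible regressor so it
composes with sklearn pipelines and model selection; the module-level
functions are thin wrappers around it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateFitError
from .spectral import PowerSpectrum

ALPHA_BAND = (7.0, 13.0)
#: Default electrode set: posterior sites carrying the dominant alpha rhythm.
POSTERIOR_ELECTRODES = ("O1", "O2", "P3", "P4", "Pz", "T5", "T6")
AGE_RANGE = (16.0, 100.0)
BR_DENOMINATOR = AGE_RANGE[1] - AGE_RANGE[0]  # 84 years


@dataclass
class AlphaFeature:
    """Alpha center-of-gravity frequency, per channel and electrode-set mean."""

    value_hz: float
    per_channel: dict
    electrode_set: tuple
    band: tuple = ALPHA_BAND


def _cog(freqs: np.ndarray, power: np.ndarray) -> float:
    total = power.sum()
    if total <= 0:
        return np.nan
    return float((freqs * power).sum() / total)


def extract_alpha_feature(
    spectrum: PowerSpectrum,
    band: tuple = ALPHA_BAND,
    electrodes: tuple = POSTERIOR_ELECTRODES,
) -> AlphaFeature:
    """Alpha-band spectral center of gravity, averaged over ``electrodes``.

    Per channel, ``f_cog = Σ f·P(f) / Σ P(f)`` over bins with
    ``band[0] ≤ f ≤ band[1]`` inclusive.  Channels with zero band power are
    excluded with a warning; if all are excluded a ValueError is raised.
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError("band edges inverted")
    if hi > spectrum.freqs_hz[-1] + 1e-9:
        raise ValueError("band exceeds spectrum range")
    have = {l.lower(): i for i, l in enumerate(spectrum.channel_labels)}
    missing = [e for e in electrodes if e.lower() not in have]
    if missing:
        raise ValueError(f"electrodes not in spectrum: {missing}")
    sel = spectrum.band_slice(lo, hi)
    freqs = spectrum.freqs_hz[sel]
    per_channel = {}
    for e in electrodes:
        v = _cog(freqs, spectrum.power[have[e.lower()], sel])
        if np.isnan(v):
            warnings.warn(f"channel {e}: zero alpha-band power, excluded from feature")
        else:
            per_channel[e] = v
    if not per_channel:
        raise ValueError("all electrodes have zero alpha-band power")
    return AlphaFeature(
        value_hz=float(np.mean(list(per_channel.values()))),
        per_channel=per_channel,
        electrode_set=tuple(per_channel),
        band=(lo, hi),
    )


class AlphaFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a sequence of :class:`PowerSpectrum` to an (n, 1)
    array of alpha center-of-gravity frequencies (Hz)."""

    def __init__(self, band: tuple = ALPHA_BAND, electrodes: tuple = POSTERIOR_ELECTRODES):
        self.band = band
        self.electrodes = electrodes

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        vals = [
            extract_alpha_feature(s, band=self.band, electrodes=self.electrodes).value_hz
            for s in X
        ]
        return np.asarray(vals, dtype=float).reshape(-1, 1)


@dataclass
class CalibrationModel:
    """Serialized form of a fitted feature→CA linear calibration."""

    slope: float  # years per Hz
    intercept: float  # years
    n_train: int
    feature_range: tuple  # (min, max) Hz seen in training
    fit_residual_sd: float  # years

    def to_json(self, path=None) -> str:
        d = {
            "slope_years_per_hz": self.slope,
            "intercept_years": self.intercept,
            "n_train": self.n_train,
            "feature_range_hz": list(self.feature_range),
            "fit_residual_sd_years": self.fit_residual_sd,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "CalibrationModel":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(
            slope=d["slope_years_per_hz"],
            intercept=d["intercept_years"],
            n_train=d["n_train"],
            feature_range=tuple(d["feature_range_hz"]),
            fit_residual_sd=d["fit_residual_sd_years"],
        )


class BrainAgeRegressor(RegressorMixin, BaseEstimator):
    """Linear brain-age model: ordinary least squares of CA on the alpha feature.

    Predictions are clamped to the meaningful age range [16, 100].  Fitted
    attributes: ``slope_`` (y/Hz), ``intercept_`` (y), ``residual_sd_`` (y),
    ``n_train_``, ``feature_range_``.
    """

    def __init__(self, clamp_range: tuple = AGE_RANGE):
        self.clamp_range = clamp_range

    @staticmethod
    def _as_feature_array(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single feature column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-d or (n, 1)")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        return X

    def fit(self, X, y):
        f = self._as_feature_array(X)
        y = np.asarray(y, dtype=float)
        if f.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if f.shape[0] < 3:
            raise DegenerateFitError(f"need at least 3 training points, got {f.shape[0]}")
        if np.ptp(f) == 0:
            raise DegenerateFitError("constant feature: calibration slope undefined")
        A = np.column_stack([f, np.ones_like(f)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1])
        resid = y - A @ coef
        dof = max(len(y) - 2, 1)
        self.residual_sd_ = float(np.sqrt((resid ** 2).sum() / dof))
        self.n_train_ = int(len(y))
        self.feature_range_ = (float(f.min()), float(f.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        f = self._as_feature_array(X)
        raw = self.intercept_ + self.slope_ * f
        return np.clip(raw, *self.clamp_range)

    def to_model(self) -> CalibrationModel:
        check_is_fitted(self, "slope_")
        return CalibrationModel(
            slope=self.slope_,
            intercept=self.intercept_,
            n_train=self.n_train_,
            feature_range=self.feature_range_,
            fit_residual_sd=self.residual_sd_,
        )

    @classmethod
    def from_model(cls, model: CalibrationModel) -> "BrainAgeRegressor":
        est = cls()
        est.slope_ = model.slope
        est.intercept_ = model.intercept
        est.residual_sd_ = model.fit_residual_sd
        est.n_train_ = model.n_train
        est.feature_range_ = tuple(model.feature_range)
        est.n_features_in_ = 1
        return est


def fit_calibration(features, cas) -> CalibrationModel:
    """OLS fit of chronological age on the alpha feature (wrapper)."""
    return BrainAgeRegressor().fit(np.asarray(features, dtype=float), cas).to_model()


@dataclass
class BBAResult:
    """Scored subject-visit: brain age, gap, brain resources, quality flags."""

    bba_years: float
    ca_years: float
    gap_years: float
    br_percent: float
    clamped: bool
    confidence_flags: tuple

    def to_dict(self) -> dict:
        return {
            "bba_years": self.bba_years,
            "ca_years": self.ca_years,
            "gap_years": self.gap_years,
            "br_percent": self.br_percent,
            "clamped": self.clamped,
            "confidence_flags": list(self.confidence_flags),
        }


def compute_br(ca: float, bba: float) -> float:
    """Brain resources: BR = 100·(CA − BBA)/84, both ages within [16, 100]."""
    lo, hi = AGE_RANGE
    if not (lo <= ca <= hi):
        raise ValueError(f"CA {ca} outside [{lo}, {hi}]")
    if not (lo <= bba <= hi):
        raise ValueError(f"BBA {bba} outside [{lo}, {hi}]")
    return 100.0 * (ca - bba) / BR_DENOMINATOR


def predict_bba(model, feature, ca: float, extra_flags=()) -> BBAResult:
    """Score one subject-visit with a fitted calibration.

    ``model`` may be a :class:`CalibrationModel` or a fitted
    :class:`BrainAgeRegressor`; ``feature`` an :class:`AlphaFeature` or Hz
    value.  The prediction is clamped to [16, 100] (flag ``clamped``) and a
    feature outside the training range raises the ``extrapolation`` flag.
    """
    if isinstance(model, CalibrationModel):
        est = BrainAgeRegressor.from_model(model)
    else:
        est = model
        check_is_fitted(est, "slope_")
    f = feature.value_hz if isinstance(feature, AlphaFeature) else float(feature)
    raw = est.intercept_ + est.slope_ * f
    lo, hi = est.clamp_range if hasattr(est, "clamp_range") else AGE_RANGE
    bba = float(np.clip(raw, lo, hi))
    flags = list(extra_flags)
    clamped = bba != raw
    if clamped:
        flags.append("clamped")
    fmin, fmax = est.feature_range_
    if not (fmin <= f <= fmax):
        flags.append("extrapolation")
    return BBAResult(
        bba_years=bba,
        ca_years=float(ca),
        gap_years=bba - float(ca),
        br_percent=compute_br(float(np.clip(ca, lo, hi)), bba),
        clamped=clamped,
        confidence_flags=tuple(flags),
    )


def classify_trajectory(pre: BBAResult, post: BBAResult, tol_years: float = 0.25) -> str:
    """Label a pre→post trajectory.

    ``rejuvenation``: BBA decreased; ``deceleration``: BBA rose more slowly
    than CA; ``normal``: BBA tracked CA within ``tol_years``;
    ``acceleration``: BBA rose faster than CA.
    """
    d_ca = post.ca_years - pre.ca_years
    if d_ca <= 0:
        raise ValueError("post visit CA must exceed pre visit CA")
    d_bba = post.bba_years - pre.bba_years
    if d_bba < 0:
        return "rejuvenation"
    if abs(d_bba - d_ca) <= tol_years:
        return "normal"
    if d_bba < d_ca:
        return "deceleration"
    return "acceleration"
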