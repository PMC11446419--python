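"""The 22 statistical features of a preprocessed reflectance trace.

Fourteen time-domain statistics treat the reflectance trace as an ordered
signal over wavelength: moments (mean, variance with n−1 denominator, SD,
skewness and non-excess kurtosis on population 1/n moments), extremes
(max, min, peak-to-peak), energy (RMS, power = mean square) and the
crest/form/pulse/margin shape-factor family:

    crest  = max / RMS
    form   = RMS / mean
    pulse  = max / mean
    margin = max / ((1/n) Σ √|s_i|)²

Eight frequency-domain statistics summarize the band power spectrum — the
squared magnitudes of the real-input discrete Fourier transform of the
trace (one-sided, unnormalized, DC included): mean, variance (m−1), SD,
max, sum, skewness, kurtosis (both population moments over variance
powers) and the relative spectral peak max/mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import Spectrum
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "time_domain_features",
    "band_power_spectrum",
    "frequency_domain_features",
    "extract_all",
    "standardize_features",
    "FeatureScaler",
]

FEATURE_NAMES = (
    "s_mean", "s_var", "s_sd", "s_max", "s_min", "s_p2p", "s_rms",
    "s_power", "s_crest", "s_skew", "s_kurt", "s_form", "s_pulse",
    "s_margin",
    "f_mean", "f_var", "f_sd", "f_max", "f_sum", "f_skew", "f_kurt",
    "f_rsp",
)


@dataclass(frozen=True)
class FeatureVector:
    """All 22 statistics of one spectrum, keyed by sample id."""

    sample_id: str
    s_mean: float
    s_var: float
    s_sd: float
    s_max: float
    s_min: float
    s_p2p: float
    s_rms: float
    s_power: float
    s_crest: float
    s_skew: float
    s_kurt: float
    s_form: float
    s_pulse: float
    s_margin: float
    f_mean: float
    f_var: float
    f_sd: float
    f_max: float
    f_sum: float
    f_skew: float
    f_kurt: float
    f_rsp: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def time_domain_features(reflectance: np.ndarray) -> dict[str, float]:
    """The 14 time-domain statistics of an ordered signal (n ≥ 3)."""
    s = np.asarray(reflectance, dtype=float)
    if s.ndim != 1 or len(s) < 3:
        raise ValidationError(f"need a 1-D signal with n >= 3, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValidationError("non-finite values in signal")
    n = len(s)
    mean = s.mean()
    dev = s - mean
    var = float(np.dot(dev, dev) / (n - 1))
    sd = np.sqrt(var)
    smax, smin = float(s.max()), float(s.min())
    power = float(np.dot(s, s) / n)
    rms = np.sqrt(power)
    if sd == 0:
        raise DegenerateInputError("constant signal: skewness and kurtosis undefined (SD = 0)")
    if mean == 0:
        raise DegenerateInputError("zero-mean signal: form and pulse factors undefined")
    root_abs_mean = float(np.mean(np.sqrt(np.abs(s))))
    if root_abs_mean == 0:
        raise DegenerateInputError("all-zero signal: margin factor undefined")
    return {
        "s_mean": float(mean),
        "s_var": var,
        "s_sd": float(sd),
        "s_max": smax,
        "s_min": smin,
        "s_p2p": smax - smin,
        "s_rms": float(rms),
        "s_power": power,
        "s_crest": smax / float(rms),
        "s_skew": float(np.mean(dev**3) / sd**3),
        "s_kurt": float(np.mean(dev**4) / sd**4),
        "s_form": float(rms / mean),
        "s_pulse": smax / float(mean),
        "s_margin": smax / root_abs_mean**2,
    }


def band_power_spectrum(reflectance: np.ndarray) -> np.ndarray:
    """One-sided periodogram of the signal: |DFT(s)_i|² for i = 0..⌊n/2⌋.

    Unnormalized real-input DFT; the zero-frequency (DC) term is included,
    so the result has ⌊n/2⌋ + 1 non-negative values.
    """
    s = np.asarray(reflectance, dtype=float)
    if s.ndim != 1 or len(s) < 4:
        raise ValidationError(f"need a 1-D signal with n >= 4, got shape {s.shape}")
    return np.abs(np.fft.rfft(s)) ** 2


def frequency_domain_features(f: np.ndarray) -> dict[str, float]:
    """The 8 statistics of a band power spectrum (length m ≥ 3)."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or len(f) < 3:
        raise ValidationError(f"need a 1-D power spectrum with m >= 3, got shape {f.shape}")
    m = len(f)
    mean = f.mean()
    dev = f - mean
    var = float(np.dot(dev, dev) / (m - 1))
    if var == 0:
        raise DegenerateInputError("zero-variance power spectrum: skewness and kurtosis undefined")
    if mean == 0:
        raise DegenerateInputError("zero-mean power spectrum: relative spectral peak undefined")
    return {
        "f_mean": float(mean),
        "f_var": var,
        "f_sd": float(np.sqrt(var)),
        "f_max": float(f.max()),
        "f_sum": float(f.sum()),
        "f_skew": float(np.mean(dev**3) / var**1.5),
        "f_kurt": float(np.mean(dev**4) / var**2),
        "f_rsp": float(f.max() / mean),
    }


def extract_all(spectra: list[Spectrum]) -> list[FeatureVector]:
    """Per-sample FeatureVector for every spectrum, order-preserving."""
    out: list[FeatureVector] = []
    for s in spectra:
        try:
            td = time_domain_features(s.reflectance)
            fd = frequency_domain_features(band_power_spectrum(s.reflectance))
        except (DegenerateInputError, ValidationError) as exc:
            raise type(exc)(f"sample {s.sample_id}: {exc}") from exc
        out.append(FeatureVector(sample_id=s.sample_id, **td, **fd))
    return out


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature z-score parameters estimated on a training set.

    Uses the population (1/n) SD convention; constant features are mapped
    to zero with a logged warning.
    """

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def transform(self, X: np.ndarray) -> np.ndarray:
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        Z = (np.asarray(X, dtype=float) - self.mean) / safe_sd
        Z[:, self.sd == 0] = 0.0
        return Z

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }


def fit_scaler(X: np.ndarray, feature_names: tuple[str, ...] = FEATURE_NAMES) -> FeatureScaler:
    """Estimate z-score parameters on a training matrix (rows = samples)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValidationError("cannot fit a scaler on an empty training set")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    if np.any(sd == 0):
        bad = [feature_names[i] for i in np.flatnonzero(sd == 0) if i < len(feature_names)]
        logger.warning("zero-variance features scaled to 0: %s", bad)
    return FeatureScaler(mean=mean, sd=sd, feature_names=feature_names)


def standardize_features(
    train: list[FeatureVector],
    apply_to: list[FeatureVector] | None = None,
) -> tuple[np.ndarray, FeatureScaler]:
    """Z-score scaling with mean/SD estimated on ``train`` only.

    Returns the scaled matrix for ``apply_to`` (default: ``train`` itself)
    and the fitted scaler for reuse on held-out data.
    """
    if not train:
        raise ValidationError("train must be non-empty")
    X_train = np.vstack([fv.as_array() for fv in train])
    scaler = fit_scaler(X_train)
    targets = apply_to if apply_to is not None else train
    if not targets:
        return np.empty((0, len(FEATURE_NAMES))), scaler
    X = np.vstack([fv.as_array() for fv in targets])
    return scaler.transform(X), scaler


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, list[str]]:
    """Stack FeatureVectors into an (n, 22) matrix plus the sample-id order."""
    if not features:
        return np.empty((0, len(FEATURE_NAMES))), []
    X = np.vstack([fv.as_array() for fv in features])
    ids = [fv.sample_id for fv in features]
    return X, ids
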