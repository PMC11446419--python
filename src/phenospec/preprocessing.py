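"""Spectral preprocessing: wavelength subsampling, multiplicative scatter
correction (MSC), z-score outlier removal and cut-wise group comparison.

MSC regresses each sample's spectrum onto a reference spectrum by ordinary
least squares over bands, ``s ≈ a·ref + b``, and corrects with
``(s − b) / a``, removing per-sample additive and multiplicative scatter.
Outlier removal z-scores one scalar summary per record (its mean
reflectance across bands) and eliminates records beyond ±z_limit in a
single pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Spectrum
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "subsample_wavelengths",
    "msc_correct",
    "remove_outliers",
    "compare_cuts",
]

_SLOPE_TOL = 1e-8


@dataclass
class PreprocessReport:
    """Bookkeeping for a preprocessing stage.

    ``per_sample_fit`` holds the MSC (slope, offset) per sample;
    ``removed_ids`` lists eliminated sample ids with the z-score that
    triggered removal; ``decision`` records the scalar-summary convention
    used for z-scoring.
    """

    reference_spectrum: Spectrum | None = None
    per_sample_fit: dict[str, tuple[float, float]] = field(default_factory=dict)
    removed_ids: list[tuple[str, float]] = field(default_factory=list)
    retained_count: int = 0
    decision: str = ""

    def to_dict(self) -> dict:
        return {
            "per_sample_fit": {k: list(v) for k, v in self.per_sample_fit.items()},
            "removed_ids": [[sid, z] for sid, z in self.removed_ids],
            "retained_count": self.retained_count,
            "decision": self.decision,
        }


def subsample_wavelengths(spectrum: Spectrum, step_nm: float) -> Spectrum:
    """Retain bands at a regular ``step_nm`` interval starting from the
    first wavelength; metadata is preserved.

    ``step_nm`` must be a positive integer multiple of the native grid
    spacing (which must itself be regular).
    """
    wl = spectrum.wavelengths_nm
    if len(wl) < 2:
        return spectrum
    native = np.diff(wl)
    native_step = float(native[0])
    if not np.allclose(native, native_step):
        raise ValidationError(f"{spectrum.sample_id}: native wavelength grid is irregular")
    if step_nm < native_step:
        raise ValidationError(
            f"step_nm {step_nm} is below the native spacing {native_step}"
        )
    ratio = step_nm / native_step
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(
            f"step_nm {step_nm} is not a multiple of the native spacing {native_step}"
        )
    stride = int(round(ratio))
    return Spectrum(
        sample_id=spectrum.sample_id,
        cultivar=spectrum.cultivar,
        cut=spectrum.cut,
        wavelengths_nm=wl[::stride],
        reflectance=spectrum.reflectance[::stride],
        meta=dict(spectrum.meta),
    )


def msc_correct(
    spectra: list[Spectrum],
    reference: Spectrum | str = "mean",
) -> tuple[list[Spectrum], PreprocessReport]:
    """Multiplicative scatter correction against a common reference.

    For each sample, fit ``s ≈ a·ref + b`` by OLS over bands and return the
    corrected spectrum ``(s − b) / a``.  ``reference="mean"`` (the default,
    standard MSC) uses the band-wise mean of the input set.
    """
    if len(spectra) < 2:
        raise ValidationError("MSC requires at least 2 spectra")
    grids = {tuple(s.wavelengths_nm.tolist()) for s in spectra}
    if len(grids) != 1:
        raise ValidationError("MSC requires all spectra on a common wavelength grid")

    X = np.vstack([s.reflectance for s in spectra])
    if isinstance(reference, str):
        if reference != "mean":
            raise ValidationError(f"unknown reference mode {reference!r}")
        ref_vals = X.mean(axis=0)
        ref_spec = Spectrum(
            sample_id="msc_mean_reference",
            cultivar="REF",
            cut=0,
            wavelengths_nm=spectra[0].wavelengths_nm,
            reflectance=ref_vals,
        )
    else:
        ref_spec = reference
        ref_vals = np.asarray(reference.reflectance, dtype=float)
        if len(ref_vals) != X.shape[1]:
            raise ValidationError("reference grid does not match the input spectra")

    ref_centered = ref_vals - ref_vals.mean()
    denom = float(np.dot(ref_centered, ref_centered))
    if denom <= 0:
        raise ValidationError("zero-variance MSC reference")

    report = PreprocessReport(reference_spectrum=ref_spec)
    corrected: list[Spectrum] = []
    for s in spectra:
        y = s.reflectance
        a = float(np.dot(ref_centered, y - y.mean()) / denom)
        b = float(y.mean() - a * ref_vals.mean())
        if abs(a) < _SLOPE_TOL:
            raise ValidationError(
                f"MSC slope below tolerance ({a:.2e}) for sample {s.sample_id}"
            )
        report.per_sample_fit[s.sample_id] = (a, b)
        corrected.append(s.with_reflectance(np.clip((y - b) / a, 0.0, None)))
    report.retained_count = len(corrected)
    return corrected, report


def remove_outliers(
    spectra: list[Spectrum],
    z_limit: float = 3.0,
) -> tuple[list[Spectrum], PreprocessReport]:
    """Single-pass z-score outlier filter over per-record mean reflectance.

    One scalar summary per record (mean reflectance across bands) is
    z-scored over records; records with |z| > ``z_limit`` are removed.
    If the summaries have zero variance nothing is removed and a warning
    is logged.
    """
    if len(spectra) < 3:
        raise ValidationError("outlier removal requires at least 3 spectra")
    summaries = np.array([s.reflectance.mean() for s in spectra])
    sd = summaries.std(ddof=1)
    report = PreprocessReport(
        decision="summary = per-record mean reflectance; sample SD (n-1); single pass"
    )
    if sd == 0:
        logger.warning("zero variance of record summaries; no outliers removed")
        report.retained_count = len(spectra)
        return list(spectra), report
    z = (summaries - summaries.mean()) / sd
    retained: list[Spectrum] = []
    for s, zi in zip(spectra, z):
        if abs(zi) > z_limit:
            report.removed_ids.append((s.sample_id, float(zi)))
        else:
            retained.append(s)
    report.retained_count = len(retained)
    return retained, report


def compare_cuts(spectra: list[Spectrum]) -> pd.DataFrame:
    """Pairwise Welch t-tests of per-sample mean reflectance between cuts.

    Returns a DataFrame with columns ``cut_i, cut_j, t, p`` (two-sided),
    one row per unordered cut pair with at least 2 samples on each side;
    underpopulated pairs are skipped with a warning.
    """
    by_cut: dict[int, list[float]] = {}
    for s in spectra:
        by_cut.setdefault(s.cut, []).append(float(s.reflectance.mean()))
    cuts = sorted(by_cut)
    if len(cuts) < 2:
        raise ValidationError("compare_cuts requires at least 2 cuts present")
    rows = []
    for i, ci in enumerate(cuts):
        for cj in cuts[i + 1:]:
            if len(by_cut[ci]) < 2 or len(by_cut[cj]) < 2:
                logger.warning("skipping cut pair (%s, %s): fewer than 2 samples", ci, cj)
                continue
            t, p = stats.ttest_ind(by_cut[ci], by_cut[cj], equal_var=False)
            rows.append({"cut_i": ci, "cut_j": cj, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows, columns=["cut_i", "cut_j", "t", "p"])
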