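"""CSV/JSON/YAML interchange for spectra, phenolics, features and reports.

Spectra travel in a wide CSV: ``sample_id, cultivar, cut`` followed by one
``wl_<nm>`` column per wavelength in ascending order.  Phenolics use
``sample_id, tpc_mg_gae_gdw``.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import PhenolicRecord, Spectrum
from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_phenolics_csv",
    "write_phenolics_csv",
    "write_features_csv",
    "read_features_csv",
]

_WL_RE = re.compile(r"^wl_(\d+(?:\.\d+)?)$")
_META_COLS = ("sample_id", "cultivar", "cut")


def write_spectra_csv(spectra: list[Spectrum], path: str | Path) -> None:
    """Wide spectra CSV: sample_id, cultivar, cut, wl_<nm>, ..."""
    if not spectra:
        pd.DataFrame(columns=list(_META_COLS)).to_csv(path, index=False)
        return
    wl = spectra[0].wavelengths_nm
    for s in spectra:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise ValidationError(f"{s.sample_id}: wavelength grid differs from the first spectrum")
    cols = [f"wl_{int(w) if float(w).is_integer() else w}" for w in wl]
    df = pd.DataFrame([s.reflectance for s in spectra], columns=cols)
    df.insert(0, "cut", [s.cut for s in spectra])
    df.insert(0, "cultivar", [s.cultivar for s in spectra])
    df.insert(0, "sample_id", [s.sample_id for s in spectra])
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Parse a wide spectra CSV; the wavelength grid comes from the header."""
    df = pd.read_csv(path)
    for col in _META_COLS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    wavelengths = []
    for c in wl_cols:
        m = _WL_RE.match(c)
        if not m:
            raise ValidationError(f"{path}: unexpected column {c!r} (want wl_<nm>)")
        wavelengths.append(float(m.group(1)))
    wl = np.array(wavelengths)
    if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
        raise ValidationError(f"{path}: wavelength columns are not strictly increasing")
    if df.empty:
        logger.warning("%s: empty data section", path)
        return []
    if df[wl_cols].isna().any().any():
        bad = df[wl_cols].isna().any(axis=1)
        raise ValidationError(
            f"{path}: missing reflectance values in rows {df.index[bad].tolist()[:5]}"
        )
    spectra = []
    for _, row in df.iterrows():
        spectra.append(
            Spectrum(
                sample_id=str(row["sample_id"]),
                cultivar=str(row["cultivar"]),
                cut=int(row["cut"]),
                wavelengths_nm=wl,
                reflectance=row[wl_cols].to_numpy(dtype=float),
            )
        )
    return spectra


def write_phenolics_csv(records: list[PhenolicRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": [r.sample_id for r in records], "tpc_mg_gae_gdw": [r.tpc for r in records]}
    ).to_csv(path, index=False)


def read_phenolics_csv(path: str | Path) -> list[PhenolicRecord]:
    """Parse phenolic measurements; duplicate sample ids are an error."""
    df = pd.read_csv(path)
    for col in ("sample_id", "tpc_mg_gae_gdw"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    return [
        PhenolicRecord(sample_id=str(row.sample_id), tpc=float(row.tpc_mg_gae_gdw))
        for row in df.itertuples()
    ]


def write_features_csv(features: list[FeatureVector], path: str | Path) -> None:
    rows = [{"sample_id": fv.sample_id, **{n: getattr(fv, n) for n in FEATURE_NAMES}} for fv in features]
    pd.DataFrame(rows, columns=["sample_id", *FEATURE_NAMES]).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing feature columns {missing}")
    return [
        FeatureVector(sample_id=str(row["sample_id"]), **{n: float(row[n]) for n in FEATURE_NAMES})
        for _, row in df.iterrows()
    ]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
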