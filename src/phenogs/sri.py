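"""Spectral reflectance indices (SRI) from plot-level canopy reflectance.

Five indices are computed from reflectance fractions R_n at wavelength n nm:

* ``NDRE1`` = (R800 - R700) / (R800 + R700)   (red edge, 700 nm)
* ``NDRE2`` = (R800 - R750) / (R800 + R750)   (red edge, 750 nm)
* ``NDVI``  = (R800 - R680) / (R800 + R680)   (visible/NIR greenness)
* ``NWI1``  = (R970 - R900) / (R970 + R900)   (NIR-only water status)
* ``SR``    = R900 / R680                     (simple ratio)

Normalized-difference indices lie in [-1, 1] for nonnegative reflectance;
SR is nonnegative. All are invariant to rescaling every band by the same
positive constant. Band keys are exact: no nearest-wavelength interpolation
is attempted, so a missing filter shows up as an error, not a silently
shifted index.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import STAGES, SpectralRecord

#: index name -> (numerator band pair or ratio pair definition)
INDEX_BANDS = {
    "NDRE1": (800, 700),
    "NDRE2": (800, 750),
    "NDVI": (800, 680),
    "NWI1": (970, 900),
    "SR": (900, 680),
}

INDEX_NAMES = tuple(INDEX_BANDS)


class MissingBandError(KeyError):
    pass


class UndefinedValueError(ZeroDivisionError):
    pass


def compute_index(record: SpectralRecord, index: str) -> float:
    """Evaluate one spectral index on a record and cache it in ``record.indices``."""
    if index not in INDEX_BANDS:
        raise KeyError(f"unknown index {index!r}; known: {sorted(INDEX_BANDS)}")
    a_nm, b_nm = INDEX_BANDS[index]
    for nm in (a_nm, b_nm):
        if nm not in record.reflectance:
            raise MissingBandError(f"index {index} needs band {nm} nm, absent from record")
    ra, rb = record.reflectance[a_nm], record.reflectance[b_nm]
    if index == "SR":
        if rb == 0:
            raise UndefinedValueError("SR undefined: R680 = 0")
        value = ra / rb
    else:
        if ra + rb == 0:
            raise UndefinedValueError(f"{index} undefined: band sum is 0")
        value = (ra - rb) / (ra + rb)
    record.indices[index] = value
    return value


def compute_all_indices(records: list[SpectralRecord]) -> pd.DataFrame:
    """All five indices for every record; one row per plot x stage."""
    rows = []
    for r in records:
        row = {
            "entry_id": r.plot_key[0],
            "environment_id": r.plot_key[1],
            "block_id": r.plot_key[2],
            "stage": r.stage,
        }
        for name in INDEX_NAMES:
            row[name] = compute_index(r, name)
        rows.append(row)
    return pd.DataFrame(rows)


def compute_stage_change(mean_from: float, mean_to: float) -> float:
    """Percent change between stage means; negative = decrease.

    Defined as 100 * (mean_to - mean_from) / |mean_from| so that the sign
    reads as the direction of change even for negative-valued indices
    (the NIR water index is negative over a healthy canopy).
    """
    if mean_from == 0:
        raise UndefinedValueError("stage change undefined from a zero mean")
    return 100.0 * (mean_to - mean_from) / abs(mean_from)


def stage_means(index_table: pd.DataFrame, per_environment: bool = False) -> pd.DataFrame:
    """Arithmetic index means per growth stage.

    Default: plain mean over all non-missing plots pooled across
    environments. With ``per_environment``, means are taken within each
    environment first and then averaged, weighting environments equally.
    """
    value_cols = [c for c in INDEX_NAMES if c in index_table.columns]
    if per_environment:
        per_env = index_table.groupby(["stage", "environment_id"])[value_cols].mean()
        out = per_env.groupby("stage").mean()
    else:
        out = index_table.groupby("stage")[value_cols].mean()
    return out.reindex([s for s in STAGES if s in out.index])
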