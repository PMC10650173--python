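"""ToF-SIMS membrane lipid-profile arithmetic.

Works on peak-intensity tables (one row per sample/replicate and lipid
component) rather than raw spectra: ion yields are the peak intensity
normalized to the total ion count of the same measurement, and fatty-acid
(FA) signals are expressed relative to the saturated-FA signal of the same
sample.  Per-component Pearson correlations against per-line membrane
microviscosity close the loop with the FLIM measurements.

Canonical component vocabulary (positive-ion peaks for the phospholipid
headgroups/cholesterol, FA classes from negative-ion spectra):
PC (m/z 224), SM (m/z 264), cholesterol (m/z 385), saturated_FA,
monounsaturated_FA, polyunsaturated_FA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: Component name -> nominal m/z (None where a class aggregates several peaks).
COMPONENT_MZ = {
    "PC": 224,
    "SM": 264,
    "cholesterol": 385,
    "saturated_FA": None,
    "monounsaturated_FA": None,
    "polyunsaturated_FA": None,
}

FA_CLASSES = ("monounsaturated_FA", "polyunsaturated_FA")
FA_DENOMINATOR = "saturated_FA"


def normalize_ion_yields(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw peak intensities to the total ion count per sample.

    ``table`` needs columns ``line``, ``component``, ``raw_intensity`` and
    ``total_ion_count`` (per-sample, already averaged over the image pixels).
    Adds ``ion_yield = raw_intensity / total_ion_count``; samples with a
    non-positive total ion count are excluded with a warning.
    """
    req = {"line", "component", "raw_intensity", "total_ion_count"}
    if not req.issubset(table.columns):
        raise ValueError(f"lipid table must have columns {sorted(req)}")
    if (table["raw_intensity"] < 0).any():
        raise ValueError("raw intensities must be non-negative")
    bad = table["total_ion_count"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} rows with non-positive total ion count",
            RuntimeWarning,
        )
    out = table[~bad].copy()
    out["ion_yield"] = out["raw_intensity"] / out["total_ion_count"]
    if (out["ion_yield"] > 1).any():
        raise ValueError("ion yield above 1: peak intensity exceeds total ion count")
    return out


def normalize_fa(
    table: pd.DataFrame,
    saturated: pd.Series | None = None,
    sample_cols: tuple[str, ...] = ("line",),
) -> pd.DataFrame:
    """Express FA-class intensities relative to the same sample's saturated-FA
    signal.

    ``table`` holds rows (sample keys, ``component``, ``raw_intensity``) with
    the FA classes and the ``saturated_FA`` denominator rows; alternatively an
    explicit ``saturated`` Series indexed by the sample keys may be supplied,
    in which case its index must match the samples in the table exactly
    (cross-sample denominators are a contract violation).  Samples with a
    non-positive denominator are excluded with a warning.
    """
    keys = list(sample_cols)
    fa = table[table["component"].isin(FA_CLASSES)].copy()
    if saturated is None:
        den_rows = table[table["component"] == FA_DENOMINATOR]
        if den_rows.empty:
            raise ValueError("no saturated_FA rows to normalize against")
        saturated = den_rows.set_index(keys)["raw_intensity"]
    else:
        sample_index = pd.MultiIndex.from_frame(fa[keys].drop_duplicates()) if len(keys) > 1 else pd.Index(fa[keys[0]].unique())
        missing = sample_index.difference(saturated.index)
        extra = saturated.index.difference(sample_index)
        if len(missing) or len(extra):
            raise ValueError(
                "saturated-FA denominators must come from the same samples "
                f"(missing={list(missing)}, extra={list(extra)})"
            )
    den = fa.set_index(keys).index.map(saturated)
    den = pd.Series(np.asarray(den, float), index=fa.index)
    bad = ~(den > 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} FA rows with non-positive saturated-FA signal",
            RuntimeWarning,
        )
    fa = fa[~bad]
    fa["fa_ratio"] = fa["raw_intensity"].to_numpy() / den[~bad].to_numpy()
    return fa


def correlate_lipids_viscosity(
    table: pd.DataFrame,
    viscosity_cP: pd.Series,
    value_col: str = "ion_yield",
) -> pd.DataFrame:
    """Per-component Pearson correlation of lipid signal with microviscosity.

    ``table`` holds per-line values (replicates are averaged per line first);
    ``viscosity_cP`` is indexed by line.  Requires at least 3 lines.  With
    fewer than 4 lines no p-value is reported; components constant across
    lines yield an undefined (NaN) r, reported as such.
    """
    per_line = (
        table.groupby(["component", "line"], sort=False)[value_col].mean().reset_index()
    )
    rows = []
    for comp, grp in per_line.groupby("component", sort=False):
        merged = grp.set_index("line")[value_col].reindex(viscosity_cP.index).dropna()
        n = len(merged)
        if n < 3:
            raise ValueError(f"component {comp!r}: need >= 3 lines, got {n}")
        x = merged.to_numpy()
        y = viscosity_cP.loc[merged.index].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = np.nan, np.nan
            note = "constant across lines; r undefined"
        else:
            r, p = stats.pearsonr(x, y)
            note = ""
        rows.append(
            {
                "component": comp,
                "pearson_r": float(r) if np.isfinite(r) else np.nan,
                "n_lines": n,
                "p_value": float(p) if (n >= 4 and np.isfinite(p)) else np.nan,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
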