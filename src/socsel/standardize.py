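"""Multi-scale mean–variance standardization of the trait table.

Contextual analysis is sensitive to the scale of standardization, so each
phenotypic level is scaled at the level where selection is expected to act:

* individual traits — intra-group: each trait is centred and scaled within its
  social group within its year (``dPi_*`` columns), so a value is a deviation
  from the group's mean in group-SD units;
* group traits and group size — inter-group: one observation per unique
  group-year, centred and scaled across all group-years of the dataset
  (``dPg_*`` and ``group_size_z``), then broadcast back to member rows.

After scaling, the signs of the group closeness and breakability measures
(average path length, cut points) are flipped so that larger values of every
predictor mean "more social"; we refer to them as inverse average path length
and inverse cut points.  Sample (n−1) standard deviations throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .netmetrics import GROUP_TRAITS, INDIVIDUAL_TRAITS

#: Columns negated by :func:`apply_sign_flips` (so + = more social).
SIGN_FLIP_COLUMNS = ("dPg_avg_path_length", "dPg_cut_points_std")


def _zscore(values: pd.Series) -> tuple[pd.Series, bool]:
    """(x - mean) / sample SD, NA-aware; degenerate variance -> zeros."""
    mean = values.mean()
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        out = pd.Series(
            np.where(values.notna(), 0.0, np.nan), index=values.index
        )
        return out, True
    return (values - mean) / sd, False


def standardize_individual(
    traits: pd.DataFrame, columns: tuple[str, ...] = INDIVIDUAL_TRAITS
) -> pd.DataFrame:
    """Intra-group standardization: ``dPi_<trait>`` per group within year.

    NA trait values are excluded from the group moments and stay NA.  A group
    with zero variance (or a single usable value) gets all zeros, with a
    warning naming the group.
    """
    out = {}
    degenerate: list[tuple] = []
    for col in columns:
        parts = []
        for key, sub in traits.groupby(["year", "group"], sort=False):
            z, degen = _zscore(sub[col].astype(float))
            if degen:
                degenerate.append((col,) + tuple(key))
            parts.append(z)
        out[f"dPi_{col}"] = pd.concat(parts).reindex(traits.index)
    if degenerate:
        warnings.warn(
            f"zero-variance intra-group standardization for {len(degenerate)} "
            f"trait-group combinations (e.g. {degenerate[0]}); values set to 0",
            stacklevel=2,
        )
    return pd.DataFrame(out, index=traits.index)


def _group_level_zscore(
    traits: pd.DataFrame, columns: tuple[str, ...], prefix: str, weighting: str
) -> pd.DataFrame:
    key = ["year", "group"]
    unique = traits.drop_duplicates(key)
    if len(unique) < 2:
        raise ValueError(
            "inter-group standardization needs at least 2 distinct group-years"
        )
    out = {}
    for col in columns:
        basis = traits[col] if weighting == "per_individual" else unique[col]
        mean = basis.astype(float).mean()
        sd = basis.astype(float).std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(
                f"all group-years identical for {col!r}; standardized to 0",
                stacklevel=3,
            )
            z = pd.Series(
                np.where(traits[col].notna(), 0.0, np.nan), index=traits.index
            )
        else:
            z = (traits[col].astype(float) - mean) / sd
        out[f"{prefix}{col}"] = z
    return pd.DataFrame(out, index=traits.index)


def standardize_group(
    traits: pd.DataFrame,
    columns: tuple[str, ...] = GROUP_TRAITS,
    weighting: str = "per_group",
) -> pd.DataFrame:
    """Inter-group standardization: ``dPg_<trait>`` across unique group-years.

    Moments are computed over the set of unique group-years — one value per
    group-year, not weighted by member count — unless
    ``weighting="per_individual"`` is requested as a sensitivity option.
    """
    if weighting not in ("per_group", "per_individual"):
        raise ValueError(f"unknown group-moment weighting {weighting!r}")
    return _group_level_zscore(traits, columns, "dPg_", weighting)


def standardize_group_size(
    traits: pd.DataFrame, weighting: str = "per_group"
) -> pd.Series:
    """Globally standardized social group size (``group_size_z``)."""
    z = _group_level_zscore(traits, ("group_size",), "gz_", weighting)
    return z["gz_group_size"].rename("group_size_z")


def apply_sign_flips(std: pd.DataFrame) -> pd.DataFrame:
    """Negate the standardized group path-length and cut-point columns.

    Guarded by a frame-level flag so a second application (which would
    silently undo the convention) raises instead.
    """
    if std.attrs.get("sign_flips_applied"):
        raise ValueError("sign flips have already been applied to this table")
    out = std.copy()
    for col in SIGN_FLIP_COLUMNS:
        if col in out.columns:
            out[col] = -out[col]
    out.attrs = dict(std.attrs)
    out.attrs["sign_flips_applied"] = True
    return out


def standardize_traits(
    traits: pd.DataFrame,
    weighting: str = "per_group",
    sign_flips: bool = True,
) -> pd.DataFrame:
    """Full standardization stage: trait table -> standardized trait table.

    Appends ``dPi_*``, ``dPg_*`` and ``group_size_z`` columns and applies the
    sign-flip convention; the raw columns are retained.
    """
    dpi = standardize_individual(traits)
    dpg = standardize_group(traits, weighting=weighting)
    gz = standardize_group_size(traits, weighting=weighting)
    out = pd.concat([traits.reset_index(drop=True),
                     dpi.reset_index(drop=True),
                     dpg.reset_index(drop=True),
                     gz.reset_index(drop=True)], axis=1)
    if sign_flips:
        out = apply_sign_flips(out)
    return out
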