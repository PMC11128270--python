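"""Diet summaries from regurgitate sample tables.

Frequency of occurrence (FOO) is the proportion of identifiable samples in a
group that contain a species; numerical abundance is the mean per-sample
count of that species. Samples with no identifiable remains are excluded
from both. By default the numerical-abundance denominator is ALL
identifiable samples in the group (samples lacking the species contribute
zero counts); pass ``occurrences_only=True`` to average only over samples
that contain the species.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError


def _prepare(samples: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample_id", "species", "count", "identifiable"):
        if col not in samples.columns:
            raise ValidationError(f"diet table missing column '{col}'")
    return samples[samples["identifiable"].astype(bool)].copy()


def _group_iter(df: pd.DataFrame, group_by):
    if not group_by:
        yield ("all",), df
    else:
        for key, grp in df.groupby(list(group_by)):
            yield (key if isinstance(key, tuple) else (key,)), grp


def foo_table(samples: pd.DataFrame, group_by=("sex",)) -> pd.DataFrame:
    """FOO per species x group over identifiable samples.

    Returns a tidy frame: group columns, species, n_samples, n_occurrence,
    foo. Presence-based: duplicating an item within a sample cannot change
    FOO. Empty groups are omitted with a warning.
    """
    ident = _prepare(samples)
    species_pool = sorted(s for s in samples["species"].dropna().unique() if s != "")
    rows = []
    for key, grp in _group_iter(ident, group_by):
        n = grp["sample_id"].nunique()
        if n == 0:
            warnings.warn(f"group {key}: no identifiable samples; omitted",
                          stacklevel=2)
            continue
        present = grp.dropna(subset=["species"])
        occ = present.groupby("species")["sample_id"].nunique()
        for sp in species_pool:
            k = int(occ.get(sp, 0))
            rows.append({**dict(zip(group_by, key)), "species": sp,
                         "n_samples": n, "n_occurrence": k, "foo": k / n})
    return pd.DataFrame(rows)


def numerical_abundance(samples: pd.DataFrame, group_by=("sex",),
                        occurrences_only: bool = False) -> pd.DataFrame:
    """Mean per-sample count of each species over identifiable samples."""
    ident = _prepare(samples)
    species_pool = sorted(s for s in samples["species"].dropna().unique() if s != "")
    rows = []
    for key, grp in _group_iter(ident, group_by):
        n = grp["sample_id"].nunique()
        if n == 0:
            warnings.warn(f"group {key}: no identifiable samples; omitted",
                          stacklevel=2)
            continue
        present = grp.dropna(subset=["species"])
        counts = present.groupby(["species", "sample_id"])["count"].sum()
        for sp in species_pool:
            if sp in counts.index.get_level_values(0):
                per_sample = counts.loc[sp]
                denom = len(per_sample) if occurrences_only else n
                mean_count = float(per_sample.sum()) / denom
            else:
                mean_count = 0.0 if not occurrences_only else np.nan
            rows.append({**dict(zip(group_by, key)), "species": sp,
                         "n_samples": n, "mean_count": mean_count})
    return pd.DataFrame(rows)


def foo_across_years(samples: pd.DataFrame, group_by=("sex",)) -> pd.DataFrame:
    """Mean +/- SE of per-year FOO for each species x group."""
    per_year = foo_table(samples, group_by=tuple(group_by) + ("year",))
    if len(per_year) == 0:
        return per_year
    out = (per_year.groupby(list(group_by) + ["species"])["foo"]
           .agg(foo_mean="mean",
                foo_se=lambda s: float(np.std(s, ddof=1) / np.sqrt(len(s)))
                if len(s) > 1 else np.nan,
                n_years="count")
           .reset_index())
    return out


def prey_length_summary(samples: pd.DataFrame, group_by=("sex",)) -> pd.DataFrame:
    """Mean +/- SE length of whole prey items (those with a recorded length).

    Groups with a single measurable item get SE = NaN and ``se_defined``
    False; groups with none are omitted with a warning.
    """
    ident = _prepare(samples)
    whole = ident.dropna(subset=["length_cm"])
    if group_by:
        have = {k for k, _ in _group_iter(whole, group_by)}
        for key, _ in _group_iter(ident, group_by):
            if key not in have:
                warnings.warn(f"group {key}: no whole prey items; omitted",
                              stacklevel=2)
    rows = []
    for key, grp in _group_iter(whole, group_by):
        lengths = grp["length_cm"].to_numpy(dtype=float)
        if lengths.size == 0:
            continue
        mean = float(np.mean(lengths))
        se = float(np.std(lengths, ddof=1) / np.sqrt(lengths.size)) \
            if lengths.size > 1 else np.nan
        rows.append({**dict(zip(group_by, key)), "n_items": lengths.size,
                     "mean_length_cm": mean, "se_length_cm": se,
                     "se_defined": lengths.size > 1})
    return pd.DataFrame(rows)
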