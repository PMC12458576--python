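"""Regional Vulnerability Index (RVI) computation.

The RVI measures how closely an individual's pattern of regional brain
deviations resembles a disease's characteristic deficit pattern.  Given
a vector Z of per-region z-score deviations from a reference group and a
vector E of per-region case-control effect sizes (Cohen's d), the score
is the normalized dot product

    RVI = (1/N) * sum_i Z_i * E_i

over the N regions present in both vectors.  Positive values mean the
individual deviates in the disease direction region-by-region (with
diagnosis coded case = 1 so that atrophy yields d < 0, a thinner-than-
average cortex in an atrophic region contributes positively).

Alignment between Z and E is always by region identifier, never by
position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    MODALITIES,
    EffectSizeBlueprint,
    PhenotypeTable,
    RunConfig,
)

__all__ = [
    "ZScoreTable",
    "average_hemispheres",
    "zscore",
    "compute_rvi",
    "score_cohort",
]

_HEMI_RE = re.compile(r"^(?P<stem>.+)_(?P<hemi>[LR])$")


class RviError(ValueError):
    """Invalid input to an RVI computation."""


@dataclass
class ZScoreTable:
    """Per-subject, per-region z deviations plus the reference stats.

    Over the reference sample each region's z column has mean 0 and
    sample SD 1 (n-1 denominator).
    """

    z: pd.DataFrame                 # subjects x regions
    reference_mean: pd.Series       # per region
    reference_sd: pd.Series         # per region

    @property
    def regions(self) -> list[str]:
        return list(self.z.columns)

    @property
    def subject_ids(self) -> pd.Index:
        return self.z.index


def average_hemispheres(table: PhenotypeTable) -> PhenotypeTable:
    """Average paired left/right region columns.

    Columns named ``<region>_L`` / ``<region>_R`` are replaced by their
    arithmetic mean under the bare ``<region>`` name; unpaired columns
    (including already-averaged ones) pass through unchanged.  When one
    hemisphere is missing for a subject, the available value is used and
    the region is flagged in a ``single_hemisphere`` warning.
    """
    pairs: dict[str, dict[str, str]] = {}
    unpaired: list[str] = []
    for col in table.regions:
        m = _HEMI_RE.match(col)
        if m:
            pairs.setdefault(m.group("stem"), {})[m.group("hemi")] = col
        else:
            unpaired.append(col)

    if not any(len(v) == 2 for v in pairs.values()) and not any(len(v) == 1 for v in pairs.values()):
        return table  # nothing hemisphere-suffixed: identity

    data = table.data.copy()
    new_regions: list[str] = []
    n_single = 0
    for col in table.regions:
        m = _HEMI_RE.match(col)
        if m is None:
            new_regions.append(col)
            continue
        stem = m.group("stem")
        if stem in data.columns or stem in new_regions:
            continue  # already produced from the other hemisphere
        cols = pairs[stem]
        if len(cols) == 2:
            left, right = data[cols["L"]], data[cols["R"]]
            merged = pd.concat([left, right], axis=1).mean(axis=1, skipna=True)
            n_single += int((left.isna() ^ right.isna()).sum())
        else:
            merged = data[next(iter(cols.values()))]
            n_single += int(merged.notna().sum())
        data[stem] = merged
        new_regions.append(stem)
    if len(new_regions) != len(set(new_regions)):
        dupes = sorted({r for r in new_regions if new_regions.count(r) > 1})
        raise RviError(f"duplicate region names after hemisphere averaging: {dupes}")
    if n_single:
        warnings.warn(f"{n_single} single-hemisphere values used as-is", stacklevel=2)
    drop = [c for c in table.regions if c not in new_regions]
    data = data.drop(columns=drop)
    # keep region-first ordering stable: regions in first-appearance order
    return table.copy_with(data, regions=new_regions)


def zscore(
    table: PhenotypeTable,
    reference: list[str] | pd.Index | tuple[pd.Series, pd.Series] | None = None,
) -> ZScoreTable:
    """Standardize each region against a reference sample.

    ``reference`` may be a list of subject ids (a subset of the table),
    a ``(means, sds)`` pair of per-region Series for scoring against an
    external norm, or None to use the full table ("deviations from the
    mean of the group").  SDs use the n-1 denominator.
    """
    values = table.region_values()
    if isinstance(reference, tuple):
        mean, sd = reference
        mean = mean.reindex(values.columns)
        sd = sd.reindex(values.columns)
        if mean.isna().any() or sd.isna().any():
            missing = values.columns[mean.isna() | sd.isna()].tolist()
            raise RviError(f"external reference lacks mean/SD for regions: {missing}")
    else:
        ref_rows = values if reference is None else values.loc[list(reference)]
        if len(ref_rows) < 2:
            raise RviError("reference sample needs >= 2 subjects")
        mean = ref_rows.mean(axis=0)
        sd = ref_rows.std(axis=0, ddof=1)
    zero = sd.index[(sd <= 0) | sd.isna()].tolist()
    if zero:
        raise RviError(f"zero or undefined SD for regions: {zero}")
    z = (values - mean) / sd
    return ZScoreTable(z=z, reference_mean=mean, reference_sd=sd)


def compute_rvi(
    z_row: pd.Series,
    blueprint: EffectSizeBlueprint,
    subset: str | None = None,
    normalize: bool = True,
    missing: str = "drop",
    max_missing_frac: float = 0.2,
) -> tuple[float, int]:
    """Blueprint-weighted similarity score for one subject.

    Parameters
    ----------
    z_row
        Per-region z deviations indexed by region_id.
    subset
        Optional modality filter (one of ``cortical_thickness``,
        ``subcortical_volume``, ``white_matter``); None scores the whole
        blueprint.
    normalize
        Divide the dot product by the number of regions used (the
        default); False returns the plain sum.
    missing
        ``"drop"`` removes regions with missing z from the sum and
        decrements N (refusing subjects missing more than
        ``max_missing_frac`` of the blueprint); ``"error"`` raises.

    Returns
    -------
    (rvi, n_used)
    """
    bp = blueprint if subset is None else blueprint.subset(subset)
    d = bp.d_series()
    common = d.index.intersection(z_row.index)
    if len(common) == 0:
        raise RviError("no overlap between z-score regions and blueprint regions")
    z = z_row.reindex(common).astype(float)
    dv = d.reindex(common).astype(float)
    nan_mask = z.isna()
    if nan_mask.any():
        if missing == "error":
            raise RviError(f"missing z for regions: {common[nan_mask].tolist()}")
        if nan_mask.mean() > max_missing_frac:
            raise RviError(
                f"subject missing {nan_mask.sum()}/{len(common)} blueprint regions "
                f"(> {max_missing_frac:.0%})"
            )
        z, dv = z[~nan_mask], dv[~nan_mask]
    n = int(len(z))
    if n == 0:
        raise RviError("no usable regions after missing-data policy")
    total = float(np.dot(z.to_numpy(), dv.to_numpy()))
    return (total / n if normalize else total), n


_SUBSET_LABELS = {
    None: "whole",
    "cortical_thickness": "cortical",
    "subcortical_volume": "subcortical",
    "white_matter": "wm",
}


def score_cohort(
    table: PhenotypeTable,
    blueprint: EffectSizeBlueprint,
    config: RunConfig | None = None,
    reference: list[str] | tuple[pd.Series, pd.Series] | None = None,
) -> pd.DataFrame:
    """Whole-brain and tissue-specific RVI for every subject.

    The table must already be hemisphere-averaged.  Returns a DataFrame
    indexed by subject_id with columns ``rvi_whole``, ``rvi_cortical``,
    ``rvi_subcortical``, ``rvi_wm`` and the region counts used for each.
    """
    config = config or RunConfig()
    zt = zscore(table, reference=reference)
    subsets = [None] + [m for m in MODALITIES if m in set(blueprint.table["modality"])]
    out: dict[str, np.ndarray] = {}
    for sub in subsets:
        label = _SUBSET_LABELS[sub]
        bp = blueprint if sub is None else blueprint.subset(sub)
        d = bp.d_series()
        common = d.index.intersection(zt.z.columns)
        if len(common) == 0:
            raise RviError(f"no overlap between z-score regions and the "
                           f"{label} blueprint subset")
        # vectorized form of compute_rvi with the drop-missing policy
        Z = zt.z[common].to_numpy(dtype=float)
        dv = d.reindex(common).to_numpy(dtype=float)
        missing = np.isnan(Z)
        n_used = (~missing).sum(axis=1)
        too_missing = missing.mean(axis=1) > config.max_missing_frac
        if too_missing.any():
            bad = zt.subject_ids[too_missing][0]
            k = int(missing[too_missing][0].sum())
            raise RviError(
                f"subject {bad!r}: subject missing {k}/{len(common)} blueprint "
                f"regions (> {config.max_missing_frac:.0%})"
            )
        total = np.nansum(Z * dv[None, :], axis=1)
        out[f"rvi_{label}"] = total / n_used if config.normalize else total
        out[f"n_{label}"] = n_used
    return pd.DataFrame(out, index=zt.subject_ids)
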