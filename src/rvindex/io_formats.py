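"""Tabular I/O and run configuration.

Every table the package touches — wide phenotype tables, effect-size
blueprints, longitudinal clinical-status panels and score outputs — is
read and written here as plain delimited text (CSV/TSV, UTF-8, header
row).  Missing values are a single sentinel (empty cell or ``NA``) and
are recorded, never imputed: downstream operations decide their own
missing-data policy.

Conventions fixed at this layer:

* ``sex`` is coded 0 = female, 1 = male everywhere.
* hemisphere-specific region columns carry ``_L`` / ``_R`` suffixes;
  hemisphere-averaged tables drop the suffix.
* blueprint row order is authoritative for vector alignment downstream;
  readers never reorder subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "MODALITIES",
    "STATUS_LEVELS",
    "COVARIATE_COLUMNS",
    "PhenotypeTable",
    "EffectSizeBlueprint",
    "StatusPanel",
    "RunConfig",
    "read_phenotypes",
    "read_blueprint",
    "read_status_panel",
    "write_scores",
    "read_scores",
]

#: Imaging modalities a blueprint row may be tagged with.
MODALITIES = ("cortical_thickness", "subcortical_volume", "white_matter")

#: Clinical states in progression order; dementia is absorbing.
STATUS_LEVELS = ("CN", "MCI", "dementia")

#: Covariate columns recognised in a phenotype table.  Everything else
#: with a numeric dtype is treated as a region column.
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "icv",
    "apoe4_carrier",
    "total_cholesterol",
    "hdl_cholesterol",
    "systolic_bp",
    "bp_treated",
    "smoker",
    "diabetic",
    "fcvrs",
    "diagnosis",
)

_NA_SENTINELS = ["", "NA", "NaN", "nan"]


class BlueprintError(ValueError):
    """Malformed effect-size blueprint."""


class PhenotypeError(ValueError):
    """Malformed phenotype table."""


@dataclass
class PhenotypeTable:
    """Subjects x regions measures plus per-subject covariates.

    ``data`` is indexed by ``subject_id`` (unique, opaque strings);
    ``regions`` and ``covariates`` partition its columns.  Region values
    are real measures (mm for thickness, mm^3 for volumes, dimensionless
    for white-matter indices).
    """

    data: pd.DataFrame
    regions: list[str]
    covariates: list[str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise PhenotypeError(f"duplicate subject_id values: {dupes}")
        for col in self.regions:
            if not pd.api.types.is_numeric_dtype(self.data[col]):
                raise PhenotypeError(f"region column {col!r} is not numeric")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    def region_values(self) -> pd.DataFrame:
        """Region columns only, in table column order."""
        return self.data[self.regions]

    def copy_with(self, data: pd.DataFrame, regions: Sequence[str] | None = None) -> "PhenotypeTable":
        return PhenotypeTable(
            data=data,
            regions=list(regions) if regions is not None else list(self.regions),
            covariates=[c for c in self.covariates if c in data.columns],
        )


@dataclass
class EffectSizeBlueprint:
    """Ordered per-region Cohen's d weights — the vector E.

    Row order is preserved from the source file and is authoritative for
    any positional reporting; numerical alignment downstream is always by
    ``region_id``.  Sign convention: diagnosis coded case = 1, so d < 0
    means cases have *lower* values (the typical direction for cortical
    thickness and gray-matter volume in Alzheimer's disease).
    """

    table: pd.DataFrame  # columns: region_id, modality, d

    def __post_init__(self) -> None:
        required = ["region_id", "modality", "d"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise BlueprintError(f"blueprint missing columns: {missing}")
        if self.table["region_id"].duplicated().any():
            dupes = self.table.loc[self.table["region_id"].duplicated(), "region_id"].tolist()
            raise BlueprintError(f"duplicate region_id values: {dupes}")
        bad = set(self.table["modality"]) - set(MODALITIES)
        if bad:
            raise BlueprintError(f"unknown modality labels: {sorted(bad)}; expected one of {MODALITIES}")
        d = pd.to_numeric(self.table["d"], errors="coerce")
        if d.isna().any():
            bad_rows = self.table.loc[d.isna(), "region_id"].tolist()
            raise BlueprintError(f"non-numeric d for regions: {bad_rows}")
        if not pd.Series(d).map(lambda x: x == x and abs(x) != float("inf")).all():
            raise BlueprintError("non-finite d values in blueprint")
        self.table = self.table.assign(d=d.astype(float)).reset_index(drop=True)

    @property
    def region_ids(self) -> list[str]:
        return self.table["region_id"].tolist()

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def modality_counts(self) -> dict[str, int]:
        counts = self.table["modality"].value_counts().to_dict()
        return {m: int(counts.get(m, 0)) for m in MODALITIES}

    def is_ad_sized(self) -> bool:
        """True for the canonical whole-brain AD layout: 33 cortical
        thickness + 7 subcortical volume + 24 white matter = 64 regions."""
        c = self.modality_counts()
        return (
            c["cortical_thickness"] == 33
            and c["subcortical_volume"] == 7
            and c["white_matter"] == 24
        )

    def subset(self, modality: str) -> "EffectSizeBlueprint":
        if modality not in MODALITIES:
            raise BlueprintError(f"unknown modality {modality!r}")
        return EffectSizeBlueprint(self.table[self.table["modality"] == modality].reset_index(drop=True))

    def d_series(self) -> pd.Series:
        """Cohen's d indexed by region_id, in blueprint order."""
        return self.table.set_index("region_id")["d"]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


@dataclass
class StatusPanel:
    """Longitudinal clinical status: one row per subject per visit year.

    ``visit_year`` counts whole years since baseline (year 0 must exist
    for every subject); ``status`` is one of CN / MCI / dementia and
    never reverts from dementia.
    """

    table: pd.DataFrame  # columns: subject_id, visit_year, status

    def __post_init__(self) -> None:
        required = ["subject_id", "visit_year", "status"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"status panel missing columns: {missing}")
        bad = set(self.table["status"]) - set(STATUS_LEVELS)
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")
        t = self.table.copy()
        t["visit_year"] = t["visit_year"].astype(int)
        if (t["visit_year"] < 0).any():
            raise ValueError("negative visit_year")
        if t.duplicated(["subject_id", "visit_year"]).any():
            raise ValueError("duplicate (subject_id, visit_year) rows")
        base = t.groupby("subject_id")["visit_year"].min()
        if (base != 0).any():
            missing_base = base.index[base != 0].tolist()
            raise ValueError(f"subjects without a year-0 baseline visit: {missing_base}")
        # dementia is absorbing
        t = t.sort_values(["subject_id", "visit_year"], kind="stable")
        is_dem = (t["status"] == "dementia").astype(int)
        seen_dem = is_dem.groupby(t["subject_id"]).cummax()
        reverts = (seen_dem == 1) & (is_dem == 0)
        if reverts.any():
            bad = t.loc[reverts, "subject_id"].unique().tolist()
            raise ValueError(f"subjects revert from dementia: {bad}")
        self.table = t.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].unique().tolist()

    def baseline_status(self) -> pd.Series:
        base = self.table[self.table["visit_year"] == 0]
        return base.set_index("subject_id")["status"]

    def last_visit(self) -> pd.Series:
        return self.table.groupby("subject_id")["visit_year"].max()

    def first_year_with_status(self, status: str) -> pd.Series:
        """First visit year at which each subject shows ``status``
        (subjects never reaching it are absent)."""
        hit = self.table[self.table["status"] == status]
        return hit.groupby("subject_id")["visit_year"].min()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


@dataclass
class RunConfig:
    """Run configuration shared by the CLI and batch helpers."""

    blueprint_path: str | None = None
    z_reference: str = "self"  # "self" or a path to a means/SDs CSV
    modalities: tuple[str, ...] = MODALITIES
    seed: int = 0
    output_dir: str = "."
    normalize: bool = True  # divide the blueprint dot product by N
    max_missing_frac: float = 0.2

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "modalities" in raw:
            raw["modalities"] = tuple(raw["modalities"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "blueprint_path": self.blueprint_path,
            "z_reference": self.z_reference,
            "modalities": list(self.modalities),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "normalize": self.normalize,
            "max_missing_frac": self.max_missing_frac,
        }


def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_phenotypes(path: str | Path, config: RunConfig | None = None) -> PhenotypeTable:
    """Read a wide phenotype CSV/TSV into a :class:`PhenotypeTable`.

    The file must have a header row containing ``subject_id``.  Columns
    named in :data:`COVARIATE_COLUMNS` become covariates; all other
    columns are treated as region measures and coerced to float.  Cells
    that fail to parse become missing values (recorded, not dropped) and
    a warning reports how many.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"subject_id": str},
                     na_values=_NA_SENTINELS, keep_default_na=False,
                     float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise PhenotypeError(f"{path}: missing required column 'subject_id'")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise PhenotypeError(f"{path}: duplicate subject_id values: {dupes}")
    df = df.set_index("subject_id")
    if df.empty:
        warnings.warn(f"{path}: header-only file, empty phenotype table", stacklevel=2)
    covariates = [c for c in df.columns if c in COVARIATE_COLUMNS]
    regions = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    n_bad = 0
    for col in regions:
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    for col in covariates:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if n_bad:
        warnings.warn(f"{path}: {n_bad} unparseable region cells recorded as missing", stacklevel=2)
    return PhenotypeTable(data=df, regions=regions, covariates=covariates)


def read_blueprint(path: str | Path) -> EffectSizeBlueprint:
    """Read an effect-size blueprint (columns ``region_id,modality,d``);
    file row order is preserved."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"region_id": str, "modality": str})
    return EffectSizeBlueprint(df)


def read_status_panel(path: str | Path) -> StatusPanel:
    """Read a longitudinal clinical-status table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"subject_id": str, "status": str})
    return StatusPanel(df)


#: Deterministic column order for score files.
SCORE_COLUMNS = [
    "rvi_whole", "rvi_cortical", "rvi_subcortical", "rvi_wm",
    "n_whole", "n_cortical", "n_subcortical", "n_wm",
]


def write_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write per-subject RVI scores (one row per subject, fixed column
    order).  ``scores`` is indexed by subject_id as produced by
    :func:`rvindex.rvi_core.score_cohort`."""
    path = Path(path)
    cols = [c for c in SCORE_COLUMNS if c in scores.columns]
    extra = [c for c in scores.columns if c not in SCORE_COLUMNS]
    out = scores[cols + extra]
    out.to_csv(path, index=True, index_label="subject_id")  # str() round-trips floats
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id", dtype={"subject_id": str},
                       float_precision="round_trip")
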