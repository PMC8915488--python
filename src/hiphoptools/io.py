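"""Domain containers and readers/writers for the delimited formats used throughout.

The central container is :class:`ScreenMatrix`, a genes-by-screens matrix of
fitness scores that carries two pieces of provenance every transform must
respect: what the numbers are (``value_kind``) and which sign means "sensitive"
(``orientation``).  The two screening sites use opposite sign conventions —
one reports log2(control/treatment), where a sensitive strain scores high and
positive, the other log2(treatment/control), where it scores low and negative —
so the orientation flag is threaded through the whole pipeline and only
changed by :func:`hiphoptools.scoring.harmonize_orientation`.

All tabular formats are tab-separated text with "." decimals; missing values
are empty cells or "NA" on read and empty cells on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALUE_KINDS = ("raw_log2ratio", "fd", "madl", "a_madl", "z")
ORIENTATIONS = ("sensitivity_positive", "sensitivity_negative")
TAGS = ("up", "down")
ROLES = ("control", "treatment")
SITES = ("HIPLAB", "NIBR")
ASSAYS = ("HIP", "HOP")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass
class ScreenMatrix:
    """Strain/gene × screen score matrix with explicit kind and orientation.

    Parameters
    ----------
    values
        DataFrame with strain/gene ids as the index and screen ids as
        columns.  ``NaN`` encodes missing; ±inf is rejected.
    value_kind
        One of ``raw_log2ratio``, ``fd``, ``madl``, ``a_madl``, ``z``.
    orientation
        ``sensitivity_positive`` (high score = sensitive strain) or
        ``sensitivity_negative`` (low/negative score = sensitive strain).
    """

    values: pd.DataFrame
    value_kind: str = "fd"
    orientation: str = "sensitivity_positive"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        dup_rows = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_rows):
            raise FormatError(f"duplicate strain ids: {list(map(str, dup_rows))}")
        dup_cols = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_cols):
            raise FormatError(f"duplicate screen ids: {list(map(str, dup_cols))}")
        if np.isinf(self.values.to_numpy()).any():
            raise ValueError("ScreenMatrix must not contain ±inf")

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, *, value_kind: str | None = None,
                    orientation: str | None = None) -> "ScreenMatrix":
        """Return a copy carrying new values; kind/orientation change only when given."""
        return ScreenMatrix(
            values=values,
            value_kind=self.value_kind if value_kind is None else value_kind,
            orientation=self.orientation if orientation is None else orientation,
        )

    def copy(self) -> "ScreenMatrix":
        return replace(self, values=self.values.copy())


TAG_TABLE_COLUMNS = ["strain_id", "tag", "array_id", "signal", "role", "batch",
                     "study_id", "used"]


@dataclass
class TagIntensityTable:
    """Per-(strain, tag, array) raw barcode-microarray signals.

    ``used`` separates strain barcode features from the unused background
    features on the array (the latter carry placeholder ids in ``strain_id``
    and drive the background threshold).  Every batch must contain at least
    one control (untreated) array.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in TAG_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"tag table missing columns: {missing}")
        df = df[TAG_TABLE_COLUMNS].copy()
        df["signal"] = df["signal"].astype(float)
        df["used"] = df["used"].astype(bool)
        bad_tag = set(df["tag"]) - set(TAGS)
        if bad_tag:
            raise ValueError(f"unknown tag kinds: {sorted(bad_tag)}")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown array roles: {sorted(bad_role)}")
        used = df[df["used"]]
        if (used["signal"] <= 0).any():
            bad = used.loc[used["signal"] <= 0, "strain_id"].unique()
            raise ValueError(f"non-positive signal for used features: {list(bad)[:5]}")
        key = used[["strain_id", "tag", "array_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate (strain, tag, array) record: {dup}")
        roles = df[["array_id", "role", "batch"]].drop_duplicates("array_id")
        for batch, grp in roles.groupby("batch"):
            if not (grp["role"] == "control").any():
                raise ValueError(f"batch {batch!r} has no control array")
        self.records = df.reset_index(drop=True)

    @property
    def arrays(self) -> pd.DataFrame:
        """One row per array: array_id, role, batch, study_id."""
        return (self.records[["array_id", "role", "batch", "study_id"]]
                .drop_duplicates("array_id").reset_index(drop=True))

    def control_arrays(self) -> list[str]:
        arr = self.arrays
        return arr.loc[arr["role"] == "control", "array_id"].tolist()

    def copy(self) -> "TagIntensityTable":
        return TagIntensityTable(self.records.copy())


@dataclass
class ScreenMeta:
    """Per-screen annotations: compound, dose, assay, site, replicate group."""

    table: pd.DataFrame

    REQUIRED = ["screen_id", "compound", "dose", "dose_unit", "assay", "site",
                "replicate_group"]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"screen metadata missing columns: {missing}")
        if df["screen_id"].duplicated().any():
            dup = df.loc[df["screen_id"].duplicated(), "screen_id"].iloc[0]
            raise FormatError(f"duplicate screen_id in metadata: {dup!r}")
        self.table = df.reset_index(drop=True)

    def resolve(self, screen_ids: Iterable[str]) -> pd.DataFrame:
        """Return metadata rows for *screen_ids*; every id must resolve uniquely."""
        idx = self.table.set_index("screen_id")
        missing = [s for s in screen_ids if s not in idx.index]
        if missing:
            raise KeyError(f"screens absent from metadata: {missing[:5]}")
        return idx.loc[list(screen_ids)].reset_index()


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis.

    Defaults follow the published pipeline: one-tailed standard-normal
    P < 0.001 for significant chemical-genetic interactions, gene-wise
    z < −5 for the NIBR convention, a clearance gap of 5.75 FD units for
    HIP hit designation, top 5% most variable genes for cofitness, σ from
    the central 70% of each strain's score distribution, and a 0.5 overlap
    coefficient for calling a response signature detected across datasets.
    """

    alpha_significant: float = 0.001
    alpha_signature_combined: float = 0.05
    nibr_z_cutoff: float = -5.0
    clearance_threshold: float = 5.75
    top_variable_fraction: float = 0.05
    quantile_window: float = 0.70
    min_shared_obs: int = 30
    overlap_match_threshold: float = 0.5
    random_seed: int = 0
    # documented variants of under-specified steps
    mad_scaled: bool = False            # apply the 1.4826 normal-consistency factor
    clearance_positive_only: bool = True
    madl_adjustment: str = "capped"     # "capped": min(0.05/p,1); "pvalue": plain p factor

    def __post_init__(self) -> None:
        for name in ("alpha_significant", "alpha_signature_combined"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.clearance_threshold <= 0:
            raise ValueError("clearance_threshold must be > 0")
        if not 0 < self.top_variable_fraction <= 1:
            raise ValueError("top_variable_fraction must be in (0,1]")
        if not 0 < self.quantile_window <= 1:
            raise ValueError("quantile_window must be in (0,1]")
        if self.min_shared_obs < 2:
            raise ValueError("min_shared_obs must be >= 2")
        if self.madl_adjustment not in ("capped", "pvalue"):
            raise ValueError("madl_adjustment must be 'capped' or 'pvalue'")


# ---------------------------------------------------------------------------
# delimited matrix I/O

def read_matrix(path: str | Path, value_kind: str = "fd",
                orientation: str = "sensitivity_positive") -> ScreenMatrix:
    """Read a tab-delimited strain × screen matrix.

    First row holds screen ids, first column strain ids.  Empty cells and
    "NA" become missing values.  Duplicate ids or non-numeric cells raise
    :class:`FormatError` naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[""])
    dup_rows = df.index[df.index.duplicated()].unique()
    if len(dup_rows):
        raise FormatError(f"{path.name}: duplicate strain ids {list(dup_rows)}")
    dup_cols = df.columns[df.columns.duplicated()].unique()
    if len(dup_cols):
        raise FormatError(f"{path.name}: duplicate screen ids {list(dup_cols)}")
    df = df.replace("NA", np.nan)
    try:
        num = df.astype(float)
    except ValueError:
        for col in df.columns:
            for row, cell in df[col].items():
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path.name}: non-numeric cell {cell!r} at "
                        f"row {row!r}, column {col!r}") from None
        raise
    return ScreenMatrix(num, value_kind=value_kind, orientation=orientation)


def write_matrix(matrix: ScreenMatrix, path: str | Path) -> Path:
    """Write a :class:`ScreenMatrix` as tab-delimited text.

    Values are written with 10 significant digits so a read/write round trip
    reproduces the matrix well inside 6 significant digits; missing values
    become empty cells.
    """
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", na_rep="", float_format="%.10g",
                         index_label="strain")
    return path


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set name: [genes]}``.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Genes
    repeated within one line are kept once (first occurrence order).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# tag table / metadata / JSON I/O

def read_tag_table(path: str | Path) -> TagIntensityTable:
    df = pd.read_csv(path, sep="\t")
    return TagIntensityTable(df)


def write_tag_table(table: TagIntensityTable, path: str | Path) -> Path:
    path = Path(path)
    table.records.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_screen_meta(path: str | Path) -> ScreenMeta:
    return ScreenMeta(pd.read_csv(path, sep="\t"))


def write_screen_meta(meta: ScreenMeta, path: str | Path) -> Path:
    path = Path(path)
    meta.table.to_csv(path, sep="\t", index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")
    return path
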