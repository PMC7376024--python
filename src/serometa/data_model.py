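"""Core domain containers and tabular I/O.

The three study inputs are plain delimited text:

* an abundance matrix (samples x metabolites, relative abundances, possibly
  log2-transformed, with below-detection-limit cells empty or ``NA``),
* per-sample metadata (disease status plus the model covariates), and
* per-metabolite annotation (metabolic group, super-class, xenobiotic flag).

:class:`AbundanceMatrix` wraps the matrix together with an explicit
missingness mask and a processing-state flag so the QC chain can enforce its
order (raw -> filtered -> imputed -> normalized -> scaled).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "STATES",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "read_annotation",
    "validate_cohort",
    "write_table",
    "read_table",
]

#: Legal processing states, in pipeline order.
STATES = ("raw", "filtered", "imputed", "normalized", "scaled")

#: Metadata columns that must be present.
METADATA_REQUIRED = ("sample_id", "status", "sex", "age", "diabetes", "bmi")

#: Annotation columns that must be present.
ANNOTATION_REQUIRED = ("metabolite_id", "group", "superclass")

#: Canonical label of the xenobiotic super-class.
XENOBIOTIC_SUPERCLASS = "xenobiotics"


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundances with an explicit missingness mask.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with metabolite-id columns. Masked
        cells may hold any placeholder (NaN by convention).
    missing_mask
        Boolean DataFrame of the same shape; ``True`` marks a value that was
        missing in the source (below detection limit). The mask survives
        imputation so the original missingness stays auditable.
    state
        One of :data:`STATES`.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    state: str = "raw"
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"values {self.values.shape} and missing_mask "
                f"{self.missing_mask.shape} differ in shape"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dups}")
        if not (
            self.values.index.equals(self.missing_mask.index)
            and self.values.columns.equals(self.missing_mask.columns)
        ):
            raise ValueError("values and missing_mask must share index and columns")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def missing_fraction_per_metabolite(self) -> pd.Series:
        return self.missing_mask.mean(axis=0)

    def missing_fraction_per_sample(self) -> pd.Series:
        return self.missing_mask.mean(axis=1)

    def with_state(self, state: str, note: str | None = None) -> "AbundanceMatrix":
        out = replace(self, state=state, log=list(self.log))
        if note:
            out.log.append(note)
        return out

    def checksum(self) -> str:
        """SHA-256 over values (NaN-stable), mask, ids and state."""
        h = hashlib.sha256()
        h.update(np.nan_to_num(self.values.to_numpy(float), nan=-1e308).tobytes())
        h.update(self.missing_mask.to_numpy(bool).tobytes())
        h.update("\t".join(map(str, self.sample_ids)).encode())
        h.update("\t".join(map(str, self.metabolite_ids)).encode())
        h.update(self.state.encode())
        return h.hexdigest()


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_abundance(
    path: str | Path,
    orientation: str = "samples_in_rows",
    missing_sentinels: Sequence[str] = ("", "NA"),
    sep: str | None = None,
    known_sample_ids: Sequence[str] | None = None,
) -> AbundanceMatrix:
    """Read a raw abundance matrix from delimited text.

    The first column holds row identifiers. ``orientation`` says whether rows
    are samples or metabolites; ``metabolites_in_rows`` input is transposed so
    the returned matrix is always samples x metabolites. With
    ``orientation="auto"`` the layout is detected by comparing row and column
    ids against ``known_sample_ids`` (typically the metadata sample ids);
    both layouts occur in the wild. Cells equal to one of
    ``missing_sentinels`` are flagged missing; any other non-numeric cell is a
    hard error naming the cell. Row and column order follow the file.
    """
    if orientation not in ("samples_in_rows", "metabolites_in_rows", "auto"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_delimited(path, sep)
    if orientation == "auto":
        if known_sample_ids is None:
            raise ValueError("orientation='auto' requires known_sample_ids")
        known = set(map(str, known_sample_ids))
        in_rows = sum(str(x) in known for x in raw.iloc[:, 0])
        in_cols = sum(str(c) in known for c in raw.columns[1:])
        if in_rows == in_cols:
            raise ValueError(
                "cannot auto-detect orientation: sample ids match rows and "
                "columns equally; pass orientation explicitly"
            )
        orientation = (
            "samples_in_rows" if in_rows > in_cols else "metabolites_in_rows"
        )
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path}: {dups}")

    sentinels = set(missing_sentinels)
    mask = raw.isin(sentinels)
    values = pd.DataFrame(
        np.full(raw.shape, np.nan), index=raw.index, columns=raw.columns
    )
    cells = raw.to_numpy(dtype=object)
    out = values.to_numpy()
    bad: tuple[str, str, str] | None = None
    for j in range(cells.shape[1]):
        col = cells[:, j]
        m = mask.iloc[:, j].to_numpy()
        try:
            out[~m, j] = np.asarray(col[~m], dtype=float)
        except ValueError:
            for i in np.flatnonzero(~m):
                try:
                    float(col[i])
                except ValueError:
                    bad = (str(raw.index[i]), str(raw.columns[j]), str(col[i]))
                    break
        if bad:
            raise ValueError(
                f"non-numeric cell at row {bad[0]!r}, column {bad[1]!r}: {bad[2]!r}"
            )
    if orientation == "metabolites_in_rows":
        values, mask = values.T, mask.T
    m = AbundanceMatrix(values=values, missing_mask=mask.astype(bool), state="raw")
    m.log.append(
        f"read {m.n_samples} samples x {m.n_metabolites} metabolites from {path}"
    )
    return m


def write_abundance(
    m: AbundanceMatrix, path: str | Path, missing_sentinel: str = "NA", sep: str = "\t"
) -> None:
    """Write samples-in-rows delimited text; masked cells get the sentinel."""
    out = m.values.copy()
    out = out.mask(m.missing_mask, other=np.nan)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep=missing_sentinel, float_format="%.12g")


def _normalize_categorical(s: pd.Series, mapping: dict[str, str], column: str) -> pd.Series:
    norm = s.astype(str).str.strip().str.lower().map(mapping)
    if norm.isna().any():
        bad = sorted(s[norm.isna()].astype(str).unique())
        raise ValueError(f"unrecognized values in column {column!r}: {bad}")
    return norm


def read_metadata(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read per-sample metadata; normalizes categorical levels.

    Required columns: sample_id, status (case/control), sex (F/M), age,
    diabetes (yes/no), bmi. Optional: ethnicity, site.
    """
    df = _read_delimited(path, sep)
    missing_cols = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    df["status"] = _normalize_categorical(
        df["status"],
        {"case": "case", "patient": "case", "mactel": "case", "control": "control",
         "ctrl": "control", "healthy": "control"},
        "status",
    )
    df["sex"] = _normalize_categorical(
        df["sex"], {"f": "F", "female": "F", "m": "M", "male": "M"}, "sex"
    )
    df["diabetes"] = _normalize_categorical(
        df["diabetes"],
        {"yes": "yes", "y": "yes", "1": "yes", "true": "yes",
         "no": "no", "n": "no", "0": "no", "false": "no"},
        "diabetes",
    )
    df["age"] = pd.to_numeric(df["age"])
    df["bmi"] = pd.to_numeric(df["bmi"])
    for opt in ("ethnicity", "site"):
        if opt in df.columns:
            df[opt] = df[opt].astype(str).str.strip()
    return df.set_index("sample_id", drop=False)


def read_annotation(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read metabolite annotation (group, superclass, xenobiotic flag).

    ``is_xenobiotic`` is derived from the superclass when absent; when present
    it must agree with the superclass.
    """
    df = _read_delimited(path, sep)
    missing_cols = [c for c in ANNOTATION_REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation missing required columns: {missing_cols}")
    df = df.copy()
    df["metabolite_id"] = df["metabolite_id"].astype(str)
    if df["metabolite_id"].duplicated().any():
        dups = sorted(df.loc[df["metabolite_id"].duplicated(), "metabolite_id"].unique())
        raise ValueError(f"duplicate metabolite ids in annotation: {dups}")
    df["group"] = df["group"].astype(str).str.strip()
    df["superclass"] = df["superclass"].astype(str).str.strip()
    derived = df["superclass"].str.lower() == XENOBIOTIC_SUPERCLASS
    if "is_xenobiotic" in df.columns:
        flag = df["is_xenobiotic"].astype(str).str.strip().str.lower().isin(
            ("true", "yes", "1")
        )
        if not flag.equals(derived):
            bad = sorted(df.loc[flag != derived, "metabolite_id"])
            raise ValueError(
                f"is_xenobiotic inconsistent with superclass for: {bad}"
            )
    df["is_xenobiotic"] = derived
    return df.set_index("metabolite_id", drop=False)


def validate_cohort(
    m: AbundanceMatrix, metadata: pd.DataFrame, annotation: pd.DataFrame
) -> None:
    """Cross-check matrix ids against metadata and annotation (hard errors)."""
    missing_samples = [s for s in m.sample_ids if s not in metadata.index]
    if missing_samples:
        raise ValueError(f"samples in matrix absent from metadata: {missing_samples}")
    missing_mets = [x for x in m.metabolite_ids if x not in annotation.index]
    if missing_mets:
        raise ValueError(
            f"metabolites in matrix absent from annotation: {missing_mets}"
        )
    status = metadata.loc[m.sample_ids, "status"]
    if status.nunique() < 2:
        raise ValueError("status must have both case and control levels")


def write_table(df: pd.DataFrame, path: str | Path, columns: Iterable[str] | None = None) -> None:
    """Write a result table as long-format TSV with a stable column order."""
    if columns is not None:
        df = df.loc[:, list(columns)]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
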