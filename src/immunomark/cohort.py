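"""Cohort data model and TSV readers/writers.

A cohort joins censoring-aware clinical metadata (outcome group,
progression-free and overall survival in months) to an analyte matrix
whose columns are either gene transcript abundances (TPM) or immune
cell-type infiltration percentages estimated upstream by deconvolution.

Survival fields follow the clinical-table grammar
``NUMBER [ "(" NUMBER ")" ] [ "+" ]``: the first number is months on the
primary therapy timeline, the optional parenthetical is the
bevacizumab-adjusted alternative, and a trailing ``+`` marks censoring
(no event observed by last follow-up).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteKind",
    "SurvivalValue",
    "SampleRecord",
    "Cohort",
    "CohortError",
    "parse_survival_field",
    "read_cohort",
    "write_cohort",
    "total_immune",
    "group_median",
    "CELL_SUBSETS",
    "GROUPS",
    "load_reference_clinical",
    "load_reference_analytes",
]

AnalyteKind = Literal["gene_tpm", "cell_percent"]

GROUPS = ("long", "intermediate", "short")

#: The eight modeled immune cell subsets whose percentages sum to the
#: "total immune" infiltration fraction.
CELL_SUBSETS = (
    "T_reg cells",
    "CD8+ T cells",
    "M2 macrophages",
    "CD4+ T cells",
    "M1 macrophages",
    "CD14+ monocytes",
    "CD19+ B cells",
    "CD56+ NK cells",
)


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort inputs."""


_SURVIVAL_RE = re.compile(
    r"""^\s*
        (?P<months>\d+(?:\.\d+)?)
        (?:\s*\(\s*(?P<alt>\d+(?:\.\d+)?)\s*\))?
        \s*(?P<cens>\+)?
        \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class SurvivalValue:
    """A survival duration in months with a censoring mark.

    ``alt_months`` carries the optional parenthetical alternative
    timeline (months excluding maintenance bevacizumab).
    """

    months: float
    censored: bool = False
    alt_months: float | None = None

    def __post_init__(self) -> None:
        if self.months < 0:
            raise CohortError(f"negative survival months: {self.months}")
        if self.alt_months is not None and self.alt_months < 0:
            raise CohortError(f"negative alt months: {self.alt_months}")


@dataclass
class SampleRecord:
    sample_id: str
    group: str | None
    pfs: SurvivalValue
    os: SurvivalValue
    maintenance_bev: bool = False
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise CohortError(
                f"unknown outcome group {self.group!r} for sample "
                f"{self.sample_id!r}; expected one of {GROUPS}"
            )


def parse_survival_field(text: str) -> SurvivalValue:
    """Parse one clinical-table survival cell.

    Examples: ``"90+"`` is 90 months censored; ``"62 (51)"`` is an
    observed event at 62 months with an adjusted value of 51;
    ``"76 (64)+"`` is censored at 76 with adjusted 64.
    """
    if not isinstance(text, str):
        raise CohortError(f"survival field must be text, got {type(text).__name__}")
    m = _SURVIVAL_RE.match(text)
    if m is None:
        raise CohortError(f"malformed survival field: {text!r}")
    alt = m.group("alt")
    return SurvivalValue(
        months=float(m.group("months")),
        censored=m.group("cens") is not None,
        alt_months=float(alt) if alt is not None else None,
    )


def _format_survival(v: SurvivalValue) -> str:
    def num(x: float) -> str:
        return f"{int(x)}" if float(x).is_integer() else repr(float(x))

    out = num(v.months)
    if v.alt_months is not None:
        out += f" ({num(v.alt_months)})"
    if v.censored:
        out += "+"
    return out


@dataclass
class Cohort:
    """Sample records joined to a samples x analytes value matrix."""

    records: list[SampleRecord]
    matrix: pd.DataFrame  # index: sample_id, columns: analytes
    kinds: dict[str, AnalyteKind]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate sample ids: {dupes}")
        if self.matrix.index.has_duplicates:
            raise CohortError("duplicate sample ids in matrix")
        if set(ids) != set(self.matrix.index):
            only_meta = sorted(set(ids) - set(self.matrix.index))
            only_matrix = sorted(set(self.matrix.index) - set(ids))
            raise CohortError(
                "sample id mismatch between metadata and matrix; "
                f"metadata-only={only_meta} matrix-only={only_matrix}"
            )
        unknown = sorted(set(self.matrix.columns) - set(self.kinds))
        if unknown:
            raise CohortError(f"analytes without a declared kind: {unknown}")
        for analyte in self.matrix.columns:
            col = self.matrix[analyte].to_numpy(dtype=float)
            if self.kinds[analyte] == "gene_tpm":
                bad = np.flatnonzero(col < 0)
                if bad.size:
                    sid = self.matrix.index[bad[0]]
                    raise CohortError(
                        f"negative TPM at sample {sid!r}, analyte {analyte!r}"
                    )
            else:
                bad = np.flatnonzero((col < 0) | (col > 100))
                if bad.size:
                    sid = self.matrix.index[bad[0]]
                    raise CohortError(
                        f"cell percentage outside [0, 100] at sample {sid!r}, "
                        f"analyte {analyte!r}"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def group_of(self, sample_id: str) -> str | None:
        return self.record(sample_id).group

    def groups(self) -> pd.Series:
        return pd.Series(
            {r.sample_id: r.group for r in self.records}, name="group"
        ).reindex(self.matrix.index)

    def analytes(self, kind: AnalyteKind | None = None) -> list[str]:
        if kind is None:
            return list(self.matrix.columns)
        return [a for a in self.matrix.columns if self.kinds[a] == kind]

    def restrict_groups(self, groups: Iterable[str]) -> "Cohort":
        keep = set(groups)
        records = [r for r in self.records if r.group in keep]
        if not records:
            raise CohortError(f"no samples in groups {sorted(keep)}")
        ids = [r.sample_id for r in records]
        return Cohort(records, self.matrix.loc[ids].copy(), dict(self.kinds))

    def values(self, analyte: str) -> pd.Series:
        if analyte not in self.matrix.columns:
            raise CohortError(f"analyte {analyte!r} not in cohort")
        return self.matrix[analyte]


def read_cohort(matrix_path: Path | str, meta_path: Path | str,
                kinds_path: Path | str) -> Cohort:
    """Read the three cohort TSVs and return a validated :class:`Cohort`."""
    for p in (matrix_path, meta_path, kinds_path):
        if not Path(p).is_file():
            raise CohortError(f"missing input file: {p}")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise CohortError(f"empty analyte matrix: {matrix_path}")
    kinds_df = pd.read_csv(kinds_path, sep="\t")
    if list(kinds_df.columns) != ["analyte", "kind"]:
        raise CohortError(
            f"kinds file must have columns [analyte, kind], got {list(kinds_df.columns)}"
        )
    kinds: dict[str, AnalyteKind] = {}
    for _, row in kinds_df.iterrows():
        if row["kind"] not in ("gene_tpm", "cell_percent"):
            raise CohortError(f"unknown analyte kind {row['kind']!r}")
        kinds[str(row["analyte"])] = row["kind"]
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    records = _records_from_meta(meta)
    return Cohort(records, matrix.astype(float), kinds)


_META_COLUMNS = ("sample_id", "group", "pfs", "os", "maint_bev",
                 "age_band", "ca125_band", "debulking")


def _records_from_meta(meta: pd.DataFrame) -> list[SampleRecord]:
    missing = [c for c in ("sample_id", "group", "pfs", "os") if c not in meta.columns]
    if missing:
        raise CohortError(f"metadata missing required columns: {missing}")
    records = []
    for _, row in meta.iterrows():
        group = row["group"].strip() or None
        covariates = {
            c: str(row[c])
            for c in meta.columns
            if c not in ("sample_id", "group", "pfs", "os", "maint_bev")
        }
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=group,
                pfs=parse_survival_field(row["pfs"]),
                os=parse_survival_field(row["os"]),
                maintenance_bev=str(row.get("maint_bev", "no")).strip().lower()
                in ("yes", "true", "1"),
                covariates=covariates,
            )
        )
    return records


def write_cohort(cohort: Cohort, matrix_path: Path | str, meta_path: Path | str,
                 kinds_path: Path | str) -> None:
    """Write the three cohort TSVs; round-trips finite decimals exactly."""
    matrix = cohort.matrix.copy()
    matrix.index.name = "sample_id"
    matrix.to_csv(matrix_path, sep="\t", float_format="%.10g")
    rows = []
    for r in cohort.records:
        row = {
            "sample_id": r.sample_id,
            "group": r.group or "",
            "pfs": _format_survival(r.pfs),
            "os": _format_survival(r.os),
            "maint_bev": "yes" if r.maintenance_bev else "no",
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    pd.DataFrame(
        {"analyte": list(cohort.matrix.columns),
         "kind": [cohort.kinds[a] for a in cohort.matrix.columns]}
    ).to_csv(kinds_path, sep="\t", index=False)


def total_immune(cohort: Cohort, sample_id: str) -> float:
    """Sum of the eight modeled cell-subset percentages for one sample.

    The assay's "total immune" infiltration is taken as the sum of the
    modeled subsets; a missing subset is an error, never silently zero.
    """
    if sample_id not in cohort.matrix.index:
        raise CohortError(f"unknown sample id {sample_id!r}")
    for subset in CELL_SUBSETS:
        if subset not in cohort.matrix.columns:
            raise CohortError(f"missing immune cell subset analyte: {subset!r}")
    return float(cohort.matrix.loc[sample_id, list(CELL_SUBSETS)].sum())


def group_median(values: Iterable[float]) -> float:
    """Plain median (mean of the central pair for even n).

    Censoring marks are deliberately ignored here: clinical summary
    tables report group medians over the recorded months regardless of
    censoring. Proper censoring handling lives in the survival module.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise CohortError("median of empty list")
    return float(np.median(arr))


# -- packaged reference tables -------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("immunomark").joinpath("data", name))  # type: ignore[arg-type]


def load_reference_clinical() -> pd.DataFrame:
    """Published clinical table of the 26-patient HGSOC discovery cohort."""
    return pd.read_csv(_data_path("reference_clinical.tsv"), sep="\t", dtype=str)


def load_reference_analytes() -> pd.DataFrame:
    """Published per-analyte summary (medians, thresholds, LOO metrics)."""
    return pd.read_csv(_data_path("reference_analytes.tsv"), sep="\t")
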