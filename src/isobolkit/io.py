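"""CSV/JSON readers and writers for the tabular dialects of the toolkit.

Three dialects, all UTF-8 with '.' decimal separator and a header row:

* raw quantal assays: ``drug,adjunct,adjunct_dose,dose,n_protected,n_total``
  (empty ``adjunct`` marks a single-drug assay; rows grouped by
  drug/adjunct/adjunct_dose form one assay);
* summary groups: ``label,mean,dispersion,dispersion_kind,n`` with an
  optional ``df`` column;
* ED50 tables: ``drug,adjunct,adjunct_dose,ed50,sem,n_effective,df``.

JSON equivalents carry the same records as a list of objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .quantal import DoseGroup, ED50Estimate, QuantalAssay
from .summaries import SummaryGroup

__all__ = [
    "read_assays",
    "read_summary_groups",
    "write_ed50_table",
    "read_ed50_table",
]

_ASSAY_COLUMNS = ["drug", "adjunct", "adjunct_dose", "dose", "n_protected", "n_total"]


def _frame_from_path(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_assays(path: str | Path) -> list[QuantalAssay]:
    """Read raw dose-group tables; one assay per (drug, adjunct, dose) key."""
    df = _frame_from_path(path, _ASSAY_COLUMNS)
    if df.empty:
        raise ValueError(f"{path}: assay table is empty")
    assays = []
    for (drug, adjunct, adjunct_dose), block in df.groupby(
        ["drug", "adjunct", "adjunct_dose"], sort=False, dropna=False
    ):
        block = block.sort_values("dose")
        groups = tuple(
            DoseGroup(
                dose=float(row.dose),
                n_protected=int(row.n_protected),
                n_total=int(row.n_total),
            )
            for row in block.itertuples()
        )
        has_adjunct = bool(str(adjunct)) and str(adjunct).lower() != "nan"
        assays.append(
            QuantalAssay(
                drug_label=str(drug),
                groups=groups,
                adjunct_label=str(adjunct) if has_adjunct else None,
                adjunct_dose=float(adjunct_dose) if has_adjunct else None,
            )
        )
    return assays


def read_summary_groups(path: str | Path) -> list[SummaryGroup]:
    """Read a summary-statistic table into SummaryGroup records."""
    df = _frame_from_path(path, ["label", "mean", "dispersion", "dispersion_kind", "n"])
    if df.empty:
        raise ValueError(f"{path}: summary table is empty")
    groups = []
    for row in df.itertuples():
        df_override = getattr(row, "df", None)
        if df_override in ("", None) or pd.isna(df_override):
            df_override = None
        else:
            df_override = float(df_override)
        groups.append(
            SummaryGroup(
                label=str(row.label),
                mean=float(row.mean),
                dispersion=float(row.dispersion),
                dispersion_kind=str(row.dispersion_kind),
                n=int(row.n),
                df=df_override,
            )
        )
    return groups


def write_ed50_table(
    records: Sequence[tuple[QuantalAssay, ED50Estimate]], path: str | Path
) -> pd.DataFrame:
    """Write fitted ED50s (one row per assay) as CSV; returns the frame."""
    rows = [
        {
            "drug": assay.drug_label,
            "adjunct": assay.adjunct_label or "",
            "adjunct_dose": assay.adjunct_dose or 0.0,
            "ed50": est.ed50,
            "sem": est.sem,
            "n_effective": est.n_effective,
            "df": est.df,
        }
        for assay, est in records
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def read_ed50_table(path: str | Path) -> pd.DataFrame:
    """Read an ED50 table (fitted output or summary fixture)."""
    df = _frame_from_path(path, ["drug", "adjunct", "adjunct_dose", "ed50", "sem"])
    if df.empty:
        raise ValueError(f"{path}: ED50 table is empty")
    return df
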