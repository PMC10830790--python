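"""Study-level orchestration: fit -> tests -> isoboles -> report bundle.

``run_study`` drives the full workflow of a fixed-dose combination
study from summary tables: per-drug one-way ANOVA with Dunnett's
post-hoc on the ED50 table, pooled t-tests on brain concentrations,
and (when single-drug adjunct ED50s are supplied) the isobolographic
transformation with interaction classification.

The report bundle is a directory of CSV files plus a JSON manifest
recording the package version, seed, significance levels and SHA-256
digests of the archived inputs; re-running on the archived inputs
reproduces every report file bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import load_brain_concentrations, load_mes_ed50_summary
from .isobole import (
    FixedDoseDesign,
    additive_ed50,
    classify_interaction,
    isobologram_coordinates,
)
from .quantal import ED50Estimate
from .summaries import (
    AnovaResult,
    DunnettResult,
    SummaryGroup,
    TTestResult,
    anova_from_summaries,
    dunnett_from_summaries,
    pooled_t_from_summaries,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "render_table", "group_label"]

logger = logging.getLogger("isobolkit")


@dataclass(frozen=True)
class StudyConfig:
    """Inputs and knobs for one study run.

    ``None`` paths fall back to the bundled reference tables; an
    isobole design table is optional (adjunct single-drug ED50s are
    often external to the ED50 table itself).
    """

    out_dir: str | Path
    ed50_summary: str | Path | None = None
    concentrations: str | Path | None = None
    isobole_design: str | Path | None = None
    alpha: float = 0.05
    alpha_strict: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5], got {self.alpha}")


@dataclass
class StudyReport:
    """All computed tables of one run plus reproducibility metadata."""

    ed50_table: pd.DataFrame
    anova: dict[str, AnovaResult]
    dunnett: dict[str, DunnettResult]
    concentration_table: pd.DataFrame | None
    concentration_tests: dict[str, TTestResult]
    interactions: pd.DataFrame | None
    coordinates: list[dict]
    metadata: dict = field(default_factory=dict)


def group_label(adjunct: str, adjunct_dose: float) -> str:
    """Row label for an ED50 table group ('vehicle' or 'ADJ (dose)')."""
    if not adjunct or adjunct_dose == 0:
        return "vehicle"
    return f"{adjunct} ({adjunct_dose:g})"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_table(
    path: str | Path | None, fallback, required: list[str], name: str
) -> tuple[pd.DataFrame, str | None]:
    if path is None:
        return fallback(), None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    df = pd.read_csv(path, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{name} table is empty: {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table {path} missing columns {missing}")
    return df, str(path)


def _ed50_summary_groups(block: pd.DataFrame) -> list[SummaryGroup]:
    return [
        SummaryGroup(
            label=group_label(str(row.adjunct), float(row.adjunct_dose)),
            mean=float(row.ed50),
            dispersion=float(row.sem),
            dispersion_kind="SEM",
            n=int(row.n),
            df=float(int(row.n) - 2),
        )
        for row in block.itertuples()
    ]


def _stars(p: float, alpha: float, alpha_strict: float) -> str:
    if p < alpha_strict:
        return "**"
    if p < alpha:
        return "*"
    return ""


def run_study(config: StudyConfig) -> StudyReport:
    """Run the complete analysis and write the report bundle.

    Stages: (1) ED50 ANOVA + Dunnett per drug; (2) brain-concentration
    pooled t-tests; (3) optional isobolographic interaction
    classification.  Any stage failure aborts with an error naming the
    stage.  Deterministic given inputs and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs_dir = out_dir / "inputs"
    inputs_dir.mkdir(exist_ok=True)
    digests: dict[str, str] = {}

    # ---- stage: ED50 table --------------------------------------------
    try:
        ed50_df, ed50_path = _load_table(
            config.ed50_summary,
            load_mes_ed50_summary,
            ["drug", "adjunct", "adjunct_dose", "ed50", "sem", "n"],
            "ed50_summary",
        )
    except Exception as exc:
        raise RuntimeError(f"stage ed50_summary: {exc}") from exc
    logger.info("ed50 stage: %d rows, %d drugs", len(ed50_df), ed50_df.drug.nunique())

    anova: dict[str, AnovaResult] = {}
    dunnett: dict[str, DunnettResult] = {}
    table_rows = []
    try:
        for drug, block in ed50_df.groupby("drug", sort=False):
            groups = _ed50_summary_groups(block)
            a = anova_from_summaries(groups)
            d = dunnett_from_summaries(
                groups, "vehicle", anova=a, rng=np.random.default_rng(config.seed)
            )
            anova[str(drug)] = a
            dunnett[str(drug)] = d
            for g in groups:
                if g.label == "vehicle":
                    stars = ""
                else:
                    cmp = d[g.label]
                    stars = _stars(cmp.p_value, config.alpha, config.alpha_strict)
                table_rows.append(
                    {
                        "drug": drug,
                        "group": g.label,
                        "ed50": g.mean,
                        "sem": g.dispersion,
                        "n": g.n,
                        "stars": stars,
                        "f_stat": a.f_stat,
                        "df_between": a.df_between,
                        "df_within": a.df_within,
                        "anova_p": a.p_value,
                    }
                )
    except Exception as exc:
        raise RuntimeError(f"stage anova_dunnett: {exc}") from exc
    ed50_table = pd.DataFrame(table_rows)

    # ---- stage: brain concentrations ----------------------------------
    concentration_tests: dict[str, TTestResult] = {}
    conc_df = None
    try:
        conc_df, conc_path = _load_table(
            config.concentrations,
            load_brain_concentrations,
            ["drug", "group", "mean", "sd", "n"],
            "concentrations",
        )
        for drug, block in conc_df.groupby("drug", sort=False):
            if len(block) != 2:
                raise ValueError(
                    f"concentration comparison for {drug!r} needs exactly 2 rows"
                )
            a_row, b_row = block.itertuples()
            sg = lambda row: SummaryGroup(
                label=str(row.group),
                mean=float(row.mean),
                dispersion=float(row.sd),
                dispersion_kind="SD",
                n=int(row.n),
            )
            concentration_tests[str(drug)] = pooled_t_from_summaries(sg(a_row), sg(b_row))
    except Exception as exc:
        raise RuntimeError(f"stage concentrations: {exc}") from exc

    # ---- stage: isobole ------------------------------------------------
    interactions = None
    coordinates: list[dict] = []
    iso_path = None
    if config.isobole_design is not None:
        try:
            design_df, iso_path = _load_table(
                config.isobole_design,
                None,
                ["varied_drug", "adjunct_drug", "adjunct_ed50", "adjunct_sem", "adjunct_n"],
                "isobole_design",
            )
            interactions = _isobole_stage(design_df, ed50_df, config, coordinates)
        except Exception as exc:
            raise RuntimeError(f"stage isobole: {exc}") from exc

    # ---- archive inputs and write the bundle ---------------------------
    for src in (ed50_path, conc_path, iso_path):
        if src is not None:
            dst = inputs_dir / Path(src).name
            if Path(src).resolve() != dst.resolve():
                shutil.copyfile(src, dst)
            digests[dst.name] = _sha256(dst)
    if ed50_path is None:
        (inputs_dir / "ed50_summary.csv").write_text(ed50_df.to_csv(index=False))
        digests["ed50_summary.csv"] = _sha256(inputs_dir / "ed50_summary.csv")
    if conc_path is None and conc_df is not None:
        (inputs_dir / "concentrations.csv").write_text(conc_df.to_csv(index=False))
        digests["concentrations.csv"] = _sha256(inputs_dir / "concentrations.csv")

    report = StudyReport(
        ed50_table=ed50_table,
        anova=anova,
        dunnett=dunnett,
        concentration_table=conc_df,
        concentration_tests=concentration_tests,
        interactions=interactions,
        coordinates=coordinates,
        metadata={
            "isobolkit_version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "alpha_strict": config.alpha_strict,
            "input_sha256": digests,
        },
    )
    _write_bundle(report, out_dir)
    return report


def _isobole_stage(
    design_df: pd.DataFrame,
    ed50_df: pd.DataFrame,
    config: StudyConfig,
    coordinates: list[dict],
) -> pd.DataFrame:
    rows = []
    for drow in design_df.itertuples():
        varied_label = str(drow.varied_drug)
        adjunct_label = str(drow.adjunct_drug)
        block = ed50_df[ed50_df.drug == varied_label]
        vehicle = block[block.adjunct_dose == 0]
        if block.empty or vehicle.empty:
            raise ValueError(f"no vehicle ED50 row for drug {varied_label!r}")
        v = vehicle.iloc[0]
        # index by name: pandas Series.sem/.n are methods, not columns
        varied = ED50Estimate(
            ed50=float(v["ed50"]), sem=float(v["sem"]),
            n_effective=int(v["n"]), df=float(int(v["n"]) - 2),
        )
        adjunct = ED50Estimate(
            ed50=float(drow.adjunct_ed50), sem=float(drow.adjunct_sem),
            n_effective=int(drow.adjunct_n), df=float(int(drow.adjunct_n) - 2),
        )
        results = []
        for _, mix in block[block.adjunct_dose > 0].iterrows():
            dose = float(mix["adjunct_dose"])
            design = FixedDoseDesign(
                varied=varied, adjunct=adjunct, adjunct_dose=dose,
                varied_label=varied_label, adjunct_label=adjunct_label,
            )
            prediction = additive_ed50(design)
            mix_est = ED50Estimate(
                ed50=float(mix["ed50"]), sem=float(mix["sem"]),
                n_effective=int(mix["n"]), df=float(int(mix["n"]) - 2),
            )
            result = classify_interaction(
                mix_est, prediction, alpha=config.alpha,
                varied_label=varied_label, adjunct_label=adjunct_label,
            )
            results.append(result)
            rows.append(
                {
                    "varied_drug": varied_label,
                    "adjunct_drug": adjunct_label,
                    "adjunct_dose": dose,
                    "ed50_mix": mix_est.ed50,
                    "sem_mix": mix_est.sem,
                    "ed50_add": prediction.ed50_add,
                    "sem_add": prediction.sem_add,
                    "t": result.test.t_stat,
                    "df": result.test.df,
                    "p": result.test.p_value,
                    "classification": result.classification,
                }
            )
        coordinates.append(
            isobologram_coordinates(
                varied, adjunct, results,
                varied_label=varied_label, adjunct_label=adjunct_label,
            ).to_dict()
        )
    return pd.DataFrame(rows)


def _write_bundle(report: StudyReport, out_dir: Path) -> None:
    report.ed50_table.to_csv(out_dir / "ed50_anova.csv", index=False)
    dunnett_rows = [
        {
            "drug": drug,
            "group": c.label,
            "t": c.t_stat,
            "p": c.p_value,
            "sig_005": c.significant_at_005,
            "sig_001": c.significant_at_001,
        }
        for drug, res in report.dunnett.items()
        for c in res.comparisons
    ]
    pd.DataFrame(dunnett_rows).to_csv(out_dir / "dunnett.csv", index=False)
    if report.concentration_tests:
        conc_rows = [
            {"drug": drug, "t": t.t_stat, "df": t.df, "p": t.p_value}
            for drug, t in report.concentration_tests.items()
        ]
        pd.DataFrame(conc_rows).to_csv(out_dir / "concentration_ttests.csv", index=False)
    if report.interactions is not None:
        report.interactions.to_csv(out_dir / "interactions.csv", index=False)
    if report.coordinates:
        (out_dir / "coordinates.json").write_text(
            json.dumps(report.coordinates, indent=2, sort_keys=True) + "\n"
        )
    (out_dir / "manifest.json").write_text(
        json.dumps(report.metadata, indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# text rendering


def _fmt_dose(x: float) -> str:
    return f"{x:.1f}" if x > 100 else f"{x:.2f}"


def render_table(report: StudyReport, which: str) -> str:
    """Fixed-width text table in 'mean +/- dispersion, n, statistic' layout.

    ``which`` selects ``'ed50'``, ``'concentrations'`` or
    ``'interactions'``.  Stars follow the usual convention: ``*`` for
    p < 0.05 and ``**`` for p < 0.01 against the vehicle control.
    """
    if which == "ed50":
        lines = [f"{'Drug combination':<24}{'ED50 (+/- SEM)':>20}{'n':>6}"]
        for drug, block in report.ed50_table.groupby("drug", sort=False):
            for row in block.itertuples():
                label = f"{drug} + {row.group}"
                value = f"{_fmt_dose(row.ed50)} +/- {_fmt_dose(row.sem)}{row.stars}"
                lines.append(f"{label:<24}{value:>20}{row.n:>6}")
            a = report.anova[str(drug)]
            lines.append(
                f"  one-way ANOVA: F({a.df_between},{a.df_within}) = "
                f"{a.f_stat:.3f}, p = {a.p_value:.4g}"
            )
        return "\n".join(lines)
    if which == "concentrations":
        if report.concentration_table is None:
            raise ValueError("report has no concentration table")
        lines = [f"{'Drug combination':<28}{'ASM (ug/ml +/- SD)':>22}{'n':>6}"]
        for drug, block in report.concentration_table.groupby("drug", sort=False):
            for row in block.itertuples():
                label = f"{drug} ({row.asm_dose:g}) + {row.group}"
                value = f"{row.mean:g} +/- {row.sd:g}"
                lines.append(f"{label:<28}{value:>22}{row.n:>6}")
            t = report.concentration_tests[str(drug)]
            lines.append(
                f"  Student's t-test: t({t.df:g}) = {abs(t.t_stat):.3f}, "
                f"p = {t.p_value:.3f}"
            )
        return "\n".join(lines)
    if which == "interactions":
        if report.interactions is None:
            raise ValueError("report has no interaction table")
        lines = [
            f"{'Combination':<22}{'ED50 mix':>12}{'ED50 add':>12}"
            f"{'t':>8}{'p':>8}  classification"
        ]
        for row in report.interactions.itertuples():
            label = f"{row.varied_drug} + {row.adjunct_drug} ({row.adjunct_dose:g})"
            lines.append(
                f"{label:<22}{row.ed50_mix:>12.2f}{row.ed50_add:>12.2f}"
                f"{row.t:>8.3f}{row.p:>8.3f}  {row.classification}"
            )
        return "\n".join(lines)
    raise ValueError(f"unknown table selector {which!r}")
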