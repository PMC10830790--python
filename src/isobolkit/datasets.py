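"""Bundled reference summary tables.

Regression fixtures from a fixed-dose imperatorin (IMP) combination
study in the mouse MES model, covering four antiseizure medications:
lacosamide (LCM), oxcarbazepine (OXC), pregabalin (PGB) and topiramate
(TPM).

``load_mes_ed50_summary`` — ED50 +/- SEM (mg/kg) of each ASM alone
(adjunct_dose 0) and combined with IMP at 25 or 50 mg/kg; ``n`` is the
number of animals in the 4th-6th probit window of each determination.
The intermediate PGB row is taken as the 25 mg/kg adjunct group,
consistent with the design of the other drug blocks.

``load_brain_concentrations`` — total brain ASM concentrations
(mean +/- SD, ug/ml, n = 8 brains) at the ASM's combination ED50 dose,
with and without IMP 50 mg/kg.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_mes_ed50_summary", "load_brain_concentrations"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("isobolkit.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, keep_default_na=False)


def load_mes_ed50_summary() -> pd.DataFrame:
    """ED50 summary table: drug, adjunct, adjunct_dose, ed50, sem, n."""
    df = _read("ed50_mes_imp.csv")
    return df.astype(
        {"adjunct_dose": float, "ed50": float, "sem": float, "n": int}
    )


def load_brain_concentrations() -> pd.DataFrame:
    """Brain concentration table: drug, asm_dose, group, mean, sd, n."""
    df = _read("brain_conc_imp.csv")
    return df.astype({"asm_dose": float, "mean": float, "sd": float, "n": int})
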