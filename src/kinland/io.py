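"""Tabular I/O for the biophysics data formats.

Plain CSV schemas, one per experiment:

* ITC: ``injection_volume_uL, heat_ucal`` with the cell/syringe protocol
  carried in ``# key = value`` header comments;
* DSF: ``temperature_C, fluorescence``;
* SPR: ``concentration_nM, response_RU``;
* activity: ``concentration_uM, activity_fraction``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .thermo import ITCIsotherm, InjectionSchedule


def write_itc_csv(isotherm: ITCIsotherm, path: str | Path) -> None:
    sched = isotherm.schedule
    header = [
        f"# cell_volume_ul = {sched.cell_volume_ul!r}",
        f"# cell_conc_M = {sched.cell_conc_M!r}",
        f"# syringe_conc_M = {sched.syringe_conc_M!r}",
        f"# temperature_K = {sched.temperature_K!r}",
    ]
    body = pd.DataFrame({
        "injection_volume_uL": sched.injection_volumes_ul,
        "heat_ucal": isotherm.heats_ucal,
    }).to_csv(index=False)
    Path(path).write_text("\n".join(header) + "\n" + body)


def read_itc_csv(path: str | Path) -> ITCIsotherm:
    meta = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") and "=" in line:
            key, value = line.lstrip("# ").split("=", 1)
            meta[key.strip()] = float(value)
    table = pd.read_csv(path, comment="#")
    schedule = InjectionSchedule(
        cell_volume_ul=meta.get("cell_volume_ul", 200.0),
        cell_conc_M=meta.get("cell_conc_M", 10e-6),
        syringe_conc_M=meta.get("syringe_conc_M", 100e-6),
        injection_volumes_ul=table["injection_volume_uL"].tolist(),
        temperature_K=meta.get("temperature_K", 303.15),
    )
    heats = table["heat_ucal"].to_numpy(float)
    # reconstruct the cumulative molar ratio from the schedule
    m, x = schedule.cell_conc_M, 0.0
    ratios = []
    for dv in schedule.injection_volumes_ul:
        f = dv / schedule.cell_volume_ul
        m *= (1.0 - f)
        x = x * (1.0 - f) + schedule.syringe_conc_M * f
        ratios.append(x / m)
    return ITCIsotherm(
        schedule=schedule, heats_ucal=heats, molar_ratio=np.asarray(ratios)
    )


def _simple_reader(columns: tuple[str, str]):
    def read(path: str | Path) -> pd.DataFrame:
        table = pd.read_csv(path, comment="#")
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return table[list(columns)]
    return read


read_dsf_csv = _simple_reader(("temperature_C", "fluorescence"))
read_spr_csv = _simple_reader(("concentration_nM", "response_RU"))
read_activity_csv = _simple_reader(("concentration_uM", "activity_fraction"))


def write_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(table.to_csv(index=False))
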