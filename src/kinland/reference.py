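"""Packaged experimental reference values.

Measured dissociation constants, thermal shifts and melting temperatures
for the CDK1/CDK2 inhibitor panel. These numbers are experimental inputs:
the package uses them as generator truths for recovery tests, as inputs to
selectivity arithmetic, and as table-formatting fixtures. Nothing in the
package computes them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("kinland.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")


def itc_affinities() -> pd.DataFrame:
    """ITC Kd panel (nM): inhibitor × state, with SD and bounded flags."""
    table = _read("reference_affinities.csv")
    table["bounded"] = table["bounded"].astype(bool)
    return table


def itc_kd_nM(inhibitor: str, state: str) -> float:
    """Convenience lookup of one measured ITC Kd in nM."""
    table = itc_affinities()
    row = table[(table.inhibitor == inhibitor) & (table.state == state)]
    if len(row) != 1:
        raise KeyError(f"no unique entry for {(inhibitor, state)!r}")
    if bool(row.bounded.iloc[0]):
        raise ValueError(
            f"{inhibitor}/{state}: only a lower bound on Kd is known"
        )
    return float(row.kd_nM.iloc[0])


def spr_and_shifts() -> pd.DataFrame:
    """SPR Kd (nM) and DSF thermal shifts (°C) for cyclin-free CDKs."""
    return _read("reference_biophys.csv")


def apo_melting() -> pd.DataFrame:
    """Apo melting temperatures of monomeric CDK1/CDK2 (°C)."""
    return _read("reference_melting.csv")
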