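"""Orchestration: structures and biophysics tables in, reports out.

A :class:`RunConfig` (YAML on disk) names the coordinate files with their
kinase/state labels and the biophysics CSVs with their fit models.
:func:`run_structural_report` computes, per structure, the inter-lobe
contact census, both spine assessments and the P-loop class, then the
pairwise superposition RMSD matrix and the contact ranking across states.
:func:`run_affinity_report` dispatches each CSV to its fitter and builds
the inhibitor × state affinity table with thermodynamic signatures and
fold-selectivity columns.

Reports are deterministic given config + seed: JSON is written with sorted
keys and fixed float precision, and single-structure failures are recorded
in the bundle rather than aborting the run. Bundles are validated against
pydantic report models (a JSON schema is exportable via
:func:`report_json_schema`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as kio
from .conformation import (
    assess_spine,
    classify_ploop,
    compare_states,
    contact_census,
    superpose,
)
from .elements import ElementMap, default_element_map
from .errors import ConfigurationError, KinlandError
from .structure import read_structure, standardize
from .synth import toy_element_map
from .thermo import (
    build_affinity_table,
    delta_tm,
    fit_boltzmann_melt,
    fit_ic50,
    fit_one_site,
    fit_spr_affinity,
    thermo_signature,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class StructureEntry(BaseModel):
    path: str
    kinase: str
    state: Literal["cyclin_free", "cyclin_bound"]
    label: str
    chain: Optional[str] = None
    chain_roles: dict[str, str] = Field(default_factory=dict)


class BiophysicsEntry(BaseModel):
    path: str
    model: Literal["itc", "dsf", "spr", "ic50"]
    inhibitor: str
    state: str
    apo: bool = False  # DSF only: marks the no-ligand reference melt


class RunConfig(BaseModel):
    structures: list[StructureEntry] = Field(default_factory=list)
    biophysics: list[BiophysicsEntry] = Field(default_factory=list)
    element_map_overrides: dict = Field(default_factory=dict)
    contact_cutoff: float = 4.0
    census_mode: Literal["lobe_vs_lobe", "element_pairs"] = "lobe_vs_lobe"
    link_threshold: float = 4.5
    coordination_threshold: float = 3.5
    atom_set: Literal["calpha", "all_heavy"] = "calpha"
    output_dir: str = "kinland_out"
    seed: int = 0

    @field_validator("contact_cutoff", "link_threshold",
                     "coordination_threshold")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v

    def validate_paths(self) -> None:
        missing = [
            e.path for e in (*self.structures, *self.biophysics)
            if not Path(e.path).exists()
        ]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**(yaml.safe_load(Path(path).read_text()) or {}))
        cfg.validate_paths()
        return cfg


def element_map_for(kinase: str, overrides: dict | None = None) -> ElementMap:
    """Element map by kinase name; 'TOY' maps to the toy two-lobe layout."""
    emap = toy_element_map() if kinase.upper() == "TOY" \
        else default_element_map(kinase)
    if overrides:
        per_kinase = overrides.get(kinase.upper(), overrides.get(kinase, {}))
        if per_kinase:
            emap = emap.with_overrides(per_kinase)
    return emap


# ---------------------------------------------------------------------------
# report models (bundle schema)
# ---------------------------------------------------------------------------

class StructureMetrics(BaseModel):
    label: str
    state: str
    kinase: str
    n_atoms: int
    total_contacts: int
    per_element_contacts: dict[str, int]
    r_spine_assembled: bool
    r_spine_gaps: list[float]
    c_spine_assembled: bool
    c_spine_gaps: list[float]
    ploop_label: str
    ploop_d_pocket: float
    ploop_d_glu: float


class StructuralReport(BaseModel):
    cutoff: float
    census_mode: str
    structures: list[StructureMetrics]
    rmsd_matrix: dict[str, dict[str, float]]
    ranking: list[dict]
    minimal_states: list[str]
    unique_minimum: bool
    failures: dict[str, str]


class AffinityFit(BaseModel):
    inhibitor: str
    state: str
    model: str
    converged: bool
    bounded: bool
    params: dict[str, list[float]]  # name -> [estimate, stderr]
    warnings: list[str]
    signature: Optional[dict[str, float]] = None


class AffinityReport(BaseModel):
    fits: list[AffinityFit]
    affinity_table: list[dict]
    delta_tm: list[dict]
    failures: dict[str, str]


def report_json_schema() -> dict:
    """JSON schema of the two report bundles."""
    return {
        "structural_report": StructuralReport.model_json_schema(),
        "affinity_report": AffinityReport.model_json_schema(),
    }


# ---------------------------------------------------------------------------
# structural report
# ---------------------------------------------------------------------------

def run_structural_report(config: RunConfig) -> dict:
    """Full structural comparison; returns the validated bundle as a dict."""
    if not config.structures:
        raise ConfigurationError("config lists no structures")
    metrics: list[StructureMetrics] = []
    models = {}
    failures: dict[str, str] = {}
    censuses = {}
    for entry in config.structures:
        try:
            model = standardize(read_structure(
                entry.path, chain_roles=entry.chain_roles or None
            ))
            emap = element_map_for(entry.kinase, config.element_map_overrides)
            census = contact_census(
                model, emap, cutoff=config.contact_cutoff,
                mode=config.census_mode, chain=entry.chain, state=entry.label,
            )
            spines = {
                s: assess_spine(model, emap, spine=s,
                                link_threshold=config.link_threshold,
                                chain=entry.chain)
                if (emap.r_spine_residues if s == "R"
                    else emap.c_spine_residues) else None
                for s in ("R", "C")
            }
            ploop = classify_ploop(
                model, emap,
                coordination_threshold=config.coordination_threshold,
                chain=entry.chain,
            ) if emap.ploop_tyrosine else None
            metrics.append(StructureMetrics(
                label=entry.label, state=entry.state, kinase=entry.kinase,
                n_atoms=len(model),
                total_contacts=census.total_contacts,
                per_element_contacts={
                    f"{a}|{b}": n
                    for (a, b), n in sorted(census.per_element_contacts.items())
                },
                r_spine_assembled=spines["R"].assembled if spines["R"] else True,
                r_spine_gaps=_finite(spines["R"].residue_gaps) if spines["R"] else [],
                c_spine_assembled=spines["C"].assembled if spines["C"] else True,
                c_spine_gaps=_finite(spines["C"].residue_gaps) if spines["C"] else [],
                ploop_label=ploop.label if ploop else "indeterminate",
                ploop_d_pocket=_round(ploop.d_pocket) if ploop else float("nan"),
                ploop_d_glu=_round(ploop.d_glu) if ploop else float("nan"),
            ))
            models[entry.label] = model
            censuses[entry.label] = census
            logger.info("structure %s: %d atoms in, %d contacts out",
                        entry.label, len(model), census.total_contacts)
        except KinlandError as exc:
            failures[entry.label] = str(exc)
            logger.warning("structure %s failed: %s", entry.label, exc)

    labels = list(models)
    rmsd = {a: {} for a in labels}
    for i, a in enumerate(labels):
        for b in labels[i:]:
            if a == b:
                value = 0.0
            else:
                try:
                    value = _round(
                        superpose(models[a], models[b],
                                  atom_set=config.atom_set).rmsd
                    )
                except KinlandError as exc:
                    failures[f"superpose:{a}|{b}"] = str(exc)
                    continue
            rmsd[a][b] = value
            rmsd[b][a] = value

    if len(censuses) >= 2:
        ranking = compare_states(censuses)
        rank_rows = ranking.table.to_dict(orient="records")
        minimal, unique = ranking.minimal_states, ranking.unique_minimum
    elif censuses:
        only = next(iter(censuses))
        rank_rows = [{"state": only,
                      "total_contacts": censuses[only].total_contacts,
                      "is_minimum": True}]
        minimal, unique = [only], True
    else:
        rank_rows, minimal, unique = [], [], False

    report = StructuralReport(
        cutoff=config.contact_cutoff, census_mode=config.census_mode,
        structures=metrics, rmsd_matrix=rmsd, ranking=rank_rows,
        minimal_states=minimal, unique_minimum=unique, failures=failures,
    )
    return report.model_dump()


def _round(x: float, digits: int = 6) -> float:
    # significant figures, not decimal places: Kd values in molar are tiny
    return float(f"{x:.{digits}g}") if np.isfinite(x) else float(x)


def _finite(gaps: list[float]) -> list[float]:
    return [_round(g) if np.isfinite(g) else -1.0 for g in gaps]


# ---------------------------------------------------------------------------
# affinity report
# ---------------------------------------------------------------------------

_FITTERS = {
    "itc": lambda path: fit_one_site(kio.read_itc_csv(path)),
    "dsf": lambda path: fit_boltzmann_melt(
        *kio.read_dsf_csv(path).to_numpy().T
    ),
    "spr": lambda path: fit_spr_affinity(
        *kio.read_spr_csv(path).to_numpy().T
    ),
    "ic50": lambda path: fit_ic50(
        *kio.read_activity_csv(path).to_numpy().T
    ),
}


def run_affinity_report(config: RunConfig) -> dict:
    """Fit every biophysics entry and assemble the comparison tables."""
    fits: list[AffinityFit] = []
    failures: dict[str, str] = {}
    itc_fits = {}
    melts: dict[tuple[str, str, bool], float] = {}
    for entry in config.biophysics:
        key = f"{entry.inhibitor}|{entry.state}|{entry.model}"
        try:
            fit = _FITTERS[entry.model](entry.path)
            signature = None
            if entry.model == "itc" and fit.converged and not fit.bounded:
                sig = thermo_signature(fit.value("kd_M"),
                                       fit.value("dh_kcal"))
                signature = {"dg": _round(sig.dg), "dh": _round(sig.dh),
                             "minus_tds": _round(sig.minus_tds)}
            fits.append(AffinityFit(
                inhibitor=entry.inhibitor, state=entry.state,
                model=entry.model, converged=fit.converged,
                bounded=fit.bounded,
                params={k: [_round(v), _round(se)]
                        for k, (v, se) in fit.params.items()},
                warnings=list(fit.warnings), signature=signature,
            ))
            if entry.model == "itc":
                itc_fits[(entry.inhibitor, entry.state)] = fit
            elif entry.model == "dsf" and fit.converged:
                melts[(entry.inhibitor, entry.state, entry.apo)] = \
                    fit.value("tm")
            logger.info("fit %s: converged=%s", key, fit.converged)
        except (KinlandError, KeyError, ValueError) as exc:
            failures[key] = str(exc)
            logger.warning("fit %s failed: %s", key, exc)

    table = build_affinity_table(itc_fits) if itc_fits else pd.DataFrame()

    shifts = []
    apo_tm = {state: tm for (_, state, apo), tm in melts.items() if apo}
    for (inhibitor, state, apo), tm in sorted(melts.items()):
        if not apo and state in apo_tm:
            shifts.append({
                "inhibitor": inhibitor, "state": state,
                "tm_C": _round(tm),
                "delta_tm_C": _round(delta_tm(tm, apo_tm[state])),
            })

    report = AffinityReport(
        fits=fits,
        affinity_table=json.loads(table.to_json(orient="records"))
        if len(table) else [],
        delta_tm=shifts,
        failures=failures,
    )
    return report.model_dump()


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def run(config: RunConfig | str | Path) -> dict[str, Path]:
    """Run both reports and write TSV + JSON bundles to the output dir."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.structures:
        bundle = run_structural_report(config)
        written["structural_json"] = _write_json(
            bundle, outdir / "structural_report.json"
        )
        rows = pd.DataFrame([
            {k: v for k, v in s.items() if not isinstance(v, (dict, list))}
            for s in bundle["structures"]
        ])
        written["structural_tsv"] = _write_tsv(
            rows, outdir / "structural_report.tsv"
        )
    if config.biophysics:
        bundle = run_affinity_report(config)
        written["affinity_json"] = _write_json(
            bundle, outdir / "affinity_report.json"
        )
        rows = pd.DataFrame([
            {
                "inhibitor": f["inhibitor"], "state": f["state"],
                "model": f["model"], "converged": f["converged"],
                "bounded": f["bounded"],
                **{f"{k}": v[0] for k, v in f["params"].items()},
            }
            for f in bundle["fits"]
        ])
        written["affinity_tsv"] = _write_tsv(
            rows, outdir / "affinity_report.tsv"
        )
    return written


def _write_json(bundle: dict, path: Path) -> Path:
    path.write_text(json.dumps(bundle, indent=2, sort_keys=True,
                               allow_nan=True) + "\n")
    return path


def _write_tsv(rows: pd.DataFrame, path: Path) -> Path:
    path.write_text(rows.to_csv(sep="\t", index=False))
    return path
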