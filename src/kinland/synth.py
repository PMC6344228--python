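"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one experiment:

* ``gen_itc`` — the emulated titration protocol (0.5 µL priming injection
  then 19 × 2 µL of 100 µM titrant into a 200 µL cell at 10 µM, 30 °C)
  with additive Gaussian heat noise;
* ``gen_melt`` — a Boltzmann melt sampled at 1 °C increments, 25–95 °C;
* ``gen_spr`` — a steady-state SPR dose series on a four-fold dilution
  ladder (top 12 500 nM, ten steps, plus a blank);
* ``gen_ic50`` — a 12-point, 0–6 µM activity titration;
* ``gen_toy_kinase`` — a two-lobe point-cloud structure with an exactly
  planted number of inter-lobe contacts under a stated cutoff;
* ``gen_rigid_copy`` — a proper rigid transform of any structure plus
  optional coordinate jitter, with the truth transform recorded.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed reproduces outputs byte-identically. Every generator returns a truth
record alongside its data so recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .elements import ElementMap, ResidueSet
from .errors import GenerationError
from .structure import AtomRecord, StructureModel
from .thermo import (
    ITCIsotherm,
    InjectionSchedule,
    OneSiteParams,
    boltzmann_melt,
    ic50_logistic,
    simulate_itc,
    spr_steady_state,
)

#: SPR concentration ladder (nM): blank + ten four-fold steps to 12.5 µM.
SPR_LADDER_NM = [0.0] + [12500.0 / 4 ** k for k in range(9, -1, -1)]

#: Activity-assay design (µM): 12 points, 0–6 µM, two-fold dilutions.
IC50_LADDER_UM = [0.0] + [6.0 / 2 ** k for k in range(10, -1, -1)]


@dataclass
class GeneratorSpec:
    """Declarative request for one synthetic dataset."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def generate(self):
        try:
            fn = {
                "itc": gen_itc,
                "dsf": gen_melt,
                "spr": gen_spr,
                "ic50": gen_ic50,
                "toy_structure": gen_toy_kinase,
                "rigid_copy": gen_rigid_copy,
            }[self.kind]
        except KeyError:
            raise GenerationError(f"unknown generator kind {self.kind!r}")
        return fn(seed=self.seed, **self.parameters)


def _check_sigma(sigma: float) -> None:
    if sigma < 0:
        raise GenerationError("noise sigma must be >= 0")


# ---------------------------------------------------------------------------
# biophysics series
# ---------------------------------------------------------------------------

def gen_itc(
    kd_M: float = 26e-9,
    dh_kcal: float = -10.0,
    n: float = 1.0,
    baseline_ucal: float = 0.0,
    schedule: InjectionSchedule | None = None,
    sigma_ucal: float = 0.0,
    seed: int = 0,
) -> tuple[ITCIsotherm, dict]:
    """Simulated one-set-of-sites isotherm with Gaussian heat noise."""
    _check_sigma(sigma_ucal)
    schedule = schedule or InjectionSchedule()
    params = OneSiteParams(kd_M=kd_M, dh_kcal=dh_kcal, n=n,
                           baseline_ucal=baseline_ucal)
    iso = simulate_itc(params, schedule)
    if sigma_ucal > 0:
        rng = np.random.default_rng(seed)
        iso.heats_ucal = iso.heats_ucal + rng.normal(
            0.0, sigma_ucal, size=len(iso.heats_ucal)
        )
    truth = {
        "kind": "itc", "kd_M": kd_M, "dh_kcal": dh_kcal, "n": n,
        "baseline_ucal": baseline_ucal, "sigma_ucal": sigma_ucal,
        "seed": seed,
    }
    return iso, truth


def gen_melt(
    tm_C: float = 51.5,
    slope_C: float = 1.4,
    f_min: float = 0.0,
    f_max: float = 1.0,
    t_start_C: float = 25.0,
    t_end_C: float = 95.0,
    t_step_C: float = 1.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Boltzmann melt curve sampled on a regular temperature grid."""
    _check_sigma(sigma)
    t = np.arange(t_start_C, t_end_C + 0.5 * t_step_C, t_step_C)
    f = boltzmann_melt(t, f_min, f_max, tm_C, slope_C)
    if sigma > 0:
        f = f + np.random.default_rng(seed).normal(0.0, sigma, size=len(t))
    curve = pd.DataFrame({"temperature_C": t, "fluorescence": f})
    truth = {
        "kind": "dsf", "tm_C": tm_C, "slope_C": slope_C,
        "f_min": f_min, "f_max": f_max, "sigma": sigma, "seed": seed,
    }
    return curve, truth


def gen_spr(
    kd_nM: float = 43.0,
    r_max: float = 100.0,
    concentrations_nM=None,
    sigma_RU: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Steady-state SPR dose series on the four-fold dilution ladder."""
    _check_sigma(sigma_RU)
    c = np.asarray(
        SPR_LADDER_NM if concentrations_nM is None else concentrations_nM,
        float,
    )
    r = spr_steady_state(c, r_max, kd_nM)
    if sigma_RU > 0:
        r = r + np.random.default_rng(seed).normal(0.0, sigma_RU, size=len(c))
    series = pd.DataFrame({"concentration_nM": c, "response_RU": r})
    truth = {
        "kind": "spr", "kd_nM": kd_nM, "r_max": r_max,
        "sigma_RU": sigma_RU, "seed": seed,
    }
    return series, truth


def gen_ic50(
    ic50_uM: float = 0.1,
    n_hill: float = -1.0,
    concentrations_uM=None,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Activity dose-response on the 12-point 0–6 µM design.

    The default slope is negative: activity falls with inhibitor
    concentration.
    """
    _check_sigma(sigma)
    c = np.asarray(
        IC50_LADDER_UM if concentrations_uM is None else concentrations_uM,
        float,
    )
    y = np.empty_like(c)
    pos = c > 0
    y[pos] = ic50_logistic(np.log10(c[pos]), np.log10(ic50_uM), n_hill)
    # limit of the logistic as concentration -> 0
    y[~pos] = 1.0 if n_hill < 0 else 0.0
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=len(c))
    series = pd.DataFrame({"concentration_uM": c, "activity_fraction": y})
    truth = {
        "kind": "ic50", "ic50_uM": ic50_uM, "n_hill": n_hill,
        "sigma": sigma, "seed": seed,
    }
    return series, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

# residue layout of the toy map (author numbering)
_TOY_ELEMENTS = {
    "c_helix": (1, 100),
    "beta_sheet_base": (101, 200),
    "p_loop": (201, 203),
    "hinge": (1001, 1100),
    "activation_segment": (1101, 1200),
}
_TOY_N_FILLER = (211, 700)
_TOY_C_FILLER = (1211, 1700)

#: N-side × C-side element combinations used for round-robin planting.
_TOY_COMBOS = [
    ("c_helix", "activation_segment"),
    ("c_helix", "hinge"),
    ("beta_sheet_base", "activation_segment"),
    ("beta_sheet_base", "hinge"),
]

# alanine-like 5-heavy-atom residue: name, element, local offset (Å)
_TOY_RESIDUE = [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.0, 0.0, 0.0)),
    ("C", "C", (0.0, 1.0, 0.0)),
    ("O", "O", (-1.0, 0.0, 0.0)),
    ("CB", "C", (0.0, -1.0, 0.0)),
]


def toy_element_map() -> ElementMap:
    """Element map matching the toy two-lobe structures."""
    return ElementMap(
        kinase="TOY",
        n_lobe=ResidueSet([(1, 700)]),
        c_lobe=ResidueSet([(1001, 1700)]),
        hinge=ResidueSet([_TOY_ELEMENTS["hinge"]]),
        p_loop=ResidueSet([_TOY_ELEMENTS["p_loop"]]),
        c_helix=ResidueSet([_TOY_ELEMENTS["c_helix"]]),
        activation_segment=ResidueSet([_TOY_ELEMENTS["activation_segment"]]),
        beta_sheet_base=ResidueSet([_TOY_ELEMENTS["beta_sheet_base"]]),
    )


def _toy_residue_atoms(resnum: int, center: np.ndarray,
                       contact_atom_pos: np.ndarray | None = None
                       ) -> list[AtomRecord]:
    """Five-atom residue around ``center``; optionally pin CB to a position."""
    atoms = []
    for name, element, offset in _TOY_RESIDUE:
        pos = center + np.asarray(offset)
        if name == "CB" and contact_atom_pos is not None:
            pos = contact_atom_pos
        pos = np.round(pos, 3)  # survive PDB serialisation exactly
        atoms.append(AtomRecord(
            chain_id="A", residue_number=resnum, insertion_code="",
            residue_name="ALA", atom_name=name, element=element,
            position=tuple(float(v) for v in pos),
        ))
    return atoms


def gen_toy_kinase(
    contacts: int | Mapping[tuple[str, str], int] = 10,
    atoms_per_lobe: int = 0,
    cutoff: float = 4.0,
    identifier: str = "toy",
    seed: int = 0,
) -> tuple[StructureModel, ElementMap, dict]:
    """Two-lobe toy structure with an exact planted inter-lobe contact count.

    Each planted contact is a dedicated "bridge": one atom per lobe facing
    the other at cutoff − 0.7 Å across the inter-lobe gap, bridges laid out
    on a 6 Å lateral grid so every non-planted inter-lobe atom pair stays
    at least 0.5 Å beyond the cutoff. ``contacts`` may be a total (spread
    round-robin over the four census element pairs) or a per-element-pair
    mapping. ``atoms_per_lobe`` adds inert filler residues away from the
    interface up to the requested atom count (0 = bridges only). The
    construction is deterministic; ``seed`` is recorded in the truth.
    """
    if cutoff <= 1.0:
        raise GenerationError("cutoff too small for the bridge geometry")
    if isinstance(contacts, int):
        if contacts < 0:
            raise GenerationError("contact count must be >= 0")
        plant: dict[tuple[str, str], int] = {}
        for k in range(contacts):
            combo = _TOY_COMBOS[k % len(_TOY_COMBOS)]
            plant[combo] = plant.get(combo, 0) + 1
    else:
        plant = {tuple(k): int(v) for k, v in contacts.items()}
        for (el_n, el_c), count in plant.items():
            if (el_n, el_c) not in _TOY_COMBOS:
                raise GenerationError(
                    f"cannot plant contacts for element pair {(el_n, el_c)!r}"
                )
            if count < 0:
                raise GenerationError("contact count must be >= 0")

    d_contact = cutoff - 0.7
    z_n, z_c = d_contact / 2.0, -d_contact / 2.0
    spacing = max(6.0, cutoff + 2.0)

    next_resnum = {el: lo for el, (lo, hi) in _TOY_ELEMENTS.items()}

    def take_resnum(el: str) -> int:
        lo, hi = _TOY_ELEMENTS[el]
        num = next_resnum[el]
        if num > hi:
            raise GenerationError(
                f"too many bridges requested for element {el!r}"
            )
        next_resnum[el] = num + 1
        return num

    atoms: list[AtomRecord] = []
    n_bridges = {"N": 0, "C": 0}
    k = 0
    per_element_truth: dict[str, int] = {}
    for (el_n, el_c), count in sorted(plant.items()):
        for _ in range(count):
            ix, iy = k % 12, k // 12
            lateral = np.array([ix * spacing, iy * spacing])
            # contact atoms face each other across the lobe gap
            pos_n = np.array([lateral[0], lateral[1], z_n])
            pos_c = np.array([lateral[0], lateral[1], z_c])
            # residue bodies retreat from the interface
            center_n = np.array([lateral[0], lateral[1], z_n + 2.5])
            center_c = np.array([lateral[0], lateral[1], z_c - 2.5])
            atoms += _toy_residue_atoms(take_resnum(el_n), center_n, pos_n)
            atoms += _toy_residue_atoms(take_resnum(el_c), center_c, pos_c)
            n_bridges["N"] += 1
            n_bridges["C"] += 1
            k += 1
        key = f"{el_n}|{el_c}"
        per_element_truth[key] = per_element_truth.get(key, 0) + count

    total_planted = sum(plant.values())
    # filler residues well away from the interface, on their own grids
    n_res_target = max(atoms_per_lobe // 5, 0)
    for side, (lo, hi), z_base in (
        ("N", _TOY_N_FILLER, z_n + 14.0),
        ("C", _TOY_C_FILLER, -(abs(z_c) + 14.0)),
    ):
        n_fill = max(n_res_target - n_bridges[side], 0)
        if n_fill > hi - lo + 1:
            raise GenerationError(
                f"atoms_per_lobe={atoms_per_lobe} needs more filler residues "
                f"than the toy numbering allows on the {side} side"
            )
        for j in range(n_fill):
            ix, iy = j % 12, j // 12
            center = np.array([ix * spacing + 3.0, iy * spacing + 3.0,
                               z_base if side == "N" else z_base])
            atoms += _toy_residue_atoms(lo + j, center)

    atoms.sort(key=lambda a: a.residue_number)
    model = StructureModel(
        identifier=identifier, atoms=atoms, chain_roles={"A": "kinase"}
    )
    truth = {
        "kind": "toy_structure",
        "planted_contacts": total_planted,
        "per_element": per_element_truth,
        "cutoff": cutoff,
        "seed": seed,
    }
    return model, toy_element_map(), truth


def gen_rigid_copy(
    model: StructureModel,
    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    jitter_sigma: float = 0.0,
    seed: int = 0,
    rotation: np.ndarray | None = None,
) -> tuple[StructureModel, dict]:
    """Proper rigid transform of a structure plus seeded coordinate jitter.

    ``jitter_sigma`` is the RMS atomic displacement in Å (per-coordinate
    std σ/√3), so superposing an otherwise identical copy onto the
    original recovers an RMSD ≈ σ. A rotation matrix may be given instead
    of Euler angles; improper (reflecting) matrices are rejected.
    """
    if len(model.atoms) == 0:
        raise GenerationError("cannot transform an empty structure")
    if jitter_sigma < 0:
        raise GenerationError("jitter sigma must be >= 0")
    if rotation is not None:
        R = np.asarray(rotation, float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise GenerationError("rotation must be a proper 3x3 rotation")
    else:
        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
    t = np.asarray(translation, float)

    xyz = model.coords() @ R.T + t
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(
            0.0, jitter_sigma / np.sqrt(3.0), size=xyz.shape
        )
    copy = model.with_coords(xyz)
    copy.identifier = f"{model.identifier}_copy"
    truth = {
        "kind": "rigid_copy",
        "rotation": R.tolist(),
        "translation": t.tolist(),
        "jitter_sigma": jitter_sigma,
        "seed": seed,
    }
    return copy, truth


def write_truth(data_path: str | Path, truth: dict) -> Path:
    """Write the sidecar truth record ``<output>.truth.json``."""
    path = Path(str(data_path) + ".truth.json")
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path
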