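"""Binding-thermodynamics analysis chain.

The core model is the one-set-of-sites ITC isotherm: per injection the
bound-complex concentration follows the single-site binding quadratic at
the current cell concentrations, with perfusion-displacement bookkeeping
(each injection expels a cell-volume fraction dV/V0 carrying the
pre-mixing composition). Differential heat per injection is the enthalpy
times the change in moles bound, plus a constant dilution-heat baseline.

Around it sit the standard companion fits: a Boltzmann sigmoid for
thermal-shift melts, a hyperbolic steady-state saturation curve for SPR,
and the four-parameter-free logistic Y = 1/(1 + 10^((logIC50 − x)·N))
(x = log10 inhibitor concentration) for activity dose-responses. All
nonlinear fits go through :mod:`lmfit` and are deterministic given the
data and the initialisation.

Units follow the conventions of the experiments emulated: Kd in molar
internally (tables render nM), energies in kcal/mol, heats in µcal,
temperatures in Kelvin for thermodynamics and °C for melts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .errors import AmbiguousLabelError, ConfigurationError

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872e-3

#: Default experiment temperature: 30 °C.
T_DEFAULT = 303.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class InjectionSchedule:
    """ITC injection protocol.

    Defaults mirror the emulated protocol: a 200 µL cell loaded at 10 µM
    titrand, 100 µM titrant in the syringe, one 0.5 µL priming injection
    followed by 19 × 2 µL injections, at 30 °C.
    """

    cell_volume_ul: float = 200.0
    cell_conc_M: float = 10e-6
    syringe_conc_M: float = 100e-6
    injection_volumes_ul: list[float] = field(
        default_factory=lambda: [0.5] + [2.0] * 19
    )
    temperature_K: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.cell_volume_ul <= 0 or self.cell_conc_M <= 0 \
                or self.syringe_conc_M <= 0:
            raise ConfigurationError("volumes and concentrations must be > 0")
        if not self.injection_volumes_ul \
                or any(v <= 0 for v in self.injection_volumes_ul):
            raise ConfigurationError("injection volumes must be positive")


@dataclass
class OneSiteParams:
    """One-set-of-sites binding parameters.

    kd in molar; dh in kcal per mol of injectant; n sites per titrand;
    baseline in µcal per injection (dilution-heat offset).
    """

    kd_M: float
    dh_kcal: float
    n: float = 1.0
    baseline_ucal: float = 0.0

    def __post_init__(self) -> None:
        if self.kd_M <= 0:
            raise ConfigurationError("kd must be > 0")
        if self.n <= 0:
            raise ConfigurationError("stoichiometry n must be > 0")


@dataclass
class ITCIsotherm:
    """Injection-level ITC data: heats (µcal) and cumulative molar ratio."""

    schedule: InjectionSchedule
    heats_ucal: np.ndarray
    molar_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, float)
        self.molar_ratio = np.asarray(self.molar_ratio, float)
        if len(self.heats_ucal) != len(self.schedule.injection_volumes_ul):
            raise ConfigurationError("one heat per scheduled injection")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ConfigurationError("molar ratio must increase strictly")


@dataclass
class ThermoSignature:
    """ΔG/ΔH/−TΔS decomposition of a binding event, kcal/mol."""

    dg: float
    dh: float
    minus_tds: float
    temperature_K: float

    def __post_init__(self) -> None:
        if abs(self.dg - (self.dh + self.minus_tds)) > 1e-9:
            raise ConfigurationError("dg must equal dh + minus_tds")


@dataclass
class CurveFitResult:
    """Generic fitted-parameter container.

    params maps name → (estimate, standard error). ``bounded`` marks fits
    where the data determine only a bound on the affinity (rendered as
    "> limit" downstream); ``warnings`` carries the diagnostics.
    """

    model_name: str
    params: dict[str, tuple[float, float]]
    residual_norm: float
    converged: bool
    bounded: bool = False
    bound_value: float | None = None
    warnings: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def value(self, name: str) -> float:
        return self.params[name][0]

    def stderr(self, name: str) -> float:
        return self.params[name][1]


def _param_table(result: lmfit.minimizer.MinimizerResult
                 ) -> dict[str, tuple[float, float]]:
    out = {}
    for name, p in result.params.items():
        se = float(p.stderr) if p.stderr is not None else 0.0
        out[name] = (float(p.value), max(se, 0.0))
    return out


# ---------------------------------------------------------------------------
# ITC forward model
# ---------------------------------------------------------------------------

def _bound_quadratic(m_tot: float, x_tot: float, kd: float, n: float) -> float:
    """Bound-ligand concentration from the single-site quadratic.

    Sites concentration is n·m_tot; returns the concentration of ligand in
    complex, the stable root of B² − B(nM + X + Kd) + nM·X = 0.
    """
    s = n * m_tot
    b = s + x_tot + kd
    disc = b * b - 4.0 * s * x_tot
    return 0.5 * (b - np.sqrt(max(disc, 0.0)))


def simulate_itc(
    params: OneSiteParams, schedule: InjectionSchedule | None = None
) -> ITCIsotherm:
    """Forward-simulate a one-set-of-sites titration.

    Stepwise bookkeeping: injection i of volume dV expels the fraction
    dV/V0 of the (pre-mixing) cell content, dilutes titrand and previously
    injected titrant accordingly, adds fresh titrant, then re-equilibrates.
    The differential heat is ΔH · V0 · (B_i − B_{i−1}·(1 − dV/V0)) plus the
    baseline, in µcal.
    """
    schedule = schedule or InjectionSchedule()
    v0_l = schedule.cell_volume_ul * 1e-6
    m = schedule.cell_conc_M
    x = 0.0
    b_prev = 0.0
    heats, ratios = [], []
    for dv_ul in schedule.injection_volumes_ul:
        f = dv_ul / schedule.cell_volume_ul
        m *= (1.0 - f)
        x = x * (1.0 - f) + schedule.syringe_conc_M * f
        b = _bound_quadratic(m, x, params.kd_M, params.n)
        dq_kcal = params.dh_kcal * v0_l * (b - b_prev * (1.0 - f))
        heats.append(dq_kcal * 1e9 + params.baseline_ucal)  # kcal → µcal
        ratios.append(x / m)
        b_prev = b
    return ITCIsotherm(
        schedule=schedule,
        heats_ucal=np.array(heats),
        molar_ratio=np.array(ratios),
    )


def bound_ligand_bisection(
    m_tot: float, x_tot: float, kd: float, n: float,
    tol: float = 1e-16, max_iter: int = 200,
) -> float:
    """Independent equilibrium solver: bisection on free ligand.

    Solves X_free + n·M·X_free/(Kd + X_free) = X_tot and returns the bound
    concentration. Used as the oracle against the closed-form quadratic.
    """
    def excess(x_free: float) -> float:
        return x_free + n * m_tot * x_free / (kd + x_free) - x_tot

    lo, hi = 0.0, x_tot
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    x_free = 0.5 * (lo + hi)
    return x_tot - x_free


# ---------------------------------------------------------------------------
# ITC fit
# ---------------------------------------------------------------------------

def fit_one_site(
    isotherm: ITCIsotherm,
    init: OneSiteParams | None = None,
    float_n: bool = True,
    skip_priming: bool = True,
    priming_volume_ul: float = 1.0,
) -> CurveFitResult:
    """Nonlinear least-squares fit of the one-set-of-sites model.

    The priming injection (volume below ``priming_volume_ul``) is simulated
    in the forward model but excluded from the residuals, the universal
    treatment of the small first injection. ``float_n=False`` fixes the
    stoichiometry at its initial value. A c-value below 1 (c = n·M0/Kd), or
    a fitted Kd beyond half the total titrant concentration probed, yields
    a bounded-affinity warning: the data then determine only a lower bound
    on Kd.
    """
    sched = isotherm.schedule
    vols = np.asarray(sched.injection_volumes_ul)
    use = ~(np.array([skip_priming] * len(vols))
            & (vols < priming_volume_ul))
    if use.sum() < 6:
        raise ConfigurationError("need at least 6 usable injections")

    obs = isotherm.heats_ucal
    if init is None:
        peak = obs[use][np.argmax(np.abs(obs[use]))]
        half = np.argmin(np.abs(np.cumsum(obs[use])
                                - 0.5 * np.sum(obs[use])))
        kd0 = max(sched.cell_conc_M * 0.1, 1e-9)
        init = OneSiteParams(
            kd_M=kd0, dh_kcal=float(np.sign(peak) * 5.0 or -5.0),
            n=1.0, baseline_ucal=0.0,
        )
        del half  # heuristic kept simple: a tenth of the cell concentration

    pars = lmfit.Parameters()
    pars.add("log10_kd", value=np.log10(init.kd_M), min=-15, max=0)
    pars.add("dh_kcal", value=init.dh_kcal)
    pars.add("n", value=init.n, min=1e-3, max=10, vary=float_n)
    pars.add("baseline_ucal", value=init.baseline_ucal)

    def residual(p):
        model = simulate_itc(
            OneSiteParams(
                kd_M=10.0 ** p["log10_kd"].value,
                dh_kcal=p["dh_kcal"].value,
                n=p["n"].value,
                baseline_ucal=p["baseline_ucal"].value,
            ),
            sched,
        )
        return model.heats_ucal[use] - obs[use]

    out = lmfit.minimize(residual, pars, method="leastsq")
    kd = 10.0 ** out.params["log10_kd"].value
    log_kd_se = out.params["log10_kd"].stderr
    kd_se = kd * np.log(10.0) * log_kd_se if log_kd_se else 0.0

    params = _param_table(out)
    params["kd_M"] = (kd, kd_se)
    result = CurveFitResult(
        model_name="one_set_of_sites",
        params=params,
        residual_norm=float(np.sqrt(np.sum(out.residual ** 2))),
        converged=bool(out.success),
        meta={"n_injections_used": int(use.sum()), "float_n": float_n},
    )

    c_value = out.params["n"].value * sched.cell_conc_M / kd
    total_titrant = sched.syringe_conc_M * (
        1.0 - np.prod(1.0 - vols / sched.cell_volume_ul)
    )
    if c_value < 1.0 or kd > 0.5 * total_titrant:
        result.bounded = True
        result.bound_value = 0.5 * total_titrant
        result.warnings.append(
            f"shallow isotherm (c = {c_value:.2f}): Kd is only bounded, "
            f"report as > {0.5 * total_titrant * 1e9:.0f} nM"
        )
        warnings.warn(result.warnings[-1], stacklevel=2)
    if not out.success:
        result.warnings.append("fit did not converge; estimates unreliable")
    return result


# ---------------------------------------------------------------------------
# signatures and selectivity
# ---------------------------------------------------------------------------

def thermo_signature(
    kd_M: float, dh_kcal: float, temperature_K: float = T_DEFAULT
) -> ThermoSignature:
    """ΔG = RT·ln(Kd) (kcal/mol) and −TΔS = ΔG − ΔH at the given temperature."""
    if kd_M <= 0 or temperature_K <= 0:
        raise ConfigurationError("kd and temperature must be positive")
    dg = R_KCAL * temperature_K * float(np.log(kd_M))
    return ThermoSignature(
        dg=dg, dh=dh_kcal, minus_tds=dg - dh_kcal,
        temperature_K=temperature_K,
    )


def selectivity_ratio(
    kd_a_M: float, kd_b_M: float, rounding: str = "none"
) -> float:
    """Fold difference kd_a / kd_b with an optional reporting convention."""
    if kd_a_M <= 0 or kd_b_M <= 0:
        raise ConfigurationError("kd values must be positive")
    fold = kd_a_M / kd_b_M
    if rounding == "none":
        return fold
    if rounding == "nearest_ten":
        return float(round(fold / 10.0) * 10.0)
    if rounding == "one_sig_fig":
        if fold == 0:
            return 0.0
        exp = np.floor(np.log10(abs(fold)))
        return float(round(fold / 10 ** exp) * 10 ** exp)
    raise ConfigurationError(f"unknown rounding rule {rounding!r}")


# ---------------------------------------------------------------------------
# DSF melt fit
# ---------------------------------------------------------------------------

def boltzmann_melt(t, f_min, f_max, tm, slope):
    """Boltzmann sigmoid F(T) = F_min + (F_max − F_min)/(1 + exp((Tm−T)/s))."""
    return f_min + (f_max - f_min) / (1.0 + np.exp((tm - t) / slope))


def fit_boltzmann_melt(
    temperature_C: Sequence[float],
    fluorescence: Sequence[float],
    window: tuple[float, float] | None = None,
) -> CurveFitResult:
    """Fit a thermal-denaturation fluorescence curve; Tm is the inflection.

    The whole curve is fitted by default (the generators emulate a pure
    two-state sigmoid without post-transition decay); ``window`` restricts
    the fit range for instrument curves that roll over after the peak.
    """
    t = np.asarray(temperature_C, float)
    f = np.asarray(fluorescence, float)
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("temperatures must be strictly increasing")
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, f = t[keep], f[keep]
    if len(t) < 5:
        raise ConfigurationError("need at least 5 points to fit a melt")

    span = f.max() - f.min()
    if span <= 0 or span < 1e-12 * max(abs(f).max(), 1.0):
        return CurveFitResult(
            model_name="boltzmann_melt", params={}, residual_norm=np.inf,
            converged=False,
            warnings=["flat curve: no transition to fit"],
        )

    model = lmfit.Model(boltzmann_melt, independent_vars=["t"])
    pars = model.make_params(
        f_min=float(np.quantile(f, 0.05)),
        f_max=float(np.quantile(f, 0.95)),
        tm=float(t[np.argmin(np.abs(f - (f.min() + 0.5 * span)))]),
        slope=max((t.max() - t.min()) / 20.0, 0.5),
    )
    pars["slope"].set(min=1e-3)
    out = model.fit(f, pars, t=t)
    result = CurveFitResult(
        model_name="boltzmann_melt",
        params=_param_table(out),
        residual_norm=float(np.sqrt(np.sum(out.residual ** 2))),
        converged=bool(out.success),
    )
    if not out.success:
        result.warnings.append("melt fit did not converge")
    return result


def delta_tm(tm_with_ligand_C: float, tm_apo_C: float) -> float:
    """Signed thermal shift: Tm(+ligand) − Tm(apo), °C (negative allowed)."""
    return tm_with_ligand_C - tm_apo_C


# ---------------------------------------------------------------------------
# SPR steady-state affinity
# ---------------------------------------------------------------------------

def spr_steady_state(c, r_max, kd):
    """Hyperbolic saturation R(C) = R_max·C/(Kd + C)."""
    return r_max * c / (kd + c)


def fit_spr_affinity(
    concentration_nM: Sequence[float],
    response_RU: Sequence[float],
) -> CurveFitResult:
    """Steady-state SPR affinity fit; returns Kd (nM) and R_max ± SE.

    Requires at least 5 concentrations including a zero/blank. When the
    fitted Kd exceeds half the top concentration, saturation was not
    reached and the result is flagged as a lower bound.
    """
    c = np.asarray(concentration_nM, float)
    r = np.asarray(response_RU, float)
    if len(c) < 5:
        raise ConfigurationError("need at least 5 concentrations")
    if not np.any(c == 0):
        raise ConfigurationError("series must include a zero concentration")

    model = lmfit.Model(spr_steady_state, independent_vars=["c"])
    pos = c > 0
    half = r[pos].max() * 0.5 if pos.any() else 1.0
    kd0 = float(c[pos][np.argmin(np.abs(r[pos] - half))]) if pos.any() else 1.0
    pars = model.make_params(r_max=float(r.max() or 1.0), kd=max(kd0, 1e-3))
    pars["kd"].set(min=1e-6)
    pars["r_max"].set(min=0)
    out = model.fit(r, pars, c=c)
    result = CurveFitResult(
        model_name="spr_steady_state",
        params=_param_table(out),
        residual_norm=float(np.sqrt(np.sum(out.residual ** 2))),
        converged=bool(out.success),
        meta={"kd_unit": "nM"},
    )
    kd = result.value("kd")
    if kd > 0.5 * c.max():
        result.bounded = True
        result.bound_value = 0.5 * c.max()
        result.warnings.append(
            f"no saturation within the concentration range: Kd bounded, "
            f"report as > {0.5 * c.max():.0f} nM"
        )
        warnings.warn(result.warnings[-1], stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# IC50 logistic
# ---------------------------------------------------------------------------

def ic50_logistic(log_c, log_ic50, n_hill):
    """Y = 1/(1 + 10^((logIC50 − x)·N)) with x = log10 concentration.

    The printed form of this equation is only dimensionally consistent when
    "[inhibitor]" is read as log10 of the inhibitor concentration; that
    reading is adopted here (and recorded in the fit metadata). At
    x = logIC50 the curve passes through Y = 0.5 for any slope N.
    """
    return 1.0 / (1.0 + 10.0 ** ((log_ic50 - log_c) * n_hill))


def fit_ic50(
    concentration_uM: Sequence[float],
    activity: Sequence[float],
) -> CurveFitResult:
    """Fit the activity dose-response logistic; returns IC50 (µM) and slope N.

    Zero concentrations cannot enter the log-transformed fit and are
    dropped (with a note in the metadata), matching common dose-response
    fitting practice.
    """
    c = np.asarray(concentration_uM, float)
    y = np.asarray(activity, float)
    pos = c > 0
    n_dropped = int((~pos).sum())
    c, y = c[pos], y[pos]
    if len(c) < 4:
        raise ConfigurationError("need at least 4 positive concentrations")
    log_c = np.log10(c)

    span = y.max() - y.min()
    if span < 0.05:
        return CurveFitResult(
            model_name="ic50_logistic", params={}, residual_norm=np.inf,
            converged=False,
            warnings=["no sigmoidal transition in the activity data"],
        )

    model = lmfit.Model(ic50_logistic, independent_vars=["log_c"])
    mid = float(log_c[np.argmin(np.abs(y - 0.5))])
    slope0 = 1.0 if np.corrcoef(log_c, y)[0, 1] > 0 else -1.0
    pars = model.make_params(log_ic50=mid, n_hill=slope0)
    out = model.fit(y, pars, log_c=log_c)
    params = _param_table(out)
    ic50 = 10.0 ** params["log_ic50"][0]
    se = params["log_ic50"][1]
    params["ic50_uM"] = (ic50, ic50 * np.log(10.0) * se if se else 0.0)
    result = CurveFitResult(
        model_name="ic50_logistic",
        params=params,
        residual_norm=float(np.sqrt(np.sum(out.residual ** 2))),
        converged=bool(out.success),
        meta={
            "x_convention": "log10 concentration",
            "zero_concentrations_dropped": n_dropped,
        },
    )
    if not out.success:
        result.warnings.append("dose-response fit did not converge")
    return result


# ---------------------------------------------------------------------------
# affinity comparison table
# ---------------------------------------------------------------------------

def render_kd(kd_nM: float, se_nM: float = 0.0, bounded: bool = False,
              bound_nM: float | None = None) -> str:
    """Human-readable Kd cell: '955 ± 246' or '> 20,000' for bounded fits."""
    if bounded:
        return f"> {bound_nM:,.0f}"
    if se_nM > 0:
        return f"{kd_nM:,.0f} ± {se_nM:,.0f}"
    return f"{kd_nM:,.0f}"


def build_affinity_table(
    fits: Mapping[tuple[str, str], CurveFitResult],
    fold_pairs: Sequence[tuple[str, str]] = (
        ("CDK1", "CDK1-cyclin B"),
        ("CDK2", "CDK2-cyclin A"),
        ("CDK1", "CDK2"),
    ),
    kd_param: str = "kd_M",
    kd_scale_nM: float = 1e9,
) -> pd.DataFrame:
    """Inhibitor × state Kd matrix with rendered cells and fold columns.

    ``fits`` maps (inhibitor, state) to a fit whose ``kd_param`` is in
    molar (scaled to nM by ``kd_scale_nM``; pass 1.0 for fits already in
    nM). Bounded entries render as "> limit" and are excluded from fold
    arithmetic. ``fold_pairs`` lists (numerator state, denominator state)
    ratio columns, the weak-over-tight convention.
    """
    seen = set()
    for key in fits:
        if key in seen:
            raise AmbiguousLabelError(f"duplicate label {key!r}")
        seen.add(key)

    inhibitors, states = [], []
    for inh, st in fits:
        if inh not in inhibitors:
            inhibitors.append(inh)
        if st not in states:
            states.append(st)

    rows = []
    for inh in inhibitors:
        row: dict = {"inhibitor": inh}
        kd_nM: dict[str, float | None] = {}
        for st in states:
            fit = fits.get((inh, st))
            if fit is None:
                row[st] = ""
                kd_nM[st] = None
                continue
            kd = fit.value(kd_param) * kd_scale_nM
            se = fit.stderr(kd_param) * kd_scale_nM
            bound = (fit.bound_value or 0.0) * kd_scale_nM
            row[st] = render_kd(kd, se, fit.bounded, bound)
            kd_nM[st] = None if fit.bounded else kd
        for num, den in fold_pairs:
            col = f"fold {num}/{den}"
            if kd_nM.get(num) is not None and kd_nM.get(den):
                row[col] = kd_nM[num] / kd_nM[den]
            else:
                row[col] = np.nan
        rows.append(row)

    columns = ["inhibitor"] + states + [f"fold {n}/{d}" for n, d in fold_pairs]
    return pd.DataFrame(rows, columns=columns if rows else None)
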