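"""DSF melt, steady-state SPR and IC50 fits on synthetic series.

Generates each companion experiment at measured CDK2 values — a Boltzmann
melt at the apo Tm (51.5 °C) and one shifted by the AZD5438 ΔTm (+8.9 °C),
an SPR dose series at Kd = 43 nM, and a 12-point activity titration — and
refits each to recover the generating parameters.
"""

from kinland import (
    delta_tm,
    fit_boltzmann_melt,
    fit_ic50,
    fit_spr_affinity,
    gen_ic50,
    gen_melt,
    gen_spr,
)

apo, _ = gen_melt(tm_C=51.5, sigma=0.01, seed=0)
holo, _ = gen_melt(tm_C=60.4, sigma=0.01, seed=1)
tm_apo = fit_boltzmann_melt(apo.temperature_C, apo.fluorescence).value("tm")
tm_holo = fit_boltzmann_melt(holo.temperature_C, holo.fluorescence).value("tm")
print(f"DSF : Tm(apo) = {tm_apo:.2f} C, Tm(+ligand) = {tm_holo:.2f} C, "
      f"dTm = {delta_tm(tm_holo, tm_apo):+.2f} C")
print("      a positive shift means ligand binding stabilises the fold")

spr, _ = gen_spr(kd_nM=43.0, r_max=100.0, sigma_RU=1.0, seed=2)
fit = fit_spr_affinity(spr.concentration_nM, spr.response_RU)
print(f"SPR : Kd = {fit.value('kd'):.1f} nM, "
      f"Rmax = {fit.value('r_max'):.1f} RU  (truth 43 nM, 100 RU)")

act, _ = gen_ic50(ic50_uM=0.1, n_hill=-1.0, sigma=0.02, seed=3)
ic = fit_ic50(act.concentration_uM, act.activity_fraction)
print(f"IC50: {ic.value('ic50_uM') * 1e3:.0f} nM, "
      f"slope N = {ic.value('n_hill'):+.2f}  (truth 100 nM, -1)")
print("      activity falls to half at the fitted IC50 by construction")
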