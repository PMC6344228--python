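"""Fold-selectivity arithmetic on the measured affinity panel.

Loads the packaged ITC Kd panel (five inhibitors × four kinase states)
and computes the fold differences that summarise the study: cyclin-free
CDK1 binds every inhibitor far more weakly than cyclin-free CDK2 or
either cyclin-bound complex.
"""

from kinland import selectivity_ratio
from kinland.reference import itc_affinities, itc_kd_nM

panel = itc_affinities()
print(panel.to_string(index=False))
print()

azd_cdk1 = itc_kd_nM("AZD5438", "CDK1")
azd_cdk2 = itc_kd_nM("AZD5438", "CDK2")
azd_cdk1b = itc_kd_nM("AZD5438", "CDK1-cyclin B")
din_cdk1 = itc_kd_nM("Dinaciclib", "CDK1")
din_cdk2 = itc_kd_nM("Dinaciclib", "CDK2")

print(f"AZD5438   cyclin-free CDK1 vs CDK2        : "
      f"{selectivity_ratio(azd_cdk1, azd_cdk2, 'nearest_ten'):.0f}-fold")
print(f"AZD5438   cyclin-free vs cyclin-bound CDK1: "
      f"{selectivity_ratio(azd_cdk1, azd_cdk1b, 'nearest_ten'):.0f}-fold")
print(f"Dinaciclib cyclin-free CDK1 vs CDK2       : "
      f"{selectivity_ratio(din_cdk1, din_cdk2, 'one_sig_fig'):.0f}-fold")
print("-> the selectivity window opens only when the cyclin is absent")
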