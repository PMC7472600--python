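"""Derived lipid parameters from a composition profile.

Feeds the published female-cohort mean percentages through the index panel.
Because every checked parameter is linear in the percentages, the panel of
the mean composition equals the cohort mean panel.
"""

from lipidbench import full_panel
from lipidbench.synthetic import TABLE_FEMALE_MEAN_SD

female_means = {code: mean for code, (mean, _) in TABLE_FEMALE_MEAN_SD.items()}

panel = full_panel(female_means, sample_id="female-cohort-mean")
print("family totals (% of cluster):")
print(f"  total SFA  = {panel.total_sfa:6.2f}")
print(f"  total MUFA = {panel.total_mufa:6.2f}")
print(f"  PUFA n-3   = {panel.pufa_n3:6.2f}")
print(f"  PUFA n-6   = {panel.pufa_n6:6.2f}")
print(f"  total PUFA = {panel.total_pufa:6.2f}")
print("ratios and indexes:")
print(f"  SFA/MUFA        = {panel.sfa_mufa_ratio:6.2f}")
print(f"  omega-6/omega-3 = {panel.n6_n3_ratio:6.2f}")
print(f"  PUFA balance    = {panel.pufa_balance:6.2f} %")
print(f"  UI              = {panel.unsaturation_index:6.2f}")
print(f"  PI              = {panel.peroxidation_index:6.2f}")
# UI weighs each unsaturated percentage by its double-bond count (1-6);
# PI weighs by oxidizability (0.025-8).  A dog cohort sits near UI ~192:
# omega-6 dominated membranes with very low omega-3.
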