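"""Build a healthy-cohort reference benchmark from a synthetic cohort.

Generates a 68-dog cohort, computes per-sample index panels, and summarizes
all twenty parameters as interval values (min-max), median and percentiles.
"""

from lipidbench import full_panel, generate, summarize_cohort

cohort = generate(seed=1, with_tables=False)
profiles = list(cohort.compositions)
panels = [full_panel(p) for p in profiles]

bench = summarize_cohort(profiles, panels)
print(f"{'parameter':>20} {'n':>3} {'min':>8} {'median':>8} {'max':>8}")
for ri in bench:
    print(f"{ri.parameter:>20} {ri.n:>3} {ri.minimum:8.2f} {ri.median:8.2f} {ri.maximum:8.2f}")
# Interval values are raw order statistics over the healthy cohort: the
# benchmark a clinical sample is compared against.  Medians always lie
# inside their own interval; with n >= 40 the rows also carry 2.5/97.5
# percentiles (ri.p2_5 / ri.p97_5).
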