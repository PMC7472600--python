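"""Calibrate a detector response and quantify a GC peak table.

Builds three-point calibration standards for each fatty acid, quantifies a
small peak table back to ug/mL, and closes the cluster to relative
percentages.
"""

from lipidbench import (
    PeakTable,
    StandardPoint,
    fit_calibration,
    get_cluster,
    profile_from_peaks,
)

# one straight-line response per fatty acid: area = 12 * conc + 3
curves = {}
for fa in get_cluster():
    points = [StandardPoint(fa.code, c, 12.0 * c + 3.0) for c in (5.0, 10.0, 20.0)]
    curves[fa.code] = fit_calibration(points)

print(f"C16:0 calibration: slope={curves['C16:0'].slope:.2f} "
      f"intercept={curves['C16:0'].intercept:.2f} r^2={curves['C16:0'].r_squared:.4f}")

# a sample whose true quantities are 2x the elution-order index + 1 (ug/mL),
# plus a small non-cluster 'other' area
rows = []
for i, fa in enumerate(get_cluster()):
    true_q = 2.0 * i + 1.0
    rows.append((fa.code, 12.0 * true_q + 3.0))
rows.append(("other", 0.01 * sum(a for _, a in rows)))

profile = profile_from_peaks(PeakTable("demo", tuple(rows)), curves)
print(f"coverage: {profile.coverage_fraction:.3f} (pass={profile.coverage_pass})")
for code, q in profile.quantity_ug_ml.items():
    print(f"  {code:>10}: {q:6.2f} ug/mL -> {profile.percent[code]:5.2f} %")
print(f"percentages sum to {sum(profile.percent.values()):.6f}")
# The percentages are each FA's share of the summed cluster quantities
# (closed to 100%); coverage is the cluster share of total chromatogram area.
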