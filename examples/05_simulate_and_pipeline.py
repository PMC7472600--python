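"""End-to-end pipeline on simulated raw data.

Simulates a cohort (metadata, calibration standards, peak tables), then runs
quantify -> profile -> benchmark -> stats, writing every artifact as CSV/JSON
under ./scratch_pipeline_demo.
"""

import pathlib

from lipidbench.config import RunConfig
from lipidbench.pipeline import run_pipeline

out = pathlib.Path("scratch_pipeline_demo")
artifacts = run_pipeline(RunConfig(), out, seed=42)

print("artifacts written:")
for p in sorted(out.iterdir()):
    print(f"  {p} ({p.stat().st_size} bytes)")

print("\nbenchmark head:")
for line in (out / "benchmark.csv").read_text().splitlines()[:6]:
    print(" ", line)
# Rerunning with the same seed reproduces every file byte-identically; the
# truth_profiles.csv holds the generator's ground-truth compositions, so the
# quantitation error of the noisy raw-data layer can be audited directly.
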