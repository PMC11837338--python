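"""One-call pipeline run with manifest and plain-text report.

Writes every stage artifact (deduplicated records, series summary,
onsets, spring index, sensitivity tables, meta-model and variance-
component tables), a reproducibility manifest, and a human-readable
report into a run directory.  The same thing is available from a shell
as `flightline run-all`.
"""

import json
import tempfile
from pathlib import Path

from flightline import AnalysisConfig, SimulationConfig, run_all, simulate

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    simulate(SimulationConfig(seed=11)).write(tmp / "sim")
    result = run_all(
        tmp / "sim/records.csv",
        tmp / "sim/climate.csv",
        tmp / "sim/traits.csv",
        tmp / "run",
    )
    print("stage row counts:")
    print(json.dumps(result.manifest["counts"], indent=2))
    print()
    report = (result.outdir / "report.txt").read_text().splitlines()
    print("\n".join(report[:12]))
    print("...")
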