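"""The whole analysis in one call: simulate -> prep -> estimate -> metareg
-> project -> decompose.

Writes synthetic survey inputs to a temporary directory, runs the pipeline
on them, and prints the resulting summary report.  The same flow is
available from the shell as `quitkinetics simulate` + `quitkinetics run`.
"""

import tempfile
from pathlib import Path

from quitkinetics import RunConfig, default_scenario, generate, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    inputs = Path(tmp) / "inputs"
    generate(default_scenario(), seed=11).write_inputs(inputs)

    cfg = RunConfig(
        prevalence_csv=str(inputs / "prevalence.csv"),
        census_csv=str(inputs / "census.csv"),
        mortality_csv=str(inputs / "mortality.csv"),
        prev18_csv=str(inputs / "prev18.csv"),
        outdir=str(Path(tmp) / "out"),
    )
    bundle = run_pipeline(cfg)
    print(open(bundle["paths"]["summary"]).read())
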