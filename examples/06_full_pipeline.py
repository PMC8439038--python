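"""The whole pipeline as one call: plates in, report tables out.

Simulates a study to disk (per-plate CSVs plus a covariates table),
then runs qc -> net -> cutoff -> index -> table -> compare/response.
Every artifact is a plain TSV; rerunning with the same seed and config
reproduces each one byte for byte.
"""

import tempfile
from pathlib import Path

from seroindex import PipelineConfig, QCConfig, demo_spec, generate_study, run_pipeline
from seroindex.simulate import write_study

with tempfile.TemporaryDirectory() as tmp:
    spec = demo_spec(seed=7, scale=0.5)
    paths = write_study(generate_study(spec), Path(tmp) / "study")
    print(f"simulated {len(paths['plates'])} plates")

    config = PipelineConfig(
        plates=[str(Path(tmp) / "study" / "plates" / "*.csv")],
        covariates_tsv=str(paths["covariates"]),
        out_dir=str(Path(tmp) / "out"),
        qc=QCConfig(
            expected_positive_control_od=spec.plate_noise.positive_control_od,
            expected_secondary_od=spec.plate_noise.secondary_mean_od,
        ),
        seed=7,
    )
    outputs = run_pipeline(config)
    print("artifacts written:")
    for name, path in outputs.items():
        print(f"  {name:>17}: {path.name}")

    cutoffs = (Path(tmp) / "out" / "cutoffs.tsv").read_text().splitlines()
    print("\ncutoffs.tsv (threshold per marker and reference):")
    for line in cutoffs:
        print(" ", line)
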