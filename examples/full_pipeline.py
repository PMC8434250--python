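"""Run the configured end-to-end pipeline on a simulated study.

Writes a two-sample synthetic gliadin-extract study to disk as ordinary
CSV spectra, builds a run configuration, executes the pipeline (average
replicates -> decompose amide I -> quantify), and shows where the JSON
reports and the feature-matrix CSV land.
"""

import json
import tempfile
import warnings
from pathlib import Path

from ramandecomp import generate_study_set, write_spectrum
from ramandecomp.pipeline import RegionConfig, RunConfig, run_pipeline

warnings.simplefilter("ignore")

workdir = Path(tempfile.mkdtemp(prefix="ramandecomp_demo_"))
blocks = []
for sample in generate_study_set("gliadin_liquid", n_samples=2, n_replicates=3, seed=41):
    paths = []
    for i, spec in enumerate(sample.replicates):
        path = workdir / f"{sample.sample_id}_rep{i}.csv"
        write_spectrum(spec, path)
        paths.append(str(path))
    blocks.append({"id": sample.sample_id, "replicates": paths})

config = RunConfig(
    samples=blocks,
    output_dir=str(workdir / "reports"),
    crop_region=None,      # the simulated trace covers only the amide window
    normalize=False,       # no 1460 cm^-1 band in a region-only trace
    regions=[RegionConfig("amide_i", (1590.0, 1710.0), scheme="amide_i")],
)
summary = run_pipeline(config)

print("config hash:", summary["config_hash"])
for path in summary["reports"]:
    report = json.load(open(path))
    block = report["regions"]["amide_i"]
    print(f"\n{report['sample_id']}  (pearson r = {block['pearson_r']:.5f})")
    for label, pct in block["fractions"].items():
        print(f"  {label:<14}{pct:6.1f}%")
print("\nfeature matrix:", summary["feature_matrix"])
# Reports embed the config hash and library version; rerunning the same
# config reproduces them byte for byte.
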