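"""Run the whole orchestrated pipeline from a YAML config.

Writes a phantom cohort to disk (TIFF stacks, label volume, region table,
subject table), then runs quantify -> correlate -> select -> bootstrap ->
validate -> render into a run directory with a reproducibility manifest.
"""

import json
import tempfile
from pathlib import Path

import numpy as np
import yaml

from mavenpy import core_io, run_pipeline, synthetic

tmp = Path(tempfile.mkdtemp(prefix="maven_example_"))
cfg = synthetic.default_config(
    seed=1, n_subjects=20, n_regions=25, causal_region=3, proxy_region=17,
    voxel_phantom=synthetic.PhantomSpec(voxel_noise_sd=0.01),
)
atlas, stacks, phenotypes, _ = synthetic.simulate_phantom(cfg)

(tmp / "stacks").mkdir()
for s in stacks:
    core_io.write_volume(tmp / "stacks" / f"{s.subject_id}.tif", s.voxels)
labels = np.zeros(atlas.shape, dtype=np.uint16)
rows = []
for j, reg in enumerate(atlas.regions, start=1):
    labels.ravel()[reg.indices] = j
    rows.append(f"{reg.region_id}\t{reg.region_name}\t{j}")
core_io.write_volume(tmp / "labels.tif", labels)
(tmp / "regions.tsv").write_text(
    "region_id\tregion_name\tlabel_value\n" + "\n".join(rows) + "\n"
)
phenotypes.to_csv(tmp / "subjects.csv")

config = {
    "input": {
        "stacks_dir": "stacks",
        "atlas_labels": "labels.tif",
        "atlas_regions": "regions.tsv",
        "subjects": "subjects.csv",
    },
    "quantify": {"norm": "per_brain_mean"},
    "correlate": {"focal": "region_003", "k": 5},
    "select": {"seed": 0, "n_folds": 4},
    "bootstrap": {"n_models": 20, "seed": 0, "n_folds": 3},
    "validate": {"region": "region_003"},
    "render": {"k": 5},
}
(tmp / "config.yaml").write_text(yaml.safe_dump(config))

run_dir = run_pipeline(tmp / "config.yaml", tmp / "run")
manifest = json.loads((run_dir / "manifest.json").read_text())
print(f"run directory: {run_dir}")
for stage in manifest["stages"]:
    extras = {k: v for k, v in stage.items() if k != "stage"}
    print(f"  stage {stage['stage']}: {extras}")
print("Rerunning with the same config reproduces every output byte-exactly;")
print("the manifest records parameters, seeds, and input-file hashes.")
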