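"""Generate the benchmark partial-view spheroid clouds and write them to disk.

Each cloud is a 2.5 x 2.5 x 2 cm spheroid at (3, 5, z0) cm with the face
invisible from the origin removed — what a depth camera at the origin would
capture of a sweet-pepper-sized fruit at depth z0.
"""

import json
import tempfile
from pathlib import Path

from symaxis import spheroid_depth_sweep, write_cloud

out = Path(tempfile.mkdtemp(prefix="symaxis_sim_"))
dataset = spheroid_depth_sweep(seed=0, n_points=2000)

entries = []
for i, (cloud, spec) in enumerate(dataset):
    name = f"cloud_{i:03d}.ply"
    write_cloud(cloud, out / name, format="ply")
    entries.append({"file": name, **spec.to_dict()})
(out / "manifest.json").write_text(json.dumps({"clouds": entries}, indent=2))

sizes = [len(c) for c, _ in dataset]
print(f"wrote {len(dataset)} clouds to {out}")
print(f"depths {dataset[0][1].center[2]:.0f}..{dataset[-1][1].center[2]:.0f} cm, "
      f"{min(sizes)}-{max(sizes)} visible points per cloud")
# manifest.json records each cloud's ellipsoid geometry and seed so the
# dataset-evaluation harness can score estimates against the known truth.
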