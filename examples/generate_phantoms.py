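"""Generate a small synthetic phantom dataset and summarize its contents.

The phantoms emulate sagittal T2-weighted pelvic MRI: a darker uterine-wall
annulus with a bright thin cavity inside, dark myomas of varying size, plus
unannotated distractor structures, a smooth bias field and noise.
"""

import collections
import tempfile
from pathlib import Path

from uteroseg.phantom import PhantomConfig, generate_dataset
from uteroseg.cocoio import read_coco

out = Path(tempfile.mkdtemp()) / "phantoms"
config = PhantomConfig(image_size=128, n_images=20, seed=0)
summary = generate_dataset(config, out, split_ratio=(8, 1, 1))

print(f"dataset written to {out}")
for split, info in summary.items():
    print(f"  {split:5s}: {info['images']:3d} images, "
          f"{info['instances']:3d} instances")

_, annotations = read_coco(out / "annotations" / "train.json")
counts = collections.Counter(rec.category for _, rec in annotations)
areas = collections.defaultdict(list)
for _, rec in annotations:
    areas[rec.category].append(rec.area)
print("training-split class balance (cavity is the rare thin class):")
for cat, n in counts.most_common():
    mean_area = sum(areas[cat]) / len(areas[cat])
    print(f"  {cat:15s} n={n:3d}  mean mask area {mean_area:7.1f} px")
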