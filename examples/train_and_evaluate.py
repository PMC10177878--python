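"""Train the desk-profile detector end-to-end on phantoms and evaluate it.

Runs the whole study pipeline — dataset generation, anchor fitting,
training, prediction, COCO-style evaluation — at a size that finishes in a
few minutes on one CPU.  For a quick demonstration the run is deliberately
small; the acceptance script runs the larger 80/10/10 configuration.
"""

import dataclasses
import tempfile
from pathlib import Path

from uteroseg.pipeline import desk_profile, run_pipeline

run_dir = Path(tempfile.mkdtemp()) / "run"
config = desk_profile(n_images=30, seed=0)
config = dataclasses.replace(
    config, train=dataclasses.replace(config.train, epochs=12))

summary = run_pipeline(config, run_dir)

print(f"\nrun directory: {run_dir}")
print(f"fitted anchors reach avg IoU {summary['anchors']['avg_iou']:.3f} "
      f"(k={summary['anchors']['k']})")
final = summary["train"]["final_loss"]
print(f"final epoch losses: cls {final['cls']:.3f}  "
      f"bbox {final['bbox']:.3f}  mask {final['mask']:.3f}")
report = summary["evaluate"]
print("test-split mask AP family (fractions in [0, 1]):")
for key in ("AP", "AP50", "AP75", "APs", "APm", "APl"):
    print(f"  {key:5s} {report['maskAP'][key]:.3f}")
print("with 24 training phantoms the model finds the large structures;")
print("the acceptance configuration (80 images, 10 epochs) reaches "
      "validation mask AP50 above 0.5.")
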