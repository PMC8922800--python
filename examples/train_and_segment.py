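"""Train the three modules on small phantoms and segment a held-out case.

A deliberately tiny run (32x32x24 phantoms, 15 epochs) that walks the whole
regime: independent training of the bone separator, the stacked-hourglass
femur net (fed ground-truth bone masks as its fusion input), and the slice
classifier; then assembly, where the upward net's predicted bone map replaces
the ground-truth fusion and the classifier's confidence gates the femur map.
Expect a modest DOC here — the acceptance-scale experiment in the test suite
trains longer on more cases.
"""

import numpy as np

from hipseg import (
    NetworkConfig,
    TrainConfig,
    generate_phantom,
    PhantomSpec,
    make_half_dataset,
    train_stage,
    assemble,
    segment_volume,
    evaluate_case,
)
from hipseg.phantom import generate_cases
from hipseg.training import STAGES

cases = [(ct, lab) for _, _, ct, lab in generate_cases(
    4, ["normal", "OA", "FNF", "ONFH"], base_seed=5, shape=(32, 32, 24))]
held_out_ct, held_out_lab = generate_phantom(PhantomSpec(shape=(32, 32, 24), seed=999))

net_cfg = NetworkConfig(in_rows=32, in_cols=16, base_channels=4)
samples = make_half_dataset(cases, net_cfg.in_rows, net_cfg.in_cols)
print(f"{len(samples)} half-slice samples "
      f"({sum(s.has_femur for s in samples)} femur-positive)")

handles = {}
for stage in STAGES:
    handles[stage], history = train_stage(
        stage, samples, TrainConfig(epochs=15, batch_size=16, seed=0), net_cfg
    )
    print(f"{stage:10s} loss {history[0]:.4f} -> {history[-1]:.4f}")

pipeline = assemble(handles["upward"], handles["main"], handles["classifier"])
result = segment_volume(held_out_ct, pipeline)
report = evaluate_case(result.labels3d, held_out_lab)

rep = report[1]
print(f"held-out femur DOC {rep.doc:.3f}")
print(f"mean slice confidence {np.mean(result.per_slice_confidence):.2f}")
# DOC is the voxel overlap with the phantom's ground truth (1.0 = perfect);
# the per-slice confidence is the classifier's femur-presence probability
# that multiplied the femur map before thresholding.
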