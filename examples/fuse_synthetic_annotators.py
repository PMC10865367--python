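"""Fuse disagreeing annotations of one object and score the consensus.

Simulates a ground-truth cell-like region and five annotators who each
displace its boundary by a few pixels, then fuses the five masks with each
algorithm and prints the Jaccard index (JI) of every result against the
known truth. A JI of 1.0 would be pixel-perfect agreement; individual
annotators land around 0.93 here, and the averaging-based fusions recover a
contour closer to the truth than a typical annotator.
"""

import numpy as np

from segfuse import (
    ALGORITHMS,
    FusionConfig,
    RaterSpec,
    ShapeSpec,
    fuse,
    jaccard,
    make_shape,
    simulate_raters,
)

truth = make_shape(ShapeSpec(kind="disk", canvas=(96, 96), radius=28))
specs = [RaterSpec(mode="boundary", amplitude=3, seed=s) for s in range(5)]
annotators = simulate_raters(truth, specs)

rater_ji = [jaccard(m, truth.pixels).value for m in annotators]
print(f"individual annotators: JI = {', '.join(f'{v:.4f}' for v in rater_ji)}")
print(f"mean annotator JI     = {np.mean(rater_ji):.4f}\n")

for algorithm in ALGORITHMS:
    cfg = FusionConfig(algorithm=algorithm, line_mode="internal", target_index=1)
    line = fuse(annotators, cfg)
    print(f"{algorithm:22s} JI = {jaccard(line, truth.pixels).value:.4f}")
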