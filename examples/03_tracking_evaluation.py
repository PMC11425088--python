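"""Evaluating a pose stream against manual annotations.

Predictions within an inclusive 10-pixel radius of the hand-labelled point
count as true positives; confident-but-wrong predictions count as a false
positive and a miss; low-confidence frames count as misses only. The same
module reports the fraction of frames a 0.9 confidence gate would discard.
"""

import numpy as np

from activecomm import PoseStream, fraction_below_accuracy, precision_sensitivity
from activecomm.pose_io import AnnotationRecord

rng = np.random.default_rng(0)
n = 50
truth = rng.uniform(50, 500, size=(n, 2))
pred = truth + rng.normal(0.0, 2.0, size=(n, 2))   # ~2 px tracker jitter
conf = np.full(n, 0.99)
pred[:3] += 40.0        # three confidently wrong frames
conf[-4:] = 0.5         # four occluded (low-confidence) frames

stream = PoseStream(np.arange(n), np.arange(n, dtype=float),
                    pred, pred - [10.0, 0.0], conf, np.full(n, 0.99))
annotations = [AnnotationRecord(i, truth[i], truth[i] - [10.0, 0.0])
               for i in range(n)]

res = precision_sensitivity(stream, annotations, radius_px=10.0,
                            conf_threshold=0.9, bodypart="head")
print(f"TP={res.n_tp}  FP={res.n_fp}  FN={res.n_fn}")
print(f"precision:   {100 * res.precision:.2f} %")
print(f"sensitivity: {100 * res.sensitivity:.2f} %")
print(f"frames below 0.9 gate: {100 * fraction_below_accuracy(stream, 0.9):.1f} %")
# 43 of 46 confident predictions land inside the radius; the 4 gated frames
# lower sensitivity but not precision.
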