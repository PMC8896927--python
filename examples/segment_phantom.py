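"""Segment a corrupted synthetic short-axis slice and score the result.

Generates a phantom at the default study conditions (bias amplitude 0.3,
noise SD 8.5), runs the full clustering + watershed pipeline, and compares
the result against the known ground truth.
"""

import numpy as np

from lgcw import PhantomSpec, generate_phantom, segment_lgcw
from lgcw.metrics import dice, evaluate

image, truth = generate_phantom(PhantomSpec(seed=1))
labels, report = segment_lgcw(image)

foreground = labels > 0
rep = evaluate(foreground, truth.foreground())
print(f"iterations:   {len(report.iteration_log)}")
print(f"regions:      {int(labels.max())}")
print(f"dice:         {rep.dice:.4f}")
print(f"mad_px:       {rep.mad:.2f}")
print(f"max_mad_px:   {rep.max_mad:.2f}")

# Dice near 1 and MAD of a couple of pixels mean the recovered anatomy
# (blood pool + myocardial ring) matches the simulated truth closely
# despite the 30% intensity shading and the added noise.
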