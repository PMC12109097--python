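"""Overlap and surface-distance metrics on a pair of masks.

Builds a ground-truth disk and a slightly shifted, slightly smaller
prediction, then prints DSC, JAC, HD95 and ASD — the four numbers used to
score every segmentation in this package.
"""

import numpy as np

from pemt import asd, dice_jaccard, evaluate_masks, hd95

yy, xx = np.mgrid[0:64, 0:64]
truth = (yy - 32) ** 2 + (xx - 32) ** 2 <= 14 ** 2
pred = (yy - 34) ** 2 + (xx - 30) ** 2 <= 13 ** 2

dsc, jac = dice_jaccard(pred, truth)
print(f"DSC  = {dsc:.4f}   (overlap, 1 = perfect)")
print(f"JAC  = {jac:.4f}   (intersection over union)")
print(f"HD95 = {hd95(pred, truth):.2f} px (95th-percentile boundary error)")
print(f"ASD  = {asd(pred, truth):.2f} px (mean boundary error, pred -> truth)")

report = evaluate_masks(pred.astype(int), truth.astype(int), num_classes=2)
print(f"\nmacro report: {report}")
print("A 2-3 px boundary misplacement on a 14 px disk costs ~0.1 DSC but")
print("shows up directly in the surface distances.")
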