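"""Compare the residual-guided (RUM) and entropy (EUM) uncertainty curves.

For a binary task a pixel's uncertainty depends only on its foreground
probability p.  This script evaluates both quantifiers over p in [0, 1] and
prints their maxima and the iteration-dependent threshold range they are
gated against during training.
"""

import math

import numpy as np

from pemt import eum, rum, tau_threshold

p = np.linspace(0.0, 1.0, 10001)
p_map = np.stack([1.0 - p, p])

print(f"{'upsilon':>8} {'max RUM':>10} {'argmax p':>10}")
for upsilon in (1.0, 2.0, 3.0):
    vals = rum(p_map, upsilon)
    print(f"{upsilon:>8.0f} {vals.max():>10.4f} {p[vals.argmax()]:>10.3f}")

e = eum(p_map)
print(f"{'entropy':>8} {e.max():>10.4f} {p[e.argmax()]:>10.3f}")

tau0, tau1 = tau_threshold(0, 6000), tau_threshold(6000, 6000)
print(f"\ntau ramps from {tau0:.4f} to {tau1:.4f} (= ln 2 = {math.log(2):.4f})")
print("At upsilon=2 the RUM maximum (0.354) sits below the smallest tau, so")
print("the RUM mask keeps every pixel under the printed threshold schedule.")
print("At upsilon=1 the 0^0 = 1 endpoint convention makes the curve jump to 1")
print("at p in {0, 1} (its value at p=0.5 is 0.707): confident pixels would be")
print("masked out, another reason upsilon=2 is the default.")
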