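"""Protein-centric CAFA evaluation on a tiny hand-made example.

Two proteins, three terms.  The predictor ranks the true terms highest for
protein 1 but confuses protein 2, so Fmax sits below 1 and Smin above 0;
term rarity enters through the information content weights.
"""

import numpy as np

from megago import fmax, aupr, smin, information_content

y = np.array([[1, 1, 0],
              [0, 1, 1]])
scores = np.array([[0.9, 0.8, 0.1],
                   [0.7, 0.2, 0.6]])
ic = information_content(np.array([0.5, 0.75, 0.25]))  # term frequencies

f, f_t = fmax(y, scores)
s, s_t = smin(y, scores, ic)
print(f"Fmax = {f:.3f} at threshold {f_t:.2f}")
print(f"Smin = {s:.3f} (IC units) at threshold {s_t:.2f}")
print(f"micro-AUPR = {aupr(y, scores):.3f}")
print(f"term IC values: {np.round(ic.ic, 3)}")
# Fmax picks the decision threshold with the best protein-averaged F1;
# Smin penalizes missed rare (high-IC) terms more than missed common ones.
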