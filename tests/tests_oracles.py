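"""Frozen hand-computed oracle values for the agreement metrics.

The kappa/AC1 values come from the standard multi-rater computation of
P-bar and P-bar_e on a 5-subject, 3-rater, 3-category table; the ICC
value from a one-way ANOVA (BMS = 22.888..., WMS = 2/3) on a 4-ROI,
3-date table.  All were derived by hand before being frozen here.
"""

import numpy as np

TOY_TABLE = np.array([[1, 1, 1], [1, 1, 0], [0, 0, -1], [-1, -1, -1], [0, 1, -1]])
# P-bar = 8/15, P-bar_e = 77/225  ->  kappa = (8/15 - 77/225)/(1 - 77/225)
KAPPA_TOY = 0.2905405405405405
# AC1 chance term: sum pi_q (1 - pi_q) / 2 = 0.302222...
AC1_TOY = 0.3046357615894040

ICC_TABLE = np.array([[9.0, 8, 7], [7, 6, 6], [4, 5, 3], [2, 2, 1]])
ICC_TOY = 0.9174311926605504
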