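"""Penalty-weight loss: cost matrices, the two equivalent loss forms, and
the gradient used for training.

For a binary (healthy/torn) problem with the default absolute-distance rule
the corrected cost matrix is [[0, 2], [2, 0]]: a confident wrong call costs
2, a confident right call costs 0, and the loss is linear in the wrong-class
probability in between.
"""

import numpy as np

from tdslice import build_penalty_matrix, penalty_loss_corrected, penalty_loss_q
from tdslice.penalty import penalty_loss_grad_logits

pm = build_penalty_matrix(2)
print("base matrix W:\n", pm.base)
print("corrected matrix W':\n", pm.corrected)

p = np.array([0.3, 0.7])  # softmax output, true class = torn (index 1)
print("q-form loss      :", round(penalty_loss_q(p, 1, pm), 4))
print("corrected loss   :", round(penalty_loss_corrected(p, 1, pm), 4))
# both print 0.6: the forms are algebraically identical for unit-diagonal W

loss, grad = penalty_loss_grad_logits(np.log(p), 1, pm)
print("gradient w.r.t. pre-softmax scores:", np.round(grad, 4))
# the gradient pushes the torn-class score up and the healthy score down

# an asymmetric override: calling a torn ligament healthy costs 3 instead of 1
pm_asym = build_penalty_matrix(2, overrides={(0, 1): 3.0})
print("asymmetric corrected:\n", pm_asym.corrected)
print("missed tear loss  :", penalty_loss_corrected([0.9, 0.1], 1, pm_asym))
print("false alarm loss  :", penalty_loss_corrected([0.1, 0.9], 0, pm_asym))
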