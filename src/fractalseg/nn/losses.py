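"""Loss functions."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, make_op


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    ``targets`` is a plain {0,1} array of the same shape as ``logits``.
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != z.shape:
        raise ValueError(f"target shape {t.shape} != logit shape {z.shape}")
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = np.float32(loss.mean())

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-z))
        return [(logits, (g * (p - t) / z.size).astype(np.float32))]

    return make_op(out, (logits,), backward)
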