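"""A sequential network with gradient access at arbitrary depth."""

from __future__ import annotations

import numpy as np


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """Ordered stack of layers producing class logits.

    ``forward`` runs the stack (training flag controls batch-norm statistics
    and dropout); ``backward`` propagates a logit-space gradient through the
    caches left by the most recent forward call.  ``input_gradient`` and
    ``class_score_gradient`` expose the gradients saliency maps and grad-CAM
    need, always in inference mode.
    """

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None, return_activations=False):
        acts = []
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
            acts.append(x)
        if return_activations:
            return x, acts
        return x

    def backward(self, dlogits, stop_at=0):
        """Backpropagate to the input of layer index ``stop_at`` and return it."""
        d = dlogits
        for layer in reversed(self.layers[stop_at:]):
            d = layer.backward(d)
        return d

    def n_parameters(self):
        return sum(layer.n_parameters() for layer in self.layers)

    def class_score_gradient(self, x, class_index, stop_at=0):
        """Gradient of the pre-softmax score of ``class_index`` w.r.t. the
        output of layer ``stop_at - 1`` (the input itself when stop_at=0).

        Runs in inference mode.  Returns (gradient, logits, activations).
        """
        logits, acts = self.forward(np.asarray(x, dtype=np.float32),
                                    training=False, return_activations=True)
        dlogits = np.zeros_like(logits)
        dlogits[..., class_index] = 1.0
        grad = self.backward(dlogits, stop_at=stop_at)
        return grad, logits, acts

    def input_gradient(self, x, class_index):
        grad, logits, _ = self.class_score_gradient(x, class_index, stop_at=0)
        return grad, logits
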