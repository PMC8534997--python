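"""Diagnostic visualizations: gradient saliency, grad-CAM, feature maps.

Both attribution methods differentiate the pre-softmax class score (scores
shifted by a constant leave the maps unchanged).  Saliency is the per-pixel
gradient magnitude at the input, max-reduced over channels; grad-CAM
weights a convolutional layer's activations by their spatially averaged
gradients, clips negatives and upsamples to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .model import GaitClassifier
from .represent import REPRESENTATION_SIZE, GaitRepresentation

N_CONV_LAYERS = 5


@dataclass(frozen=True)
class ExplanationMap:
    """A 224x224 attribution map in [0, 1]."""

    values: np.ndarray
    method: str                     # "saliency" | "grad_cam"
    target_class: int
    conv_layer: int | None = None   # 1-based, grad-CAM only

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32)
        if v.shape != (REPRESENTATION_SIZE, REPRESENTATION_SIZE):
            raise ValueError("explanation maps are 224x224")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("explanation maps live in [0, 1]")
        object.__setattr__(self, "values", v)


def _as_input(classifier, representation):
    px = (representation.pixels if isinstance(representation, GaitRepresentation)
          else np.asarray(representation, dtype=np.float32))
    return classifier._to_batch([px])


def _check_class(classifier, target_class):
    if not 0 <= target_class < len(classifier.class_labels):
        raise ValueError(f"class index {target_class} out of range")


def _rescale(values):
    """Scale max to 1; an all-zero map stays all-zero (not rescaled)."""
    m = values.max()
    return values / m if m > 0 else values


def _conv_positions(network):
    """Indices of the post-ReLU activation of each conv block."""
    positions = []
    for i, layer in enumerate(network.layers):
        if type(layer).__name__ == "Conv2D":
            positions.append(i + 2)  # conv -> batchnorm -> relu
    return positions


def saliency_map(classifier, representation, target_class: int) -> ExplanationMap:
    """Gradient of the target pre-softmax score w.r.t. the input image.

    The per-pixel magnitude is max-reduced over the (replicated) input
    channels and rescaled so the maximum is 1; the map of an identically
    zero gradient is returned as all zeros.
    """
    _check_class(classifier, target_class)
    x = _as_input(classifier, representation)
    grad, _ = classifier.network.input_gradient(x, target_class)
    sal = np.abs(grad[0]).max(axis=-1)
    return ExplanationMap(values=_rescale(sal), method="saliency",
                          target_class=target_class)


def grad_cam(classifier: GaitClassifier, representation, target_class: int,
             layer_index: int = N_CONV_LAYERS) -> ExplanationMap:
    """Class-activation map at one of the five conv layers (1-based index).

    cam = ReLU( sum_c alpha_c A_c ),  alpha_c = spatial mean of dscore/dA_c,
    upsampled to 224x224 and rescaled to [0, 1].
    """
    _check_class(classifier, target_class)
    if not 1 <= layer_index <= N_CONV_LAYERS:
        raise ValueError(f"layer_index must be in 1..{N_CONV_LAYERS}")
    x = _as_input(classifier, representation)
    pos = _conv_positions(classifier.network)[layer_index - 1]
    grad, _, acts = classifier.network.class_score_gradient(
        x, target_class, stop_at=pos)
    activation = acts[pos - 1][0]          # (h, w, c), post-ReLU
    alphas = grad[0].mean(axis=(0, 1))     # (c,)
    cam = np.maximum((activation * alphas).sum(axis=-1), 0.0)
    cam = resize(cam, (REPRESENTATION_SIZE, REPRESENTATION_SIZE), order=1,
                 anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    return ExplanationMap(values=_rescale(cam), method="grad_cam",
                          target_class=target_class, conv_layer=layer_index)


def dump_feature_maps(classifier: GaitClassifier, representation,
                      layer_index: int) -> np.ndarray:
    """Per-channel activations of one conv layer: (channels, size, size).

    Spatial sizes follow the architecture: layers 1..5 give 112, 56, 28,
    14 and 7 pixels respectively.
    """
    if not 1 <= layer_index <= N_CONV_LAYERS:
        raise ValueError(f"layer_index must be in 1..{N_CONV_LAYERS}")
    x = _as_input(classifier, representation)
    pos = _conv_positions(classifier.network)[layer_index - 1]
    _, acts = classifier.network.forward(x, training=False,
                                         return_activations=True)
    return np.moveaxis(acts[pos - 1][0], -1, 0)


def overlay(representation, explanation: ExplanationMap, alpha: float = 0.5):
    """Composite an attribution map over the energy image (RGB uint8).

    Uses a perceptually uniform colormap for the map and renders the energy
    image in grayscale underneath.
    """
    import matplotlib
    px = (representation.pixels if isinstance(representation, GaitRepresentation)
          else np.asarray(representation, dtype=np.float32))
    cmap = matplotlib.colormaps["viridis"]
    heat = cmap(explanation.values)[..., :3]
    base = np.repeat(px[..., None], 3, axis=2)
    out = (1 - alpha) * base + alpha * heat
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)
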