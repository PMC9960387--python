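"""Grad-CAM attribution for the 1D CNN and slope-masked class importance.

For a window x and target class c, Grad-CAM weights each channel k of the
last convolutional feature map f_k by the time-averaged gradient of the
pre-softmax class score y^c with respect to that map,

    a_k^c = mean_t d y^c / d f_k(t),        L_c = ReLU(sum_k a_k^c f_k),

then upsamples the nonnegative map L_c to the input time axis by linear
interpolation (endpoints pinned).

The dataset-level slope score splits total saliency between rising and
falling parts of the input. With the discrete derivative x' (x'_1 = 0), the
rising mask g+ flags positions with x'_i > 0 and g- the complement, so
g+ + g- = 1 everywhere. Per window, w_c+ = L_c . g+ and w_c- = L_c . g-;
summed over the windows the model assigns to class c and normalised,

    w_c+_norm = w_c+ / (w_c+ + w_c-),   w_c-_norm = 1 - w_c+_norm,

which is invariant to any positive rescaling of the saliency maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .neural import Model, predict_label_indices
from .preprocess import discrete_derivative

__all__ = [
    "SaliencyMap",
    "SlopeImportanceResult",
    "gradcam",
    "slope_masks",
    "window_slope_weights",
    "dataset_slope_importance",
]


@dataclass(frozen=True)
class SaliencyMap:
    """Nonnegative per-timestep relevance for one window and one class."""

    raw: np.ndarray  # over the last-conv time axis
    upsampled: np.ndarray  # over the input time axis, length l
    class_idx: int


def _upsample(scores: np.ndarray, length: int) -> np.ndarray:
    if scores.size == length:
        return scores.copy()
    src = np.linspace(0.0, 1.0, scores.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, scores)


def gradcam(model: Model, values: np.ndarray, class_idx: int) -> SaliencyMap:
    """Saliency of one model-input trace toward ``class_idx``.

    ``values`` is a 1-D array in the model's input space (i.e. after the
    deep-learning preprocessing pipeline).
    """
    values = np.asarray(values, dtype=float)
    x = values.reshape(1, -1, 1)
    fmap, grad = model.class_score_gradient(x, class_idx)  # (1, t', k)
    weights = grad.mean(axis=1)  # a_k^c, global average over the time axis
    raw = np.maximum((fmap * weights[:, None, :]).sum(axis=2), 0.0)[0]
    return SaliencyMap(raw=raw, upsampled=_upsample(raw, values.size),
                       class_idx=class_idx)


def slope_masks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary rising/falling masks from the discrete derivative.

    g_plus[i] = 1 iff x'_i > 0, g_minus = 1 - g_plus; since x'_1 = 0 the
    first position always belongs to the falling mask.
    """
    deriv = discrete_derivative(np.asarray(values, dtype=float))
    g_plus = (deriv > 0).astype(float)
    return g_plus, 1.0 - g_plus


def window_slope_weights(saliency: SaliencyMap,
                         masks: tuple[np.ndarray, np.ndarray]
                         ) -> tuple[float, float]:
    """Scalar saliency mass over rising and falling regions of one window."""
    g_plus, g_minus = masks
    s = saliency.upsampled
    if s.size != g_plus.size:
        raise ValueError("saliency and mask lengths differ")
    return float(s @ g_plus), float(s @ g_minus)


@dataclass(frozen=True)
class SlopeImportanceResult:
    """Dataset-level rising/falling saliency split for one target class."""

    class_idx: int
    w_plus: float
    w_minus: float
    w_plus_norm: float | None
    w_minus_norm: float | None
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "class_idx": self.class_idx,
            "w_plus": self.w_plus,
            "w_minus": self.w_minus,
            "w_plus_norm": self.w_plus_norm,
            "w_minus_norm": self.w_minus_norm,
            "n_windows": self.n_windows,
        }


def dataset_slope_importance(model: Model, inputs: np.ndarray, class_idx: int,
                             mode: str = "predicted",
                             true_labels: np.ndarray | None = None
                             ) -> SlopeImportanceResult:
    """Aggregate the per-window slope weights over a whole dataset.

    ``inputs`` is (n, time) in model-input space. Heat maps are computed with
    respect to the classification outcome: in the default ``"predicted"``
    mode a window contributes to class ``class_idx`` only if the model
    assigns it that class, which keeps the per-class scores undiluted by
    windows the network attributes to the other class. ``"correct"``
    additionally requires the prediction to match ``true_labels`` (0/1
    indices); ``"all"`` aggregates saliency toward ``class_idx`` over every
    window regardless of outcome.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[0] == 0:
        raise ValueError("inputs must be a non-empty (n, time) array")
    if mode == "all":
        keep = np.ones(inputs.shape[0], dtype=bool)
    elif mode in ("predicted", "correct"):
        pred = predict_label_indices(model, inputs[:, :, None])
        keep = pred == class_idx
        if mode == "correct":
            if true_labels is None:
                raise ValueError("mode='correct' requires true_labels")
            keep &= pred == np.asarray(true_labels)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total_plus = 0.0
    total_minus = 0.0
    n_used = 0
    for row in inputs[keep]:
        sal = gradcam(model, row, class_idx)
        wp, wm = window_slope_weights(sal, slope_masks(row))
        total_plus += wp
        total_minus += wm
        n_used += 1
    denom = total_plus + total_minus
    if denom <= 0:
        warnings.warn("total saliency is zero; normalised weights undefined")
        wpn = wmn = None
    else:
        wpn = total_plus / denom
        wmn = 1.0 - wpn
    return SlopeImportanceResult(class_idx=class_idx, w_plus=total_plus,
                                 w_minus=total_minus, w_plus_norm=wpn,
                                 w_minus_norm=wmn, n_windows=n_used)
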