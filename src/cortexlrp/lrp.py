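"""Composite layer-wise relevance propagation through the trained classifier.

Relevance starts at the network output as the pre-sigmoid score of the
predicted class and is redistributed backwards layer by layer.  For a linear
(dense or convolutional) layer with inputs a_j, weights w_jk and bias b_k,
the contribution of input j to output k is z_jk = a_j * w_jk and

    LRP-0:       R_j = sum_k z_jk / (sum_j z_jk + b_k) * R_k
    LRP-eps:     denominator additionally stabilized by eps * sign(.)
    LRP-gamma:   weights (and bias) replaced by w + gamma * w^+, amplifying
                 positive contributions; gamma -> inf keeps only z^+

Bias terms enter the denominator but receive no redistributed relevance, so
with zero bias LRP-0 conserves total relevance exactly.  Max-pooling routes
relevance winner-take-all to the argmax input of each window.  The composite
assignment follows common practice for this architecture: LRP-0 on the fully
connected layers, LRP-eps on the upper (second) convolution block, LRP-gamma
on the lower (first) block.

Pixel relevance returns to the cortex through the projection map: each vertex
receives its pixel's relevance split equally among the vertices sharing the
pixel; empty pixels contribute to no vertex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cortexlrp.cnn import CNNModel, Conv2D, Dense, Flatten, MaxPool2D, col2im
from cortexlrp.projection import ProjectionMap

__all__ = [
    "LRPRuleParams",
    "RelevanceMap",
    "default_composite",
    "propagate_dense",
    "propagate_conv",
    "propagate_pool",
    "explain",
    "pixel_to_vertex",
    "aggregate_heatmaps",
    "render_heatmap",
]

_ZERO_GUARD = 1e-9


@dataclass(frozen=True)
class LRPRuleParams:
    """One propagation rule: 'lrp0', 'epsilon' (eps > 0) or 'gamma' (gamma >= 0)."""

    rule: str = "lrp0"
    eps: float = 0.01
    gamma: float = 0.25

    def __post_init__(self) -> None:
        if self.rule not in ("lrp0", "epsilon", "gamma"):
            raise ValueError(f"unknown LRP rule {self.rule!r}")
        if self.rule == "epsilon" and self.eps <= 0:
            raise ValueError("epsilon rule requires eps > 0")
        if self.rule == "gamma" and self.gamma < 0:
            raise ValueError("gamma rule requires gamma >= 0")


def default_composite() -> dict[str, LRPRuleParams]:
    """LRP-0 on dense layers, eps on the upper conv block, gamma on the lower."""
    return {
        "dense": LRPRuleParams("lrp0"),
        "block2": LRPRuleParams("epsilon", eps=0.01),
        "block1": LRPRuleParams("gamma", gamma=0.25),
    }


@dataclass
class RelevanceMap:
    """Relevance for one trial, in pixel space and (optionally) vertex space."""

    pixel: np.ndarray  # (H, W)
    vertex: np.ndarray | None = None  # (n_vertices,)
    trial_id: int | None = None
    subject_id: int | None = None
    true_label: int | None = None
    predicted_label: int | None = None

    @property
    def correct(self) -> bool:
        if self.true_label is None or self.predicted_label is None:
            raise ValueError("prediction provenance not set")
        return self.true_label == self.predicted_label


def _modified(W: np.ndarray, b: np.ndarray, params: LRPRuleParams):
    if params.rule == "gamma":
        return W + params.gamma * np.clip(W, 0.0, None), b + params.gamma * np.clip(b, 0.0, None)
    return W, b


def _stabilize(z: np.ndarray, params: LRPRuleParams) -> np.ndarray:
    sign = np.where(z >= 0, 1.0, -1.0)
    if params.rule == "epsilon":
        return z + params.eps * sign
    small = np.abs(z) < _ZERO_GUARD
    if np.any(small):
        warnings.warn("zero denominator in LRP; stabilizing with eps=1e-9")
        return np.where(small, z + _ZERO_GUARD * sign, z)
    return z


def propagate_dense(
    R_next: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    activations: np.ndarray,
    params: LRPRuleParams,
) -> np.ndarray:
    """Redistribute dense-layer relevance (batched: rows are samples).

    ``activations`` are the stored forward-pass inputs of the layer (dropout
    disabled).  The bias contributes to the denominator only.
    """
    R_next = np.atleast_2d(R_next)
    a = np.atleast_2d(activations)
    Wm, bm = _modified(weights, bias, params)
    z = a @ Wm + bm
    s = R_next / _stabilize(z, params)
    return a * (s @ Wm.T)


def propagate_conv(R_next: np.ndarray, layer: Conv2D, params: LRPRuleParams) -> np.ndarray:
    """Conv-layer relevance via the im2col linear map (matches the unrolled
    dense propagation exactly)."""
    if not layer.cache:
        raise ValueError("conv layer has no cached forward pass")
    n, f, ho, wo = R_next.shape
    exp_shape = layer.out_shape(layer.cache["x_shape"][1:])
    if (f, ho, wo) != exp_shape:
        raise ValueError(f"relevance shape {(f, ho, wo)} does not match conv output {exp_shape}")
    cols = layer.cache["cols"]
    Wm, bm = _modified(layer.W, layer.b, params)
    z = cols @ Wm + bm  # (N, P, F)
    s = R_next.transpose(0, 2, 3, 1).reshape(n, ho * wo, f) / _stabilize(z, params)
    c = s @ Wm.T  # (N, P, C*k*k)
    return col2im(c, layer.cache["x_shape"], layer.kernel) * layer.cache["input"]


def propagate_pool(R_next: np.ndarray, layer: MaxPool2D) -> np.ndarray:
    """Winner-take-all: each window's relevance goes to its argmax input."""
    return layer.unpool(R_next)


def _assign_rules(model: CNNModel, composite: dict[str, LRPRuleParams]) -> list:
    rules: list = []
    pools_seen = 0
    for layer in model.layers:
        if isinstance(layer, Conv2D):
            rules.append(composite["block1" if pools_seen == 0 else "block2"])
        elif isinstance(layer, Dense):
            rules.append(composite["dense"])
        else:
            rules.append(None)
        if isinstance(layer, MaxPool2D):
            pools_seen += 1
    return rules


def explain(
    model: CNNModel,
    images: np.ndarray,
    composite: dict[str, LRPRuleParams] | None = None,
) -> np.ndarray:
    """Pixel relevance for one image (H, W) or a stack (N, H, W).

    Runs an evaluation-mode forward pass (caching activations and pool
    switches), initializes the output relevance to the pre-sigmoid score of
    the predicted class, and propagates backward under the composite rule
    assignment.
    """
    if composite is None:
        composite = default_composite()
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 2

    p = model.forward(images)
    logit = model.logits()
    predicted = p >= 0.5
    R = np.where(predicted, logit, -logit)[:, None]

    rules = _assign_rules(model, composite)
    for layer, rule in reversed(list(zip(model.layers, rules))):
        if isinstance(layer, Dense):
            R = propagate_dense(R, layer.W, layer.b, layer.cache["input"], rule)
        elif isinstance(layer, Flatten):
            R = R.reshape(layer.cache["x_shape"])
        elif isinstance(layer, MaxPool2D):
            R = propagate_pool(R, layer)
        elif isinstance(layer, Conv2D):
            R = propagate_conv(R, layer, rule)
        else:  # pragma: no cover
            raise TypeError(f"cannot propagate through {type(layer).__name__}")
    pixel = R[:, 0]  # drop channel axis
    return pixel[0] if single else pixel


def pixel_to_vertex(
    R_pixels: np.ndarray, left_map: ProjectionMap, right_map: ProjectionMap
) -> np.ndarray:
    """Back-project (H, 2H) pixel relevance to per-vertex relevance.

    The image is left raster | right raster.  A pixel's relevance is split
    equally among the vertices assigned to it; empty pixels are ignored.
    Conservation: the vertex total equals the non-empty-pixel total.
    """
    g = left_map.grid_size
    if right_map.grid_size != g:
        raise ValueError("hemisphere projection maps use different grids")
    if R_pixels.shape != (g, 2 * g):
        raise ValueError(f"expected pixel map of shape {(g, 2 * g)}, got {R_pixels.shape}")
    n_vertices = int(max(left_map.vertex_index.max(), right_map.vertex_index.max())) + 1
    out = np.zeros(n_vertices)
    for pmap, col_offset in ((left_map, 0), (right_map, g)):
        counts = pmap.counts()
        share = R_pixels[pmap.rows, pmap.cols + col_offset] / counts[pmap.rows, pmap.cols]
        out[pmap.vertex_index] = share
    return out


def aggregate_heatmaps(maps: list[RelevanceMap], scope: str = "pooled"):
    """Mean relevance over correctly classified trials.

    scope="pooled" returns one RelevanceMap averaging all correct trials;
    scope="per_subject" returns {subject_id: RelevanceMap}.
    """
    correct = [m for m in maps if m.correct]
    if not correct:
        raise ValueError("no correctly classified trials to aggregate")
    if scope == "pooled":
        return _mean_map(correct)
    if scope == "per_subject":
        subjects = sorted({m.subject_id for m in correct})
        return {s: _mean_map([m for m in correct if m.subject_id == s]) for s in subjects}
    raise ValueError(f"unknown scope {scope!r}")


def render_heatmap(rmap: RelevanceMap, path, dpi: int = 150) -> None:
    """Write the pixel relevance map to a PNG (symmetric diverging scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    vmax = np.abs(rmap.pixel).max() or 1.0
    im = ax.imshow(rmap.pixel, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.axvline(rmap.pixel.shape[1] / 2 - 0.5, color="k", lw=0.5)
    fig.colorbar(im, ax=ax, label="relevance")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def _mean_map(maps: list[RelevanceMap]) -> RelevanceMap:
    pixel = np.mean([m.pixel for m in maps], axis=0)
    vertex = None
    if all(m.vertex is not None for m in maps):
        vertex = np.mean([m.vertex for m in maps], axis=0)
    subject_ids = {m.subject_id for m in maps}
    return RelevanceMap(
        pixel=pixel,
        vertex=vertex,
        subject_id=subject_ids.pop() if len(subject_ids) == 1 else None,
    )
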