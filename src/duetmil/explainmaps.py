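"""Explainability: attention rollout, per-tile classification scores,
contribution (attention x classification) maps and heatmap rendering.

Attention rollout attributes the class-token output to input tiles by
averaging each layer's heads into one row-stochastic matrix and multiplying
the layer matrices in order; the class-token row of the product, restricted
to tile columns and renormalized, is the per-tile attention score. The
default follows the canonical formulation, which mixes the identity into
each layer matrix (0.5 A + 0.5 I) to account for residual connections —
without it, the near-uniform token mixing of early layers washes out the
informative class-token rows of later layers. The bare matrix product is
available with ``residual=False``. The
classification channel scores each tile by running it alone through the
trained model; the contribution channel is the elementwise product of the
two raw channels. For display, each channel is min-max normalized to [0, 1]
after clipping at the 1st/99th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .duonet import DuetTransformer, ForwardTrace
from .tileenc import EmbeddingBag

_STOCH_TOL = 1e-4


@dataclass
class AttentionMap:
    """Per-tile score channels of one slide, aligned with its tile boxes."""

    case_id: str
    modality: str
    attention: np.ndarray  # raw rollout scores, sum to 1
    classification: np.ndarray  # single-tile model probabilities in [0, 1]
    contribution: np.ndarray  # elementwise product of the raw channels
    tile_boxes: np.ndarray  # (N, 4) int: x0, y0, w, h
    constant_channels: tuple = ()  # channels degenerate under min-max display scaling

    def display(self, channel: str, clip_pct: float = 1.0) -> np.ndarray:
        """Channel normalized to [0, 1] with percentile clipping; a constant
        channel maps to all zeros (flagged in ``constant_channels``)."""
        v = getattr(self, channel).astype(float)
        lo, hi = np.percentile(v, [clip_pct, 100.0 - clip_pct])
        if hi - lo < 1e-12:
            return np.zeros_like(v)
        return np.clip((v - lo) / (hi - lo), 0.0, 1.0)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "case_id": self.case_id, "modality": self.modality,
            "x0": self.tile_boxes[:, 0], "y0": self.tile_boxes[:, 1],
            "attention": self.attention, "classification": self.classification,
            "contribution": self.contribution,
        })


def _check_row_stochastic(mat: np.ndarray) -> None:
    if (mat < -_STOCH_TOL).any() or np.abs(mat.sum(axis=-1) - 1.0).max() > _STOCH_TOL:
        raise ValueError("attention rows must be non-negative and sum to 1")


def attention_rollout(per_layer_attention: list[np.ndarray],
                      residual: bool = True) -> np.ndarray:
    """Per-tile attribution scores from stacked attention tensors.

    ``per_layer_attention``: one ``(n_heads, T, T)`` row-stochastic tensor
    per layer over (class token + N tiles), in layer order. Heads are
    averaged arithmetically per layer, the layer matrices multiplied
    last-layer-first, and the class-token row restricted to tile columns and
    renormalized to sum to one. With the default ``residual=True`` the
    identity is mixed in (0.5 I + 0.5 A, renormalized) before multiplying —
    the canonical rollout, which accounts for the skip connections the raw
    attention matrices ignore; ``residual=False`` gives the bare product.

    If the class token retains essentially no tile mass (e.g. identity
    attention), a uniform attribution is returned with a warning rather than
    a division by ~0.
    """
    if not per_layer_attention:
        raise ValueError("need at least one layer of attention")
    rollout = None
    for layer in per_layer_attention:
        a = np.asarray(layer, dtype=float)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("each layer must be (n_heads, T, T)")
        _check_row_stochastic(a)
        m = a.mean(axis=0)
        if residual:
            m = 0.5 * m + 0.5 * np.eye(m.shape[0])
            m /= m.sum(axis=-1, keepdims=True)
        rollout = m if rollout is None else m @ rollout
    _check_row_stochastic(rollout)  # product of row-stochastic matrices
    tile_mass = rollout[0, 1:]
    total = tile_mass.sum()
    n = tile_mass.size
    if total < 1e-9:
        warnings.warn("class token attends only to itself; falling back to uniform scores")
        return np.full(n, 1.0 / n)
    return tile_mass / total


def rollout_from_trace(trace: ForwardTrace, modality: str, residual: bool = True) -> np.ndarray:
    if modality not in trace.attention:
        raise KeyError(f"trace has no attention for branch {modality}")
    return attention_rollout(trace.attention[modality], residual=residual)


def per_head_class_attention(trace: ForwardTrace, modality: str) -> np.ndarray:
    """Last-layer class-token attention per head, tile columns only (n_heads, N)."""
    last = trace.attention[modality][-1]
    rows = last[:, 0, 1:]
    return rows / rows.sum(axis=-1, keepdims=True)


def per_tile_classification(model: DuetTransformer, bag: EmbeddingBag) -> np.ndarray:
    """Score each tile by a forward pass on a bag containing that tile alone."""
    if bag.n_tiles < 1:
        raise ValueError("empty bag")
    mode = "HE_ONLY" if bag.modality == "HE" else "IHC_ONLY"
    scores = np.empty(bag.n_tiles)
    for i in range(bag.n_tiles):
        single = bag.subset(np.array([i]))
        he = single if bag.modality == "HE" else None
        ihc = single if bag.modality == "IHC" else None
        scores[i] = model.forward(he, ihc, mode=mode, training=False).probability
    return scores


def contribution_map(attention_scores: np.ndarray, classification_scores: np.ndarray,
                     tile_boxes: np.ndarray, case_id: str = "case",
                     modality: str = "HE") -> AttentionMap:
    """Assemble the three channels; contribution = attention x classification."""
    att = np.asarray(attention_scores, dtype=float)
    cls = np.asarray(classification_scores, dtype=float)
    if att.shape != cls.shape or att.ndim != 1:
        raise ValueError("attention and classification scores must be 1-D and aligned")
    boxes = np.asarray(tile_boxes, dtype=np.int64)
    if boxes.shape != (att.size, 4):
        raise ValueError("tile_boxes must be (N, 4) aligned with the scores")
    contrib = att * cls
    constant = tuple(
        name for name, v in (("attention", att), ("classification", cls),
                             ("contribution", contrib))
        if v.size and float(v.max() - v.min()) < 1e-12
    )
    return AttentionMap(case_id, modality, att, cls, contrib, boxes,
                        constant_channels=constant)


def explain_case(model: DuetTransformer, bag: EmbeddingBag, residual: bool = True) -> AttentionMap:
    """Full single-modality explanation of one slide with a trained model."""
    mode = "HE_ONLY" if bag.modality == "HE" else "IHC_ONLY"
    he = bag if bag.modality == "HE" else None
    ihc = bag if bag.modality == "IHC" else None
    trace = model.forward(he, ihc, mode=mode, training=False)
    att = rollout_from_trace(trace, bag.modality, residual=residual)
    cls = per_tile_classification(model, bag)
    return contribution_map(att, cls, bag.tile_boxes, bag.case_id, bag.modality)


def render_heatmap(amap: AttentionMap, slide_dims: tuple[int, int],
                   channel: str = "contribution", colormap: str = "viridis",
                   path=None) -> np.ndarray:
    """Paint each tile box with its display-normalized score.

    Uses a perceptually uniform purple-low / yellow-high colormap; background
    stays white. Returns the RGB uint8 canvas and optionally writes a PNG.
    """
    h, w = slide_dims
    if amap.tile_boxes.size and (
        (amap.tile_boxes[:, 0] + amap.tile_boxes[:, 2]).max() > w
        or (amap.tile_boxes[:, 1] + amap.tile_boxes[:, 3]).max() > h
    ):
        raise ValueError("tile boxes exceed slide dims")
    canvas = np.full((h, w, 3), 255, dtype=np.uint8)
    if amap.attention.size == 0:
        warnings.warn("empty attention map; rendering a blank canvas")
    else:
        cmap = colormaps[colormap]
        vals = amap.display(channel)
        occupancy = np.zeros((h, w), dtype=bool)
        for (x0, y0, bw, bh), v in zip(amap.tile_boxes, vals):
            if occupancy[y0:y0 + bh, x0:x0 + bw].any():
                raise ValueError("overlapping tile boxes in attention map")
            occupancy[y0:y0 + bh, x0:x0 + bw] = True
            rgb = (np.array(cmap(float(v))[:3]) * 255).astype(np.uint8)
            canvas[y0:y0 + bh, x0:x0 + bw] = rgb
    if path is not None:
        from PIL import Image

        Image.fromarray(canvas).save(path)
    return canvas
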