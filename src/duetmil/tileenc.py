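"""Tile encoders and the per-slide embedding bag container.

The encoder contract is deliberately thin: anything with an
``embed_dim`` attribute and an ``encode(tiles) -> (N, embed_dim)`` method
plugs in (a pretrained histopathology encoder in production; the
deterministic :class:`ToyEncoder` at desk scale). Bags persist to HDF5,
one ``case/modality`` group with ``embeddings`` (N x d float32) and
``tile_boxes`` (N x 4 int: x0, y0, w, h) datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from .slideprep import TileBox

EMBED_DIM = 768  # default per-tile feature width

MODALITIES = ("HE", "IHC")


@dataclass
class EmbeddingBag:
    """All tile embeddings of one slide: the multiple-instance-learning unit."""

    case_id: str
    modality: str
    embeddings: np.ndarray  # (N, d) float32
    tile_boxes: np.ndarray  # (N, 4) int64
    scanner: str = "synthetic"
    site: str = "primary"

    def __post_init__(self) -> None:
        self.embeddings = np.ascontiguousarray(self.embeddings, dtype=np.float32)
        self.tile_boxes = np.ascontiguousarray(self.tile_boxes, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError("embeddings must be a non-empty (N, d) matrix")
        if self.tile_boxes.shape != (self.embeddings.shape[0], 4):
            raise ValueError("tile_boxes must align with embeddings row-for-row")
        if not np.isfinite(self.embeddings).all():
            raise ValueError("non-finite values in embeddings")

    @property
    def n_tiles(self) -> int:
        return self.embeddings.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.embeddings.shape[1]

    def subset(self, idx: np.ndarray) -> "EmbeddingBag":
        return EmbeddingBag(
            self.case_id, self.modality, self.embeddings[idx], self.tile_boxes[idx],
            scanner=self.scanner, site=self.site,
        )


class ToyEncoder:
    """Deterministic handcrafted-feature tile encoder.

    Computes per-channel 8-bin intensity histograms, channel means and
    standard deviations, horizontal/vertical gradient energy and a local
    texture (Laplacian-energy) moment per tile, then projects the feature
    vector to ``embed_dim`` through a fixed seeded Gaussian matrix. Runs
    anywhere, needs no weights, and maps identical tiles to identical rows.
    """

    N_RAW = 3 * 8 + 3 * 2 + 2 + 1  # histograms + moments + gradients + texture

    def __init__(self, embed_dim: int = EMBED_DIM, seed: int = 1234):
        self.embed_dim = embed_dim
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((self.N_RAW, embed_dim)) / np.sqrt(self.N_RAW)

    def _raw_features(self, tile: np.ndarray) -> np.ndarray:
        img = np.asarray(tile, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("tiles must be RGB (H, W, 3)")
        if img.max() > 1.5:  # uint8 input
            img = img / 255.0
        feats: list[float] = []
        for c in range(3):
            ch = img[:, :, c]
            hist, _ = np.histogram(ch, bins=8, range=(0.0, 1.0))
            feats.extend(hist / ch.size)
        for c in range(3):
            ch = img[:, :, c]
            feats.extend([ch.mean(), ch.std()])
        gray = img.mean(axis=2)
        feats.append(float(np.square(np.diff(gray, axis=0)).mean()))
        feats.append(float(np.square(np.diff(gray, axis=1)).mean()))
        lap = gray[:-2, 1:-1] + gray[2:, 1:-1] + gray[1:-1, :-2] + gray[1:-1, 2:] - 4 * gray[1:-1, 1:-1]
        feats.append(float(np.square(lap).mean()) if lap.size else 0.0)
        return np.asarray(feats)

    def encode(self, tiles: Sequence[np.ndarray]) -> np.ndarray:
        raw = np.stack([self._raw_features(t) for t in tiles])
        return (raw @ self._proj).astype(np.float32)


def encode_tiles(
    tiles: Sequence[np.ndarray],
    boxes: Sequence[TileBox],
    encoder,
    case_id: str = "case",
    modality: str = "HE",
    scanner: str = "synthetic",
    site: str = "primary",
) -> EmbeddingBag:
    """Encode image tiles into an :class:`EmbeddingBag`, order preserved."""
    if len(tiles) != len(boxes):
        raise ValueError("tiles and boxes must align")
    if len(tiles) == 0:
        raise ValueError("cannot encode an empty tile list")
    shapes = {np.asarray(t).shape for t in tiles}
    if len(shapes) > 1:
        raise ValueError(f"tiles have inconsistent geometry: {shapes}")
    emb = np.asarray(encoder.encode(tiles))
    if emb.shape != (len(tiles), encoder.embed_dim):
        raise ValueError("encoder returned wrong output shape")
    box_arr = np.stack([b.as_array() for b in boxes])
    return EmbeddingBag(case_id, modality, emb, box_arr, scanner=scanner, site=site)


def save_bag(bag: EmbeddingBag, path, mode: str = "a") -> None:
    """Append one bag to an HDF5 file under ``/<case_id>/<modality>``."""
    with h5py.File(path, mode) as f:
        grp = f.require_group(bag.case_id).create_group(bag.modality)
        grp.create_dataset("embeddings", data=bag.embeddings.astype(np.float32))
        grp.create_dataset("tile_boxes", data=bag.tile_boxes.astype(np.int64))
        grp.attrs["scanner"] = bag.scanner
        grp.attrs["site"] = bag.site


def load_bag(path, case_id: str, modality: str) -> EmbeddingBag:
    """Load one bag; schema is validated (shapes, finiteness, non-emptiness)."""
    with h5py.File(path, "r") as f:
        key = f"{case_id}/{modality}"
        if key not in f:
            raise KeyError(f"no group {key!r} in {path}")
        grp = f[key]
        for ds in ("embeddings", "tile_boxes"):
            if ds not in grp:
                raise ValueError(f"group {key!r} missing dataset {ds!r}")
        emb = np.asarray(grp["embeddings"])
        boxes = np.asarray(grp["tile_boxes"])
        scanner = str(grp.attrs.get("scanner", "unknown"))
        site = str(grp.attrs.get("site", "unknown"))
    return EmbeddingBag(case_id, modality, emb, boxes, scanner=scanner, site=site)


def list_bags(path) -> list[tuple[str, str]]:
    """Enumerate (case_id, modality) pairs stored in an HDF5 bag file."""
    out: list[tuple[str, str]] = []
    with h5py.File(path, "r") as f:
        for cid in f:
            for mod in f[cid]:
                out.append((cid, mod))
    return out
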