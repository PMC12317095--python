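"""Deterministic seed fan-out: one master seed, independent per-stage streams."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tags) -> int:
    """Map (master seed, tag path) to a stable 31-bit seed.

    Hash-based so that streams for different stages/folds/epochs are
    statistically independent and adding a new stage never perturbs the
    draws of existing ones.
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
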