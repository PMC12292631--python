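"""Deterministic seed derivation.

Every stochastic stage derives its seed from a single top-level seed and a
stage name, so that a pipeline run is reproducible end to end while stages
remain statistically decoupled. The scheme is a SHA-256 hash of
``"{seed}:{name}"`` reduced modulo 2**31.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)
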