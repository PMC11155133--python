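"""Small shared helpers."""

from __future__ import annotations

import zlib

__all__ = ["stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from a master seed and stage name.

    Keeps every stochastic stage independently reproducible while threading a
    single user-facing seed through the pipeline. Result is < 2**31.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
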