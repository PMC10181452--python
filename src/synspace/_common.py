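"""Shared constants and helpers for the synergy-space decoding pipeline."""

from __future__ import annotations

import zlib

# Channel order is fixed everywhere: three shoulder orientation angles
# (internal-external rotation, flexion-extension, abduction-adduction)
# followed by the two forearm angles (pronation-supination, elbow
# flexion-extension).
CHANNELS: tuple[str, ...] = ("SH_x", "SH_y", "SH_z", "FA_x", "FA_y")
SHOULDER_IDX = slice(0, 3)
FOREARM_IDX = slice(3, 5)
N_CHANNELS = len(CHANNELS)

VELOCITY_CHANNELS: tuple[str, ...] = ("dSH_x", "dSH_y", "dSH_z")


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a stage seed from a master seed and a tuple of tokens.

    Stable across runs and platforms (CRC32 of the repr), and kept below
    2**31 so it is always a valid seed for NumPy generators.
    """
    payload = repr((int(master_seed),) + tuple(tokens)).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF
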