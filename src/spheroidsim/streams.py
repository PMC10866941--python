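"""Counter-based random streams for per-cell, per-cycle fate draws.

Fate decisions at mitosis are drawn from Philox streams keyed by
(simulation seed, cell id, cycle index, channel).  Two consequences:

* re-evaluating the same decision within one cell cycle (a space-blocked
  cell re-attempting mitosis) reuses the same uniforms, so the decision is
  idempotent within the cycle;
* each drug owns its own channel, so adding a second drug to a run never
  perturbs the realized draws of the first.  A combination run at dose
  (c, 0) is therefore bitwise identical to the monotherapy run at c.
"""

from __future__ import annotations

import zlib

import numpy as np

SPONTANEOUS_CHANNEL = 0
POLICY_CHANNEL = 1
_DRUG_CHANNEL_BASE = 16


def drug_channel(name: str) -> int:
    """Stable channel id for a drug, derived from its name only."""
    return _DRUG_CHANNEL_BASE + (zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF)


def keyed_generator(
    seed_root: int, cell_id: int, cycle_index: int, channel: int
) -> np.random.Generator:
    """Generator for one (cell, cycle, channel) decision stream."""
    # (cell_id, channel) both fit 32 bits, so word 1 is injective; word 0 is
    # injective in cycle_index via multiplication by an odd constant.
    w0 = (seed_root ^ (cycle_index * 0x9E3779B97F4A7C15)) & 0xFFFFFFFFFFFFFFFF
    w1 = ((cell_id & 0xFFFFFFFF) << 32) | (channel & 0xFFFFFFFF)
    return np.random.Generator(np.random.Philox(key=[np.uint64(w0), np.uint64(w1)]))
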