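"""Server-side central blocked randomization with variable block sizes.

Allocation proceeds per stratum: each stratum owns an independent
pending sequence built from uniformly shuffled blocks. A block contains
each arm exactly ``size / n_arms`` times, so within-stratum arm counts
can never diverge by the largest configured block size or more.
Variable block sizes (chosen uniformly per block) hide the block
boundaries from anyone observing the allocation stream.

Determinism contract: given the seed and the ordered sequence of
assignment requests per stratum, the emitted allocations are fully
reproducible. Stratum sub-streams are spawned independently from the
master seed, so traffic in one stratum never perturbs another.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import Stratum, TrialConfig
from .errors import ConfigError


def next_block(arms: list[str], block_sizes: list[int],
               rng: np.random.Generator) -> list[str]:
    """Produce one randomized block.

    The block size is drawn uniformly from ``block_sizes``; the block
    holds each arm exactly ``size / len(arms)`` times in uniformly
    shuffled order.
    """
    if not arms:
        raise ConfigError("arms must be non-empty")
    for size in block_sizes:
        if size <= 0 or size % len(arms) != 0:
            raise ConfigError(f"block size {size} is not a positive multiple of {len(arms)}")
    size = int(block_sizes[int(rng.integers(len(block_sizes)))])
    block = list(arms) * (size // len(arms))
    perm = rng.permutation(len(block))
    return [block[i] for i in perm]


@dataclass
class _StratumState:
    pending: deque = field(default_factory=deque)
    counts: Counter = field(default_factory=Counter)
    block_id: int = 0
    position: int = 0


@dataclass
class AuditEntry:
    """One line of the allocation audit log."""

    participant_id: str
    stratum: Stratum
    arm: str
    block_id: int
    position: int
    day: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps({
            "participant_id": self.participant_id, "stratum": list(self.stratum),
            "arm": self.arm, "block_id": self.block_id,
            "position": self.position, "day": self.day,
        })


class Allocator:
    """Central allocation service holding per-stratum state.

    Parameters
    ----------
    arms : ordered arm tags.
    block_sizes : positive multiples of the arm count.
    strata : the fixed stratum universe (a single empty tuple when the
        design is unstratified, as in the Australian profile).
    seed : master seed; each stratum's random sub-stream is spawned from
        it by stratum index so streams stay independent.
    """

    def __init__(self, arms: list[str], block_sizes: list[int],
                 strata: list[Stratum], seed: int):
        if not arms:
            raise ConfigError("arms must be non-empty")
        for size in block_sizes:
            if size <= 0 or size % len(arms) != 0:
                raise ConfigError(f"block size {size} is not a positive multiple of {len(arms)}")
        self.arms = list(arms)
        self.block_sizes = list(block_sizes)
        self._strata = {s: i for i, s in enumerate(strata)}
        root = np.random.SeedSequence(seed)
        children = root.spawn(len(strata))
        self._rngs = {s: np.random.default_rng(children[i]) for s, i in self._strata.items()}
        self._state: dict[Stratum, _StratumState] = {s: _StratumState() for s in strata}
        self.audit_log: list[AuditEntry] = []

    @classmethod
    def from_config(cls, config: TrialConfig, seed: int) -> "Allocator":
        return cls(config.arms, config.block_sizes, config.strata(), seed)

    def counts(self, stratum: Stratum) -> Counter:
        return Counter(self._state[stratum].counts)

    def assign(self, stratum: Stratum, participant_id: str = "",
               day: Optional[int] = None) -> str:
        """Pop the next allocation for ``stratum``, refilling as needed."""
        if stratum not in self._state:
            raise ConfigError(f"unknown stratum {stratum!r}")
        st = self._state[stratum]
        if not st.pending:
            st.pending.extend(next_block(self.arms, self.block_sizes, self._rngs[stratum]))
            st.block_id += 1
            st.position = 0
        arm = st.pending.popleft()
        st.position += 1
        st.counts[arm] += 1
        self.audit_log.append(AuditEntry(
            participant_id=participant_id, stratum=stratum, arm=arm,
            block_id=st.block_id, position=st.position, day=day,
        ))
        return arm

    def write_audit_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.audit_log:
                fh.write(entry.to_json() + "\n")
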