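"""Shared helpers: errors, seeded substreams, coordinate conventions.

Coordinate conventions are centralized here: site tables (counts, truth, ASB
sites) use 1-based positions; every interval file (BED/narrowPeak) is 0-based
half-open.
"""

from __future__ import annotations

import re
import zlib

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$")


class AsbqtlError(Exception):
    """Base class for user-facing errors (bad inputs, infeasible configs)."""


class ConfigError(AsbqtlError):
    pass


class InputError(AsbqtlError):
    pass


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named RNG substream derived from one root seed.

    Every stochastic stage draws from its own stream so that stages can be
    re-run in isolation with identical results.
    """
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def is_autosome(chrom: str) -> bool:
    return bool(_AUTOSOME_RE.match(chrom))


def pos_to_bed(pos: int) -> tuple[int, int]:
    """1-based site position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def bed_to_pos(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    return start + 1
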