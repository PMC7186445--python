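"""Seed fan-out.

A single global seed is expanded into independent per-stage streams by
hashing the stage name into a :class:`numpy.random.SeedSequence` spawn key,
so that reordering or skipping stages never silently reuses a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def _stage_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def stage_rng(global_seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Return a Generator for ``stage`` derived from ``global_seed``.

    ``extra`` integers (e.g. a patient index or repeat number) further key
    the stream.
    """
    ss = np.random.SeedSequence([int(global_seed), _stage_key(stage), *map(int, extra)])
    return np.random.default_rng(ss)


def stage_seed(global_seed: int, stage: str, *extra: int) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    ss = np.random.SeedSequence([int(global_seed), _stage_key(stage), *map(int, extra)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
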