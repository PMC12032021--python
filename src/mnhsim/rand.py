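"""Counter-based random streams for common-random-number (CRN) simulation.

Paired scenario runs must share randomness person-by-person and event-by-event,
otherwise paired differencing of rare outcomes (maternal death) carries the full
between-run Monte-Carlo variance and desk-scale comparisons are uninformative.
Each uniform is derived by hashing (seed, purpose, person id, timestep) through
splitmix64, so the same person facing the same decision at the same time draws
the same number in every scenario, regardless of execution order.
"""

from __future__ import annotations

import numpy as np

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
# 2^-64 for converting a uint64 to a uniform in [0, 1)
_INV = 1.0 / 18446744073709551616.0


def _mix(z: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """One splitmix64 finalisation round (vectorised over uint64 arrays)."""
    z = (z ^ (z >> np.uint64(30))) * _M1 & _MASK
    z = (z ^ (z >> np.uint64(27))) * _M2 & _MASK
    return z ^ (z >> np.uint64(31))


def _hash_parts(*parts: int | np.ndarray) -> np.ndarray | np.uint64:
    """Hash a sequence of integer keys (scalars or aligned arrays) to uint64."""
    with np.errstate(over="ignore"):
        h = np.uint64(0x243F6A8885A308D3)
        for p in parts:
            p = np.asarray(p, dtype=np.uint64) if not np.isscalar(p) else np.uint64(int(p) & 0xFFFFFFFFFFFFFFFF)
            h = _mix((h + _GOLDEN) & _MASK ^ p)
        return _mix(h)


def stream_key(name: str) -> int:
    """Stable 64-bit key for a named purpose stream."""
    h = 1469598103934665603  # FNV-1a offset basis
    for b in name.encode():
        h = ((h ^ b) * 1099511628211) & 0xFFFFFFFFFFFFFFFF
    return h


class RandomSource:
    """Keyed uniform generator for one simulation run.

    ``uniform(purpose, ids, t)`` is deterministic in (seed, purpose, ids, t):
    the CRN contract.  ``generator(purpose)`` returns an ordinary numpy
    Generator for draws where alignment across scenarios is irrelevant.
    """

    def __init__(self, seed: int):
        if not (0 <= int(seed) < 2**63):
            raise ValueError("seed must be a non-negative 63-bit integer")
        self.seed = int(seed)

    def uniform(self, purpose: str | int, ids, t: int):
        """Uniform(0,1) draws keyed by purpose, entity id(s) and timestep."""
        key = purpose if isinstance(purpose, int) else stream_key(purpose)
        with np.errstate(over="ignore"):
            raw = _hash_parts(self.seed, key, ids, t)
        out = np.asarray(raw, dtype=np.uint64).astype(np.float64) * _INV
        return float(out) if np.isscalar(ids) or np.ndim(ids) == 0 else out

    def bernoulli(self, p, purpose: str | int, ids, t: int):
        u = self.uniform(purpose, ids, t)
        return u < p

    def generator(self, purpose: str) -> np.random.Generator:
        """Independent numpy Generator for non-CRN bulk draws."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream_key(purpose) % 2**32,))
        )


class KeyedRng:
    """CRN uniform source scoped to one entity and timestep.

    ``draw(key)`` depends only on (seed, entity, t, key) — not on how many
    draws preceded it — so two scenario runs consume identical uniforms for
    identical decisions even when their event sequences diverge.
    """

    def __init__(self, source: RandomSource, entity_id: int, t: int, scope: str = ""):
        self._source = source
        self._entity = int(entity_id)
        self._t = int(t)
        self._scope = scope
        self._n = 0

    def draw(self, key: str) -> float:
        return self._source.uniform(self._scope + key, self._entity, self._t)

    def random(self) -> float:  # Generator-compatible fallback
        self._n += 1
        return self.draw(f"__seq__{self._n}")


class HashedStream:
    """Minimal Generator-compatible facade over one (purpose, id, t) key.

    Library operations take an ``rng`` exposing ``random()``; the engine
    hands them one of these so their draws stay CRN-aligned.  Successive calls
    advance an internal counter.
    """

    def __init__(self, source: RandomSource, purpose: str, entity_id: int, t: int):
        self._source = source
        self._key = (stream_key(purpose) ^ int(_hash_parts(entity_id, t))) & 0xFFFFFFFFFFFFFFFF
        self._n = 0

    def random(self) -> float:
        u = self._source.uniform(self._key, self._n, 0)
        self._n += 1
        return u
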