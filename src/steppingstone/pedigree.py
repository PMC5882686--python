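"""Pedigrees and the additive (numerator) relationship matrix.

The benchmark pedigree has discrete non-overlapping generations with random
mating: founders are unrelated, and every later individual draws a sire and a
dam uniformly (sire != dam) from the previous generation.  The relationship
matrix A is built by the standard tabular recursion

    A_ii = 1 + A_{s(i), d(i)} / 2
    A_ij = (A_{j, s(i)} + A_{j, d(i)}) / 2     for j earlier than i,

with unknown parents contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "simulate_pedigree", "relationship_matrix"]


@dataclass
class Pedigree:
    """(individual, sire, dam) triples; id 0 marks an unknown parent.

    Individuals are numbered 1..n and must appear after both of their parents,
    which the constructor verifies (this also rules out cycles).
    """

    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        n = self.sire.size
        ids = np.arange(1, n + 1)
        if np.any(self.sire >= ids) or np.any(self.dam >= ids):
            raise ValueError("parents must precede offspring (acyclic pedigree)")
        if np.any(self.sire < 0) or np.any(self.dam < 0):
            raise ValueError("parent ids must be 0 (unknown) or positive")

    @property
    def n(self) -> int:
        return int(self.sire.size)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "id": np.arange(1, self.n + 1),
                "sire": self.sire,
                "dam": self.dam,
                "generation": self.generation,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path).sort_values("id")
        return cls(
            sire=df["sire"].to_numpy(),
            dam=df["dam"].to_numpy(),
            generation=df["generation"].to_numpy(),
        )


def simulate_pedigree(
    n_per_gen: int = 50, n_gen: int = 4, seed: int | np.random.Generator = 0
) -> Pedigree:
    """Random-mating pedigree with unrelated founders in generation 1."""
    if n_per_gen < 2 or n_gen < 1:
        raise ValueError("need at least 2 individuals per generation and 1 generation")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sire = [0] * n_per_gen
    dam = [0] * n_per_gen
    gen = [1] * n_per_gen
    for g in range(2, n_gen + 1):
        prev = np.arange((g - 2) * n_per_gen + 1, (g - 1) * n_per_gen + 1)
        for _ in range(n_per_gen):
            s, d = rng.choice(prev, size=2, replace=False)
            sire.append(int(s))
            dam.append(int(d))
            gen.append(g)
    return Pedigree(sire=np.array(sire), dam=np.array(dam), generation=np.array(gen))


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix A via the tabular recursion."""
    n = ped.n
    A = np.zeros((n, n))
    s = ped.sire - 1  # -1 encodes unknown
    d = ped.dam - 1
    for i in range(n):
        si, di = s[i], d[i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        for j in range(i):
            aij = 0.0
            if si >= 0:
                aij += 0.5 * A[j, si]
            if di >= 0:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
    return A
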