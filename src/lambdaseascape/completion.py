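"""Per-trial completion of a partial fitness landscape.

Each simulation trial gets its own complete landscape, built in two steps:

1. *Replicate bootstrap*: for each measured genotype with ``n`` replicate
   selection rates, resample ``n`` values with replacement and take their
   mean (a genotype with one replicate always keeps that value).  This
   propagates measurement error into the simulations.
2. *Random-order nearest-neighbor imputation*: repeatedly pick, uniformly at
   random, a missing genotype that currently has at least one non-missing
   one-mutation neighbor, and assign it the mean of its non-missing neighbors
   (measured or previously imputed).  Iterate until the hypercube is full.
   The fill order changes the imputed values from trial to trial — an
   intentional extra source of variation reflecting imputation uncertainty.

Restricting the pick to genotypes with a known neighbor keeps the update
well defined; since the hypercube is connected, completion always terminates
in at most ``2**L`` assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import FitnessLandscape
from .genotypes import neighbor_matrix, to_string

__all__ = ["CompleteLandscape", "bootstrap_measured", "impute_missing", "complete_landscape"]


@dataclass
class CompleteLandscape:
    """A gap-free fitness assignment over all ``2**L`` genotypes."""

    host: str
    L: int
    values: np.ndarray  # (2**L,) selection rate per assay
    imputed: np.ndarray  # (2**L,) bool, True where the value was imputed
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": [to_string(g, self.L) for g in range(2**self.L)],
                "fitness": self.values,
                "provenance": np.where(self.imputed, "imputed", "measured"),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.insert(0, "host", self.host)
        frame.to_csv(path, index=False, float_format="%.10g")


def bootstrap_measured(
    landscape: FitnessLandscape, rng: np.random.Generator
) -> dict[int, float]:
    """One bootstrap draw per measured genotype: mean of ``n_i`` resamples
    (with replacement) of its ``n_i`` replicate selection rates."""
    out = {}
    for g in landscape.genotypes:
        reps = landscape.records[g]
        if len(reps) == 1:
            out[g] = float(reps[0])
        else:
            out[g] = float(rng.choice(reps, size=len(reps), replace=True).mean())
    return out


def impute_missing(
    measured: dict[int, float],
    L: int,
    rng: np.random.Generator,
    host: str = "unknown",
) -> CompleteLandscape:
    """Fill the hypercube by random-order nearest-neighbor means."""
    if not measured:
        raise ValueError("cannot impute with no measured genotypes")
    size = 2**L
    values = np.full(size, np.nan)
    for g, v in measured.items():
        values[g] = v
    imputed = np.isnan(values)
    nbrs = neighbor_matrix(L)
    known = ~np.isnan(values)
    missing = np.nonzero(~known)[0]
    while missing.size:
        has_known_nbr = known[nbrs[missing]].any(axis=1)
        candidates = missing[has_known_nbr]
        pick = candidates[rng.integers(candidates.size)]
        nbr_vals = values[nbrs[pick]]
        values[pick] = np.nanmean(nbr_vals)
        known[pick] = True
        missing = missing[missing != pick]
    return CompleteLandscape(host=host, L=L, values=values, imputed=imputed)


def complete_landscape(
    landscape: FitnessLandscape, seed: int | np.random.Generator
) -> CompleteLandscape:
    """Bootstrap + impute one trial-ready landscape."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot = bootstrap_measured(landscape, rng)
    out = impute_missing(boot, landscape.L, rng, host=landscape.host)
    out.seed = None if isinstance(seed, np.random.Generator) else int(seed)
    return out
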