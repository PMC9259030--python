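"""Modified Wright-Fisher evolution of the phage on shifting landscapes.

Each generation, reproduction is a single multinomial draw of ``N`` offspring
with success probabilities ``p_i = n_i w_i / sum_j n_j w_j`` where
``w_i = exp(s_i)`` is the fitness weight from the active landscape.  Mutation
then acts only on the *increment*: for every genotype whose count increased
(``z_i = k_i - n_i > 0``), each of the ``z_i`` new individuals keeps its
parent's genotype with probability ``exp(-mu)`` and otherwise jumps to a
uniformly random one-mutation neighbor (multiple simultaneous mutations are
ignored; back-mutations are allowed).

This increment-only rule is non-standard and is implemented exactly as
stated.  A provable consequence: a monomorphic population is an absorbing
state (the multinomial with a degenerate ``p`` returns ``k = n``, so ``z = 0``
and no mutant ever appears).  Simulations that must escape the unmutated
ancestor therefore use ``mutate_all_offspring=True``, which exposes all ``k_i``
offspring of every genotype to mutation instead; see the methods note.

Host switching moves the population from the ancestral-host landscape to the
malT- landscape after a configured fraction of the generations, carrying
genotype counts over unchanged.  A run is scored OmpF+ (the receptor
innovation) as soon as any genotype satisfying the '3+1' rule reaches the
detection threshold; the flag latches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .completion import CompleteLandscape, complete_landscape
from .fitness import FitnessLandscape
from .genotypes import MutationCatalog, neighbor_matrix, ompf_plus_mask

__all__ = [
    "SimulationConfig",
    "TrialRecord",
    "TreatmentResult",
    "fitness_weights",
    "wf_step",
    "run_trial",
    "run_treatments",
    "compare_treatments",
    "replicate_null_probability",
    "DEFAULT_SWITCH_FRACTIONS",
]

DEFAULT_SWITCH_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: N ~ 6.3e9 phage particles, 960 generations
    (two doublings per hour for 20 days), per-base mutation rate 7.7e-8 per
    replication summed over the L focal sites, detection threshold 5000
    particles, 300 trials per treatment batched by 30."""

    N: int = 6_300_000_000
    generations: int = 960
    mu_base: float = 7.7e-8
    L: int = 10
    detection_threshold: int = 5000
    switch_fractions: tuple[float, ...] = DEFAULT_SWITCH_FRACTIONS
    trials: int = 300
    batch_size: int = 30
    mutate_all_offspring: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.N, self.generations, self.trials, self.batch_size) <= 0:
            raise ValueError("N, generations, trials, batch_size must be positive")
        if self.detection_threshold > self.N:
            raise ValueError("detection threshold exceeds population size")
        if self.trials % self.batch_size:
            raise ValueError("trials must be divisible by batch_size")

    @property
    def mu(self) -> float:
        """Total per-replication mutation probability over the focal sites."""
        return self.L * self.mu_base

    @property
    def mutation_probability(self) -> float:
        """Per-individual per-generation probability 1 - exp(-mu)."""
        return -np.expm1(-self.mu)


def fitness_weights(landscape: CompleteLandscape | np.ndarray) -> np.ndarray:
    """w_i = exp(s_i), s in per-assay units as stored."""
    values = landscape.values if isinstance(landscape, CompleteLandscape) else landscape
    return np.exp(np.asarray(values, dtype=float))


def wf_step(
    counts: np.ndarray,
    weights: np.ndarray,
    mutation_probability: float,
    rng: np.random.Generator,
    neighbors: np.ndarray,
    mutate_all_offspring: bool = False,
) -> np.ndarray:
    """One generation: multinomial reproduction, then increment mutation.

    ``counts`` is the integer genotype census (sums to N), ``weights`` the
    positive fitness weights, ``neighbors`` the (2**L, L) neighbor index
    matrix.  Population size is conserved exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(weights <= 0):
        raise ValueError("fitness weights must be positive")
    N = int(counts.sum())
    p = counts * weights
    p = p / p.sum()
    k = rng.multinomial(N, p).astype(np.int64)
    if mutation_probability > 0:
        z = k.copy() if mutate_all_offspring else k - counts
        src = np.nonzero(z > 0)[0]
        if src.size:
            n_mut = rng.binomial(z[src], mutation_probability)
            for i, nm in zip(src[n_mut > 0], n_mut[n_mut > 0]):
                dest = rng.multinomial(nm, np.full(neighbors.shape[1],
                                                   1.0 / neighbors.shape[1]))
                k[i] -= nm
                np.add.at(k, neighbors[i], dest)
    assert k.sum() == N, "population size not conserved"
    return k


@dataclass
class TrialRecord:
    ompf: bool
    detection_generation: int | None
    final_counts: np.ndarray


def run_trial(
    anc: CompleteLandscape | np.ndarray,
    malt: CompleteLandscape | np.ndarray,
    switch_fraction: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    catalog: MutationCatalog,
    initial_counts: np.ndarray | None = None,
) -> TrialRecord:
    """One evolution run with a host switch after ``switch_fraction`` of the
    generations on the ancestral-host landscape (1.0 = ancestral only,
    0.0 = malT- only).  The population starts monomorphic for the unmutated
    ancestor unless ``initial_counts`` is given.  Detection is checked at
    initialization and after every generation; the OmpF+ flag latches."""
    w_anc, w_malt = fitness_weights(anc), fitness_weights(malt)
    nbrs = neighbor_matrix(config.L)
    ompf = ompf_plus_mask(catalog)
    switch_gen = int(np.floor(switch_fraction * config.generations + 0.5))
    if initial_counts is None:
        counts = np.zeros(2**config.L, dtype=np.int64)
        counts[0] = config.N
    else:
        counts = np.asarray(initial_counts, dtype=np.int64).copy()
        if counts.sum() != config.N:
            raise ValueError("initial counts must sum to N")
    detected_at: int | None = None
    if counts[ompf].max(initial=0) >= config.detection_threshold:
        detected_at = 0
    pmut = config.mutation_probability
    for gen in range(config.generations):
        w = w_anc if gen < switch_gen else w_malt
        counts = wf_step(counts, w, pmut, rng, nbrs, config.mutate_all_offspring)
        if detected_at is None and counts[ompf].max(initial=0) >= config.detection_threshold:
            detected_at = gen + 1
    return TrialRecord(
        ompf=detected_at is not None,
        detection_generation=detected_at,
        final_counts=counts,
    )


@dataclass
class TreatmentResult:
    label: str
    switch_fraction: float
    flags: np.ndarray  # per-trial OmpF+ booleans
    detection_generations: list[int | None]
    batch_size: int

    @property
    def frequency(self) -> float:
        return float(self.flags.mean())

    @property
    def batch_frequencies(self) -> np.ndarray:
        return self.flags.reshape(-1, self.batch_size).mean(axis=1)

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Student-t CI on the batch frequencies (df = n_batches - 1)."""
        b = self.batch_frequencies
        if b.size < 2:
            return (float("nan"), float("nan"))
        half = stats.t.ppf(0.5 + level / 2, b.size - 1) * b.std(ddof=1) / np.sqrt(b.size)
        return (float(b.mean() - half), float(b.mean() + half))


def treatment_schedule(config: SimulationConfig) -> list[tuple[str, float]]:
    """The 11 coevolution treatments: single-host baselines plus the nine
    switch fractions."""
    sched = [("ancestral_only", 1.0)]
    sched += [(f"switch_{f:.1f}", f) for f in config.switch_fractions]
    sched.append(("malt_only", 0.0))
    return sched


def run_treatments(
    anc: FitnessLandscape,
    malt: FitnessLandscape,
    config: SimulationConfig,
    catalog: MutationCatalog,
    schedule: list[tuple[str, float]] | None = None,
) -> list[TreatmentResult]:
    """Run every treatment; each trial regenerates both landscapes by
    replicate bootstrap + random-order imputation from its own substream
    (master seed -> (treatment index, trial index) counters)."""
    schedule = schedule if schedule is not None else treatment_schedule(config)
    results = []
    for ti, (label, frac) in enumerate(schedule):
        flags = np.zeros(config.trials, dtype=bool)
        gens: list[int | None] = []
        for trial in range(config.trials):
            rng = np.random.default_rng([config.seed, ti, trial])
            anc_c = complete_landscape(anc, rng)
            malt_c = complete_landscape(malt, rng)
            rec = run_trial(anc_c, malt_c, frac, config, rng, catalog)
            flags[trial] = rec.ompf
            gens.append(rec.detection_generation)
        results.append(
            TreatmentResult(
                label=label,
                switch_fraction=frac,
                flags=flags,
                detection_generations=gens,
                batch_size=config.batch_size,
            )
        )
    return results


def summarize_treatments(results: list[TreatmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.confidence_interval()
        rows.append(
            {
                "treatment": r.label,
                "switch_fraction": r.switch_fraction,
                "trials": r.flags.size,
                "frequency": r.frequency,
                "batch_mean": float(r.batch_frequencies.mean()),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def compare_treatments(
    results: list[TreatmentResult],
) -> tuple[dict, pd.DataFrame]:
    """One-way ANOVA on batch frequencies (units = batches) plus Tukey HSD.

    Returns ``(anova, tukey)`` where ``anova`` has F, p and degrees of
    freedom (marked degenerate when every group has zero within-batch
    variance), and ``tukey`` lists pairwise adjusted p-values.
    """
    if len(results) < 2:
        raise ValueError("need at least two treatments to compare")
    groups = [r.batch_frequencies for r in results]
    sizes = {g.size for g in groups}
    if len(sizes) != 1:
        raise ValueError("treatments must have equal batch counts")
    nb = groups[0].size
    k = len(groups)
    degenerate = all(np.allclose(g, g[0]) for g in groups)
    if degenerate and all(np.isclose(g.mean(), groups[0].mean()) for g in groups):
        anova = {"F": 0.0, "p": 1.0, "df_between": k - 1, "df_within": k * (nb - 1),
                 "degenerate": True}
    elif degenerate:
        anova = {"F": float("inf"), "p": 0.0, "df_between": k - 1,
                 "df_within": k * (nb - 1), "degenerate": True}
    else:
        f, p = stats.f_oneway(*groups)
        anova = {"F": float(f), "p": float(p), "df_between": k - 1,
                 "df_within": k * (nb - 1), "degenerate": False}
    rows = []
    if not degenerate:
        hsd = stats.tukey_hsd(*groups)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "treatment_a": results[i].label,
                        "treatment_b": results[j].label,
                        "mean_diff": float(groups[i].mean() - groups[j].mean()),
                        "p_adj": float(hsd.pvalue[i, j]),
                    }
                )
    tukey = pd.DataFrame(rows, columns=["treatment_a", "treatment_b", "mean_diff", "p_adj"])
    return anova, tukey


def replicate_null_probability(p_success: float, n_replicates: int, k: int) -> float:
    """Exact binomial point probability C(n,k) p^k (1-p)^(n-k).

    E.g. with a true OmpF+ success rate of 0.25 per replay population, the
    probability that none of 12 replicates evolves the innovation is
    0.75**12 ~ 0.03167.
    """
    if not (0 <= p_success <= 1):
        raise ValueError("p_success must be in [0, 1]")
    if not (0 <= k <= n_replicates):
        raise ValueError("k must be in 0..n_replicates")
    return float(stats.binom.pmf(k, n_replicates, p_success))
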