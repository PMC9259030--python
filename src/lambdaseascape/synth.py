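"""Synthetic MAGE-seq competition experiments with known ground truth.

Emulates the statistical structure of a one-pot bulk competition of a
combinatorial phage genome library against its ancestor, replicated on two
host genotypes:

* a ground-truth pair of fitness landscapes drawn from the additive /
  pairwise-epistatic / host-interaction linear model used downstream,
* an uneven, partially missing library composition (the randomness of the
  MAGE editing process),
* deterministic exponential growth over the assay at genotype-specific
  Malthusian rates, with per-replicate growth noise,
* multinomial amplicon sequencing at a configured depth with two independent
  PCR barcodes per sample, and
* optional FASTQ emission with i.i.d. per-base substitution error.

The non-amplifiable 1:9 ancestral spike of the real assay is modeled
implicitly: its primer site is disrupted, so it never appears in count tables;
the sequencing-visible reference is the library's own wild-type genotype.
Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MutationCatalog, enumerate_genotypes, to_string

__all__ = [
    "TrueLandscapeSpec",
    "LibraryCompositionSpec",
    "SequencingSpec",
    "sample_true_landscape",
    "simulate_library",
    "simulate_competition_counts",
    "simulate_experiment",
    "emit_reads",
    "COUNT_COLUMNS",
]

COUNT_COLUMNS = ["sample", "barcode", "timepoint", "genotype", "variant", "count"]

HOSTS = ("ancestral", "malT_minus")


@dataclass(frozen=True)
class TrueLandscapeSpec:
    """Effect-size scales (selection-rate units per assay) for the generating
    linear model.  ``host_main_shift`` is the host indicator's main effect;
    it defaults to 0 so that the wild type has selection rate 0 on both hosts
    (rates are defined relative to the same-host wild type).
    ``watermark_effects`` optionally gives each locus's variant-2 watermark a
    fitness side effect, for neutrality-test power studies."""

    main_effect_sd: float = 0.5
    pairwise_effect_sd: float = 0.15
    host_main_shift: float = 0.0
    host_by_main_sd: float = 0.5
    host_by_pair_sd: float = 0.15
    measurement_noise_sd: float = 0.1
    watermark_effects: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("main_effect_sd", "pairwise_effect_sd", "host_by_main_sd",
                     "host_by_pair_sd", "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LibraryCompositionSpec:
    lognormal_sigma: float = 1.5
    missing_fraction: float = 0.345  # the study engineered 671 of 1024 genotypes
    reference_spike_ratio: float = 1 / 9  # library : ancestor, non-amplifiable

    def __post_init__(self) -> None:
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.reference_spike_ratio <= 0:
            raise ValueError("reference_spike_ratio must be positive")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


@dataclass(frozen=True)
class SequencingSpec:
    reads_per_sample: int = 100_000
    per_base_error: float = 1e-3
    barcodes_per_sample: int = 2
    replicates_per_host: int = 4
    assay_duration_T: float = 4.0  # hours

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not (0 <= self.per_base_error < 1):
            raise ValueError("per_base_error must be in [0, 1)")


def _design_columns(L: int, genotypes: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Indicator columns G_i and G_iG_j (i<j) for the generating model."""
    bits = ((genotypes[:, None] >> np.arange(L)) & 1).astype(float)
    names = [f"G{i + 1}" for i in range(L)]
    cols = [bits[:, i] for i in range(L)]
    for i in range(L):
        for j in range(i + 1, L):
            names.append(f"G{i + 1}:G{j + 1}")
            cols.append(bits[:, i] * bits[:, j])
    return names, np.column_stack(cols)


def sample_true_landscape(
    spec: TrueLandscapeSpec, catalog: MutationCatalog
) -> tuple[dict[str, np.ndarray], pd.Series]:
    """Draw a ground-truth landscape pair from the G/GxG/E/GxE/GxGxE model.

    Returns ``({"ancestral": s, "malT_minus": s}, coefficients)`` where each
    ``s`` is the true per-assay selection rate for all ``2**L`` genotypes in
    canonical order and ``coefficients`` is the generating coefficient set
    named like the regression design columns (``G1``, ``G1:G2``, ``E``,
    ``G1:E``, ``G1:G2:E``).
    """
    rng = np.random.default_rng(spec.seed)
    L = catalog.L
    genotypes = enumerate_genotypes(L)
    names, X = _design_columns(L, genotypes)
    n_main, n_pair = L, L * (L - 1) // 2
    beta_g = np.concatenate([
        rng.normal(0.0, spec.main_effect_sd, n_main),
        rng.normal(0.0, spec.pairwise_effect_sd, n_pair),
    ])
    beta_e = np.concatenate([
        rng.normal(0.0, spec.host_by_main_sd, n_main),
        rng.normal(0.0, spec.host_by_pair_sd, n_pair),
    ])
    s_anc = X @ beta_g
    s_malt = s_anc + spec.host_main_shift + X @ beta_e
    coeffs = pd.Series(
        np.concatenate([beta_g, [spec.host_main_shift], beta_e]),
        index=names + ["E"] + [f"{n}:E" for n in names],
        name="beta",
    )
    return {"ancestral": s_anc, "malT_minus": s_malt}, coeffs


def landscape_from_coefficients(coeffs: pd.Series, L: int) -> dict[str, np.ndarray]:
    """Rebuild the true landscape pair from a generating coefficient set
    (self-consistency check for :func:`sample_true_landscape`)."""
    genotypes = enumerate_genotypes(L)
    names, X = _design_columns(L, genotypes)
    beta_g = coeffs[names].to_numpy()
    beta_e = coeffs[[f"{n}:E" for n in names]].to_numpy()
    s_anc = X @ beta_g
    return {"ancestral": s_anc, "malT_minus": s_anc + coeffs["E"] + X @ beta_e}


def simulate_library(
    spec: LibraryCompositionSpec, catalog: MutationCatalog, seed: int
) -> pd.DataFrame:
    """Initial library composition at the watermark-variant level.

    Returns a frame with columns ``genotype`` (int bitmask), ``variant``
    (the watermark option carried at each mutant locus, in locus order: the
    two sub-libraries are ``"11..1"`` and ``"22..2"``; ``""`` for the wild
    type) and ``frequency`` (sums to 1).
    The wild type is always present: it is the sequencing-visible reference.
    A ``missing_fraction`` of the other genotypes never gets constructed.
    """
    rng = np.random.default_rng(seed)
    genotypes = enumerate_genotypes(catalog.L)
    present = rng.random(genotypes.size) >= spec.missing_fraction
    present[0] = True
    weights = (
        np.ones(genotypes.size)
        if spec.lognormal_sigma == 0
        else rng.lognormal(0.0, spec.lognormal_sigma, genotypes.size)
    )
    weights = np.where(present, weights, 0.0)
    freqs = weights / weights.sum()
    rows = []
    for g, f in zip(genotypes, freqs):
        if f == 0:
            continue
        if g == 0:
            rows.append((int(g), "", f))
        else:  # 50/50 split across the two watermark sub-libraries
            k = int(g).bit_count()
            rows.append((int(g), "1" * k, f / 2))
            rows.append((int(g), "2" * k, f / 2))
    return pd.DataFrame(rows, columns=["genotype", "variant", "frequency"])


def _variant_rates(
    library: pd.DataFrame,
    true_s: np.ndarray,
    watermark_effects: np.ndarray | None,
    L: int,
) -> np.ndarray:
    """Per library row, the true per-assay rate including any variant-2
    watermark side effect summed over that genome's mutant loci."""
    rates = true_s[library["genotype"].to_numpy()]
    if watermark_effects is not None:
        eff = np.asarray(watermark_effects, dtype=float)
        extra = np.zeros(len(library))
        for row_i, (g, v) in enumerate(zip(library["genotype"], library["variant"])):
            loci = [i for i in range(L) if (int(g) >> i) & 1]
            extra[row_i] = sum(
                eff[loc] for loc, opt in zip(loci, v) if opt == "2"
            )
        rates = rates + extra
    return rates


def simulate_competition_counts(
    true_s: np.ndarray,
    library: pd.DataFrame,
    seq: SequencingSpec,
    seed: int,
    *,
    measurement_noise_sd: float = 0.0,
    watermark_effects: np.ndarray | None = None,
    L: int | None = None,
) -> pd.DataFrame:
    """Sequence-count tables for one host's replicated bulk competitions.

    Growth is deterministic exponential over the assay: the expected final
    frequency of library member ``i`` is proportional to
    ``f_i(0) * exp(s_i)`` with ``s`` in per-assay units (any common ancestral
    growth factor cancels in the normalization).  Counts at each timepoint are
    drawn multinomially at ``reads_per_sample`` once per PCR barcode.

    Returns a long frame with columns
    ``sample, barcode, timepoint, genotype, variant, count`` where
    ``sample`` is ``"rep1"``.. and ``timepoint`` is ``"t0"`` or ``"tT"``;
    zero-count rows are omitted.
    """
    if library.empty:
        raise ValueError("empty library: nothing to compete")
    if L is None:
        L = int(library["genotype"].max()).bit_length()
    rng = np.random.default_rng(seed)
    f0 = library["frequency"].to_numpy()
    f0 = f0 / f0.sum()
    base_rates = _variant_rates(library, true_s, watermark_effects, L)
    frames = []
    for r in range(1, seq.replicates_per_host + 1):
        noise = (
            rng.normal(0.0, measurement_noise_sd, f0.size)
            if measurement_noise_sd > 0
            else 0.0
        )
        fT = f0 * np.exp(base_rates + noise)
        fT = fT / fT.sum()
        for b in range(1, seq.barcodes_per_sample + 1):
            for tp, f in (("t0", f0), ("tT", fT)):
                counts = rng.multinomial(seq.reads_per_sample, f)
                keep = counts > 0
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": f"rep{r}",
                            "barcode": b,
                            "timepoint": tp,
                            "genotype": library["genotype"].to_numpy()[keep],
                            "variant": library["variant"].to_numpy()[keep],
                            "count": counts[keep],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def simulate_experiment(
    landscape_spec: TrueLandscapeSpec,
    library_spec: LibraryCompositionSpec,
    seq: SequencingSpec,
    catalog: MutationCatalog,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], dict[str, np.ndarray], pd.Series, pd.DataFrame]:
    """Full two-host synthetic experiment.

    Returns ``(counts_by_host, true_landscapes, coefficients, library)``.
    """
    truth, coeffs = sample_true_landscape(landscape_spec, catalog)
    library = simulate_library(library_spec, catalog, seed)
    wm = landscape_spec.watermark_effects
    counts = {
        host: simulate_competition_counts(
            truth[host],
            library,
            seq,
            seed + 1 + i,
            measurement_noise_sd=landscape_spec.measurement_noise_sd,
            watermark_effects=None if wm is None else np.asarray(wm),
            L=catalog.L,
        )
        for i, host in enumerate(HOSTS)
    }
    return counts, truth, coeffs, library


def funnel_landscape_pair(
    catalog: MutationCatalog,
    *,
    nontrio_benefit_host1: float = 0.25,
    trio_cost_host1: float = 0.7,
    trio_benefit_host2: float = 1.0,
    nontrio_cost_host2: float = 0.5,
):
    """A stylized landscape pair where the path to the OmpF innovation opens
    only under host switching.

    On host 1 (ancestral-like) each non-trio mutation is beneficial and each
    OmpF-required trio mutation is deleterious; on host 2 (resistant-like)
    the trio is strongly beneficial and non-trio mutations are costly.  A
    population evolving on host 1 accumulates non-trio background, and only
    after the switch can it ascend through the trio — passing through
    trio-plus-background genotypes that satisfy the '3+1' rule.  Evolving on
    either single host never favors that combination.

    Returns ``(host1, host2)`` as complete single-replicate
    :class:`~lambdaseascape.fitness.FitnessLandscape` objects (so replicate
    bootstrap and imputation are identity operations).
    """
    from .fitness import FitnessLandscape
    from .genotypes import popcount

    L = catalog.L
    g = enumerate_genotypes(L)
    req = catalog.required_mask
    n_trio = np.asarray(popcount(g & req))
    n_nontrio = np.asarray(popcount(g & ~np.int64(req) & np.int64(2**L - 1)))
    s1 = nontrio_benefit_host1 * n_nontrio - trio_cost_host1 * n_trio
    s2 = trio_benefit_host2 * n_trio - nontrio_cost_host2 * n_nontrio
    mk = lambda vals, host: FitnessLandscape(
        host=host, L=L,
        records={int(gi): np.array([float(v)]) for gi, v in zip(g, vals)},
    )
    return mk(s1, "ancestral"), mk(s2, "malT_minus")


# --- read emission --------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def genotype_sequence(genotype: int, variant: str, catalog: MutationCatalog) -> str:
    """Amplicon sequence of a library genome: focal mutations applied at each
    mutant locus together with that locus's chosen watermark option.

    ``variant`` lists the option ("1"/"2") per mutant locus in locus order,
    as produced by :func:`simulate_library` and the read caller."""
    seq = list(catalog.amplicon_reference)
    j = 0
    for m in catalog.loci:
        if (genotype >> m.locus_index) & 1:
            seq[catalog.to_amplicon_index(m.genome_position)] = m.mut_base
            option = variant[j] if j < len(variant) else "1"
            wm = m.watermarks[1 if option == "2" else 0]
            seq[catalog.to_amplicon_index(wm.genome_position)] = wm.mut_base
            j += 1
    return "".join(seq)


def _apply_errors(seqs: np.ndarray, error: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitution errors on a (n_reads, length) byte array."""
    if error <= 0:
        return seqs
    hits = rng.random(seqs.shape) < error
    n = int(hits.sum())
    if n:
        # substitute with a uniformly random *different* base
        idx = np.nonzero(hits)
        shift = rng.integers(1, 4, n)
        current = np.searchsorted(_BASES.view(np.uint8), seqs[idx].view(np.uint8))
        seqs[idx] = _BASES[(current + shift) % 4]
    return seqs


def emit_reads(
    counts: pd.DataFrame,
    catalog: MutationCatalog,
    seq_spec: SequencingSpec,
    seed: int,
    outdir: str | Path,
    *,
    prefix: str = "sample",
    paired: bool = False,
) -> pd.DataFrame:
    """Write FASTQ files (one per sample/barcode/timepoint) for a count table.

    Each read is the genotype's amplicon sequence with i.i.d. substitution
    error applied; quality is constant Phred 33 'I'.  In paired mode the
    forward read covers the first half of the amplicon and the reverse read
    is the reverse complement of the second half (concatenation layout).

    Returns the sample sheet as a DataFrame (also written to
    ``<outdir>/<prefix>_samples.csv``) with columns
    ``file, file2, sample, barcode, timepoint``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    amp_len = len(catalog.amplicon_reference)
    half = amp_len // 2
    sheet_rows = []
    for (sample, barcode, tp), grp in counts.groupby(
        ["sample", "barcode", "timepoint"], sort=True
    ):
        stem = f"{prefix}_{sample}_bc{barcode}_{tp}"
        reads = []
        for _, row in grp.iterrows():
            n = int(row["count"])
            if n == 0:
                continue
            template = np.frombuffer(
                genotype_sequence(int(row["genotype"]), row["variant"], catalog).encode(),
                dtype="S1",
            )
            block = np.tile(template, (n, 1))
            reads.append(_apply_errors(block, seq_spec.per_base_error, rng))
        block = np.concatenate(reads) if reads else np.empty((0, amp_len), dtype="S1")
        qual = "I" * amp_len
        if paired:
            f1, f2 = outdir / f"{stem}_R1.fastq", outdir / f"{stem}_R2.fastq"
            with open(f1, "w") as h1, open(f2, "w") as h2:
                for i, arr in enumerate(block):
                    s = arr.tobytes().decode()
                    name = f"{prefix}|{sample}|bc{barcode}|{tp}|{i}"
                    h1.write(f"@{name}/1\n{s[:half]}\n+\n{qual[:half]}\n")
                    rc = s[half:].translate(_COMPLEMENT)[::-1]
                    h2.write(f"@{name}/2\n{rc}\n+\n{qual[half:]}\n")
            sheet_rows.append((str(f1), str(f2), sample, barcode, tp))
        else:
            f1 = outdir / f"{stem}.fastq"
            with open(f1, "w") as h1:
                for i, arr in enumerate(block):
                    s = arr.tobytes().decode()
                    h1.write(f"@{prefix}|{sample}|bc{barcode}|{tp}|{i}\n{s}\n+\n{qual}\n")
            sheet_rows.append((str(f1), "", sample, barcode, tp))
    sheet = pd.DataFrame(
        sheet_rows, columns=["file", "file2", "sample", "barcode", "timepoint"]
    )
    sheet.to_csv(outdir / f"{prefix}_samples.csv", index=False)
    return sheet
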