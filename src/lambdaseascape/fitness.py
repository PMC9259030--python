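"""Selection-rate estimation from competition count tables.

Fitness is quantified as the selection rate ``s``: the difference of
Malthusian (log-growth) parameters between a genotype and the reference
competitor over the assay,

    s = [ln(X_T / X_0) - ln(Y_T / Y_0)] / T,

reported per assay period by convention (``per_assay=True`` leaves out the
division by ``T``).  Because both competitors are measured in the same
sequencing sample, totals cancel: counts, frequencies and densities give the
identical ``s``.  The sequencing-visible reference is the library's wild-type
genotype (the 1:9 ancestral spike is non-amplifiable by design).

Genotypes falling below the detection threshold at either timepoint of a
replicate contribute no value for that replicate — no pseudocounts are added;
genotypes with no usable replicate are absent from the landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counts import barcode_mean
from .genotypes import from_string, to_string

__all__ = [
    "selection_rate",
    "merge_watermark_variants",
    "FitnessLandscape",
    "landscape_from_counts",
    "variant_selection_rates",
    "watermark_neutrality_test",
]


def selection_rate(
    x0: float, xT: float, y0: float, yT: float, T: float = 1.0, per_assay: bool = True
) -> float:
    """Difference of Malthusian parameters of X (focal) vs Y (reference)."""
    if min(x0, xT, y0, yT) <= 0:
        raise ValueError("selection_rate requires positive abundances at both timepoints")
    s = math.log(xT / x0) - math.log(yT / y0)
    return s if per_assay else s / T


def merge_watermark_variants(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over watermark variants per focal genotype."""
    if counts.empty:
        return counts.drop(columns=["variant"], errors="ignore")
    keys = [c for c in ["sample", "barcode", "timepoint", "genotype"] if c in counts]
    return counts.groupby(keys, as_index=False)["count"].sum()


@dataclass
class FitnessLandscape:
    """Per-host map genotype -> replicate selection rates (may be partial).

    ``records`` maps the genotype bitmask to a float array of per-replicate
    selection rates (per assay period ``T``).  The reference genotype carries
    ``s = 0`` in every replicate by construction.
    """

    host: str
    L: int
    T: float = 4.0
    reference: int = 0
    records: dict[int, np.ndarray] = field(default_factory=dict)

    def mean(self, genotype: int) -> float:
        return float(np.mean(self.records[genotype]))

    @property
    def genotypes(self) -> list[int]:
        return sorted(self.records)

    def means(self) -> pd.Series:
        return pd.Series(
            {g: self.mean(g) for g in self.genotypes}, name="mean_s"
        ).sort_index()

    def n_replicates(self, genotype: int) -> int:
        return len(self.records[genotype])

    def to_frame(self) -> pd.DataFrame:
        max_rep = max((len(v) for v in self.records.values()), default=0)
        rows = []
        for g in self.genotypes:
            reps = self.records[g]
            row = {"genotype": to_string(g, self.L)}
            for i in range(max_rep):
                row[f"rep{i + 1}"] = reps[i] if i < len(reps) else np.nan
            row["mean_s"] = float(np.mean(reps))
            row["n_reps"] = len(reps)
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.insert(0, "host", self.host)
        return frame

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, T: float = 4.0, reference: int = 0
    ) -> "FitnessLandscape":
        host = str(frame["host"].iloc[0]) if "host" in frame else "unknown"
        L = len(str(frame["genotype"].iloc[0]))
        rep_cols = [c for c in frame.columns if c.startswith("rep")]
        records = {}
        for _, row in frame.iterrows():
            reps = np.array([row[c] for c in rep_cols if pd.notna(row[c])], dtype=float)
            records[from_string(str(row["genotype"]))] = reps
        ls = cls(host=host, L=L, T=T, reference=reference, records=records)
        if "mean_s" in frame:  # recomputation check on load
            stored = frame.set_index("genotype")["mean_s"]
            for g_str, m in stored.items():
                if not math.isclose(ls.mean(from_string(str(g_str))), float(m),
                                    rel_tol=1e-6, abs_tol=1e-9):
                    raise ValueError(f"stored mean_s for {g_str} != replicate mean")
        return ls

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(
        cls, path: str | Path, T: float = 4.0, reference: int = 0
    ) -> "FitnessLandscape":
        return cls.from_frame(
            pd.read_csv(path, dtype={"genotype": str}), T=T, reference=reference
        )


def landscape_from_counts(
    counts: pd.DataFrame,
    host: str,
    L: int,
    T: float = 4.0,
    reference: int = 0,
    min_count: float = 1.0,
) -> FitnessLandscape:
    """Estimate a per-host landscape from long count tables.

    Per replicate sample: watermark variants are summed, barcode counts
    averaged, and every genotype whose mean count reaches ``min_count`` at
    both timepoints gets ``s_i = ln(c_iT/c_i0) - ln(c_refT/c_ref0)``.
    The reference genotype must pass the threshold in every replicate.
    """
    merged = merge_watermark_variants(counts)
    means = barcode_mean(merged)
    records: dict[int, list[float]] = {}
    for sample in sorted(means["sample"].unique()):
        sub = means[means["sample"] == sample]
        c0 = sub[sub["timepoint"] == "t0"].set_index("genotype")["mean_count"]
        cT = sub[sub["timepoint"] == "tT"].set_index("genotype")["mean_count"]
        if (
            reference not in c0.index
            or reference not in cT.index
            or c0[reference] < min_count
            or cT[reference] < min_count
        ):
            raise ValueError(
                f"reference genotype below detection in replicate {sample!r}"
            )
        ref_ratio = math.log(cT[reference] / c0[reference])
        usable = [
            g
            for g in c0.index.intersection(cT.index)
            if c0[g] >= min_count and cT[g] >= min_count
        ]
        for g in usable:
            s = math.log(cT[g] / c0[g]) - ref_ratio
            records.setdefault(int(g), []).append(s)
    return FitnessLandscape(
        host=host,
        L=L,
        T=T,
        reference=reference,
        records={g: np.array(v) for g, v in sorted(records.items())},
    )


def variant_selection_rates(
    counts: pd.DataFrame,
    L: int,
    reference: int = 0,
    min_count: float = 1.0,
) -> pd.DataFrame:
    """Per-sample selection rates resolved at the watermark-variant level.

    The reference ratio uses the variant-merged wild-type counts.  Returns a
    long frame ``sample, genotype, variant, s`` for the watermark-neutrality
    test.
    """
    means = (
        counts.groupby(["sample", "timepoint", "barcode", "genotype", "variant"],
                       as_index=False)["count"].sum()
        .groupby(["sample", "timepoint", "genotype", "variant"], as_index=False)[
            "count"
        ].mean()
        .rename(columns={"count": "mean_count"})
    )
    ref_means = barcode_mean(merge_watermark_variants(counts))
    rows = []
    for sample in sorted(means["sample"].unique()):
        ref = ref_means[
            (ref_means["sample"] == sample) & (ref_means["genotype"] == reference)
        ].set_index("timepoint")["mean_count"]
        if (
            "t0" not in ref
            or "tT" not in ref
            or ref["t0"] < min_count
            or ref["tT"] < min_count
        ):
            raise ValueError(f"reference genotype below detection in {sample!r}")
        ref_ratio = math.log(ref["tT"] / ref["t0"])
        sub = means[means["sample"] == sample]
        piv = sub.pivot_table(
            index=["genotype", "variant"], columns="timepoint", values="mean_count"
        )
        for (g, v), row in piv.iterrows():
            c0, cT = row.get("t0", np.nan), row.get("tT", np.nan)
            if pd.notna(c0) and pd.notna(cT) and c0 >= min_count and cT >= min_count:
                rows.append((sample, int(g), v, math.log(cT / c0) - ref_ratio))
    return pd.DataFrame(rows, columns=["sample", "genotype", "variant", "s"])


def watermark_neutrality_test(variant_rates: pd.DataFrame, L: int) -> pd.DataFrame:
    """Per-locus paired test of the two watermark options.

    For each locus, pairs the selection rates of identical focal genotypes
    measured under watermark option 1 vs option 2 within the same replicate
    sample (genomes carry one option at every mutant locus) and applies a
    two-sided paired t-test to the differences.  Loci with fewer than two
    pairs are reported as not testable rather than raising.

    Returns columns ``locus, n_pairs, mean_diff, statistic, df, pvalue,
    testable``.
    """
    v1 = variant_rates[variant_rates["variant"].str.contains("1", na=False) &
                       ~variant_rates["variant"].str.contains("2", na=False)]
    v2 = variant_rates[variant_rates["variant"].str.contains("2", na=False) &
                       ~variant_rates["variant"].str.contains("1", na=False)]
    paired = pd.merge(
        v1[["sample", "genotype", "s"]],
        v2[["sample", "genotype", "s"]],
        on=["sample", "genotype"],
        suffixes=("_w1", "_w2"),
    )
    rows = []
    for locus in range(L):
        has_locus = (paired["genotype"].to_numpy() >> locus) & 1 == 1
        diffs = (paired["s_w2"] - paired["s_w1"]).to_numpy()[has_locus]
        if diffs.size < 2 or np.allclose(diffs, diffs[0]):
            if diffs.size >= 2 and np.allclose(diffs, 0.0):
                # exactly neutral: zero difference everywhere
                rows.append((locus, diffs.size, 0.0, 0.0, diffs.size - 1, 1.0, True))
            else:
                rows.append(
                    (locus, int(diffs.size), float(np.mean(diffs)) if diffs.size else np.nan,
                     np.nan, np.nan, np.nan, False)
                )
            continue
        res = stats.ttest_1samp(diffs, 0.0)
        rows.append(
            (locus, diffs.size, float(np.mean(diffs)), float(res.statistic),
             diffs.size - 1, float(res.pvalue), True)
        )
    return pd.DataFrame(
        rows,
        columns=["locus", "n_pairs", "mean_diff", "statistic", "df", "pvalue", "testable"],
    )
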