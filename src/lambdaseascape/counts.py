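"""Watermark-conditioned genotype calling from amplicon reads.

Reads are fixed-layout amplicons, so calling is exact positional lookup — no
alignment, no indel tolerance.  The calling rules:

* a focal locus is scored mutant only when its mutant base AND one of its two
  watermark bases are observed on the same read; a focal mutant base with no
  watermark is scored wild-type (a sequencing-error interpretation),
* reads carrying more than one mismatch outside focal + watermark positions
  are rejected (``excess_mismatches``) — this acted as the quality filter in
  the original assay, so no Phred filtering is applied,
* watermark positions are always whitelisted: a watermark base without its
  focal mutation never counts as an extraneous mismatch.

Counts are tallied per sample / PCR barcode / timepoint, then barcode counts
are averaged (over however many barcodes are present).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .genotypes import MutationCatalog

__all__ = [
    "ReadObservation",
    "merge_pairs",
    "call_genotype",
    "count_genotypes",
    "barcode_mean",
    "observations_from_fastq",
    "count_fastq",
    "LayoutError",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

REJECT_LAYOUT = "layout"
REJECT_EXCESS = "excess_mismatches"


class LayoutError(ValueError):
    """Read geometry incompatible with the configured amplicon layout."""


@dataclass(frozen=True)
class ReadObservation:
    sample: str
    barcode: int
    timepoint: str  # "t0" | "tT"
    sequence: str


def merge_pairs(fwd: str, rev: str | None, amplicon_length: int) -> str:
    """Assemble the amplicon-spanning sequence from a read (pair).

    Concatenation layout: the forward read covers the amplicon start and the
    reverse read (given 5'->3' on the opposite strand) covers the amplicon
    end; together they must tile the window exactly.  Single-end mode
    (``rev is None``) is an identity pass-through.  Geometry mismatches raise
    :class:`LayoutError` (callers record the read as rejected for "layout").
    """
    if rev is None:
        if len(fwd) != amplicon_length:
            raise LayoutError(
                f"single-end read length {len(fwd)} != amplicon {amplicon_length}"
            )
        return fwd
    if len(fwd) + len(rev) != amplicon_length:
        raise LayoutError(
            f"mate lengths {len(fwd)}+{len(rev)} != amplicon {amplicon_length}"
        )
    return fwd + rev.translate(_COMPLEMENT)[::-1]


def call_genotype(
    seq: str, catalog: MutationCatalog
) -> tuple[int, str] | tuple[None, str]:
    """Call one merged read.

    Returns ``(genotype_bitmask, variant_string)`` on acceptance, where the
    variant string lists the watermark option ("1"/"2") observed at each
    mutant locus in locus order (empty for the wild type), or
    ``(None, reason)`` on rejection.
    """
    if len(seq) != len(catalog.amplicon_reference):
        return None, REJECT_LAYOUT
    ref = catalog.amplicon_reference
    whitelisted = set()
    genotype = 0
    variant_parts = []
    for m in catalog.loci:
        fi = catalog.to_amplicon_index(m.genome_position)
        whitelisted.add(fi)
        wm_seen = None
        for option, wm in enumerate(m.watermarks, start=1):
            wi = catalog.to_amplicon_index(wm.genome_position)
            whitelisted.add(wi)
            if wm_seen is None and seq[wi] == wm.mut_base:
                wm_seen = option
        if seq[fi] == m.mut_base and wm_seen is not None:
            genotype |= 1 << m.locus_index
            variant_parts.append(str(wm_seen))
    mismatches = sum(
        1 for i, (a, b) in enumerate(zip(seq, ref)) if a != b and i not in whitelisted
    )
    if mismatches > 1:
        return None, REJECT_EXCESS
    return genotype, "".join(variant_parts)


def count_genotypes(
    observations: Iterable[ReadObservation], catalog: MutationCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally calls into long count tables.

    Returns ``(counts, rejects)``: ``counts`` has columns
    ``sample, barcode, timepoint, genotype, variant, count``; ``rejects`` has
    ``sample, barcode, timepoint, reason, count``.  Accepted + rejected read
    totals equal the input total.
    """
    counts: dict[tuple, int] = {}
    rejects: dict[tuple, int] = {}
    for obs in observations:
        g, info = call_genotype(obs.sequence, catalog)
        if g is None:
            key = (obs.sample, obs.barcode, obs.timepoint, info)
            rejects[key] = rejects.get(key, 0) + 1
        else:
            key = (obs.sample, obs.barcode, obs.timepoint, g, info)
            counts[key] = counts.get(key, 0) + 1
    counts_df = pd.DataFrame(
        [k + (v,) for k, v in sorted(counts.items())],
        columns=["sample", "barcode", "timepoint", "genotype", "variant", "count"],
    )
    rejects_df = pd.DataFrame(
        [k + (v,) for k, v in sorted(rejects.items())],
        columns=["sample", "barcode", "timepoint", "reason", "count"],
    )
    return counts_df, rejects_df


def barcode_mean(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean count across the barcodes present, per sample/timepoint/genotype.

    Watermark variants are summed first (the landscape is defined over focal
    genotypes).  The mean divides by the number of barcodes observed for that
    sample/timepoint (a genotype absent from one barcode contributes 0 there).
    """
    if counts.empty:
        return pd.DataFrame(columns=["sample", "timepoint", "genotype", "mean_count"])
    merged = (
        counts.groupby(["sample", "timepoint", "barcode", "genotype"], as_index=False)[
            "count"
        ].sum()
    )
    n_bc = merged.groupby(["sample", "timepoint"])["barcode"].nunique()
    summed = merged.groupby(["sample", "timepoint", "genotype"], as_index=False)[
        "count"
    ].sum()
    summed["mean_count"] = summed["count"] / summed.set_index(
        ["sample", "timepoint"]
    ).index.map(n_bc).to_numpy()
    return summed[["sample", "timepoint", "genotype", "mean_count"]]


def observations_from_fastq(
    sample_sheet: pd.DataFrame, amplicon_length: int
) -> Iterator[ReadObservation | tuple[str, int, str, str]]:
    """Stream observations from a sample sheet.

    The sheet has columns ``file, file2, sample, barcode, timepoint``
    (``file2`` empty for single-end).  Layout failures are yielded as
    ``(sample, barcode, timepoint, "layout")`` tuples so the caller can keep
    read accounting exact.
    """
    for _, row in sample_sheet.iterrows():
        paired = isinstance(row.get("file2"), str) and row["file2"] != ""
        fwd_records = SeqIO.parse(row["file"], "fastq")
        rev_records = SeqIO.parse(row["file2"], "fastq") if paired else None
        for fwd in fwd_records:
            rev = next(rev_records) if rev_records is not None else None
            try:
                seq = merge_pairs(
                    str(fwd.seq), None if rev is None else str(rev.seq), amplicon_length
                )
            except LayoutError:
                yield (row["sample"], int(row["barcode"]), row["timepoint"], REJECT_LAYOUT)
                continue
            yield ReadObservation(row["sample"], int(row["barcode"]), row["timepoint"], seq)


def count_fastq(
    sample_sheet: pd.DataFrame, catalog: MutationCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FASTQ -> count tables, with layout rejects folded into the reject table."""
    layout_rejects: dict[tuple, int] = {}

    def _gen():
        for item in observations_from_fastq(
            sample_sheet, len(catalog.amplicon_reference)
        ):
            if isinstance(item, ReadObservation):
                yield item
            else:
                sample, barcode, tp, reason = item
                key = (sample, barcode, tp, reason)
                layout_rejects[key] = layout_rejects.get(key, 0) + 1

    counts_df, rejects_df = count_genotypes(_gen(), catalog)
    if layout_rejects:
        extra = pd.DataFrame(
            [k + (v,) for k, v in sorted(layout_rejects.items())],
            columns=["sample", "barcode", "timepoint", "reason", "count"],
        )
        rejects_df = (
            pd.concat([rejects_df, extra], ignore_index=True)
            .groupby(["sample", "barcode", "timepoint", "reason"], as_index=False)[
                "count"
            ]
            .sum()
        )
    return counts_df, rejects_df
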