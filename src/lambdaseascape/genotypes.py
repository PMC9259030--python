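"""Combinatorial genotype space over focal *J*-gene mutations.

A genotype is a presence/absence vector over the ``L`` focal mutations of the
catalog, stored compactly as a non-negative integer bitmask: bit ``i`` (least
significant) is locus ``i``.  The canonical enumeration order is binary
counting, and the human-readable string form writes locus 0 leftmost, e.g.
``"0110000000"`` for loci 1 and 2 mutant at ``L = 10``.

The catalog describes, for each focal mutation, its genomic position, the
wild-type and mutant base, its two synonymous *watermark* mutations (co-edited
markers that let a true genome edit be distinguished from a sequencing error),
and whether the locus belongs to the trio of changes required for infection
through the OmpF receptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WatermarkMutation",
    "FocalMutation",
    "MutationCatalog",
    "CatalogError",
    "enumerate_genotypes",
    "hamming_neighbors",
    "neighbor_matrix",
    "is_ompf_plus",
    "ompf_plus_mask",
    "to_string",
    "from_string",
    "popcount",
]

MAX_L = 20


class CatalogError(ValueError):
    """Raised for an inconsistent mutation catalog or genotype-space request."""


@dataclass(frozen=True)
class WatermarkMutation:
    """A synonymous marker substitution adjacent to a focal mutation."""

    genome_position: int  # 1-based coordinate on the phage genome
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        if self.wt_base == self.mut_base:
            raise CatalogError("watermark wt and mut base identical")


@dataclass(frozen=True)
class FocalMutation:
    """One focal locus: a host-recognition-gene substitution plus its two
    watermark options."""

    locus_index: int
    genome_position: int
    wt_base: str
    mut_base: str
    watermarks: tuple[WatermarkMutation, WatermarkMutation]
    ompf_required: bool = False

    def __post_init__(self) -> None:
        if self.wt_base == self.mut_base:
            raise CatalogError(f"locus {self.locus_index}: wt == mut base")
        if len(self.watermarks) != 2:
            raise CatalogError(f"locus {self.locus_index}: need exactly 2 watermarks")
        for wm in self.watermarks:
            if wm.genome_position == self.genome_position:
                raise CatalogError(
                    f"locus {self.locus_index}: watermark collides with focal position"
                )


@dataclass(frozen=True)
class MutationCatalog:
    """Ordered focal-mutation list plus the amplicon reference it lives on.

    ``amplicon_offset`` maps genome coordinates onto the amplicon: genome
    position ``p`` is amplicon index ``p - amplicon_offset - 1`` (0-based).
    """

    loci: tuple[FocalMutation, ...]
    amplicon_reference: str
    amplicon_offset: int = 0

    def __post_init__(self) -> None:
        positions = [m.genome_position for m in self.loci]
        if len(set(positions)) != len(positions):
            raise CatalogError("focal genome positions must be unique")
        for i, m in enumerate(self.loci):
            if m.locus_index != i:
                raise CatalogError("loci must be ordered by locus_index starting at 0")
        wm_positions = [w.genome_position for m in self.loci for w in m.watermarks]
        if set(wm_positions) & set(positions):
            raise CatalogError("watermark position collides with a focal position")
        for p in positions + wm_positions:
            if not (0 <= self.to_amplicon_index(p) < len(self.amplicon_reference)):
                raise CatalogError(f"position {p} outside amplicon window")
        for m in self.loci:
            ref = self.amplicon_reference[self.to_amplicon_index(m.genome_position)]
            if ref != m.wt_base:
                raise CatalogError(
                    f"locus {m.locus_index}: wt base {m.wt_base} != reference {ref}"
                )
            for w in m.watermarks:
                ref = self.amplicon_reference[self.to_amplicon_index(w.genome_position)]
                if ref != w.wt_base:
                    raise CatalogError(
                        f"locus {m.locus_index}: watermark wt {w.wt_base} != reference {ref}"
                    )

    @property
    def L(self) -> int:
        return len(self.loci)

    def to_amplicon_index(self, genome_position: int) -> int:
        return genome_position - self.amplicon_offset - 1

    @property
    def required_loci(self) -> tuple[int, ...]:
        return tuple(m.locus_index for m in self.loci if m.ompf_required)

    @property
    def required_mask(self) -> int:
        mask = 0
        for i in self.required_loci:
            mask |= 1 << i
        return mask

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "loci": [
                {
                    "index": m.locus_index,
                    "position": m.genome_position,
                    "wt": m.wt_base,
                    "mut": m.mut_base,
                    "watermarks": [
                        {"position": w.genome_position, "wt": w.wt_base, "mut": w.mut_base}
                        for w in m.watermarks
                    ],
                    "ompf_required": m.ompf_required,
                }
                for m in self.loci
            ],
            "amplicon": {"offset": self.amplicon_offset, "sequence": self.amplicon_reference},
        }

    @classmethod
    def from_dict(cls, d: dict, amplicon_sequence: str | None = None) -> "MutationCatalog":
        amp = d["amplicon"]
        seq = amplicon_sequence or amp.get("sequence")
        if seq is None:
            raise CatalogError("catalog dict lacks an amplicon sequence")
        loci = tuple(
            FocalMutation(
                locus_index=entry["index"],
                genome_position=entry["position"],
                wt_base=entry["wt"],
                mut_base=entry["mut"],
                watermarks=tuple(
                    WatermarkMutation(w["position"], w["wt"], w["mut"])
                    for w in entry["watermarks"]
                ),
                ompf_required=bool(entry.get("ompf_required", False)),
            )
            for entry in sorted(d["loci"], key=lambda e: e["index"])
        )
        return cls(loci=loci, amplicon_reference=seq, amplicon_offset=amp["offset"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MutationCatalog":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --- genotype arithmetic --------------------------------------------------


def _check_L(L: int) -> None:
    if not (1 <= L <= MAX_L):
        raise CatalogError(f"L must be in 1..{MAX_L}, got {L}")


def enumerate_genotypes(L: int) -> np.ndarray:
    """All ``2**L`` genotypes in canonical binary-counting order."""
    _check_L(L)
    return np.arange(2**L, dtype=np.int64)


def hamming_neighbors(g: int, L: int) -> np.ndarray:
    """The ``L`` genotypes one mutation away (gains and losses)."""
    _check_L(L)
    return np.int64(g) ^ (np.int64(1) << np.arange(L, dtype=np.int64))


def neighbor_matrix(L: int) -> np.ndarray:
    """``(2**L, L)`` array: row ``g`` lists the neighbors of genotype ``g``."""
    _check_L(L)
    g = enumerate_genotypes(L)
    return g[:, None] ^ (np.int64(1) << np.arange(L, dtype=np.int64))[None, :]


def popcount(g) -> np.ndarray | int:
    """Number of mutant loci (Hamming weight)."""
    arr = np.asarray(g, dtype=np.uint64)
    out = np.bitwise_count(arr).astype(np.int64)
    return out if out.ndim else int(out)


def is_ompf_plus(g: int, catalog: MutationCatalog) -> bool:
    """The '3+1' rule: all three required loci mutant plus >=1 other locus."""
    req = catalog.required_mask
    if len(catalog.required_loci) != 3:
        raise CatalogError("catalog must designate exactly 3 OmpF-required loci")
    return (g & req) == req and (g & ~req & ((1 << catalog.L) - 1)) != 0


def ompf_plus_mask(catalog: MutationCatalog) -> np.ndarray:
    """Boolean vector over all ``2**L`` genotypes flagging OmpF+ status."""
    req = catalog.required_mask
    if len(catalog.required_loci) != 3:
        raise CatalogError("catalog must designate exactly 3 OmpF-required loci")
    g = enumerate_genotypes(catalog.L)
    other = ~np.int64(req) & np.int64((1 << catalog.L) - 1)
    return ((g & req) == req) & ((g & other) != 0)


def to_string(g: int, L: int) -> str:
    """Bitstring form, locus 0 leftmost: g=1, L=3 -> ``'100'``."""
    return "".join("1" if (int(g) >> i) & 1 else "0" for i in range(L))


def from_string(s: str) -> int:
    if set(s) - {"0", "1"}:
        raise CatalogError(f"invalid genotype string {s!r}")
    return sum(1 << i for i, c in enumerate(s) if c == "1")
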