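"""Default mutation catalog.

The main text of the study names only the three OmpF-required changes
(A3034G, G3319A, T3321A); the identities of the remaining seven focal loci
and their watermarks live in supplementary material.  The catalog shipped
here is therefore a *synthetic* stand-in: the trio sits at its real genome
coordinates with its real base changes, the other seven loci and the amplicon
sequence are deterministic placeholders.  Users wanting bit-compatibility
with the deposited data supply their own catalog JSON via
:meth:`MutationCatalog.from_json`.

Coordinate conventions: the amplicon spans genome positions 3001-3400
(offset 3000).  The declared reading frame puts codon third ("wobble")
positions at coordinates divisible by 3 — matching the six wobble edits the
study used at 3381-3396 — and every watermark sits on a wobble position, so
the declared synonymy is frame-consistent.  Synonymy is declared metadata,
not validated against a codon table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from ..genotypes import FocalMutation, MutationCatalog, WatermarkMutation

__all__ = ["synthetic_catalog", "write_packaged_catalog", "load_packaged_catalog"]

AMPLICON_OFFSET = 3000
AMPLICON_LENGTH = 400

# (genome position, ompf_required); trio at its real coordinates
_FOCAL_POSITIONS = [
    (3034, True),
    (3052, False),
    (3076, False),
    (3103, False),
    (3127, False),
    (3151, False),
    (3175, False),
    (3199, False),
    (3319, True),
    (3321, True),
]
_WATERMARK_POSITIONS = {
    3034: (3036, 3039),
    3052: (3054, 3057),
    3076: (3078, 3081),
    3103: (3105, 3108),
    3127: (3129, 3132),
    3151: (3153, 3156),
    3175: (3177, 3180),
    3199: (3201, 3204),
    3319: (3312, 3315),
    3321: (3324, 3327),
}
# real wild-type bases of the trio (A3034G, G3319A, T3321A)
_FIXED_WT = {3034: "A", 3319: "G", 3321: "T"}
_FIXED_MUT = {3034: "G", 3319: "A", 3321: "A"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _reference_sequence() -> str:
    """Deterministic synthetic amplicon with the trio's wild-type bases fixed."""
    rng = np.random.default_rng(20200731)
    seq = rng.choice(list("ACGT"), AMPLICON_LENGTH)
    for pos, base in _FIXED_WT.items():
        seq[pos - AMPLICON_OFFSET - 1] = base
    return "".join(seq)


def synthetic_catalog() -> MutationCatalog:
    """The default 10-locus catalog (deterministic; see module docstring)."""
    ref = _reference_sequence()

    def wt(pos: int) -> str:
        return ref[pos - AMPLICON_OFFSET - 1]

    loci = []
    for idx, (pos, required) in enumerate(_FOCAL_POSITIONS):
        wms = tuple(
            WatermarkMutation(p, wt(p), _TRANSITION[wt(p)])
            for p in _WATERMARK_POSITIONS[pos]
        )
        loci.append(
            FocalMutation(
                locus_index=idx,
                genome_position=pos,
                wt_base=wt(pos),
                mut_base=_FIXED_MUT.get(pos, _TRANSITION[wt(pos)]),
                watermarks=wms,
                ompf_required=required,
            )
        )
    return MutationCatalog(
        loci=tuple(loci), amplicon_reference=ref, amplicon_offset=AMPLICON_OFFSET
    )


def write_packaged_catalog(directory: str | Path) -> None:
    """Regenerate the packaged catalog JSON + FASTA (maintenance helper)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cat = synthetic_catalog()
    cat.to_json(directory / "synthetic_catalog.json")
    with open(directory / "synthetic_amplicon.fasta", "w") as fh:
        fh.write(">synthetic_amplicon offset=3000 positions=3001-3400\n")
        seq = cat.amplicon_reference
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def load_packaged_catalog() -> MutationCatalog:
    """Load the catalog shipped as package data (round-trips the JSON path)."""
    with resources.files("lambdaseascape.data").joinpath(
        "synthetic_catalog.json"
    ).open() as fh:
        import json

        return MutationCatalog.from_dict(json.load(fh))
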