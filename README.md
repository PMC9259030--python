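# lambdaseascape

Tools for measuring and simulating the fitness landscape of bacteriophage λ
on coevolving *Escherichia coli* hosts.

When λ and *E. coli* are cocultured, the host evolves resistance through
*malT* mutations that reduce expression of LamB, λ's native receptor, and
about a quarter of λ populations respond by evolving to use a second
receptor, OmpF — an innovation requiring a specific trio of *J*-gene changes
(A3034G, G3319A, T3321A) plus at least one more mutation (the "3+1" rule).
This package implements the computational side of testing whether the host's
coevolution *deforms λ's fitness landscape into a seascape* that opens
otherwise inaccessible paths to that innovation:

1. **Genotype space** (`genotypes`) — the 2¹⁰ hypercube over 10 focal *J*
   mutations, a configurable mutation catalog with per-locus synonymous
   *watermark* markers, and the 3+1 OmpF⁺ classification.
2. **Synthetic experiments** (`synth`) — a generative twin of the bulk
   competition assay: combinatorial library with uneven/missing composition,
   exponential growth at genotype-specific Malthusian rates, multinomial
   amplicon sequencing with two PCR barcodes, optional FASTQ emission.
3. **Genotype calling** (`counts`) — watermark-conditioned calling from
   amplicon reads (a focal mutation counts only if a watermark confirms it)
   with the >1-extraneous-mismatch read filter and barcode-averaged counts.
4. **Selection rates** (`fitness`) — per-genotype fitness as the difference
   of Malthusian parameters versus the wild type over the assay,

   *s* = ln(X_T/X_0) − ln(Y_T/Y_0)   (per assay period T),

   with detection-limit exclusions, replicate means, and a paired
   watermark-neutrality test.
5. **Epistasis regression** (`regression`) — the single-host model
   y = β\*\* + Σᵢ βᵢGᵢ + Σᵢ<ⱼ βᵢⱼGᵢGⱼ (55 terms at L=10) and the combined
   two-host model with a host indicator E (111 terms: G, G×G, E, G×E,
   G×G×E), Benjamini–Hochberg FDR control, R-`step`-style bidirectional AIC
   selection with marginality, and sequential variance partitioning.
6. **Landscape completion** (`completion`) — per-trial replicate bootstrap
   plus random-order nearest-neighbor imputation of unmeasured genotypes.
7. **Evolution** (`simulate`) — a modified Wright–Fisher model (multinomial
   reproduction weighted by wᵢ = exp(sᵢ); mutation acting on count
   increments) run on static or host-switching landscape schedules, with
   OmpF⁺ detection at a particle threshold, batched Student-t confidence
   intervals, and ANOVA + Tukey treatment comparison.

## Worked example

Generate a synthetic two-host experiment, estimate both landscapes, and fit
the combined host-interaction model:

```bash
lambdaseascape synthesize --seed 42 --outdir demo
lambdaseascape fitness --counts demo/counts_ancestral.csv  --host ancestral  --out demo/anc.csv
lambdaseascape fitness --counts demo/counts_malT_minus.csv --host malT_minus --out demo/malt.csv
lambdaseascape regress --landscape demo/anc.csv --landscape2 demo/malt.csv --combined --out demo/reg.csv
lambdaseascape power --p 0.25 --n 12 --k 0
```

which prints

```
wrote counts for 2 hosts to demo
landscape for ancestral: 657 genotypes
landscape for malT_minus: 648 genotypes
R2adj=0.9689 F=367.16 (111 terms, 101 AIC-retained)
0.031676
```

The landscapes are partial (657 and 648 of 1024 genotypes) because rare
library members fall below the detection limit during the competition —
exactly the gap structure the downstream bootstrap/imputation step handles.
The combined regression explains 97% of fitness variance; the accompanying
`demo/reg.summary.json` partitions it sequentially: 71.97% direct mutation
effects, 6.66% pairwise epistasis (G×G), 0.92% host main effect, 15.87%
mutation-by-host (G×E) and 1.74% epistasis-by-host (G×G×E), 2.84% residual.
The final line is the binomial replay-power calculation: with a true OmpF⁺
success rate of 0.25, twelve all-negative replicate populations occur with
probability 0.75¹² ≈ 0.0317.

The full pipeline (synthesis → calling → fitness → regression → completion →
evolution → comparison, with a manifest and idempotent re-runs) is driven by
`lambdaseascape run --config pipeline.json` or, for a self-contained demo,
`lambdaseascape run --outdir out --seed 1`.

The default mutation catalog places the OmpF-required trio at its real λ
coordinates; the other seven focal loci and the amplicon sequence are
synthetic placeholders (see `lambdaseascape/data/`), and a user catalog can
be supplied as JSON via `--catalog`.

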