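# thawvir

Viromics inference chain for soil viral communities along a permafrost
thaw gradient (palsa → bog → fen), built for researchers who study how
viruses shape carbon-cycling microbial communities in thawing peatlands
— and who need the standard sequence-to-ecology pipeline as a tested,
scriptable library rather than a collection of one-off tools.

The chain:

1. **Dereplication** — contigs cluster into viral populations (vOTUs,
   ~species rank) at ≥95% average nucleotide identity (ANI) across ≥80%
   of the shorter contig, greedy longest-first.
2. **Read recruitment** — a vOTU is *detected* in a virome when reads at
   ≥90% identity cover ≥75% of its length; its abundance is
   `(mapped bp / contig length) / library bp × 10⁹` (per Gbp), with
   total-sum scaling for community comparisons.
3. **Gene-sharing network** — genomes sharing protein clusters (PCs) are
   scored with the hypergeometric tail `P` of sharing at least `c` of
   `n` PCs given per-genome counts `a, b`; edges require
   `S = −log10(P·T) ≥ 1` with `T = N(N−1)` genome comparisons, and
   Markov clustering (inflation scanned 1.0–5.0 in 21 steps) yields
   viral clusters (~genus rank), doubletons and singletons.
4. **Host prediction** — CRISPR spacers found in host genomes matched
   exactly against vOTUs, plus similarity links at ≥50 bits, E ≤ 1e-3,
   ≥70% ANI over ≥2,500 bp.
5. **Ecology** — richness / Shannon H′ / Pielou J, Bray–Curtis PCoA,
   habitat-sharing Euler regions, randomized collector curves,
   codon-usage ordination, and a contaminant screen.

Because the original sequencing data are not needed to validate the
machinery, the package includes a synthetic-community generator
(`thawvir.synthio`) producing habitat-structured communities with full
ground truth — planted vOTU memberships, abundance gradients, protein
families, CRISPR protospacers — against which the entire chain is
scored. See `docs/methods.md` for the model and its limits.

## Worked example

Run the default synthetic scenario end to end (the numbered scripts in
`analysis/` break the same run into narrative steps):

```bash
thawvir run --seed 1 --out scratch/demo
```

    pipeline complete: 20 vOTUs, 40 network edges, 21 host links -> scratch/demo

Stage by stage (`python analysis/01_simulate.py` … `06_ecology.py`):

    screen: 1 of 52 contigs flagged as contaminant (contam1.c1)
    dereplicate: 51 contigs -> 20 vOTUs (member counts 2-3)
      palsa_1: 9,479 mapped, 8,954 kept (525 below identity), 8/20 vOTUs detected
      ...
    network: 40 edges at S >= 1.0; optimum inflation 1.0 (modularity 0.750)
    CRISPR: 4 arrays / 20 spacers across 4 of 6 hosts
    host links: 21 ({'crispr': 20, 'similarity': 1})
    habitat sharing: regions {'bog': 4, 'palsa': 6, 'bog+palsa': 2, 'fen': 6,
                              'bog+fen': 2}; 20% of vOTUs in >1 habitat;
                              palsa-fen shared = 0
    habitat abundance folds vs palsa: {'bog': 3.14, 'fen': 12.05, 'palsa': 1.0}
        (configured 1/3/12)

Reading those numbers: the planted contaminant was screened out; all 51
genuine contigs dereplicated into exactly the 20 planted populations; the
four planted protein-sharing clusters reappear as 40 significant network
edges grouping the 20 genomes; all 21 planted host links (20 CRISPR, 1
similarity) are recovered with none spurious; no population crosses from
intact permafrost (palsa) to full thaw (fen); and the measured abundance
gradient (bog ≈ 3×, fen ≈ 12× palsa) recovers the configured fold
factors — the ~3% excess on bog is background host reads recruiting into
a planted prophage-like segment, a realistic contamination signature the
detection threshold keeps out of the presence calls.

The published per-virome read-accounting table for the seven
thaw-gradient peat viromes ships with the package:

```bash
python analysis/07_virome_table_stats.py
```

    mean assembled: 18.5% (range 4.9-32.4%)
    pooled vOTU reads: 10.0% of assembled, 53.8% of putative-viral
    bog chilled-B vs frozen-B assembled reads: 9.04-fold

which round to the conventionally printed 19% (5–32%), 10%, 54% and
9-fold.

Each subcommand (`simulate`, `screen`, `dereplicate`, `quantify`,
`network`, `hostlink`, `ecology`, `run`) also works on your own FASTA /
SAM / BLAST-tabular files; `thawvir --help` lists the options, and every
threshold above is a flag or YAML config key with the defaults shown.

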