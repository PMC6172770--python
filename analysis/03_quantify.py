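"""Recruit reads to vOTU representatives and quantify detection/abundance.

Each sample's reads map with the built-in k-mer-seeded mapper, alignments
below 90% identity are dropped (best hit per read), and a vOTU counts as
detected only where reads cover >= 75% of its length.  Abundances are
per-Gbp normalised, then total-sum scaled for the community analyses.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, RUN_DIR, default_config, ensure_dirs

from thawvir.abundance import AbundanceMatrix, detect_and_quantify, filter_alignments, total_sum_scale
from thawvir.io import read_fasta, write_alignments_tsv, write_tsv_matrix
from thawvir.mapping import ReadMapper


def main() -> None:
    ensure_dirs()
    cfg = default_config()
    reps = read_fasta(RUN_DIR / "representatives.fasta")
    lengths = {v: len(s) for v, s in reps.items()}
    samples = pd.read_csv(RUN_DIR / "sample_table.tsv", sep="\t", index_col=0)

    mapper = ReadMapper(reps)
    rows = {}
    for sid, row in samples.iterrows():
        reads = read_fasta(RUN_DIR / "reads" / f"{sid}.fasta")
        raw = mapper.map_reads(reads.items())
        kept = filter_alignments(raw, min_read_ani=cfg.quantify.min_read_ani)
        write_alignments_tsv(kept, RUN_DIR / "reads" / f"{sid}.alignments.tsv")
        rows[sid] = detect_and_quantify(
            kept, lengths, total_bp=int(row.total_bp), min_breadth=cfg.quantify.min_breadth
        )
        print(f"  {sid}: {len(raw):,} mapped, {len(kept):,} kept "
              f"({len(raw) - len(kept)} below identity), "
              f"{int(rows[sid].detected.sum())}/{len(reps)} vOTUs detected")

    matrix = AbundanceMatrix.from_samples(rows)
    write_tsv_matrix(matrix.values, RUN_DIR / "abundance.tsv")
    write_tsv_matrix(matrix.detected.astype(int), RUN_DIR / "detected.tsv")
    write_tsv_matrix(matrix.breadth, RUN_DIR / "breadth.tsv")
    write_tsv_matrix(total_sum_scale(matrix.values), RUN_DIR / "abundance_scaled.tsv")
    write_tsv_matrix(matrix.values.round(2), RESULTS / "abundance_per_gbp.tsv")
    print(f"abundance matrix: {matrix.values.shape[0]} samples x "
          f"{matrix.values.shape[1]} vOTUs -> {RESULTS / 'abundance_per_gbp.tsv'}")


if __name__ == "__main__":
    main()
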