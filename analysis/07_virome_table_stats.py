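"""Derived statistics of the published seven-virome read-accounting table.

Per-virome assembled-read percentages, the pooled vOTU read fractions,
and the chilled-vs-frozen bog assembly fold -- the bundled counts are the
published per-library read accounting for the seven thaw-gradient peat
viromes.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, ensure_dirs

from thawvir.abundance import summarize_viromes
from thawvir.data import load_stordalen_virome_table


def main() -> None:
    ensure_dirs()
    table = load_stordalen_virome_table()
    stats = summarize_viromes(table)
    out = stats.per_sample.round(2)
    out.to_csv(RESULTS / "virome_summary.tsv", sep="\t")
    print(out[["total_reads", "assembled_reads", "assembled_pct"]])
    print(f"\nmean assembled: {stats.mean_assembled_pct:.1f}% "
          f"(range {stats.min_assembled_pct:.1f}-{stats.max_assembled_pct:.1f}%)")
    print(f"pooled vOTU reads: {stats.pooled_votu_of_assembled_pct:.1f}% of assembled, "
          f"{stats.pooled_votu_of_viral_pct:.1f}% of putative-viral")
    print(f"bog chilled-B vs frozen-B assembled reads: "
          f"{stats.fold_ratio('bog_chilled_B', 'bog_frozen_B'):.2f}-fold")


if __name__ == "__main__":
    main()
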