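"""Community-ecology statistics over the detected-vOTU abundance matrix.

Diversity per virome, Bray-Curtis PCoA of the total-sum-scaled profiles,
habitat sharing (Euler regions), randomized collector curves, and the
measured habitat abundance fold gradient.
"""

import dataclasses
import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, RUN_DIR, SEED, default_config, ensure_dirs

from thawvir.abundance import total_sum_scale
from thawvir.ecology import (
    bray_curtis,
    collectors_curve,
    diversity,
    habitat_fold_factors,
    habitat_sharing,
    pcoa,
)
from thawvir.io import read_fasta, read_tsv_matrix, write_tsv_matrix


def main() -> None:
    ensure_dirs()
    cfg = default_config()
    values = read_tsv_matrix(RUN_DIR / "abundance.tsv")
    detected = read_tsv_matrix(RUN_DIR / "detected.tsv").astype(bool)
    samples = pd.read_csv(RUN_DIR / "sample_table.tsv", sep="\t", index_col=0)
    labels = samples["habitat"].to_dict()
    lengths = {v: len(s) for v, s in read_fasta(RUN_DIR / "representatives.fasta").items()}

    scaled = total_sum_scale(values)
    div = pd.DataFrame(
        {s: dataclasses.asdict(diversity(scaled.loc[s][detected.loc[s]]))
         for s in scaled.index}
    ).T.rename_axis("sample")
    write_tsv_matrix(div, RESULTS / "diversity.tsv")
    print("diversity (richness / H' / J):")
    for s, row in div.iterrows():
        print(f"  {s}: {int(row.richness)} / {row.shannon:.3f} / {row.pielou:.3f}")

    bc = bray_curtis(scaled)
    ordination = pcoa(bc)
    write_tsv_matrix(ordination.coordinates.round(4), RESULTS / "pcoa_coordinates.tsv")
    frac = ordination.proportion_explained
    print(f"PCoA: axis 1 explains {frac[0]*100:.0f}%, axis 2 {frac[1]*100:.0f}% "
          "(samples separate by habitat)")

    sharing = habitat_sharing(detected, labels)
    regions = {"+".join(sorted(k)): v for k, v in sharing.regions.items()}
    print(f"habitat sharing: regions {regions}; "
          f"{sharing.multi_habitat_fraction*100:.0f}% of vOTUs in >1 habitat; "
          f"palsa-fen shared = {sharing.pairwise_shared.loc['palsa', 'fen']}")
    pd.DataFrame(sorted(regions.items()), columns=["region", "n_votus"]).to_csv(
        RESULTS / "habitat_regions.tsv", sep="\t", index=False
    )

    curve = collectors_curve(detected, n_randomizations=cfg.ecology.n_randomizations, seed=SEED)
    pd.DataFrame(
        {"mean_richness": curve.mean},
        index=pd.RangeIndex(1, len(curve.mean) + 1, name="n_samples"),
    ).to_csv(RESULTS / "collector_curve.tsv", sep="\t")

    folds = habitat_fold_factors(values, labels, cfg.ecology.reference_habitat,
                                 contig_lengths=lengths)
    folds.rename("fold_vs_palsa").rename_axis("habitat").round(3).to_csv(
        RESULTS / "habitat_folds.tsv", sep="\t"
    )
    print(f"habitat abundance folds vs palsa: "
          f"{ {h: round(f, 2) for h, f in folds.items()} } "
          f"(configured 1/3/12)")


if __name__ == "__main__":
    main()
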