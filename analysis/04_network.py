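"""Gene-sharing network and viral-cluster assignment.

Protein similarity edges (50-bit / 1e-4 thresholds) are clustered into
protein clusters; genome pairs are scored with the hypergeometric
similarity statistic S = -log10(P*T); edges with S >= 1 form the network,
partitioned by MCL across the 21-value inflation grid with the weighted-
modularity optimum reported.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, RUN_DIR, default_config, ensure_dirs

from thawvir.network import assign_viral_clusters, build_protein_clusters


def main() -> None:
    ensure_dirs()
    cfg = default_config()
    edges = pd.read_csv(RUN_DIR / "protein_edges.tsv", sep="\t")
    pg = pd.read_csv(RUN_DIR / "protein_genomes.tsv", sep="\t", index_col=0)["genome"].to_dict()

    pcs, profiles = build_protein_clusters(
        edges, pg, min_bitscore=cfg.network.min_bitscore, max_evalue=cfg.network.max_evalue
    )
    singletons = sum(p.singleton_count for p in profiles)
    print(f"protein clusters: {len(pcs)} PCs spanning >=2 genomes; "
          f"{singletons} singleton proteins excluded from scoring")

    vc = assign_viral_clusters(
        profiles,
        inflation_grid=cfg.network.inflation_grid,
        score_threshold=cfg.network.score_threshold,
    )
    print(f"network: {len(vc.edges)} edges at S >= {cfg.network.score_threshold}; "
          f"optimum inflation {vc.inflation:.1f} "
          f"(modularity {vc.modularity[vc.inflation]:.3f})")
    classes = pd.Series(vc.classes).value_counts().to_dict()
    print(f"genome classes: {classes}")

    out = pd.DataFrame({"vc": pd.Series(vc.membership), "class": pd.Series(vc.classes)})
    out.rename_axis("genome").to_csv(RUN_DIR / "vcs.tsv", sep="\t")
    out.rename_axis("genome").to_csv(RESULTS / "viral_clusters.tsv", sep="\t")
    pd.Series(vc.modularity, name="modularity").rename_axis("inflation").to_csv(
        RESULTS / "inflation_scan.tsv", sep="\t"
    )


if __name__ == "__main__":
    main()
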