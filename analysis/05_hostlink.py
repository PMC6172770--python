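"""Predict vOTU hosts from CRISPR spacers and nucleotide similarity.

CRISPR arrays are detected in the host genomes, their spacers matched
exactly (zero mismatches) against the vOTU representatives on both
strands; independently, viral-host local alignments passing 50 bit /
E 1e-3 / 70% ANI / 2,500 bp yield similarity links.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, RUN_DIR, default_config, ensure_dirs

from thawvir.hostlink import crispr_links, find_crispr_arrays, similarity_link
from thawvir.io import read_fasta


def main() -> None:
    ensure_dirs()
    cfg = default_config()
    hosts = read_fasta(RUN_DIR / "hosts.fasta")
    reps = read_fasta(RUN_DIR / "representatives.fasta")

    arrays = {
        h: find_crispr_arrays(
            s, host=h,
            repeat_len_range=cfg.hostlink.repeat_len_range,
            spacer_len_range=cfg.hostlink.spacer_len_range,
            min_repeats=cfg.hostlink.min_repeats,
        )
        for h, s in hosts.items()
    }
    n_arrays = sum(len(a) for a in arrays.values())
    n_spacers = sum(len(x.spacers) for a in arrays.values() for x in a)
    print(f"CRISPR: {n_arrays} arrays / {n_spacers} spacers "
          f"across {sum(bool(a) for a in arrays.values())} of {len(hosts)} hosts")

    links = crispr_links(arrays, reps, max_mismatch=cfg.hostlink.max_mismatch)
    links += similarity_link(
        reps, hosts,
        min_bitscore=cfg.hostlink.min_bitscore,
        max_evalue=cfg.hostlink.max_evalue,
        min_ani=cfg.hostlink.min_ani,
        min_len=cfg.hostlink.min_len,
    )
    by_kind = pd.Series([l.evidence for l in links]).value_counts().to_dict()
    print(f"host links: {len(links)} ({by_kind})")

    out = pd.DataFrame(
        [(l.votu, l.host, l.evidence) for l in links],
        columns=["votu", "host", "evidence"],
    )
    out.to_csv(RUN_DIR / "host_links.tsv", sep="\t", index=False)
    out.to_csv(RESULTS / "host_links.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
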