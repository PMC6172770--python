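"""Generate the default habitat-structured synthetic scenario.

Three thaw-gradient habitats (palsa, bog, fen) with 8 vOTUs each, sharing
2 populations palsa-bog and 2 bog-fen (none palsa-fen); per-habitat
log-normal abundances; viral library fractions following the 1/3/12 fold
gradient; two read replicates per habitat with library sizes decreasing
along the gradient; six host genomes (four CRISPR, one carrying a shared
viral segment, one untouched); planted protein-family content defining
four viral clusters; and one lab-contaminant contig.

Writes the full run directory (FASTA, reads, truth tables) to scratch/.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RUN_DIR, default_config, ensure_dirs

from thawvir.pipeline import simulate_scenario


def main() -> None:
    ensure_dirs()
    cfg = default_config()
    sim = simulate_scenario(cfg, RUN_DIR)
    n_shared = sum(n for n in cfg.community.overlaps.values())
    print(f"community: {len(sim.community.genomes)} viral genomes "
          f"({n_shared} shared between habitat pairs), "
          f"{len(sim.community.contigs)} member contigs")
    print(f"hosts: {len(sim.hosts)} genomes, "
          f"{len(sim.truth.host_links)} planted host links")
    for sid, reads in sim.sample_reads.items():
        print(f"  {sid}: {len(reads):,} reads "
              f"({sim.sample_habitats[sid]}, {sim.sample_total_bp[sid]/1e6:.1f} Mbp)")
    print(f"run directory: {RUN_DIR}")


if __name__ == "__main__":
    main()
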