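"""Bundled reference tables.

``stordalen_viromes.tsv`` holds the published per-virome read accounting
for the seven Stordalen Mire peat viromes (palsa, bog and fen habitats
along the permafrost thaw gradient): total reads, reads assembling into
contigs, reads recruiting to putative viral contigs, and reads recruiting
to the 53 well-sampled vOTUs.  These printed counts are the input to
:func:`thawvir.abundance.summarize_viromes`.
"""

from importlib.resources import files

import pandas as pd


def load_stordalen_virome_table() -> pd.DataFrame:
    """The seven-virome read-count table, indexed by sample name."""
    path = files(__package__).joinpath("stordalen_viromes.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
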