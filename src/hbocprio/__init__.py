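"""Family-based rare-variant prioritization for hereditary breast/ovarian cancer.

Discovery in multiplex families (rare segregating LoF variants), kinship
QC with the KING-robust estimator, cross-cohort replication on the same
transcript, three variant-level shortlisting strategies, and case-control
allele-count association — exercised end-to-end on a synthetic pedigree
gene-dropping simulator.
"""

from importlib.resources import files

__version__ = "0.1.0"


def published_counts_path():
    """Path to the bundled cohort allele-count table (printed study counts)."""
    return files("hbocprio").joinpath("data/published_counts.tsv")
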