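"""Published reference summaries from the piglet weaning-diet study.

Three small tables ship with the package: the pre/post-weaning core-taxon
lists with average counts (the synthetic generator's default taxon panel),
the per-cell alpha-diversity index summary, and the growth/mortality group
summary. They serve as worked-example inputs and as the targets the
synthetic study design emulates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("pigbiome.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_core_taxa_reference() -> pd.DataFrame:
    """Pre/post-weaning core taxa with six-rank lineages and average counts."""
    return _load("core_taxa_reference.tsv")


def load_alpha_summary_reference() -> pd.DataFrame:
    """Alpha-diversity indices per period and treatment cell, with p-values."""
    return _load("alpha_summary_reference.tsv").set_index("index")


def load_growth_summary_reference() -> pd.DataFrame:
    """Group-level body weight, daily gain and mortality summary."""
    return _load("growth_summary_reference.tsv")
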