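import numpy as np
import pandas as pd
import pytest

import pigbiome as pb


@pytest.fixture(scope="session")
def sim_params():
    return pb.SimParams(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(sim_params):
    """A full synthetic study: table, truth bundle, filtered and normalized
    views, shared across tests (read-only)."""
    design = pb.generate_design(sim_params)
    table, truth = pb.generate_otu_table(design, sim_params)
    filtered = pb.filter_otus(table)
    norm = pb.css_normalize(filtered)
    return {"design": design, "table": table, "truth": truth,
            "filtered": filtered, "norm": norm}


def _meta(samples, pigs, treatments, timepoints):
    return pd.DataFrame(
        {"pig": pigs, "treatment": treatments, "timepoint": timepoints},
        index=pd.Index(samples, name="sample"))


@pytest.fixture
def small_table():
    """3 taxa x 4 samples, two pigs x two timepoints, hand-checkable."""
    counts = pd.DataFrame(
        [[10, 0, 3, 7],
         [5, 5, 0, 1],
         [0, 20, 9, 2]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2", "s3", "s4"])
    lineages = pd.DataFrame(
        [["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
          "Lactobacillaceae", "Lactobacillus"],
         ["Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
          "Lachnospiraceae", "Blautia"],
         ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
          "Prevotellaceae", "Prevotella 9"]],
        index=["t1", "t2", "t3"], columns=list(pb.RANKS))
    meta = _meta(["s1", "s2", "s3", "s4"],
                 ["p1", "p1", "p2", "p2"],
                 ["white", "white", "oil", "oil"],
                 ["T0", "T2", "T0", "T2"])
    return pb.OtuTable(counts=counts, lineages=lineages, metadata=meta)
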