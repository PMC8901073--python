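"""Core-microbiome extraction and the pre/post-weaning comparison.

First reproduces the published overlap (10 core taxa before weaning, 43
after, 7 shared) from the reference lists shipped with the package, then
extracts a 90%-prevalence core from simulated data.
"""

import pigbiome as pb
from pigbiome.core import compare_cores, coreset_from_lineages
from pigbiome.reference import load_core_taxa_reference

ref = load_core_taxa_reference()
pre = coreset_from_lineages(ref[ref["period"] == "pre"], "pre")
post = coreset_from_lineages(ref[ref["period"] == "post"], "post")
report = compare_cores(pre, post)
print(f"published core lists: {report['n_pre']} pre, "
      f"{report['n_post']} post, {report['n_shared']} shared")
print("shared genera:",
      ", ".join(sorted(l.split(";")[-1] for l in report["shared"])))

params = pb.SimParams(seed=11)
design = pb.generate_design(params)
table, _ = pb.generate_otu_table(design, params)
cores = pb.core_by_period(pb.filter_otus(table), prevalence_threshold=0.9)
sim_report = compare_cores(cores["pre"], cores["post"])
print(f"\nsimulated study: {sim_report['n_pre']} pre, "
      f"{sim_report['n_post']} post, {sim_report['n_shared']} shared")
# the simulated panel is dense (46 abundant taxa), so nearly every taxon
# is core in both periods; real tables are much sparser
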