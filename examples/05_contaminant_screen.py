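"""Screen assembled contigs for non-plant contamination via BLAST hits.

A contig is kept when at least one of its ten lowest-e-value hits below
1e-25 comes from a green-plant genus; it is then annotated with the
best informative green-plant description.
"""

import pandas as pd

from contigvar import assign_annotation, screen_contaminants

hits = pd.DataFrame(
    [
        ("ctg1", 1, "Populus trichocarpa", "Populus", 1e-80, "cellulose synthase"),
        ("ctg1", 2, "Vitis vinifera", "Vitis", 1e-60, "hypothetical protein"),
        ("ctg2", 1, "Escherichia coli", "Escherichia", 1e-90, "DNA gyrase"),
        ("ctg2", 2, "Homo sapiens", "Homo", 1e-70, "topoisomerase"),
        ("ctg3", 1, "Vitis vinifera", "Vitis", 1e-10, "kinase"),
    ],
    columns=["contig_id", "hit_rank", "subject_species", "subject_genus", "evalue", "description"],
)
taxonomy = {"Populus": True, "Vitis": True, "Escherichia": False, "Homo": False}

partition = screen_contaminants(hits, taxonomy)
for contig, status in partition.items():
    print(f"{contig}: {status}")
# ctg1 has a strong green-plant hit -> clean; ctg2 only non-plant hits
# below the e-value ceiling -> contaminant (excluded downstream); ctg3
# has no hit under 1e-25 -> retained but unannotated.

print("annotations:", assign_annotation(hits, taxonomy))
# the uninformative 'hypothetical protein' hit is skipped automatically
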