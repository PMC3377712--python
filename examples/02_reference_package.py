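"""Curate a niche-specific reference package.

Plants a mislabeled public sequence (a BVAB1 sequence claimed to be
L. crispatus), then runs the curation chain: primary reference "S" by
smallest median distance, discard of sequences > 0.015 from S (below
98.5% identity), greedy max-spread representative selection, and a
neighbor-joining tree over the retained alignment.
"""

import tempfile

from vaginome import refpkg, synthetic

world = synthetic.simulate_reference_world(n_taxa=6, seqs_per_taxon=5, seed=3)
seq_taxids = dict(world.leaf_taxids)

# mislabel one BVAB1 sequence as L. crispatus
stray = world.clade_leaves("s__BVAB1")[0]
seq_taxids[stray] = "s__Lactobacillus_crispatus"
print(f"planted mislabel: {stray} claimed to be L. crispatus")

pkg = refpkg.build_reference_package(
    world.sequences, seq_taxids, world.taxonomy,
    cutoff=0.015, n_representatives=5,
)
for entry in pkg.log:
    if entry["action"] == "discard":
        print(f"discarded {entry['seq']} at distance "
              f"{entry['distance_to_primary']} from its taxon's primary")
print(f"retained sequences: {len(pkg.sequences)}")
print(f"tree leaves:        {len(pkg.tree.leaf_names())}")
pkg.write(tempfile.mkdtemp() + "/refpkg")
# The planted stray sits ~0.10 from the crispatus primary — far beyond the
# 0.015 cutoff — so curation removes it before the tree is built.
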