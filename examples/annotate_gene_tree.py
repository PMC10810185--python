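"""Annotate a toy gene tree: lineage labels, duplication nodes, signatures.

A small homolog tree with two human and two mouse paralogs illustrates the
species-overlap duplication rule; a toy alignment shows the conserved-
cysteine signature screen used to reject remote homologs.
"""

import dendropy

from xrquant.phylo_annotation import (add_lineage, duplication_nodes,
                                      label_duplication_nodes, presence_absence,
                                      signature_conservation)

LINEAGES = {
    "Human": ["Eukaryota", "Metazoa", "Chordata", "Mammalia", "Primates"],
    "Mouse": ["Eukaryota", "Metazoa", "Chordata", "Mammalia", "Rodentia"],
    "Fly": ["Eukaryota", "Metazoa", "Arthropoda", "Insecta"],
}
SPECIES = {"HumanA": "Human", "HumanB": "Human",
           "MouseA": "Mouse", "MouseB": "Mouse", "Fly": "Fly"}

tree = dendropy.Tree.get(data="(((HumanA,MouseA),(HumanB,MouseB)),Fly);",
                         schema="newick")
add_lineage(tree, LINEAGES, SPECIES)
label_duplication_nodes(tree, species_map=SPECIES)

for node in tree.preorder_internal_node_iter():
    dup = bool(node.annotations.get_value("duplication"))
    print(f"node label={node.label:<10} duplication={dup}")
print("-> the Mammalia node whose children both contain Human and Mouse is "
      "flagged: two shared species imply a gene duplication before the "
      "human-mouse split")

matrix = presence_absence(
    ["Human", "Mouse", "Fly", "Arabidopsis"],
    {"XPA": {"p1": "Human", "p2": "Mouse", "p3": "Fly"},
     "XPC": {"q1": "Human", "q2": "Mouse", "q3": "Fly", "q4": "Arabidopsis"}})
print("\npresence/absence matrix:")
print(matrix.astype(int).to_string())
print("-> the plant has the global-repair sensor XPC but no XPA homolog")

msa = {"human_ref": "MC-CCKQC-CM",
       "homolog":   "MC-CCRQC-CM",
       "remote":    "MA-AGKQA-GM"}
result = signature_conservation(msa, "human_ref", positions=[2, 3, 4, 7, 8],
                                residue="C")
print("\nsignature-residue screen (cysteines):")
print(result.per_sequence.to_string(index=False))
print("-> the remote homolog lacks the conserved cysteines and is rejected")
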