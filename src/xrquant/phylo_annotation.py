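"""Gene-tree curation: lineage labels, duplication nodes, presence/absence,
and signature-residue conservation.

These are the bookkeeping computations used to curate a large homolog tree
by hand: every internal node is labelled with the deepest taxonomic rank
shared by all species beneath it (the lineage LCA), nodes whose child clades
share species are flagged as gene-duplication nodes, a species x gene
presence/absence matrix summarises homolog coverage per clade, and a set of
alignment columns carrying invariant residues (for XPA, the cysteines at
reference positions 105-108, 126-128 and 261-264) screens remote homologs.

Trees are dendropy objects; rooting, outgroup choice and clade pruning stay
manual -- this module annotates, it does not root.

Duplication rule: the flag requires *more than one* shared species between
the child clades (min_shared=2), stricter than the classical >=1
species-overlap rule; the threshold is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import pandas as pd

#: Conserved-cysteine reference positions (1-based, ungapped) in human XPA.
DEFAULT_SIGNATURE_POSITIONS = (105, 106, 107, 108, 126, 127, 128,
                               261, 262, 263, 264)


def read_lineage_map(path: str | Path) -> dict[str, list[str]]:
    """Read a species -> lineage TSV: ``species<TAB>taxon1;taxon2;...``."""
    lineages: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            lineages[parts[0]] = [t for t in parts[1].split(";") if t]
    return lineages


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_annotations=False, suppress_rooting=True)


def _species_resolver(species_map: Mapping[str, str] | Callable[[str], str] | None
                      ) -> Callable[[str], str]:
    if species_map is None:
        return lambda label: label
    if callable(species_map):
        return species_map
    return lambda label: species_map[label]


def _leaf_species(node: dendropy.Node,
                  resolve: Callable[[str], str]) -> set[str]:
    return {resolve(leaf.taxon.label) for leaf in node.leaf_iter()}


def add_lineage(tree: dendropy.Tree, lineage_map: Mapping[str, Sequence[str]],
                species_map: Mapping[str, str] | Callable[[str], str] | None = None,
                ) -> dendropy.Tree:
    """Label every internal node with the deepest taxon shared by its leaves.

    Lineages are root->species ordered taxon lists and must agree on their
    first element.  The label lands both in ``node.label`` and in the node
    annotation ``lineage``.  Missing species raise an error listing them.
    """
    resolve = _species_resolver(species_map)
    missing = sorted({resolve(l.taxon.label) for l in tree.leaf_node_iter()}
                     - set(lineage_map))
    if missing:
        raise KeyError(f"species missing from lineage map: {missing}")
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        species = sorted(_leaf_species(node, resolve))
        lineages = [list(lineage_map[s]) for s in species]
        label = None
        for ranks in zip(*lineages):
            if len(set(ranks)) == 1:
                label = ranks[0]
            else:
                break
        if label is None:
            raise ValueError(
                f"leaf species {species} share no common lineage root")
        node.label = label
        node.annotations["lineage"] = label
    return tree


def label_duplication_nodes(tree: dendropy.Tree, min_shared: int = 2,
                            species_map: Mapping[str, str] | Callable[[str], str] | None = None,
                            ) -> dendropy.Tree:
    """Flag internal nodes whose child clades share >= min_shared species.

    The default (2) is the "more than one common species" rule.  At
    multifurcations every child pair is evaluated and any qualifying pair
    flags the node.  The flag is stored in the ``duplication`` annotation.
    """
    resolve = _species_resolver(species_map)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        sets = [_leaf_species(c, resolve) for c in children]
        flagged = any(len(sets[i] & sets[j]) >= min_shared
                      for i in range(len(sets))
                      for j in range(i + 1, len(sets)))
        node.annotations["duplication"] = flagged
    return tree


def duplication_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    return [n for n in tree.preorder_node_iter()
            if n.annotations.get_value("duplication")]


def presence_absence(species_list: Sequence[str],
                     homolog_assignments: Mapping[str, Mapping[str, str]],
                     ) -> pd.DataFrame:
    """Boolean species x gene matrix: has >= 1 accepted homolog.

    ``homolog_assignments`` maps gene name -> {protein_id: species_id}.
    Species appearing in assignments but not in ``species_list`` are excluded
    with a warning.
    """
    import warnings

    known = set(species_list)
    matrix = pd.DataFrame(False, index=list(species_list),
                          columns=list(homolog_assignments))
    for gene, proteins in homolog_assignments.items():
        stray = sorted({sp for sp in proteins.values() if sp not in known})
        if stray:
            warnings.warn(f"gene {gene!r}: species not in species list, "
                          f"excluded: {stray}", stacklevel=2)
        for species in proteins.values():
            if species in known:
                matrix.loc[species, gene] = True
    matrix.index.name = "species"
    return matrix


def clade_summary(matrix: pd.DataFrame,
                  clades: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-clade counts of species carrying each gene (present / total)."""
    rows = []
    for clade, members in clades.items():
        present = matrix.loc[[m for m in members if m in matrix.index]]
        row = {"clade": clade, "n_species": len(members)}
        for gene in matrix.columns:
            row[f"{gene}_present"] = int(present[gene].sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SignatureResult:
    columns: list[int]                 # 1-based alignment columns checked
    per_sequence: pd.DataFrame         # id, matches, fraction, passes
    per_column: pd.DataFrame           # column, ref_position, conservation


def map_reference_positions(reference_row: str,
                            positions: Sequence[int]) -> list[int]:
    """Map 1-based ungapped reference positions to 1-based alignment columns."""
    cols = []
    ungapped = 0
    lookup = {}
    for col, ch in enumerate(reference_row, start=1):
        if ch != "-":
            ungapped += 1
            lookup[ungapped] = col
    for pos in positions:
        if pos not in lookup:
            raise ValueError(
                f"reference position {pos} beyond ungapped reference length "
                f"{ungapped}")
        cols.append(lookup[pos])
    return cols


def signature_conservation(msa: Mapping[str, str] | Sequence[tuple[str, str]],
                           reference_id: str,
                           positions: Sequence[int] = DEFAULT_SIGNATURE_POSITIONS,
                           residue: str = "C",
                           pass_fraction: float = 0.7) -> SignatureResult:
    """Check signature-residue conservation across an alignment.

    Positions are reference-sequence coordinates (1-based, ungapped) mapped
    to alignment columns through the reference row's gap structure.  A
    sequence passes when at least ``pass_fraction`` of the signature columns
    carry ``residue``; per-column conservation over all rows is also
    reported.
    """
    rows = dict(msa) if not isinstance(msa, Mapping) else dict(msa)
    if reference_id not in rows:
        raise KeyError(f"reference row {reference_id!r} not in alignment")
    width = {len(s) for s in rows.values()}
    if len(width) != 1:
        raise ValueError("alignment rows have unequal lengths")
    cols = map_reference_positions(rows[reference_id], positions)

    per_seq = []
    for seq_id, seq in rows.items():
        matches = sum(seq[c - 1].upper() == residue for c in cols)
        frac = matches / len(cols)
        per_seq.append({"id": seq_id, "matches": matches,
                        "fraction": frac, "passes": frac >= pass_fraction})
    per_col = []
    for ref_pos, c in zip(positions, cols):
        conserved = sum(seq[c - 1].upper() == residue for seq in rows.values())
        per_col.append({"column": c, "ref_position": ref_pos,
                        "conservation": conserved / len(rows)})
    return SignatureResult(cols, pd.DataFrame(per_seq), pd.DataFrame(per_col))
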