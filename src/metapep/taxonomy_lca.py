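"""Peptide taxonomy by the lowest-common-ancestor (LCA) principle.

Query peptides are I/L-normalized, split into fully tryptic fragments
(missed cleavages), each fragment looked up against the peptide→taxon-set
map, the fragment results combined, and the LCA of the combined taxon set
reported together with a domain classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .data_io import (AMINO_ACIDS, AnnotationMaps, DataFormatError,
                      PeptideObservation, TaxonomyTree)

DOMAIN_CLASSES = ("bacterial", "archaeal", "eukaryotic", "ambiguous",
                  "unassigned")

_DOMAIN_NAME_TO_CLASS = {
    "Bacteria": "bacterial",
    "Archaea": "archaeal",
    "Eukaryota": "eukaryotic",
}


@dataclass(frozen=True)
class TaxonAssignment:
    """LCA outcome for one normalized peptide."""

    peptide: str
    lca_taxon: str  # taxon_id, or "unassigned"
    domain_class: str

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"bad domain_class {self.domain_class!r}")


def normalize_peptide(peptide: str) -> str:
    """Equate isoleucine and leucine: every I becomes L.  Idempotent."""
    bad = set(peptide) - AMINO_ACIDS
    if bad:
        raise DataFormatError(
            f"peptide {peptide!r} contains non-standard residues "
            f"{sorted(bad)}")
    return peptide.replace("I", "L")


def tryptic_fragments(peptide: str) -> list[str]:
    """Fully tryptic fragments: cut after K or R unless followed by P.

    The fragments concatenate back to the input; a peptide without an
    internal cleavage site is returned unchanged as a single fragment.
    """
    if not peptide:
        raise DataFormatError("empty peptide")
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(peptide[:-1]):
        if aa in "KR" and peptide[i + 1] != "P":
            fragments.append(peptide[start:i + 1])
            start = i + 1
    fragments.append(peptide[start:])
    return fragments


def lowest_common_ancestor(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Deepest node ancestral to (or equal to) every taxon in ``taxa``.

    Implemented by climbing: walk the deeper node up until both are at
    equal depth, then walk both up together, folding pairwise over the set.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("LCA of an empty taxon set")
    lca = taxa[0]
    for t in taxa[1:]:
        a, b = lca, t
        while tree.depth(a) > tree.depth(b):
            a = tree.parent(a)
        while tree.depth(b) > tree.depth(a):
            b = tree.parent(b)
        while a != b:
            a, b = tree.parent(a), tree.parent(b)
        lca = a
    return lca


def _classify_domain(taxa: frozenset[str], lca: str,
                     tree: TaxonomyTree) -> str:
    domain = tree.domain_of(lca)
    if domain is not None:
        return _DOMAIN_NAME_TO_CLASS.get(tree.name(domain), "ambiguous")
    # LCA sits above the domain rank: ambiguous when the matched taxa span
    # at least two domains (or themselves sit above any domain node)
    return "ambiguous"


def assign_lca(peptide: str, maps: AnnotationMaps, tree: TaxonomyTree,
               combine: Literal["intersection", "union"] = "intersection",
               ) -> TaxonAssignment:
    """Assign the LCA taxon and domain class to one peptide.

    The peptide is normalized and split into tryptic fragments; each
    fragment's taxon set is looked up (duplicates within a fragment are
    inherently collapsed by the set representation).  Under the default
    ``intersection`` combining, *every* fragment must have at least one
    match and the peptide's taxon set is the intersection over fragments;
    any unmatched fragment, or an empty intersection, yields
    ``unassigned``.  Under ``union``, fragments with matches are unioned
    and only a fully unmatched peptide is unassigned.
    """
    norm = normalize_peptide(peptide)
    fragment_sets = [maps.peptide_to_taxa.get(f)
                     for f in tryptic_fragments(norm)]
    if combine == "intersection":
        if any(s is None for s in fragment_sets):
            return TaxonAssignment(norm, "unassigned", "unassigned")
        taxa = frozenset.intersection(*fragment_sets)
    elif combine == "union":
        matched = [s for s in fragment_sets if s is not None]
        taxa = frozenset.union(*matched) if matched else frozenset()
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    if not taxa:
        return TaxonAssignment(norm, "unassigned", "unassigned")
    lca = lowest_common_ancestor(taxa, tree)
    return TaxonAssignment(norm, lca, _classify_domain(taxa, lca, tree))


def assign_all(peptides: Iterable[str], maps: AnnotationMaps,
               tree: TaxonomyTree,
               combine: Literal["intersection", "union"] = "intersection",
               ) -> dict[str, TaxonAssignment]:
    """assign_lca over distinct peptides, keyed by the *input* peptide."""
    return {p: assign_lca(p, maps, tree, combine=combine)
            for p in set(peptides)}


def domain_fractions(assignments: dict[str, TaxonAssignment],
                     observations: Iterable[PeptideObservation],
                     weighting: Literal["peptide", "spectrum"] = "peptide",
                     ):
    """Per-sample percentages of bacterial/archaeal/eukaryotic/ambiguous.

    Percentages are computed over taxonomically *assigned* peptides only
    (the unassigned class is excluded from the denominator).  With
    ``weighting="peptide"`` each distinct peptide counts once; with
    ``"spectrum"`` peptides are weighted by their spectral counts.
    Returns a pandas DataFrame, classes x samples, columns summing to 100.
    """
    import pandas as pd

    classes = ("bacterial", "archaeal", "eukaryotic", "ambiguous")
    per_sample: dict[str, dict[str, float]] = {}
    for obs in observations:
        a = assignments.get(obs.peptide)
        if a is None:
            a = assignments.get(obs.peptide.replace("I", "L"))
        if a is None or a.domain_class == "unassigned":
            continue
        w = obs.spectral_count if weighting == "spectrum" else 1
        bucket = per_sample.setdefault(obs.sample_id,
                                       {c: 0.0 for c in classes})
        bucket[a.domain_class] += w
    if not per_sample:
        raise ValueError("no sample has any domain-assigned peptide")
    out = {}
    for sample, bucket in per_sample.items():
        total = sum(bucket.values())
        if total == 0:
            raise ValueError(f"sample {sample!r} has no assigned peptides")
        out[sample] = {c: 100.0 * bucket[c] / total for c in classes}
    df = pd.DataFrame(out).reindex(list(classes))
    return df[sorted(df.columns)]


def chordata_subset(assignments: dict[str, TaxonAssignment],
                    tree: TaxonomyTree,
                    host_clade: str = "Chordata") -> set[str]:
    """Peptides whose LCA is the host clade or one of its descendants.

    Assignments at ancestors of the clade (e.g. a whole-domain LCA) are
    excluded: only "at least host-clade" specificity qualifies.
    """
    clade_id = tree.find_by_name(host_clade)
    if clade_id is None:
        raise DataFormatError(
            f"taxon named {host_clade!r} not found in the taxonomy; set the "
            f"host clade name in the configuration (host_clade = <name>)")
    return {p for p, a in assignments.items()
            if a.lca_taxon != "unassigned"
            and tree.is_descendant(a.lca_taxon, clade_id)}


def write_assignments(assignments: dict[str, TaxonAssignment],
                      path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tlca_taxon\tdomain_class\n")
        for p in sorted(assignments):
            a = assignments[p]
            fh.write(f"{p}\t{a.lca_taxon}\t{a.domain_class}\n")
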