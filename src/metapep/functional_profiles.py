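"""Spectral-count aggregation into functional and taxonomic profiles.

Spectra per peptide are summed per feature class (KO, COG, COG family,
taxon at a rank, or a taxon-restricted KO profile), optionally filtered
by a max-per-sample abundance threshold, and converted to per-sample
relative percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .data_io import (AbundanceMatrix, AnnotationMaps, DataFormatError,
                      PeptideObservation, TaxonomyTree, RANKS, UNASSIGNED)
from .taxonomy_lca import TaxonAssignment, normalize_peptide


@dataclass(frozen=True)
class ProfileLevel:
    """What to aggregate spectra into.

    ``kind`` is one of peptide | KO | COG | COG_family | taxon_rank |
    taxon_restricted.  ``rank`` is required for taxon_rank;
    ``taxon_id`` (plus KO features) for taxon_restricted.
    """

    kind: str
    rank: str | None = None
    taxon_id: str | None = None

    def __post_init__(self) -> None:
        kinds = ("peptide", "KO", "COG", "COG_family", "taxon_rank",
                 "taxon_restricted")
        if self.kind not in kinds:
            raise DataFormatError(f"unknown profile level {self.kind!r}")
        if self.kind == "taxon_rank" and self.rank not in RANKS:
            raise DataFormatError(
                f"taxon_rank level needs a valid rank, got {self.rank!r}")
        if self.kind == "taxon_restricted" and not self.taxon_id:
            raise DataFormatError("taxon_restricted level needs a taxon_id")


def _peptide_features(peptide: str, level: ProfileLevel,
                      maps: AnnotationMaps,
                      assignments: dict[str, TaxonAssignment] | None,
                      tree: TaxonomyTree | None) -> frozenset[str]:
    """Feature ids a peptide contributes to at this level (may be empty)."""
    norm = normalize_peptide(peptide)
    if level.kind == "peptide":
        return frozenset([norm])
    if level.kind == "KO":
        return maps.peptide_to_kos.get(peptide,
                                       maps.peptide_to_kos.get(norm,
                                                               frozenset()))
    if level.kind == "COG":
        cogs = maps.peptide_to_cogs.get(peptide,
                                        maps.peptide_to_cogs.get(
                                            norm, frozenset()))
        return frozenset(cog for cog, _ in cogs)
    if level.kind == "COG_family":
        fams = maps.cog_families(peptide) or maps.cog_families(norm)
        if not fams:
            return frozenset()
        if len(fams) > 1:
            return frozenset(["ambiguous"])
        return fams
    # taxon levels need an LCA assignment
    if assignments is None or tree is None:
        raise DataFormatError(
            "taxon-level aggregation requires LCA assignments and a tree")
    a = assignments.get(peptide, assignments.get(norm))
    if a is None or a.lca_taxon == "unassigned":
        return frozenset()
    if level.kind == "taxon_rank":
        # a peptide counts at rank r only if its LCA is at or below r
        anc = tree.ancestor_at_rank(a.lca_taxon, level.rank)
        return frozenset([anc]) if anc is not None else frozenset()
    # taxon_restricted: KO features of peptides whose LCA lies within taxon
    if not tree.is_descendant(a.lca_taxon, level.taxon_id):
        return frozenset()
    return maps.peptide_to_kos.get(peptide,
                                   maps.peptide_to_kos.get(norm, frozenset()))


def aggregate(observations: Iterable[PeptideObservation],
              maps: AnnotationMaps,
              level: ProfileLevel,
              assignments: dict[str, TaxonAssignment] | None = None,
              tree: TaxonomyTree | None = None,
              share: Literal["full", "fractional"] = "full",
              include_unassigned: bool = True) -> AbundanceMatrix:
    """Sum spectral counts per (feature, sample) at the requested level.

    A peptide mapping to k > 1 features contributes its full count to each
    feature under ``share="full"`` (the default), or 1/k of it under
    ``share="fractional"``.  Spectra from peptides with no feature at this
    level are collected under the explicit ``unassigned`` feature when
    ``include_unassigned`` is set, so that aggregate + unassigned always
    accounts for every spectrum.
    """
    cells: dict[str, dict[str, float]] = {}
    samples: list[str] = []
    for obs in observations:
        if obs.sample_id not in cells:
            cells[obs.sample_id] = {}
            samples.append(obs.sample_id)
        feats = _peptide_features(obs.peptide, level, maps, assignments,
                                  tree)
        col = cells[obs.sample_id]
        if not feats:
            if include_unassigned:
                col[UNASSIGNED] = col.get(UNASSIGNED, 0) + obs.spectral_count
            continue
        w = (obs.spectral_count / len(feats) if share == "fractional"
             else obs.spectral_count)
        for f in feats:
            col[f] = col.get(f, 0) + w
    df = pd.DataFrame(cells).fillna(0.0)
    df = df.reindex(sorted(df.index))[sorted(samples)]
    return AbundanceMatrix(df, scale="counts")


def abundance_filter(matrix: AbundanceMatrix,
                     min_max_count: int) -> AbundanceMatrix:
    """Keep features reaching ``min_max_count`` spectra in >=1 sample."""
    if matrix.scale != "counts":
        raise DataFormatError("abundance_filter requires a counts matrix")
    if min_max_count < 1:
        raise DataFormatError("min_max_count must be >= 1")
    keep = matrix.df.max(axis=1) >= min_max_count
    return AbundanceMatrix(matrix.df.loc[keep], scale="counts")


def to_percent(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Column-wise conversion to relative percentages (sum to 100)."""
    if matrix.scale != "counts":
        raise DataFormatError("to_percent requires a counts matrix")
    totals = matrix.df.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataFormatError(
            f"samples with zero total count: {list(zero.index)}")
    return AbundanceMatrix(100.0 * matrix.df / totals, scale="percent")


def cog_family_profile(observations: Iterable[PeptideObservation],
                       maps: AnnotationMaps) -> AbundanceMatrix:
    """Per-sample percent distribution over COG family letters.

    Peptides whose COGs span more than one family are pooled under
    ``ambiguous``; peptides with no COG annotation under ``unassigned``.
    Columns sum to 100.
    """
    counts = aggregate(observations, maps, ProfileLevel("COG_family"),
                       include_unassigned=True)
    return to_percent(counts)
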