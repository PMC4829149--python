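"""Gut metabolic module (GMM) detection and abundance scoring.

A module lists alternative pathways; each pathway is an ordered list of
steps; each step is a set of interchangeable KOs.  For one sample's KO
counts, a step's abundance is the max count over its alternative KOs,
pathway coverage is the fraction of steps with positive abundance, the
best pathway is the one with the highest coverage (ties broken by higher
median abundance, then lower index), the module is detected when the best
coverage strictly exceeds 2/3, and module abundance is the median step
abundance of the best pathway (zero when not detected).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping

import pandas as pd

from .data_io import AbundanceMatrix, ModuleDefinition

DETECTION_THRESHOLD = 2.0 / 3.0  # strict: coverage must exceed this


@dataclass(frozen=True)
class GmmResult:
    module_id: str
    best_pathway_index: int
    coverage: float
    detected: bool
    abundance: float


def score_module(module: ModuleDefinition,
                 ko_abundance: Mapping[str, float]) -> GmmResult:
    """Score one module against one sample's KO counts (absent KO = 0)."""
    best: tuple[float, float, int] | None = None  # (coverage, median, -idx)
    for idx, pathway in enumerate(module.pathways):
        step_abundances = [max((ko_abundance.get(ko, 0.0) for ko in step),
                               default=0.0)
                           for step in pathway]
        coverage = sum(a > 0 for a in step_abundances) / len(step_abundances)
        med = float(median(step_abundances))
        key = (coverage, med, -idx)
        if best is None or key > best:
            best = key
    coverage, med, neg_idx = best
    detected = coverage > DETECTION_THRESHOLD
    return GmmResult(module_id=module.module_id,
                     best_pathway_index=-neg_idx,
                     coverage=coverage,
                     detected=detected,
                     abundance=med if detected else 0.0)


def score_all(modules: Iterable[ModuleDefinition],
              ko_matrix: AbundanceMatrix) -> dict[str, pd.DataFrame]:
    """Score every module against every sample of a KO counts matrix.

    Returns ``{"coverage": df, "abundance": df, "detected": df}``, each a
    module x sample DataFrame, plus a ``"summary"`` Series flagging the
    modules detected in at least one sample.
    """
    modules = list(modules)
    cov, abund, det = {}, {}, {}
    for sample in ko_matrix.sample_ids:
        counts = ko_matrix.df[sample].to_dict()
        c, a, d = {}, {}, {}
        for mod in modules:
            res = score_module(mod, counts)
            c[mod.module_id] = res.coverage
            a[mod.module_id] = res.abundance
            d[mod.module_id] = res.detected
        cov[sample], abund[sample], det[sample] = c, a, d
    index = [m.module_id for m in modules]
    coverage = pd.DataFrame(cov).reindex(index)
    abundance = pd.DataFrame(abund).reindex(index)
    detected = pd.DataFrame(det).reindex(index)
    return {
        "coverage": coverage,
        "abundance": abundance,
        "detected": detected,
        "summary": detected.any(axis=1),
    }
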