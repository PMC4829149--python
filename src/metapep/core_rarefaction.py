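"""Bootstrap rarefaction of accumulated and shared (core) KOs.

All samples of an individual are pooled into one KO presence set; at each
interval n, subjects are drawn without replacement and the sizes of the
union (accumulation) and the intersection (core) of the drawn sets are
recorded over bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix, SampleMeta


@dataclass
class RarefactionCurve:
    """Bootstrap distribution of a set-size statistic per interval n."""

    statistic: str  # "accumulation" | "core"
    intervals: list[int]
    bootstrap_counts: dict[int, np.ndarray] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for n in self.intervals:
            counts = self.bootstrap_counts[n]
            rows.append({
                "n": n,
                "statistic": self.statistic,
                "mean": float(np.mean(counts)),
                "q025": float(np.quantile(counts, 0.025)),
                "q975": float(np.quantile(counts, 0.975)),
            })
        return pd.DataFrame(rows)


def per_individual_ko_sets(ko_matrix: AbundanceMatrix,
                           meta: Iterable[SampleMeta],
                           ) -> dict[str, frozenset[str]]:
    """Union of KOs with count > 0 over each subject's samples."""
    meta = list(meta)
    subjects = sorted({m.subject_id for m in meta})
    by_subject: dict[str, list[str]] = {s: [] for s in subjects}
    for m in meta:
        by_subject[m.subject_id].append(m.sample_id)
    out: dict[str, frozenset[str]] = {}
    for subject, samples in by_subject.items():
        samples = [s for s in samples if s in ko_matrix.df.columns]
        if not samples:
            raise ValueError(f"subject {subject!r} has no samples in the "
                             f"KO matrix")
        present = ko_matrix.df[samples].sum(axis=1) > 0
        out[subject] = frozenset(ko_matrix.df.index[present])
    return out


def rarefy(ko_sets: Mapping[str, frozenset[str]],
           intervals: Sequence[int],
           replicates: int = 1000,
           seed: int = 0) -> tuple[RarefactionCurve, RarefactionCurve]:
    """Bootstrap accumulation and core curves over subject subsets.

    At each interval n, ``replicates`` subsets of n subjects are drawn
    uniformly *without replacement*; accumulation is the size of the union
    of their KO sets and core the size of the intersection.  Fully
    reproducible for a given seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    subjects = sorted(ko_sets)
    k = len(subjects)
    for n in intervals:
        if not 1 <= n <= k:
            raise ValueError(
                f"interval {n} outside 1..{k} (number of subjects)")
    rng = np.random.default_rng(seed)
    acc = RarefactionCurve("accumulation", list(intervals))
    core = RarefactionCurve("core", list(intervals))
    for n in intervals:
        acc_counts = np.empty(replicates, dtype=int)
        core_counts = np.empty(replicates, dtype=int)
        for r in range(replicates):
            drawn = rng.choice(k, size=n, replace=False)
            sets = [ko_sets[subjects[i]] for i in drawn]
            acc_counts[r] = len(frozenset.union(*sets))
            core_counts[r] = len(frozenset.intersection(*sets))
        acc.bootstrap_counts[n] = acc_counts
        core.bootstrap_counts[n] = core_counts
    return acc, core


def curves_to_table(acc: RarefactionCurve,
                    core: RarefactionCurve) -> pd.DataFrame:
    return pd.concat([acc.summary(), core.summary()], ignore_index=True)
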