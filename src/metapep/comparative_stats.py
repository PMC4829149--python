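"""Comparative statistics for metaproteome profiles.

Covers presence/absence Jaccard clustering of identified peptides,
1 - Pearson correlation clustering of abundance profiles, the
human x bacterial Spearman correlation screen with FDR-adjusted q-values,
the bacterial/eukaryotic ratio group analysis (Fisher exact test plus a
paired Wilcoxon check), Shannon diversity, and per-phylum concordance
between spectral counts and 16S-based relative abundances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import AbundanceMatrix, PeptideObservation, SampleMeta
from .taxonomy_lca import TaxonAssignment


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Complete-linkage merge tree over samples, serializable as Newick."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k flat clusters; returns sample -> cluster id."""
        assignments = hierarchy.fcluster(self.linkage, t=k,
                                         criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.get_left(), node.dist)
            right = fmt(node.get_right(), node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = fmt(root.get_left(), root.dist)
        right = fmt(root.get_right(), root.dist)
        return f"({left},{right});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def jaccard_distance(a: frozenset | set, b: frozenset | set) -> float:
    """1 - |A n B| / |A u B|; both sets must be non-empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard distance of two empty sets")
    return 1.0 - len(a & b) / union


def _complete_linkage(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(labels=labels, linkage=linkage)


def jaccard_cluster(peptide_presence: Mapping[str, frozenset | set],
                    ) -> Dendrogram:
    """Complete-linkage clustering of samples by peptide Jaccard distance.

    Samples are ordered lexicographically by id, which fixes tie-breaking.
    """
    labels = sorted(peptide_presence)
    if len(labels) < 2:
        raise ValueError("need at least two samples to cluster")
    for s in labels:
        if not peptide_presence[s]:
            raise ValueError(f"sample {s!r} has an empty peptide set")
    m = len(labels)
    dist = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        d = jaccard_distance(peptide_presence[labels[i]],
                             peptide_presence[labels[j]])
        dist[i, j] = dist[j, i] = d
    return _complete_linkage(dist, labels)


def correlation_cluster(matrix: AbundanceMatrix) -> Dendrogram:
    """Complete-linkage clustering with d = 1 - Pearson r between samples."""
    labels = sorted(matrix.sample_ids)
    if len(labels) < 2:
        raise ValueError("need at least two samples to cluster")
    values = matrix.df[labels].values
    sd = values.std(axis=0)
    zero_var = [labels[i] for i in np.flatnonzero(sd == 0)]
    if zero_var:
        raise ValueError(f"zero-variance sample columns: {zero_var}")
    r = np.corrcoef(values, rowvar=False)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return _complete_linkage(dist, labels)


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def qvalues(p: np.ndarray,
            method: Literal["bh", "storey"] = "bh") -> np.ndarray:
    """FDR-adjusted p-values: Benjamini-Hochberg, optionally scaled by a
    Storey pi0 estimate (cubic-smoother over a lambda grid)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        q = np.minimum(_storey_pi0(p) * q, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    return q


def _storey_pi0(p: np.ndarray) -> float:
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0 = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
    from scipy.interpolate import UnivariateSpline

    spline = UnivariateSpline(lambdas, pi0, k=3)
    est = float(spline(lambdas[-1]))
    return float(np.clip(est, 1e-8, 1.0))


# ---------------------------------------------------------------------------
# human x bacterial correlation screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationRecord:
    human_ko: str
    bacterial_ko: str
    rho: float
    p_value: float
    q_value: float


def _spearman_p_exact(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p-value for small n (< 10)."""
    n = len(rx)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        hits += r >= obs - 1e-12
        total += 1
    return hits / total


def correlate_human_bacterial(human_ko: AbundanceMatrix,
                              bacterial_ko: AbundanceMatrix,
                              alpha: float = 0.05,
                              p_threshold: float = 0.05,
                              method: Literal["bh", "storey"] = "bh",
                              ) -> tuple[list[CorrelationRecord],
                                         pd.DataFrame]:
    """Spearman correlation of every human x bacterial KO pair.

    Mid-rank ties; two-sided p via the t approximation for n >= 10 and
    exact permutation below that; q-values over the full pair family.
    Returns the records passing both p < ``p_threshold`` and
    q < ``alpha``, plus the full table of all pairs.
    """
    common = sorted(set(human_ko.sample_ids) & set(bacterial_ko.sample_ids))
    n = len(common)
    if n < 4:
        raise ValueError(
            f"only {n} shared samples; need >= 4 for a meaningful rho")
    h = human_ko.df[common]
    b = bacterial_ko.df[common]
    hr = np.apply_along_axis(stats.rankdata, 1, h.values)
    br = np.apply_along_axis(stats.rankdata, 1, b.values)

    def _standardize(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan  # constant features yield rho = nan
        return m / sd

    hz, bz = _standardize(hr), _standardize(br)
    rho = hz @ bz.T / n  # (n_human, n_bacterial)
    if n >= 10:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.clip(1 - rho ** 2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        p = np.empty_like(rho)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                p[i, j] = (np.nan if np.isnan(rho[i, j])
                           else _spearman_p_exact(hr[i], br[j]))
    flat_p = p.ravel()
    valid = ~np.isnan(flat_p)
    q = np.full_like(flat_p, np.nan)
    if valid.any():
        q[valid] = qvalues(flat_p[valid], method=method)
    q = q.reshape(p.shape)

    human_ids = np.repeat(h.index.values, len(b.index))
    bact_ids = np.tile(b.index.values, len(h.index))
    full = pd.DataFrame({
        "human_ko": human_ids,
        "bacterial_ko": bact_ids,
        "rho": rho.ravel(),
        "p_value": p.ravel(),
        "q_value": q.ravel(),
    })
    hits = full[(full.p_value < p_threshold) & (full.q_value < alpha)]
    records = [CorrelationRecord(r.human_ko, r.bacterial_ko, float(r.rho),
                                 float(r.p_value), float(r.q_value))
               for r in hits.itertuples()]
    return records, full


# ---------------------------------------------------------------------------
# bacterial/eukaryotic ratio group analysis
# ---------------------------------------------------------------------------

@dataclass
class RatioGroupResult:
    ratios: pd.DataFrame          # columns sample_id, subject_id, tp, ratio
    trajectories: pd.DataFrame    # time_point x subject ratio matrix
    cluster_labels: dict[str, int]
    contingency: np.ndarray       # 2 x 2 cluster x group
    fisher_p: float
    wilcoxon_p: float | None      # TP1 vs TP2 within the probiotic group


def ratio_group_test(assignments: dict[str, TaxonAssignment],
                     observations: Iterable[PeptideObservation],
                     meta: Iterable[SampleMeta],
                     pseudocount: float = 0.0) -> RatioGroupResult:
    """Bacterial-to-eukaryotic spectral ratio per sample, clustered per
    subject trajectory, with a Fisher exact cluster x group test.

    Per-subject 3-time-point ratio trajectories are compared with Pearson
    correlation (distance 1 - r), complete linkage, cut into 2 clusters;
    the 2x2 cluster-membership x study-group table is tested with a
    two-sided Fisher exact test.  A paired two-sided Wilcoxon signed-rank
    test of TP1 vs TP2 ratios within the probiotic group is also run.
    """
    meta = list(meta)
    by_sample = {m.sample_id: m for m in meta}
    counts: dict[str, dict[str, float]] = {}
    for obs in observations:
        a = assignments.get(obs.peptide,
                            assignments.get(obs.peptide.replace("I", "L")))
        if a is None:
            continue
        col = counts.setdefault(obs.sample_id, {"bacterial": 0.0,
                                                "eukaryotic": 0.0})
        if a.domain_class in col:
            col[a.domain_class] += obs.spectral_count
    rows = []
    for sample, col in sorted(counts.items()):
        euk = col["eukaryotic"] + pseudocount
        if euk == 0:
            raise ValueError(
                f"sample {sample!r} has no eukaryotic spectra; pass "
                f"pseudocount > 0 to stabilise the ratio")
        m = by_sample[sample]
        rows.append({"sample_id": sample, "subject_id": m.subject_id,
                     "time_point": m.time_point,
                     "group": m.group,
                     "ratio": (col["bacterial"] + pseudocount) / euk})
    ratios = pd.DataFrame(rows)
    traj = ratios.pivot(index="time_point", columns="subject_id",
                        values="ratio").sort_index()
    if traj.isna().any().any():
        raise ValueError("incomplete ratio trajectories (missing samples)")

    subjects = sorted(traj.columns)
    values = traj[subjects].values
    r = np.corrcoef(values, rowvar=False)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dend = _complete_linkage(dist, subjects)
    labels = dend.cut(2)

    group_of = {m.subject_id: m.group for m in meta}
    table = np.zeros((2, 2), dtype=int)
    for s in subjects:
        i = labels[s] - 1
        j = 0 if group_of[s] == "placebo" else 1
        table[i, j] += 1
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])

    wilcoxon_p: float | None = None
    prob_subjects = [s for s in subjects if group_of[s] == "probiotic"]
    if prob_subjects and {1, 2} <= set(traj.index):
        tp1 = traj.loc[1, prob_subjects].values
        tp2 = traj.loc[2, prob_subjects].values
        diff = tp1 - tp2
        if np.any(diff != 0):
            wilcoxon_p = float(stats.wilcoxon(
                tp1, tp2, alternative="two-sided").pvalue)
        else:
            wilcoxon_p = 1.0
    return RatioGroupResult(ratios=ratios, trajectories=traj,
                            cluster_labels=labels, contingency=table,
                            fisher_p=fisher_p, wilcoxon_p=wilcoxon_p)


# ---------------------------------------------------------------------------
# diversity and cross-platform concordance
# ---------------------------------------------------------------------------

def shannon(relative_abundances: Iterable[float]) -> float:
    """Shannon index H = -sum p_i ln p_i over renormalized proportions."""
    x = np.asarray(list(relative_abundances), dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def phylum_concordance(proteome_phyla: AbundanceMatrix,
                       sixteen_s_phyla: AbundanceMatrix,
                       method: Literal["bh", "storey"] = "bh",
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phylum Pearson correlation between spectral-count and 16S
    relative abundances across shared samples.

    Phyla present on only one platform are excluded with a warning.
    Returns (per-phylum r/p/q table, paired distribution summary with
    median and quartiles per phylum per platform for split-violin plots).
    """
    import logging

    log = logging.getLogger("metapep")
    samples = sorted(set(proteome_phyla.sample_ids)
                     & set(sixteen_s_phyla.sample_ids))
    if len(samples) < 3:
        raise ValueError("need >= 3 shared samples")
    shared = sorted(set(proteome_phyla.feature_ids)
                    & set(sixteen_s_phyla.feature_ids))
    only = (set(proteome_phyla.feature_ids)
            ^ set(sixteen_s_phyla.feature_ids))
    for ph in sorted(only):
        log.warning("phylum %r present on one platform only; excluded", ph)
    rows, summary_rows = [], []
    pvals = []
    for ph in shared:
        x = proteome_phyla.df.loc[ph, samples].values
        y = sixteen_s_phyla.df.loc[ph, samples].values
        if x.std() == 0 or y.std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"phylum": ph, "r": r, "p_value": p})
        pvals.append(p)
        for platform, v in (("proteome", x), ("16S", y)):
            summary_rows.append({
                "phylum": ph, "platform": platform,
                "median": float(np.median(v)),
                "q25": float(np.quantile(v, 0.25)),
                "q75": float(np.quantile(v, 0.75)),
            })
    per_phylum = pd.DataFrame(rows)
    pvals = np.asarray(pvals, dtype=float)
    q = np.full(len(pvals), np.nan)
    valid = ~np.isnan(pvals)
    if valid.any():
        q[valid] = qvalues(pvals[valid], method=method)
    per_phylum["q_value"] = q
    return per_phylum, pd.DataFrame(summary_rows)
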