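"""Synthetic faecal-metaproteome cohort generator.

Produces everything the pipeline consumes: a taxonomy with four bacterial
phyla, an archaeal lineage and a Chordata lineage; bacterial/human KO
catalogues partitioned into a common core, per-subject cores and a rare
tail; a peptide universe with taxonomic and functional annotations
(including taxonomically degenerate peptides, missed-cleavage peptides and
I/L spelling variants); per-sample spectral counts drawn from a
Dirichlet-multinomial hierarchy that makes profiles personalised and
temporally stable; a module catalogue; and a matched 16S-style relative
abundance table with a configurable planted cross-platform correlation.

Everything is reproducible bit-for-bit from the seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .data_io import (AbundanceMatrix, AnnotationMaps, ModuleDefinition,
                      PeptideObservation, SampleMeta, TaxonNode,
                      TaxonomyTree)
from .taxonomy_lca import lowest_common_ancestor

_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
_WORD_ALPHABET = "ACDEFGHLMNQSTVWY"  # no K/R/P/I: canonical tryptic words
_COG_FAMILIES = "GECJKLMPTOU"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are desk-scale versions of
    the study design (16 subjects x 3 time points, 8/8 group split)."""

    n_subjects: int = 16
    time_points: int = 3
    n_placebo: int = 8
    n_bacterial_kos: int = 300
    n_human_kos: int = 73
    n_archaeal_kos: int = 5
    common_core_kos: int = 100
    subject_core_size: int = 8
    peptides_per_ko: int = 4
    spectra_per_sample: int = 4000
    eukaryotic_fraction: float = 0.14
    archaeal_fraction: float = 0.005
    degenerate_fraction: float = 0.10
    cross_domain_fraction: float = 0.01
    missed_cleavage_fraction: float = 0.10
    unmapped_fraction: float = 0.04
    il_swap_fraction: float = 0.20
    ambiguous_cog_fraction: float = 0.05
    base_core_weight: float = 10.0
    base_pool_weight: float = 0.5
    base_tail_weight: float = 0.2
    subject_core_boost: float = 20.0
    dirichlet_scale: float = 0.5
    temporal_sigma: float = 0.3
    probiotic_effect: float = 0.0
    n_effect_kos: int = 10
    cross_platform_rho: float = 0.7
    n_planted_pairs: int = 0
    n_modules: int = 12
    n_genera_per_phylum: int = 3
    n_species_per_genus: int = 2
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.eukaryotic_fraction, self.archaeal_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("domain fractions must lie in [0,1] and sum "
                             "to < 1")
        for name in ("n_subjects", "time_points", "n_bacterial_kos",
                     "n_human_kos", "common_core_kos", "peptides_per_ko",
                     "spectra_per_sample", "n_genera_per_phylum",
                     "n_species_per_genus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        need = (self.common_core_kos
                + self.n_subjects * self.subject_core_size)
        if need > self.n_bacterial_kos:
            raise ValueError(
                f"common core ({self.common_core_kos}) plus subject cores "
                f"({self.n_subjects} x {self.subject_core_size}) exceed the "
                f"bacterial KO catalogue ({self.n_bacterial_kos})")
        if not 0 <= self.n_placebo <= self.n_subjects:
            raise ValueError("n_placebo out of range")
        if not -1 < self.cross_platform_rho < 1:
            raise ValueError("cross_platform_rho must lie in (-1, 1)")


@dataclass
class PeptideTruth:
    peptide: str          # canonical (I/L-normalized) sequence
    emitted: str          # spelling used in the sample tables
    ko: str
    category: str         # simple|degenerate|missed_cleavage|cross_domain|unmapped
    taxa: frozenset[str]  # combined taxon set (empty if unmapped)
    lca: str
    domain_class: str


@dataclass
class CohortBundle:
    """Everything the analysis consumes, plus ground truth for tests."""

    config: GeneratorConfig
    meta: list[SampleMeta]
    observations: list[PeptideObservation]
    tree: TaxonomyTree
    maps: AnnotationMaps
    modules: list[ModuleDefinition]
    sixteen_s_phyla: AbundanceMatrix
    sixteen_s_genera: AbundanceMatrix
    peptide_truth: dict[str, PeptideTruth]
    subject_profiles: pd.DataFrame       # bacterial KO x subject weights
    expected_phyla: pd.DataFrame         # phylum x sample percent (of bacteria)
    planted_pairs: list[tuple[str, str]]
    bacterial_kos: list[str] = field(default_factory=list)
    human_kos: list[str] = field(default_factory=list)
    core_kos: list[str] = field(default_factory=list)
    subject_core_kos: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def _build_taxonomy(cfg: GeneratorConfig) -> tuple[TaxonomyTree, list[str]]:
    """Fixed-shape taxonomy; returns the tree and the bacterial species."""
    nodes = [TaxonNode("root", "root", "root", "root"),
             TaxonNode("Bacteria", "root", "domain", "Bacteria"),
             TaxonNode("Archaea", "root", "domain", "Archaea"),
             TaxonNode("Eukaryota", "root", "domain", "Eukaryota")]
    species: list[str] = []
    for phylum in _PHYLA:
        nodes.append(TaxonNode(phylum, "Bacteria", "phylum", phylum))
        for mid_rank in ("class", "order", "family"):
            child = f"{phylum}_{mid_rank}"
            parent = (phylum if mid_rank == "class"
                      else f"{phylum}_" + {"order": "class",
                                           "family": "order"}[mid_rank])
            nodes.append(TaxonNode(child, parent, mid_rank, child))
        for g in range(cfg.n_genera_per_phylum):
            genus = f"{phylum}_genus{g + 1}"
            nodes.append(TaxonNode(genus, f"{phylum}_family", "genus", genus))
            for s in range(cfg.n_species_per_genus):
                sp = f"{genus}_sp{s + 1}"
                nodes.append(TaxonNode(sp, genus, "species", sp))
                species.append(sp)
    # archaeal lineage
    arch = [("Euryarchaeota", "Archaea", "phylum"),
            ("Methanobacteria", "Euryarchaeota", "class"),
            ("Methanobacteriales", "Methanobacteria", "order"),
            ("Methanobacteriaceae", "Methanobacteriales", "family"),
            ("Methanobrevibacter", "Methanobacteriaceae", "genus"),
            ("Methanobrevibacter_smithii", "Methanobrevibacter", "species")]
    # host lineage (two hominid species so "at least Chordata" is exercised)
    euk = [("Chordata", "Eukaryota", "phylum"),
           ("Mammalia", "Chordata", "class"),
           ("Primates", "Mammalia", "order"),
           ("Hominidae", "Primates", "family"),
           ("Homo", "Hominidae", "genus"),
           ("Homo_sapiens", "Homo", "species"),
           ("Pan", "Hominidae", "genus"),
           ("Pan_troglodytes", "Pan", "species")]
    for tid, parent, rank in arch + euk:
        nodes.append(TaxonNode(tid, parent, rank, tid))
    return TaxonomyTree(nodes), species


# ---------------------------------------------------------------------------
# peptide universe
# ---------------------------------------------------------------------------

def _tryptic_word(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        length = int(rng.integers(6, 12))
        body = "".join(rng.choice(list(_WORD_ALPHABET), size=length))
        word = body + ("K" if rng.random() < 0.5 else "R")
        if word not in used:
            used.add(word)
            return word


def _maybe_il_variant(rng: np.random.Generator, cfg: GeneratorConfig,
                      canonical: str) -> str:
    if "L" in canonical and rng.random() < cfg.il_swap_fraction:
        i = canonical.index("L")
        return canonical[:i] + "I" + canonical[i + 1:]
    return canonical


def _make_peptides_for_ko(ko: str, home_taxa: list[str], domain: str,
                          cfg: GeneratorConfig, rng: np.random.Generator,
                          tree: TaxonomyTree, species_pool: list[str],
                          used_words: set[str],
                          maps: AnnotationMaps,
                          truth: dict[str, PeptideTruth]) -> list[str]:
    """Generate the peptides of one KO, fill the annotation maps, record
    ground truth, and return the canonical peptide list."""
    peptides = []
    for _ in range(cfg.peptides_per_ko):
        u = rng.random()
        if domain != "bacterial":
            category = "simple"
        elif u < cfg.unmapped_fraction:
            category = "unmapped"
        elif u < cfg.unmapped_fraction + cfg.missed_cleavage_fraction:
            category = "missed_cleavage"
        elif (u < cfg.unmapped_fraction + cfg.missed_cleavage_fraction
                + cfg.degenerate_fraction):
            category = "degenerate"
        elif (u < cfg.unmapped_fraction + cfg.missed_cleavage_fraction
                + cfg.degenerate_fraction + cfg.cross_domain_fraction):
            category = "cross_domain"
        else:
            category = "simple"

        home = home_taxa[int(rng.integers(len(home_taxa)))]
        if category == "missed_cleavage":
            w1 = _tryptic_word(rng, used_words)
            w2 = _tryptic_word(rng, used_words)
            peptide = w1 + w2
            # fragment sets intersect to exactly the home species
            extras1 = {str(x) for x in
                       rng.choice(species_pool, size=2, replace=False)}
            extras2 = {str(x) for x in
                       rng.choice(species_pool, size=2, replace=False)}
            extras2 -= extras1
            maps.peptide_to_taxa[w1] = frozenset({home} | extras1)
            maps.peptide_to_taxa[w2] = frozenset({home} | (extras2 - {home}))
            taxa = frozenset(maps.peptide_to_taxa[w1]
                             & maps.peptide_to_taxa[w2])
        else:
            peptide = _tryptic_word(rng, used_words)
            if category == "degenerate":
                # extra species, mostly from the same phylum
                phylum = tree.ancestor_at_rank(home, "phylum")
                same = [s for s in species_pool
                        if tree.ancestor_at_rank(s, "phylum") == phylum]
                pool = same if rng.random() < 0.8 else species_pool
                k = int(rng.integers(1, 3))
                extras = {str(x) for x in
                          rng.choice(pool, size=min(k, len(pool)),
                                     replace=False)}
                taxa = frozenset({home} | extras)
            elif category == "cross_domain":
                taxa = frozenset({home, "Homo_sapiens"})
            elif category == "unmapped":
                taxa = frozenset()
            else:
                taxa = frozenset({home})
            if taxa:
                maps.peptide_to_taxa[peptide] = taxa

        if taxa:
            lca = lowest_common_ancestor(taxa, tree)
            dom = tree.domain_of(lca)
            dom_class = {"Bacteria": "bacterial", "Archaea": "archaeal",
                         "Eukaryota": "eukaryotic"}.get(
                tree.name(dom) if dom else "", "ambiguous")
        else:
            lca, dom_class = "unassigned", "unassigned"
        maps.peptide_to_kos[peptide] = frozenset({ko})
        truth[peptide] = PeptideTruth(
            peptide=peptide,
            emitted=_maybe_il_variant(rng, cfg, peptide),
            ko=ko, category=category, taxa=taxa, lca=lca,
            domain_class=dom_class)
        peptides.append(peptide)
    return peptides


# ---------------------------------------------------------------------------
# module catalogue
# ---------------------------------------------------------------------------

def _build_modules(cfg: GeneratorConfig, core_kos: list[str],
                   other_kos: list[str],
                   rng: np.random.Generator) -> list[ModuleDefinition]:
    modules = []
    for m in range(cfg.n_modules):
        # first module is built purely from the common core: always on
        pool = core_kos if m == 0 else (core_kos + other_kos)
        n_pathways = 1 if m == 0 else int(rng.integers(1, 3))
        pathways = []
        for _ in range(n_pathways):
            n_steps = int(rng.integers(3, 6))
            steps = []
            for _ in range(n_steps):
                n_alt = int(rng.integers(1, 3))
                steps.append(frozenset(
                    str(x) for x in rng.choice(pool, size=n_alt,
                                               replace=False)))
            pathways.append(tuple(steps))
        modules.append(ModuleDefinition(
            module_id=f"MF{m + 1:04d}",
            name=f"synthetic module {m + 1}",
            pathways=tuple(pathways)))
    return modules


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tree, bacterial_species = _build_taxonomy(cfg)

    bact_kos = [f"K{i + 1:05d}" for i in range(cfg.n_bacterial_kos)]
    human_kos = [f"K9{i + 1:04d}" for i in range(cfg.n_human_kos)]
    arch_kos = [f"K8{i + 1:04d}" for i in range(cfg.n_archaeal_kos)]
    core_kos = bact_kos[:cfg.common_core_kos]
    subject_ids = [f"subj{i + 1:02d}" for i in range(cfg.n_subjects)]
    subject_cores: dict[str, list[str]] = {}
    cursor = cfg.common_core_kos
    for s in subject_ids:
        subject_cores[s] = bact_kos[cursor:cursor + cfg.subject_core_size]
        cursor += cfg.subject_core_size

    maps = AnnotationMaps()
    truth: dict[str, PeptideTruth] = {}
    used_words: set[str] = set()
    ko_home: dict[str, str] = {}
    ko_peptides: dict[str, list[str]] = {}

    for ko in bact_kos:
        home = bacterial_species[int(rng.integers(len(bacterial_species)))]
        ko_home[ko] = home
        ko_peptides[ko] = _make_peptides_for_ko(
            ko, [home], "bacterial", cfg, rng, tree, bacterial_species,
            used_words, maps, truth)
    for ko in human_kos:
        # some human peptides are hominid-degenerate ("at least Chordata")
        host = (["Homo_sapiens", "Pan_troglodytes"]
                if rng.random() < 0.2 else ["Homo_sapiens"])
        ko_peptides[ko] = []
        for _ in range(cfg.peptides_per_ko):
            pep = _tryptic_word(rng, used_words)
            taxa = frozenset(host)
            maps.peptide_to_taxa[pep] = taxa
            maps.peptide_to_kos[pep] = frozenset({ko})
            lca = lowest_common_ancestor(taxa, tree)
            truth[pep] = PeptideTruth(
                peptide=pep, emitted=_maybe_il_variant(rng, cfg, pep),
                ko=ko, category="simple", taxa=taxa, lca=lca,
                domain_class="eukaryotic")
            ko_peptides[ko].append(pep)
    for ko in arch_kos:
        ko_peptides[ko] = []
        for _ in range(2):
            pep = _tryptic_word(rng, used_words)
            taxa = frozenset({"Methanobrevibacter_smithii"})
            maps.peptide_to_taxa[pep] = taxa
            maps.peptide_to_kos[pep] = frozenset({ko})
            truth[pep] = PeptideTruth(
                peptide=pep, emitted=_maybe_il_variant(rng, cfg, pep),
                ko=ko, category="simple", taxa=taxa,
                lca="Methanobrevibacter_smithii", domain_class="archaeal")
            ko_peptides[ko].append(pep)

    # COG annotations: one COG per KO; a slice of peptides span two families
    for i, ko in enumerate(bact_kos + human_kos):
        fam = _COG_FAMILIES[i % len(_COG_FAMILIES)]
        fams = fam
        if rng.random() < cfg.ambiguous_cog_fraction:
            other = _COG_FAMILIES[(i + 3) % len(_COG_FAMILIES)]
            fams = "".join(sorted({fam, other}))
        cog = (f"COG{i + 1:04d}", fams)
        for pep in ko_peptides[ko]:
            maps.peptide_to_cogs[pep] = frozenset({cog})
    maps.ko_domain = {ko: "bacterial" for ko in bact_kos}
    maps.ko_domain.update({ko: "human" for ko in human_kos})

    modules = _build_modules(cfg, core_kos,
                             bact_kos[cfg.common_core_kos:], rng)

    # ---- subject-level profiles (Dirichlet around a structured base) ----
    base = np.full(cfg.n_bacterial_kos, cfg.base_tail_weight)
    base[:cfg.common_core_kos] = cfg.base_core_weight
    pool_lo = cfg.common_core_kos
    pool_hi = cfg.common_core_kos + cfg.n_subjects * cfg.subject_core_size
    base[pool_lo:pool_hi] = cfg.base_pool_weight
    subject_profile_b: dict[str, np.ndarray] = {}
    for si, s in enumerate(subject_ids):
        b = base.copy()
        lo = pool_lo + si * cfg.subject_core_size
        b[lo:lo + cfg.subject_core_size] *= cfg.subject_core_boost
        alpha = cfg.dirichlet_scale * b
        subject_profile_b[s] = rng.dirichlet(alpha)
    human_base = np.full(cfg.n_human_kos, 0.5)
    human_base[:15] = 5.0
    subject_profile_h = {
        s: rng.dirichlet(cfg.dirichlet_scale * human_base * 2)
        for s in subject_ids}

    planted = [(human_kos[i], core_kos[i]) for i in range(cfg.n_planted_pairs)]
    effect_kos = set(core_kos[-cfg.n_effect_kos:]) if cfg.probiotic_effect \
        else set()

    meta: list[SampleMeta] = []
    observations: list[PeptideObservation] = []
    expected_phyla_cols: dict[str, pd.Series] = {}
    expected_genera_cols: dict[str, pd.Series] = {}
    ko_phylum = {ko: tree.ancestor_at_rank(sp, "phylum")
                 for ko, sp in ko_home.items()}
    ko_genus = {ko: tree.ancestor_at_rank(sp, "genus")
                for ko, sp in ko_home.items()}

    bact_pep_index: list[str] = []
    bact_pep_ko_idx: list[int] = []
    for j, ko in enumerate(bact_kos):
        for pep in ko_peptides[ko]:
            bact_pep_index.append(pep)
            bact_pep_ko_idx.append(j)
    bact_pep_ko_idx = np.asarray(bact_pep_ko_idx)
    human_pep_index: list[str] = []
    human_pep_ko_idx: list[int] = []
    for j, ko in enumerate(human_kos):
        for pep in ko_peptides[ko]:
            human_pep_index.append(pep)
            human_pep_ko_idx.append(j)
    human_pep_ko_idx = np.asarray(human_pep_ko_idx)
    arch_peps = [p for ko in arch_kos for p in ko_peptides[ko]]

    for si, s in enumerate(subject_ids):
        group = "placebo" if si < cfg.n_placebo else "probiotic"
        for tp in range(1, cfg.time_points + 1):
            sample_id = f"S{si + 1:02d}T{tp}"
            meta.append(SampleMeta(sample_id, s, tp, group))
            wb = subject_profile_b[s] * rng.lognormal(
                0.0, cfg.temporal_sigma, cfg.n_bacterial_kos)
            if group == "probiotic" and tp == 2 and effect_kos:
                for j, ko in enumerate(bact_kos):
                    if ko in effect_kos:
                        wb[j] *= np.exp(cfg.probiotic_effect)
            wb /= wb.sum()
            wh = subject_profile_h[s] * rng.lognormal(
                0.0, cfg.temporal_sigma, cfg.n_human_kos)
            for hi, (hko, bko) in enumerate(planted):
                wh[human_kos.index(hko)] = (
                    wb[bact_kos.index(bko)] * rng.lognormal(0.0, 0.15))
            wh /= wh.sum()

            n_bact, n_euk, n_arch = rng.multinomial(
                cfg.spectra_per_sample,
                [1 - cfg.eukaryotic_fraction - cfg.archaeal_fraction,
                 cfg.eukaryotic_fraction, cfg.archaeal_fraction])
            pep_w_b = wb[bact_pep_ko_idx]
            pep_w_b /= pep_w_b.sum()
            counts_b = rng.multinomial(n_bact, pep_w_b)
            pep_w_h = wh[human_pep_ko_idx]
            pep_w_h /= pep_w_h.sum()
            counts_h = rng.multinomial(n_euk, pep_w_h)
            counts_a = rng.multinomial(n_arch,
                                       np.full(len(arch_peps),
                                               1 / len(arch_peps)))
            for peps, counts in ((bact_pep_index, counts_b),
                                 (human_pep_index, counts_h),
                                 (arch_peps, counts_a)):
                for pep, c in zip(peps, counts):
                    if c > 0:
                        observations.append(PeptideObservation(
                            sample_id, truth[pep].emitted, int(c)))

            phylum_w = pd.Series(0.0, index=list(_PHYLA))
            genus_w: dict[str, float] = {}
            for j, ko in enumerate(bact_kos):
                phylum_w[ko_phylum[ko]] += wb[j]
                genus_w[ko_genus[ko]] = genus_w.get(ko_genus[ko], 0) + wb[j]
            expected_phyla_cols[sample_id] = 100 * phylum_w / phylum_w.sum()
            gseries = pd.Series(genus_w)
            expected_genera_cols[sample_id] = 100 * gseries / gseries.sum()

    observations.sort(key=lambda o: (o.sample_id, o.peptide))
    expected_phyla = pd.DataFrame(expected_phyla_cols)
    expected_genera = pd.DataFrame(expected_genera_cols).fillna(0.0)

    sixteen_s_phyla = _platform_copy(expected_phyla, cfg.cross_platform_rho,
                                     rng)
    sixteen_s_genera = _platform_copy(expected_genera, 0.8, rng)

    return CohortBundle(
        config=cfg, meta=meta, observations=observations, tree=tree,
        maps=maps, modules=modules, sixteen_s_phyla=sixteen_s_phyla,
        sixteen_s_genera=sixteen_s_genera, peptide_truth=truth,
        subject_profiles=pd.DataFrame(subject_profile_b, index=bact_kos),
        expected_phyla=expected_phyla, planted_pairs=planted,
        bacterial_kos=bact_kos, human_kos=human_kos, core_kos=core_kos,
        subject_core_kos=subject_cores)


def _platform_copy(expected: pd.DataFrame, rho: float,
                   rng: np.random.Generator) -> AbundanceMatrix:
    """Second-platform table correlated with the expected composition.

    Per feature (across samples): standardize, mix with independent noise
    at the requested correlation, restore the feature's location/scale,
    shrink to leave headroom and add an explicit remainder so columns sum
    to 100.
    """
    values = expected.values
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        x = values[i]
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eps = rng.normal(size=len(x))
        y = rho * z + np.sqrt(1 - rho ** 2) * eps
        out[i] = np.clip(x.mean() + sd * y, 0.05, None)
    out *= 0.85
    col_sums = out.sum(axis=0)
    over = col_sums > 99.0
    if over.any():
        out[:, over] *= 99.0 / col_sums[over]
    remainder = 100.0 - out.sum(axis=0)
    df = pd.DataFrame(out, index=expected.index, columns=expected.columns)
    df.loc[data_io.UNASSIGNED] = remainder
    return AbundanceMatrix(df, scale="percent")


# ---------------------------------------------------------------------------
# truth tables and bundle output
# ---------------------------------------------------------------------------

def truth_record(config: GeneratorConfig,
                 bundle: CohortBundle) -> dict[str, pd.DataFrame]:
    """Assemble ground-truth tables for use as test oracles."""
    pep_rows = [{
        "peptide": t.peptide, "emitted": t.emitted, "ko": t.ko,
        "category": t.category, "taxa": ",".join(sorted(t.taxa)),
        "lca": t.lca, "domain_class": t.domain_class,
    } for t in bundle.peptide_truth.values()]
    planted = pd.DataFrame(bundle.planted_pairs,
                           columns=["human_ko", "bacterial_ko"])
    planted["target_rho"] = 1.0  # weights are proportional up to noise
    return {
        "peptides": pd.DataFrame(pep_rows).sort_values("peptide"),
        "subject_profiles": bundle.subject_profiles,
        "planted_pairs": planted,
        "expected_phyla": bundle.expected_phyla,
    }


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write every bundle component in its data_io format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_peptide_table(bundle.observations, out / "peptides.tsv")
    data_io.write_sample_metadata(bundle.meta, out / "metadata.tsv")
    data_io.write_taxonomy(bundle.tree, out / "taxonomy.tsv")
    data_io.write_annotation_maps(bundle.maps, out)
    data_io.write_module_definitions(bundle.modules, out / "modules.txt")
    data_io.write_abundance_matrix(bundle.sixteen_s_phyla,
                                   out / "sixteen_s_phyla.tsv")
    data_io.write_abundance_matrix(bundle.sixteen_s_genera,
                                   out / "sixteen_s_genera.tsv")
    for name, df in truth_record(bundle.config, bundle).items():
        df.to_csv(out / f"truth_{name}.tsv", sep="\t",
                  index=name != "peptides" and name != "planted_pairs")
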