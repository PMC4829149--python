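"""Domain types and file I/O for the metaproteome profiling pipeline.

All tabular formats are tab-separated with a mandatory header row.
Taxonomies are accepted either as a child/parent TSV or as an NCBI-style
taxdump (``nodes.dmp`` + ``names.dmp``); the dialect is auto-detected.
Gut metabolic module (GMM) definitions use a small plain-text dialect:
a ``module_id<TAB>name`` header line, one line per step listing
comma-separated alternative KOs, ``//`` separating alternative pathways
and ``///`` terminating a module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

log = logging.getLogger("metapep")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
COG_FAMILY_ALPHABET = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus",
         "species", "no_rank")
GROUPS = ("placebo", "probiotic")
UNASSIGNED = "unassigned"

_KO_RE = re.compile(r"^K\d{5}$")


class DataFormatError(ValueError):
    """Raised for malformed input files, with file/line context."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """One sample: who it came from, when, and which study arm."""

    sample_id: str
    subject_id: str
    time_point: int
    group: str

    def __post_init__(self) -> None:
        if self.time_point not in (1, 2, 3):
            raise DataFormatError(
                f"sample {self.sample_id!r}: time_point must be 1, 2 or 3, "
                f"got {self.time_point}")
        if self.group not in GROUPS:
            raise DataFormatError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}")


def validate_metadata(meta: Iterable[SampleMeta]) -> list[SampleMeta]:
    """Check uniqueness/consistency invariants across a metadata table."""
    meta = list(meta)
    seen_samples: set[str] = set()
    seen_tp: set[tuple[str, int]] = set()
    subject_group: dict[str, str] = {}
    for m in meta:
        if m.sample_id in seen_samples:
            raise DataFormatError(f"duplicate sample_id {m.sample_id!r}")
        seen_samples.add(m.sample_id)
        key = (m.subject_id, m.time_point)
        if key in seen_tp:
            raise DataFormatError(
                f"subject {m.subject_id!r} has more than one sample at "
                f"time_point {m.time_point}")
        seen_tp.add(key)
        prev = subject_group.setdefault(m.subject_id, m.group)
        if prev != m.group:
            raise DataFormatError(
                f"subject {m.subject_id!r} appears in both groups")
    return meta


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide in one sample with its spectral count."""

    sample_id: str
    peptide: str
    spectral_count: int

    def __post_init__(self) -> None:
        bad = set(self.peptide) - AMINO_ACIDS
        if bad or not self.peptide:
            raise DataFormatError(
                f"peptide {self.peptide!r} contains non-amino-acid "
                f"characters {sorted(bad)}")
        if self.spectral_count < 1:
            raise DataFormatError(
                f"peptide {self.peptide!r} in sample {self.sample_id!r}: "
                f"spectral_count must be >= 1, got {self.spectral_count}")


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str


class TaxonomyTree:
    """Rooted taxonomy with ranks; the substrate for LCA queries.

    The root is the unique node whose parent is itself.  Construction
    validates that the tree is a single connected, acyclic component.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for n in nodes:
            if n.rank not in RANKS:
                raise DataFormatError(
                    f"taxon {n.taxon_id!r}: unknown rank {n.rank!r}")
            if n.taxon_id in self.nodes:
                raise DataFormatError(f"duplicate taxon_id {n.taxon_id!r}")
            self.nodes[n.taxon_id] = n
        roots = [t for t, n in self.nodes.items() if n.parent_id == t]
        if len(roots) == 0:
            raise DataFormatError("taxonomy has no root (self-parented node)")
        if len(roots) > 1:
            raise DataFormatError(
                f"taxonomy has multiple roots: {sorted(roots)}")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {t: [] for t in self.nodes}
        for t, n in self.nodes.items():
            if t == self.root:
                continue
            if n.parent_id not in self.nodes:
                raise DataFormatError(
                    f"taxon {t!r} has parent {n.parent_id!r} absent from the "
                    f"tree (orphan)")
            self._children[n.parent_id].append(t)
        # reachability from the root also proves acyclicity
        self._depth: dict[str, int] = {self.root: 0}
        stack = [self.root]
        while stack:
            t = stack.pop()
            for c in self._children[t]:
                self._depth[c] = self._depth[t] + 1
                stack.append(c)
        unreachable = set(self.nodes) - set(self._depth)
        if unreachable:
            raise DataFormatError(
                f"taxa not reachable from root (cycle or orphan): "
                f"{sorted(unreachable)[:5]}")
        self._domain_of: dict[str, str | None] = {}
        self._name_index: dict[str, str] = {}
        for t, n in self.nodes.items():
            self._name_index.setdefault(n.name, t)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def depth(self, taxon_id: str) -> int:
        return self._depth[taxon_id]

    def parent(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].parent_id

    def rank(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def name(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name

    def find_by_name(self, name: str) -> str | None:
        """taxon_id of the first node with this name, or None."""
        return self._name_index.get(name)

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Node ids from ``taxon_id`` up to and including the root."""
        path = [taxon_id]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor (or self) of the given rank, or None if above it."""
        for t in self.path_to_root(taxon_id):
            if self.rank(t) == rank:
                return t
        return None

    def domain_of(self, taxon_id: str) -> str | None:
        """Cached domain-rank ancestor lookup."""
        if taxon_id not in self._domain_of:
            self._domain_of[taxon_id] = self.ancestor_at_rank(taxon_id,
                                                              "domain")
        return self._domain_of[taxon_id]

    def is_descendant(self, taxon_id: str, ancestor_id: str) -> bool:
        """True if ``ancestor_id`` lies on the root path of ``taxon_id``
        (a node counts as its own descendant)."""
        return ancestor_id in self.path_to_root(taxon_id)


@dataclass
class AnnotationMaps:
    """Peptide-level annotation lookups.

    Keys of ``peptide_to_taxa`` are I/L-normalized.  ``peptide_to_cogs``
    maps a peptide to a set of ``(cog_id, family_letters)`` pairs, where
    ``family_letters`` is a string of one-letter COG family codes.
    """

    peptide_to_taxa: dict[str, frozenset[str]] = field(default_factory=dict)
    peptide_to_kos: dict[str, frozenset[str]] = field(default_factory=dict)
    peptide_to_cogs: dict[str, frozenset[tuple[str, str]]] = field(
        default_factory=dict)
    ko_domain: dict[str, str] = field(default_factory=dict)

    def validate(self, tree: TaxonomyTree) -> None:
        for pep, taxa in self.peptide_to_taxa.items():
            for t in taxa:
                if t not in tree:
                    raise DataFormatError(
                        f"peptide {pep!r} maps to taxon {t!r} absent from "
                        f"the taxonomy")
        for pep, cogs in self.peptide_to_cogs.items():
            for cog, fams in cogs:
                bad = set(fams) - COG_FAMILY_ALPHABET
                if bad or not fams:
                    raise DataFormatError(
                        f"COG {cog!r} for peptide {pep!r} has invalid "
                        f"family letters {fams!r}")
        for ko, dom in self.ko_domain.items():
            if dom not in ("bacterial", "human"):
                raise DataFormatError(
                    f"KO {ko!r}: ko_domain must be bacterial or human, got "
                    f"{dom!r}")

    def cog_families(self, peptide: str) -> frozenset[str]:
        """Union of individual family letters over the peptide's COGs."""
        letters: set[str] = set()
        for _, fams in self.peptide_to_cogs.get(peptide, ()):
            letters.update(fams)
        return frozenset(letters)

    def ambiguous_peptides(self) -> frozenset[str]:
        """Peptides whose COG annotation spans more than one family."""
        return frozenset(p for p in self.peptide_to_cogs
                         if len(self.cog_families(p)) > 1)


@dataclass
class AbundanceMatrix:
    """Feature x sample matrix of spectral counts or relative percentages.

    ``df`` holds features as the index and samples as columns.  When
    ``scale == "percent"`` each sample column must sum to 100 (within
    1e-9), unless an explicit ``unassigned`` remainder feature is present
    in which case the named features may sum to less.
    """

    df: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "percent"):
            raise DataFormatError(f"unknown scale {self.scale!r}")
        self.df = self.df.astype(float)
        if (self.df.values < 0).any():
            raise DataFormatError("abundance values must be non-negative")
        if self.scale == "percent":
            sums = self.df.sum(axis=0)
            if UNASSIGNED in self.df.index:
                bad = sums[(sums - 100.0).abs() > 1e-6]
            else:
                bad = sums[(sums - 100.0).abs() > 1e-9]
            if len(bad):
                raise DataFormatError(
                    f"percent columns do not sum to 100: "
                    f"{list(bad.index[:3])}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self):
        return self.df.values


@dataclass(frozen=True)
class ModuleDefinition:
    """One gut metabolic module: alternative pathways of ordered steps,
    each step a set of interchangeable KOs."""

    module_id: str
    name: str
    pathways: tuple[tuple[frozenset[str], ...], ...]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise DataFormatError(f"module {self.module_id!r}: no pathways")
        for pw in self.pathways:
            if not pw:
                raise DataFormatError(
                    f"module {self.module_id!r}: empty pathway")
            for step in pw:
                if not step:
                    raise DataFormatError(
                        f"module {self.module_id!r}: empty step")
                for ko in step:
                    if not _KO_RE.match(ko):
                        raise DataFormatError(
                            f"module {self.module_id!r}: malformed KO token "
                            f"{ko!r}")


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read a sample_id/peptide/spectral_count TSV.

    Duplicate (sample_id, peptide) rows are summed with a logged warning.
    Output is sorted by (sample_id, peptide).  I/L normalization is *not*
    applied here; that is an explicit downstream step.
    """
    path = Path(path)
    counts: dict[tuple[str, str], int] = {}
    duplicates = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample_id", "peptide", "spectral_count"]
        if header[:3] != required:
            raise DataFormatError(
                f"{path}: expected header {required}, got {header[:3]}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataFormatError(f"{path}:{lineno}: malformed row")
            sample_id, peptide, raw_count = fields[:3]
            try:
                count = int(raw_count)
            except ValueError:
                raise DataFormatError(
                    f"{path}:{lineno}: spectral_count {raw_count!r} is not "
                    f"an integer") from None
            # constructor validates alphabet and count >= 1
            PeptideObservation(sample_id, peptide, count)
            key = (sample_id, peptide)
            if key in counts:
                duplicates += 1
            counts[key] = counts.get(key, 0) + count
    if duplicates:
        log.warning("%s: summed %d duplicate (sample, peptide) rows",
                    path, duplicates)
    return [PeptideObservation(s, p, c)
            for (s, p), c in sorted(counts.items())]


def write_peptide_table(observations: Iterable[PeptideObservation],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpeptide\tspectral_count\n")
        for o in sorted(observations,
                        key=lambda o: (o.sample_id, o.peptide)):
            fh.write(f"{o.sample_id}\t{o.peptide}\t{o.spectral_count}\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "time_point", "group"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    meta = [SampleMeta(r.sample_id, r.subject_id, int(r.time_point), r.group)
            for r in df.itertuples()]
    meta.sort(key=lambda m: m.sample_id)
    return validate_metadata(meta)


def write_sample_metadata(meta: Iterable[SampleMeta],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsubject_id\ttime_point\tgroup\n")
        for m in sorted(meta, key=lambda m: m.sample_id):
            fh.write(f"{m.sample_id}\t{m.subject_id}\t{m.time_point}\t"
                     f"{m.group}\n")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_NCBI_RANK_MAP = {
    "superkingdom": "domain", "domain": "domain", "kingdom": "no_rank",
    "phylum": "phylum", "class": "class", "order": "order",
    "family": "family", "genus": "genus", "species": "species",
}


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read a taxonomy, auto-detecting the dialect.

    A directory (or a ``nodes.dmp`` file) is treated as an NCBI taxdump;
    anything else must be a TSV with header
    ``taxon_id  parent_id  rank  name``.
    """
    path = Path(path)
    if path.is_dir():
        return _read_taxdump(path / "nodes.dmp", path / "names.dmp")
    with open(path) as fh:
        first = fh.readline()
    if "\t|" in first or path.name == "nodes.dmp":
        return _read_taxdump(path, path.with_name("names.dmp"))
    return _read_taxonomy_tsv(path)


def _read_taxonomy_tsv(path: Path) -> TaxonomyTree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon_id", "parent_id", "rank", "name"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    nodes = [TaxonNode(r.taxon_id, r.parent_id, r.rank, r.name)
             for r in df.itertuples()]
    return TaxonomyTree(nodes)


def _read_taxdump(nodes_path: Path, names_path: Path) -> TaxonomyTree:
    names: dict[str, str] = {}
    if names_path.exists():
        with open(names_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.split("|")]
                if len(parts) >= 4 and parts[3] == "scientific name":
                    names[parts[0]] = parts[1]
    nodes = []
    with open(nodes_path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.split("|")]
            if len(parts) < 3:
                raise DataFormatError(f"{nodes_path}: malformed line")
            tid, parent, rank = parts[0], parts[1], parts[2]
            rank = _NCBI_RANK_MAP.get(rank,
                                      "root" if tid == parent else "no_rank")
            if tid == parent:
                rank = "root"
            nodes.append(TaxonNode(tid, parent, rank,
                                   names.get(tid, tid)))
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tparent_id\trank\tname\n")
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")


# ---------------------------------------------------------------------------
# annotation maps
# ---------------------------------------------------------------------------

def read_annotation_maps(taxa_path: str | Path | None = None,
                         ko_path: str | Path | None = None,
                         cog_path: str | Path | None = None,
                         ko_domain_path: str | Path | None = None,
                         tree: TaxonomyTree | None = None) -> AnnotationMaps:
    """Assemble AnnotationMaps from up to four TSV files.

    * taxa map:      ``peptide  taxon_ids``  (comma-separated ids)
    * KO map:        ``peptide  kos``        (comma-separated K#####)
    * COG map:       ``peptide  cog_id  families``
    * KO domain map: ``ko  domain``          (bacterial | human)
    """
    maps = AnnotationMaps()
    if taxa_path is not None:
        df = pd.read_csv(taxa_path, sep="\t", dtype=str)
        _require(df, taxa_path, ["peptide", "taxon_ids"])
        for r in df.itertuples():
            maps.peptide_to_taxa[r.peptide] = frozenset(
                r.taxon_ids.split(","))
    if ko_path is not None:
        df = pd.read_csv(ko_path, sep="\t", dtype=str)
        _require(df, ko_path, ["peptide", "kos"])
        for r in df.itertuples():
            kos = frozenset(r.kos.split(","))
            for ko in kos:
                if not _KO_RE.match(ko):
                    raise DataFormatError(
                        f"{ko_path}: malformed KO token {ko!r}")
            maps.peptide_to_kos[r.peptide] = kos
    if cog_path is not None:
        df = pd.read_csv(cog_path, sep="\t", dtype=str)
        _require(df, cog_path, ["peptide", "cog_id", "families"])
        grouped: dict[str, set[tuple[str, str]]] = {}
        for r in df.itertuples():
            grouped.setdefault(r.peptide, set()).add((r.cog_id, r.families))
        maps.peptide_to_cogs = {p: frozenset(v) for p, v in grouped.items()}
    if ko_domain_path is not None:
        df = pd.read_csv(ko_domain_path, sep="\t", dtype=str)
        _require(df, ko_domain_path, ["ko", "domain"])
        maps.ko_domain = dict(zip(df.ko, df.domain))
    if tree is not None:
        maps.validate(tree)
    return maps


def _require(df: pd.DataFrame, path, cols: list[str]) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")


def write_annotation_maps(maps: AnnotationMaps, out_dir: str | Path,
                          prefix: str = "") -> dict[str, Path]:
    """Write the four map files; returns the paths keyed by map name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = out_dir / f"{prefix}peptide_taxa.tsv"
    with open(p, "w") as fh:
        fh.write("peptide\ttaxon_ids\n")
        for pep in sorted(maps.peptide_to_taxa):
            fh.write(f"{pep}\t{','.join(sorted(maps.peptide_to_taxa[pep]))}\n")
    paths["taxa"] = p
    p = out_dir / f"{prefix}peptide_ko.tsv"
    with open(p, "w") as fh:
        fh.write("peptide\tkos\n")
        for pep in sorted(maps.peptide_to_kos):
            fh.write(f"{pep}\t{','.join(sorted(maps.peptide_to_kos[pep]))}\n")
    paths["ko"] = p
    p = out_dir / f"{prefix}peptide_cog.tsv"
    with open(p, "w") as fh:
        fh.write("peptide\tcog_id\tfamilies\n")
        for pep in sorted(maps.peptide_to_cogs):
            for cog, fams in sorted(maps.peptide_to_cogs[pep]):
                fh.write(f"{pep}\t{cog}\t{fams}\n")
    paths["cog"] = p
    p = out_dir / f"{prefix}ko_domain.tsv"
    with open(p, "w") as fh:
        fh.write("ko\tdomain\n")
        for ko in sorted(maps.ko_domain):
            fh.write(f"{ko}\t{maps.ko_domain[ko]}\n")
    paths["ko_domain"] = p
    return paths


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

def read_abundance_matrix(path: str | Path) -> AbundanceMatrix:
    """Read a feature x sample TSV; scale comes from a ``# scale=`` line."""
    path = Path(path)
    scale = "counts"
    with open(path) as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("# scale="):
            scale = first.strip().split("=", 1)[1]
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return AbundanceMatrix(df, scale=scale)


def write_abundance_matrix(matrix: AbundanceMatrix,
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.df.to_csv(fh, sep="\t", index_label="feature_id",
                         lineterminator="\n")


# ---------------------------------------------------------------------------
# module definitions
# ---------------------------------------------------------------------------

def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    path = Path(path)
    modules: list[ModuleDefinition] = []
    header: tuple[str, str] | None = None
    pathways: list[tuple[frozenset[str], ...]] = []
    steps: list[frozenset[str]] = []

    def close_pathway(lineno: int) -> None:
        nonlocal steps
        if not steps:
            raise DataFormatError(f"{path}:{lineno}: empty pathway")
        pathways.append(tuple(steps))
        steps = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "///":
                if header is None:
                    raise DataFormatError(
                        f"{path}:{lineno}: module terminator without header")
                close_pathway(lineno)
                modules.append(ModuleDefinition(header[0], header[1],
                                                tuple(pathways)))
                header, pathways = None, []
            elif line == "//":
                close_pathway(lineno)
            elif header is None:
                parts = line.split("\t")
                if len(parts) < 2:
                    raise DataFormatError(
                        f"{path}:{lineno}: module header must be "
                        f"'module_id<TAB>name'")
                header = (parts[0], parts[1])
            else:
                kos = [k.strip() for k in line.split(",")]
                for ko in kos:
                    if not _KO_RE.match(ko):
                        raise DataFormatError(
                            f"{path}:{lineno}: malformed KO token {ko!r}")
                steps.append(frozenset(kos))
    if header is not None:
        raise DataFormatError(f"{path}: unterminated module {header[0]!r}")
    return modules


def write_module_definitions(modules: Iterable[ModuleDefinition],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        for mod in modules:
            fh.write(f"{mod.module_id}\t{mod.name}\n")
            for i, pw in enumerate(mod.pathways):
                if i:
                    fh.write("//\n")
                for step in pw:
                    fh.write(",".join(sorted(step)) + "\n")
            fh.write("///\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Plain-text ``key = value`` configuration; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
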