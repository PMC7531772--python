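"""Orthogroup count matrices, domain-architecture tables and gene-set maps.

The central observable of the analysis is a taxa x orthogroups matrix of
non-negative integer gene counts (one Orthofinder-style orthogroup per
column). Two side tables feed the comparative stages: locus-level
domain-architecture records (Pfam-style domain names per p53-family locus,
from which per-taxon domain profiles are tabulated) and a curated gene-set
map that links, say, KEGG apoptosis loci to the orthogroups that contain
them, defining the focal orthogroup set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DomainArchitectureRecord",
    "GeneSetMap",
    "GeneSetSummary",
    "read_count_matrix",
    "read_domain_architectures",
    "read_gene_set_map",
    "map_gene_set",
    "tabulate_domain_counts",
    "repertoire_size",
    "DEFAULT_DOMAIN_VOCABULARY",
]

#: The four p53-family domain types analysed by default: transactivation,
#: DNA-binding, tetramerization and sterile-alpha-motif.
DEFAULT_DOMAIN_VOCABULARY = ("TAD", "p53", "TET", "SAM")


class CountMatrix:
    """Taxa x orthogroups matrix of non-negative integer gene counts.

    ``data`` is a pandas DataFrame (rows = taxa, columns = orthogroup IDs);
    ``tags`` maps a tag name (e.g. ``"apoptosis"``) to the set of orthogroup
    IDs carrying it.
    """

    def __init__(self, data: pd.DataFrame, tags: Mapping[str, Iterable[str]] | None = None):
        if data.index.has_duplicates:
            raise ValueError("duplicate taxon labels in count matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate orthogroup IDs in count matrix")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("count matrix entries must be integers")
            data = data.round().astype(np.int64)
        if (data.to_numpy() < 0).any():
            raise ValueError("count matrix entries must be non-negative")
        self.data = data.astype(np.int64)
        self.tags: dict[str, frozenset[str]] = {}
        for tag, ogs in (tags or {}).items():
            self.tag(tag, ogs)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.data.columns)

    def tag(self, name: str, orthogroups: Iterable[str]) -> None:
        ogs = frozenset(orthogroups)
        unknown = ogs - set(self.data.columns)
        if unknown:
            raise KeyError(f"tag {name!r} references unknown orthogroups: {sorted(unknown)}")
        self.tags[name] = ogs

    def tagged(self, name: str) -> frozenset[str]:
        if name not in self.tags:
            raise KeyError(f"unknown tag: {name!r}")
        return self.tags[name]

    def reorder_taxa(self, order: Sequence[str]) -> "CountMatrix":
        """Reindex rows by label; raises if labels are missing."""
        missing = [t for t in order if t not in self.data.index]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        return CountMatrix(self.data.loc[list(order)], self.tags)

    def validate_against_tree(self, phylogeny) -> None:
        extra = set(self.data.index) - set(phylogeny.tip_labels)
        if extra:
            raise ValueError(f"matrix taxa not on the tree: {sorted(extra)}")

    def write_tsv(self, path) -> None:
        out = self.data.sort_index(axis=0).sort_index(axis=1)
        out.to_csv(path, sep="\t", index_label="taxon")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({self.data.shape[0]} taxa x {self.data.shape[1]} orthogroups)"


def read_count_matrix(path, *, taxa: Iterable[str] | None = None) -> CountMatrix:
    """Read a TSV count matrix (header = orthogroup IDs, first column = taxa).

    Empty cells are read as 0 with a logged warning. If *taxa* (e.g. the
    tree's tip labels) is given, a table whose *header* matches those labels
    while its first column does not is rejected as transposed rather than
    silently transposed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    n_empty = int((df.to_numpy() == "").sum())
    if n_empty:
        logger.warning("%s: %d empty cells read as 0", path, n_empty)
        df = df.replace("", "0")
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in count matrix ({exc})") from exc
    if not np.allclose(numeric.to_numpy(), np.round(numeric.to_numpy())):
        raise ValueError(f"{path}: non-integer counts")
    if (numeric.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    counts = numeric.astype(np.int64)
    if taxa is not None:
        taxa = set(taxa)
        in_header = len(taxa & set(counts.columns))
        in_index = len(taxa & set(counts.index))
        if in_header > in_index:
            raise ValueError(
                f"{path}: taxon labels found in the header row — the table "
                "looks transposed (expected taxa as rows, orthogroups as columns)"
            )
    return CountMatrix(counts)


# ---------------------------------------------------------------------------
# domain architectures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainArchitectureRecord:
    """One locus of one taxon with its ordered Pfam-style domain list."""

    taxon: str
    locus: str
    domains: tuple[str, ...]
    evalues: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.taxon or not self.locus:
            raise ValueError("taxon and locus must be non-empty")
        if not self.domains:
            raise ValueError(f"{self.taxon}/{self.locus}: empty domain list")


def read_domain_architectures(path) -> list[DomainArchitectureRecord]:
    """Read `taxon<TAB>locus<TAB>dom1;dom2;...[<TAB>e1;e2;...]` records."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns")
            taxon, locus, domstr = parts[:3]
            domains = tuple(d for d in domstr.split(";") if d)
            evalues = None
            if len(parts) == 4 and parts[3].strip():
                evalues = tuple(float(e) for e in parts[3].split(";"))
            records.append(DomainArchitectureRecord(taxon, locus, domains, evalues))
    return records


def tabulate_domain_counts(
    records: Iterable[DomainArchitectureRecord],
    vocabulary: Sequence[str] = DEFAULT_DOMAIN_VOCABULARY,
    *,
    binarize: bool = False,
) -> pd.DataFrame:
    """Per-taxon domain-occurrence profile over a fixed domain vocabulary.

    Counts domain *occurrences* (a locus carrying two SAM domains contributes
    2 to that taxon's SAM column); ``binarize=True`` collapses each cell to
    presence/absence, the encoding used when mapping domains as Dollo
    characters. Domains outside the vocabulary are ignored with a logged
    tally. Returns a DataFrame (taxa x vocabulary), empty for empty input.
    """
    vocabulary = list(vocabulary)
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    rows: dict[str, Counter] = {}
    ignored: Counter = Counter()
    for rec in records:
        row = rows.setdefault(rec.taxon, Counter())
        for dom in rec.domains:
            if dom in vocabulary:
                row[dom] += 1
            else:
                ignored[dom] += 1
    if ignored:
        logger.info(
            "ignored %d domain occurrences outside vocabulary: %s",
            sum(ignored.values()),
            dict(ignored),
        )
    profile = pd.DataFrame(
        [[rows[t].get(d, 0) for d in vocabulary] for t in sorted(rows)],
        index=sorted(rows),
        columns=vocabulary,
        dtype=np.int64,
    )
    if binarize:
        profile = (profile > 0).astype(np.int64)
    return profile


# ---------------------------------------------------------------------------
# curated gene sets
# ---------------------------------------------------------------------------

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class GeneSetMap:
    """Curated gene IDs mapped to orthogroup IDs (or UNMAPPED)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("a curated gene maps to more than one orthogroup")

    @property
    def mapped(self) -> list[tuple[str, str]]:
        return [(g, og) for g, og in self.entries if og != UNMAPPED]

    @property
    def orthogroups(self) -> frozenset[str]:
        return frozenset(og for _, og in self.mapped)


@dataclass(frozen=True)
class GeneSetSummary:
    """Bookkeeping of a gene-set -> orthogroup mapping.

    ``total = unmapped + mapped`` and ``shared = mapped - distinct`` (the
    number of curated genes homologized to an orthogroup already claimed by
    another curated gene).
    """

    total: int
    unmapped: int
    mapped: int
    distinct: int
    shared: int
    unknown_orthogroups: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.total, self.unmapped, self.mapped, self.distinct, self.shared)


def read_gene_set_map(path) -> GeneSetMap:
    """Read `gene_id<TAB>orthogroup_id|UNMAPPED` ('#' comments allowed)."""
    entries = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>orthogroup'")
            entries.append((parts[0].strip(), parts[1].strip()))
    return GeneSetMap(tuple(entries))


def map_gene_set(
    genes: GeneSetMap, matrix: CountMatrix, *, tag: str = "focal"
) -> tuple[CountMatrix, GeneSetSummary]:
    """Tag the orthogroups hit by a curated gene set as the focal set.

    Unknown orthogroup IDs (present in the map but absent from the matrix)
    are reported in the summary and excluded with a warning, mirroring
    curated loci that elude orthology assignment. Returns the tagged matrix
    and the mapping summary.
    """
    if not genes.entries:
        raise ValueError("empty gene set")
    known = set(matrix.orthogroups)
    mapped = genes.mapped
    unknown = sorted({og for _, og in mapped if og not in known})
    if unknown:
        logger.warning("gene-set map references %d unknown orthogroups: %s",
                       len(unknown), unknown)
    usable = [(g, og) for g, og in mapped if og in known]
    focal = sorted({og for _, og in usable})
    tagged = CountMatrix(matrix.data, matrix.tags)
    tagged.tag(tag, focal)
    summary = GeneSetSummary(
        total=len(genes.entries),
        unmapped=len(genes.entries) - len(mapped),
        mapped=len(mapped),
        distinct=len({og for _, og in mapped}),
        shared=len(mapped) - len({og for _, og in mapped}),
        unknown_orthogroups=tuple(unknown),
    )
    return tagged, summary


def repertoire_size(matrix: CountMatrix, focal: str) -> pd.Series:
    """Per-taxon total gene count across the orthogroups carrying *focal* tag."""
    ogs = sorted(matrix.tagged(focal))
    if not ogs:
        return pd.Series(0, index=matrix.data.index, dtype=np.int64)
    return matrix.data[ogs].sum(axis=1)
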