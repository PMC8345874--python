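"""Core sequence/alignment/tree/metadata types and on-disk formats.

Everything downstream (candidate harvesting, tree inspection, supermatrix
assembly, exploration utilities) works on the containers defined here:

* :class:`SequenceRecord` — a named amino-acid sequence belonging to a taxon.
* :class:`Alignment` — an ordered set of equal-length records with at most one
  sequence per taxon (the one-ortholog-per-taxon invariant).
* :class:`TaxonMeta` — per-taxon metadata including the ordered list of
  "blast seed" taxa used by the phylogenetically informed harvesting route.
* :class:`GeneDatabase` — the starting database: per-gene ortholog and paralog
  record sets plus assigned orthogroup ids.

Formats: FASTA (configurable wrap), relaxed PHYLIP (sequential, one line per
sequence), Newick (via dendropy), TSV metadata / decision / partition files.
Readers are strict: duplicate ids, header/content mismatches and dangling
references are hard errors, never silent drops.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import dendropy
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: characters legal in residue strings besides the 20 amino acids
EXTRA_CHARS = "X-*"

PARALOG_SEP = ".."


def taxon_of(seq_id: str) -> str:
    """Taxon code of a database sequence id (strips the ``..p<k>`` suffix)."""
    return seq_id.split(PARALOG_SEP, 1)[0]


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence.

    ``unique_id`` must contain no whitespace and be unique within any
    container; ``taxon_code`` ties the sequence to a taxon (empty for raw
    proteome sequences whose taxon is implied by the file).
    """

    unique_id: str
    residues: str
    taxon_code: str = ""

    def __post_init__(self):
        if not self.unique_id or any(c.isspace() for c in self.unique_id):
            raise ValueError(f"invalid sequence id {self.unique_id!r}")
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.unique_id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def taxon(self) -> str:
        return self.taxon_code or taxon_of(self.unique_id)


class Alignment:
    """Ordered list of equal-length records, at most one per taxon."""

    def __init__(self, records: list[SequenceRecord], check_taxa: bool = True):
        if not records:
            raise ValueError("alignment must contain at least one record")
        n = len(records[0].residues)
        seen_ids: set[str] = set()
        seen_taxa: set[str] = set()
        for r in records:
            if len(r.residues) != n:
                raise ValueError(
                    f"record {r.unique_id!r} has length {len(r.residues)}, expected {n}"
                )
            if r.unique_id in seen_ids:
                raise ValueError(f"duplicate id {r.unique_id!r} in alignment")
            seen_ids.add(r.unique_id)
            if check_taxa:
                if r.taxon in seen_taxa:
                    raise ValueError(f"taxon {r.taxon!r} appears twice in alignment")
                seen_taxa.add(r.taxon)
        self.records = list(records)
        self.n_cols = n

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def taxa(self) -> list[str]:
        return [r.taxon for r in self.records]

    def get(self, taxon: str) -> SequenceRecord | None:
        for r in self.records:
            if r.taxon == taxon:
                return r
        return None

    def columns(self, idx: list[int]) -> "Alignment":
        """Sub-alignment keeping 0-based columns ``idx`` in the given order."""
        recs = [
            replace(r, residues="".join(r.residues[i] for i in idx)) for r in self.records
        ]
        return Alignment(recs, check_taxa=False)

    def restrict(self, taxa: set[str]) -> "Alignment":
        recs = [r for r in self.records if r.taxon in taxa]
        return Alignment(recs, check_taxa=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Parse FASTA; id = header up to first whitespace, residues upper-cased.

    Duplicate ids and empty files are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    handle = open(path) if not hasattr(path, "read") else path
    try:
        for header, seq in SimpleFastaParser(handle):
            uid = header.split()[0]
            if uid in seen:
                raise ValueError(f"duplicate sequence id {uid!r} in {path}")
            seen.add(uid)
            records.append(SequenceRecord(uid, seq.upper().replace(" ", "")))
    finally:
        if handle is not path:
            handle.close()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    """Write records as FASTA; ``wrap=0`` puts each sequence on one line."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.unique_id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(r.residues), wrap):
                    fh.write(r.residues[i : i + wrap] + "\n")
            else:
                fh.write(r.residues + "\n")


# ---------------------------------------------------------------------------
# Relaxed PHYLIP (sequential; "<name> <sequence>" per line, no name length cap)

def read_relaxed_phylip(path) -> Alignment:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"bad relaxed-PHYLIP header in {path}")
        n_taxa, n_cols = int(header[0]), int(header[1])
        records = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            name, seq = parts[0], "".join(parts[1:]).upper()
            if len(seq) != n_cols:
                raise ValueError(
                    f"row {name!r}: {len(seq)} columns, header promised {n_cols}"
                )
            records.append(SequenceRecord(name, seq))
    if len(records) != n_taxa:
        raise ValueError(
            f"{path}: header promised {n_taxa} taxa, found {len(records)}"
        )
    return Alignment(records, check_taxa=False)


def write_relaxed_phylip(aln: Alignment, path) -> None:
    width = max(len(r.unique_id) for r in aln.records) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(aln.records)} {aln.n_cols}\n")
        for r in aln.records:
            fh.write(f"{r.unique_id.ljust(width)}{r.residues}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)

def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree from a path or a string.

    Support values on internal branches are kept as internal node labels;
    trees are treated as unrooted throughout the package.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        data = open(source).read()
    else:
        data = str(source)
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    for edge in tree.edges():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartition_sides(tree: dendropy.Tree) -> list[frozenset]:
    """Leaf sets on the child side of every edge (trivial splits included)."""
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        sides.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return sides


def bipartition_set(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical non-trivial splits of an unrooted tree.

    Each split is represented by the side not containing the lexicographically
    smallest leaf, which makes the set invariant under rerooting.
    """
    all_leaves = frozenset(leaf_names(tree))
    anchor = min(all_leaves)
    out = set()
    for side in bipartition_sides(tree):
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# Taxon metadata

METADATA_COLUMNS = [
    "unique_id",
    "higher_taxonomy",
    "lower_taxonomy",
    "data_type",
    "blast_seeds",
]


@dataclass
class TaxonMeta:
    unique_id: str
    higher_taxonomy: str
    lower_taxonomy: str = ""
    data_type: str = ""
    blast_seeds: list[str] = field(default_factory=list)


def read_metadata(path, known_taxa: set[str] | None = None) -> dict[str, TaxonMeta]:
    """Read the tab-separated taxon metadata table.

    Required columns: ``unique_id``, ``higher_taxonomy``, ``lower_taxonomy``,
    ``data_type``, ``blast_seeds`` (comma-separated, order meaningful, may be
    empty). If ``known_taxa`` is given, every blast seed must be a member.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"metadata file {path} is missing required columns {missing}; "
            f"expected header: {METADATA_COLUMNS}"
        )
    table: dict[str, TaxonMeta] = {}
    for _, row in df.iterrows():
        uid = row["unique_id"].strip()
        if uid in table:
            raise ValueError(f"duplicate taxon unique_id {uid!r} in metadata")
        seeds = [s.strip() for s in row["blast_seeds"].split(",") if s.strip()]
        if known_taxa is not None:
            for s in seeds:
                if s not in known_taxa:
                    raise ValueError(
                        f"blast seed {s!r} of taxon {uid!r} is not in the starting database"
                    )
        table[uid] = TaxonMeta(
            unique_id=uid,
            higher_taxonomy=row["higher_taxonomy"].strip(),
            lower_taxonomy=row["lower_taxonomy"].strip(),
            data_type=row["data_type"].strip(),
            blast_seeds=seeds,
        )
    return table


# ---------------------------------------------------------------------------
# Gene database

class GeneEntry:
    """Orthologs (one per taxon), paralogs (suffixed ids) and orthogroups."""

    def __init__(self):
        self.orthologs: dict[str, SequenceRecord] = {}  # taxon -> record
        self.paralogs: dict[str, SequenceRecord] = {}  # seq id -> record
        self.orthogroups: set[str] = set()

    def n_sequences(self) -> int:
        return len(self.orthologs) + len(self.paralogs)

    def next_paralog_id(self, taxon: str) -> str:
        k = 1
        while f"{taxon}{PARALOG_SEP}p{k}" in self.paralogs:
            k += 1
        return f"{taxon}{PARALOG_SEP}p{k}"


class GeneDatabase:
    """The starting ortholog/paralog database, keyed by gene name."""

    def __init__(self):
        self.genes: dict[str, GeneEntry] = {}

    def __contains__(self, gene):
        return gene in self.genes

    def __iter__(self):
        return iter(self.genes)

    def entry(self, gene: str) -> GeneEntry:
        return self.genes.setdefault(gene, GeneEntry())

    def taxa(self) -> set[str]:
        out: set[str] = set()
        for e in self.genes.values():
            out.update(e.orthologs)
            out.update(taxon_of(i) for i in e.paralogs)
        return out

    def add_ortholog(self, gene: str, taxon: str, residues: str) -> SequenceRecord:
        e = self.entry(gene)
        if taxon in e.orthologs:
            raise ValueError(f"taxon {taxon!r} already has an ortholog for {gene!r}")
        rec = SequenceRecord(taxon, residues, taxon_code=taxon)
        e.orthologs[taxon] = rec
        return rec

    def add_paralog(self, gene: str, taxon: str, residues: str) -> SequenceRecord:
        e = self.entry(gene)
        pid = e.next_paralog_id(taxon)
        rec = SequenceRecord(pid, residues, taxon_code=taxon)
        e.paralogs[pid] = rec
        return rec

    def copy(self) -> "GeneDatabase":
        other = GeneDatabase()
        for g, e in self.genes.items():
            ne = other.entry(g)
            ne.orthologs = dict(e.orthologs)
            ne.paralogs = dict(e.paralogs)
            ne.orthogroups = set(e.orthogroups)
        return other


def read_gene_database(dirpath) -> GeneDatabase:
    """Load a database directory of ``<gene>.fasta`` (+ ``<gene>.paralogs.fasta``).

    Ortholog record ids are taxon codes; paralog ids carry the ``..p<k>`` suffix.
    """
    db = GeneDatabase()
    for fn in sorted(os.listdir(dirpath)):
        if not fn.endswith(".fasta") or fn.endswith(".paralogs.fasta"):
            continue
        gene = fn[: -len(".fasta")]
        for rec in read_fasta(os.path.join(dirpath, fn)):
            db.add_ortholog(gene, rec.unique_id, rec.residues)
        pfile = os.path.join(dirpath, f"{gene}.paralogs.fasta")
        if os.path.exists(pfile):
            entry = db.entry(gene)
            for rec in read_fasta(pfile):
                entry.paralogs[rec.unique_id] = SequenceRecord(
                    rec.unique_id, rec.residues, taxon_code=taxon_of(rec.unique_id)
                )
    if not db.genes:
        raise ValueError(f"no gene FASTA files found in {dirpath}")
    return db


def write_gene_database(db: GeneDatabase, dirpath) -> None:
    os.makedirs(dirpath, exist_ok=True)
    for gene, e in db.genes.items():
        if e.orthologs:
            write_fasta(
                [e.orthologs[t] for t in sorted(e.orthologs)],
                os.path.join(dirpath, f"{gene}.fasta"),
            )
        if e.paralogs:
            write_fasta(
                [e.paralogs[i] for i in sorted(e.paralogs)],
                os.path.join(dirpath, f"{gene}.paralogs.fasta"),
            )


# ---------------------------------------------------------------------------
# Decision file (plain-text replacement for interactive ortholog curation)

DECISIONS = ("ortholog", "paralog", "delete")


@dataclass(frozen=True)
class DecisionRow:
    gene: str
    sequence_id: str
    decision: str

    def __post_init__(self):
        if self.decision not in DECISIONS:
            raise ValueError(
                f"decision {self.decision!r} for {self.sequence_id!r}: must be one of {DECISIONS}"
            )


def read_decision_file(path) -> list[DecisionRow]:
    rows: list[DecisionRow] = []
    seen: set[tuple[str, str]] = set()
    ortho_claims: set[tuple[str, str]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            row = DecisionRow(*parts)
            key = (row.gene, row.sequence_id)
            if key in seen:
                raise ValueError(f"{path}:{ln}: duplicate row for {key}")
            seen.add(key)
            if row.decision == "ortholog":
                claim = (row.gene, taxon_of(row.sequence_id))
                if claim in ortho_claims:
                    raise ValueError(
                        f"{path}:{ln}: second ortholog row for gene/taxon {claim}"
                    )
                ortho_claims.add(claim)
            rows.append(row)
    return rows


def write_decision_file(rows, path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.gene}\t{r.sequence_id}\t{r.decision}\n")


# ---------------------------------------------------------------------------
# Partition table ("gene<TAB>start<TAB>end", 1-based inclusive)

def read_partitions(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, start, end = line.split("\t")
            out.append((gene, int(start), int(end)))
    return out


def write_partitions(partitions, path) -> None:
    with open(path, "w") as fh:
        for gene, start, end in partitions:
            fh.write(f"{gene}\t{start}\t{end}\n")
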