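"""Single-gene processing contracts and supermatrix assembly.

A supermatrix is the concatenation of per-gene trimmed alignments over a
shared taxon set: genes are laid out left to right in lexicographic order,
each contributing a contiguous 1-based inclusive partition; a taxon missing
from a gene is padded with gaps ('-') across that gene's columns. Occupancy
(fraction of genes with data, per taxon) and per-(taxon, gene) presence are
tracked alongside.

External alignment/trimming/tree tools are wrapped as pluggable stage
runners: a stage is a command template with {input}/{output} placeholders
and a declared output kind whose parser validates the result. A passthrough
mode lets the pipeline be exercised without any external binary.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field, replace

from .seqio import (Alignment, SequenceRecord, GeneDatabase, read_fasta,
                    read_newick, write_fasta, write_relaxed_phylip,
                    write_partitions)

GAP = "-"
MISSING_CHARS = set("-X")


# ---------------------------------------------------------------------------
# Per-gene sequence operations

def strip_alignment_chars(records) -> list[SequenceRecord]:
    """Remove gaps and stop characters ('-' and '*') from every record.

    Records left empty are dropped with a warning; the operation is
    idempotent.
    """
    out = []
    for r in records:
        stripped = r.residues.replace(GAP, "").replace("*", "")
        if not stripped:
            warnings.warn(f"sequence {r.unique_id!r} empty after stripping; dropped")
            continue
        out.append(replace(r, residues=stripped))
    return out


def length_filter(aln: Alignment, fraction: float = 0.5) -> Alignment:
    """Drop sequences covering less than ``fraction`` of the alignment.

    Coverage counts non-gap, non-X residues; a sequence at exactly the
    boundary is retained ("less than half" is strict).
    """
    threshold = fraction * aln.n_cols
    kept = [r for r in aln.records
            if sum(c not in MISSING_CHARS for c in r.residues) >= threshold]
    if not kept:
        raise ValueError("length filter removed every sequence")
    return Alignment(kept, check_taxa=False)


# ---------------------------------------------------------------------------
# External stage runner

@dataclass
class StageSpec:
    """One external processing stage.

    ``command`` is a shell-free template containing ``{input}`` and
    ``{output}`` exactly once each (``{threads}`` optional); ``kind``
    declares how the output is validated: ``sequences`` | ``alignment`` |
    ``tree``. ``command=None`` is the passthrough mode used in tests.
    """

    name: str
    command: str | None
    kind: str = "sequences"

    def __post_init__(self):
        if self.kind not in ("sequences", "alignment", "tree"):
            raise ValueError(f"stage {self.name!r}: unknown output kind {self.kind!r}")
        if self.command is not None:
            for ph in ("{input}", "{output}"):
                if self.command.count(ph) != 1:
                    raise ValueError(
                        f"stage {self.name!r}: template must reference {ph} exactly once")


#: Default stage chains; parameters mirror the workflow's published presets.
STAGE_PRESETS = {
    # quick homolog-tree path used while sorting orthologs from paralogs
    "homolog-tree": [
        StageSpec("align", "mafft --auto --reorder {input} > {output}", "alignment"),
        StageSpec("trim", "trimal -in {input} -gt 0.2 -out {output}", "alignment"),
        StageSpec("tree", "fasttree {input} > {output}", "tree"),
    ],
    # single-gene tree path: BMGE gap rate 0.3, permissive trimAl before trees
    "sgt": [
        StageSpec("align", "mafft --globalpair --maxiterate 1000 --unalignlevel 0.6 "
                           "{input} > {output}", "alignment"),
        StageSpec("divvy", "divvier -partial -mincol 4 -divvygap {input} -o {output}",
                  "alignment"),
        StageSpec("bmge", "bmge -i {input} -t AA -g 0.3 -of {output}", "alignment"),
        StageSpec("trim", "trimal -in {input} -gt 0.01 -out {output}", "alignment"),
    ],
    # supermatrix path: strict 80% gap threshold after partial divvying
    "matrix": [
        StageSpec("align", "mafft --globalpair --maxiterate 1000 --unalignlevel 0.6 "
                           "{input} > {output}", "alignment"),
        StageSpec("divvy", "divvier -partial -mincol 4 -divvygap {input} -o {output}",
                  "alignment"),
        StageSpec("trim", "trimal -in {input} -gt 0.80 -out {output}", "alignment"),
    ],
}


def _validate_stage_output(stage: StageSpec, out_path) -> None:
    if stage.kind == "tree":
        read_newick(out_path)
        return
    records = read_fasta(out_path)  # raises on empty
    if stage.kind == "alignment":
        Alignment(records, check_taxa=False)


def run_stage(stage: StageSpec, in_path, out_path):
    """Run one stage; passthrough copies the input byte-for-byte.

    A nonzero exit raises with the captured stderr; the produced file is
    parsed according to the stage's declared kind before being accepted.
    """
    if stage.command is None:
        shutil.copyfile(in_path, out_path)
    else:
        cmd = stage.command.format(input=str(in_path), output=str(out_path), threads=1)
        prog = cmd.split()[0]
        if shutil.which(prog) is None:
            raise FileNotFoundError(
                f"stage {stage.name!r}: required program {prog!r} is not on PATH")
        # '>' redirection is common in these templates; route through a shell
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"stage {stage.name!r} failed (exit {proc.returncode}):\n{proc.stderr}")
    _validate_stage_output(stage, out_path)
    return out_path


def schedule_gene_jobs(n_genes: int, n_threads: int) -> list[tuple[int, int]]:
    """Thread allocation for a batch of per-gene jobs.

    More genes than threads: every job gets one thread (the runner keeps at
    most ``n_threads`` concurrent). Fewer genes than threads: the threads are
    split as evenly as possible (per-job difference at most one).
    """
    if n_genes < 1 or n_threads < 1:
        raise ValueError("need at least one gene and one thread")
    if n_genes >= n_threads:
        return [(g, 1) for g in range(n_genes)]
    base, extra = divmod(n_threads, n_genes)
    return [(g, base + (1 if g < extra else 0)) for g in range(n_genes)]


# ---------------------------------------------------------------------------
# Supermatrix

@dataclass
class Supermatrix:
    alignment: Alignment
    partitions: list[tuple[str, int, int]]  # (gene, start, end), 1-based inclusive
    gene_presence: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols

    def taxa(self) -> list[str]:
        return self.alignment.taxa()

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.partitions]

    @property
    def occupancy(self) -> dict[str, float]:
        genes = self.genes()
        return {t: sum(self.gene_presence.get((t, g), False) for g in genes) / len(genes)
                for t in self.taxa()}

    def slice_gene(self, gene: str) -> Alignment:
        """The input alignment of one gene: its columns, its taxa only."""
        for g, start, end in self.partitions:
            if g == gene:
                idx = list(range(start - 1, end))
                rows = [r for r in self.alignment.records
                        if self.gene_presence.get((r.taxon, gene), False)]
                return Alignment(rows, check_taxa=False).columns(idx)
        raise KeyError(gene)


def concatenate(gene_alignments: dict[str, Alignment],
                taxa: list[str] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix.

    Genes are laid out in lexicographic name order; taxa default to the
    sorted union of all genes' taxa. Missing (taxon, gene) blocks are filled
    with gaps. Partitions tile [1, n_cols] exactly.
    """
    if not gene_alignments:
        raise ValueError("no gene alignments to concatenate")
    gene_order = sorted(gene_alignments)
    if taxa is None:
        all_taxa: set[str] = set()
        for aln in gene_alignments.values():
            all_taxa.update(aln.taxa())
        taxa = sorted(all_taxa)

    partitions: list[tuple[str, int, int]] = []
    presence: dict[tuple[str, str], bool] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for gene in gene_order:
        aln = gene_alignments[gene]
        seen: set[str] = set()
        for r in aln.records:
            if r.taxon in seen:
                raise ValueError(f"duplicate taxon {r.taxon!r} within gene {gene!r}")
            seen.add(r.taxon)
        width = aln.n_cols
        by_taxon = {r.taxon: r.residues for r in aln.records}
        for t in taxa:
            row = by_taxon.get(t)
            presence[(t, gene)] = row is not None
            chunks[t].append(row if row is not None else GAP * width)
        partitions.append((gene, pos, pos + width - 1))
        pos += width

    records = [SequenceRecord(t, "".join(chunks[t]), taxon_code=t) for t in taxa]
    return Supermatrix(Alignment(records), partitions, presence)


def remove_columns(matrix: Supermatrix, cols: set[int]) -> Supermatrix:
    """Drop 0-based columns, preserving survivor order and re-tiling partitions.

    Partitions that lose all their columns are dropped; per-gene presence is
    carried over for surviving genes.
    """
    keep = [i for i in range(matrix.n_cols) if i not in cols]
    new_partitions: list[tuple[str, int, int]] = []
    pos = 1
    kept_genes = []
    import bisect
    for gene, start, end in matrix.partitions:
        width = bisect.bisect_right(keep, end - 1) - bisect.bisect_left(keep, start - 1)
        if width == 0:
            continue
        new_partitions.append((gene, pos, pos + width - 1))
        kept_genes.append(gene)
        pos += width
    if not keep:
        raise ValueError("removal would empty the supermatrix")
    aln = matrix.alignment.columns(keep)
    presence = {(t, g): v for (t, g), v in matrix.gene_presence.items()
                if g in set(kept_genes)}
    return Supermatrix(aln, new_partitions, presence)


def remove_taxa(matrix: Supermatrix, taxa: set[str]) -> Supermatrix:
    kept = [r for r in matrix.alignment.records if r.taxon not in taxa]
    if not kept:
        raise ValueError("removal would drop every taxon")
    presence = {(t, g): v for (t, g), v in matrix.gene_presence.items()
                if t not in taxa}
    return Supermatrix(Alignment(kept), list(matrix.partitions), presence)


def subset_by_occupancy(presence: dict[tuple[str, str], bool],
                        taxa: list[str], genes: list[str],
                        min_taxon_fraction: float = 0.0,
                        min_gene_fraction: float = 0.0):
    """Occupancy-based gene/taxon selection (genes filtered first).

    A gene is kept when the fraction of taxa possessing it is at least
    ``min_gene_fraction``; a taxon is then kept when the fraction of *kept*
    genes it possesses is at least ``min_taxon_fraction``. Single pass.
    """
    for f in (min_taxon_fraction, min_gene_fraction):
        if not 0 <= f <= 1:
            raise ValueError("occupancy fractions must be in [0, 1]")
    n_taxa = len(taxa)
    kept_genes = [g for g in genes
                  if sum(presence.get((t, g), False) for t in taxa) / n_taxa
                  >= min_gene_fraction]
    if not kept_genes:
        raise ValueError("occupancy thresholds removed every gene")
    kept_taxa = [t for t in taxa
                 if sum(presence.get((t, g), False) for g in kept_genes) / len(kept_genes)
                 >= min_taxon_fraction]
    if not kept_taxa:
        raise ValueError("occupancy thresholds removed every taxon")
    return kept_genes, kept_taxa


def collapse_taxa(db: GeneDatabase, otu_map: dict[str, str]) -> GeneDatabase:
    """Combine member taxa into hybrid OTUs building a "most complete" taxon.

    ``otu_map`` maps member taxon -> hybrid name (insertion order breaks
    ties). Per gene, the hybrid's ortholog is the member ortholog with the
    most non-gap residues; remaining member orthologs and all member
    paralogs become paralogs of the hybrid.
    """
    members_of: dict[str, list[str]] = {}
    for member, hybrid in otu_map.items():
        members_of.setdefault(hybrid, []).append(member)
    existing = db.taxa()
    for hybrid in members_of:
        if hybrid in existing:
            raise ValueError(f"hybrid name {hybrid!r} collides with an existing taxon")
    missing = [m for m in otu_map if m not in existing]
    if missing:
        raise ValueError(f"unknown member taxa: {missing}")

    out = db.copy()
    for gene, entry in out.genes.items():
        for hybrid, members in members_of.items():
            present = [m for m in members if m in entry.orthologs]
            if present:
                best = max(present, key=lambda m: (
                    sum(c not in MISSING_CHARS for c in entry.orthologs[m].residues),
                    -members.index(m)))
                rec = entry.orthologs.pop(best)
                entry.orthologs[hybrid] = SequenceRecord(
                    hybrid, rec.residues, taxon_code=hybrid)
                for m in present:
                    if m == best:
                        continue
                    old = entry.orthologs.pop(m)
                    pid = entry.next_paralog_id(hybrid)
                    entry.paralogs[pid] = SequenceRecord(pid, old.residues,
                                                         taxon_code=hybrid)
            for pid in list(entry.paralogs):
                rec = entry.paralogs[pid]
                if rec.taxon_code in members or pid.split("..")[0] in members:
                    del entry.paralogs[pid]
                    npid = entry.next_paralog_id(hybrid)
                    entry.paralogs[npid] = SequenceRecord(npid, rec.residues,
                                                          taxon_code=hybrid)
    return out


# ---------------------------------------------------------------------------
# Output helpers

def write_supermatrix(matrix: Supermatrix, prefix) -> None:
    """Write FASTA + relaxed-PHYLIP supermatrix, partition and occupancy TSVs."""
    write_fasta(matrix.alignment.records, f"{prefix}.fasta", wrap=60)
    write_relaxed_phylip(matrix.alignment, f"{prefix}.phy")
    write_partitions(matrix.partitions, f"{prefix}.partitions.tsv")
    with open(f"{prefix}.occupancy.tsv", "w") as fh:
        for t, frac in sorted(matrix.occupancy.items()):
            fh.write(f"{t}\t{frac:.6f}\n")
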