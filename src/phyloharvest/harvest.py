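"""Ortholog candidate harvesting and prioritization.

Given homology-search results for a new taxon's predicted proteome against a
curated starting database, the harvester builds a per-gene priority list of
candidate sequences, filters it through a fixed rule chain and labels the
top-ranked survivor the putative ortholog (everything else a putative
paralog). Two routes exist:

* **default** — candidates from the profile-HMM search are screened against
  orthogroups (bacterial hit => discard; no hit to the gene's expected
  orthogroup => discard) and then best-hit checked against the database
  (non-reciprocal => discard).
* **informed** — an ortholog of a closely related "seed" taxon is used as a
  BLAST query against the proteome; the HMM candidate list is reprioritized
  by BLAST significance (intersection semantics), then orthogroup-screened;
  non-reciprocal best hits are *retained* but logged. A gene-tree
  taxonomy check (see :mod:`phyloharvest.treecheck`) may finally promote
  candidates nesting with their own higher-taxonomy clade.

Search engines are never invoked here: everything operates on engine-agnostic
:class:`HitTable` objects, parsed from HMMER tabular or BLAST/DIAMOND
outfmt-6 files, or supplied precomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .seqio import SequenceRecord, GeneDatabase, TaxonMeta

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_MAX_CANDIDATES = 5


@dataclass(frozen=True)
class HitRow:
    query_id: str
    target_id: str
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("negative e-value")


class HitTable:
    """Homology-search rows; one row per (query, target), best e-value kept."""

    def __init__(self, rows=(), engine_tag: str = ""):
        best: dict[tuple[str, str], HitRow] = {}
        for row in rows:
            key = (row.query_id, row.target_id)
            old = best.get(key)
            if old is None or (row.evalue, -row.bitscore) < (old.evalue, -old.bitscore):
                best[key] = row
        self.rows = list(best.values())
        self.engine_tag = engine_tag

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def sorted_rows(self) -> list[HitRow]:
        """Deterministic significance order: e-value asc, bitscore desc, id asc."""
        return sorted(self.rows, key=lambda r: (r.evalue, -r.bitscore, r.target_id))

    def significant(self, cutoff: float = DEFAULT_EVALUE_CUTOFF) -> "HitTable":
        return HitTable([r for r in self.rows if r.evalue < cutoff], self.engine_tag)

    def best(self) -> HitRow | None:
        rows = self.sorted_rows()
        return rows[0] if rows else None


def parse_hmmer_tblout(path, engine_tag: str = "hmmsearch") -> HitTable:
    """Parse HMMER3 per-target tabular output (``--tblout``).

    Only the full-sequence e-value/score columns are used; domain rows are
    represented once per target by construction of the table.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            # target, t-acc, query, q-acc, full-seq E-value, full-seq score
            rows.append(HitRow(query_id=f[2], target_id=f[0],
                               evalue=float(f[4]), bitscore=float(f[5])))
    return HitTable(rows, engine_tag)


def parse_tabular_hits(path, engine_tag: str = "blast",
                       evalue_col: int = 10, bitscore_col: int = 11) -> HitTable:
    """Parse BLAST/DIAMOND tabular output (default outfmt-6 column order)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(HitRow(query_id=f[0], target_id=f[1],
                               evalue=float(f[evalue_col]),
                               bitscore=float(f[bitscore_col])))
    return HitTable(rows, engine_tag)


@dataclass
class HarvestConfig:
    max_candidates: int = DEFAULT_MAX_CANDIDATES
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    redundancy_threshold: float = 0.98
    orthogroup_min_fraction: float = 0.10

    def __post_init__(self):
        if self.max_candidates <= 0:
            raise ValueError("max_candidates must be positive")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if not 0 < self.redundancy_threshold <= 1:
            raise ValueError("redundancy_threshold must be in (0, 1]")


@dataclass
class OrthogroupMap:
    """Orthogroup domain tags plus each gene's expected orthogroup ids."""

    domain: dict[str, str] = field(default_factory=dict)  # og id -> bacterial / non_bacterial
    expected: dict[str, set[str]] = field(default_factory=dict)  # gene -> og ids

    def is_bacterial(self, og: str) -> bool:
        return self.domain.get(og) == "bacterial"

    def expected_for(self, gene: str) -> set[str]:
        groups = self.expected.get(gene)
        if not groups:
            raise ValueError(f"gene {gene!r} has no expected orthogroup; unusable")
        return groups


STATUS_ORTHOLOG = "putative_ortholog"
STATUS_PARALOG = "putative_paralog"
STATUS_DISCARDED = "discarded"


@dataclass
class Candidate:
    record: SequenceRecord
    rank: int | None = None
    status: str = STATUS_DISCARDED
    discard_reason: str | None = None
    nonreciprocal_note: str | None = None

    @property
    def seq_id(self) -> str:
        return self.record.unique_id


@dataclass
class CandidateSet:
    """Ordered, status-annotated candidates of one gene for one taxon."""

    gene: str
    taxon: str
    candidates: list[Candidate] = field(default_factory=list)

    def survivors(self) -> list[Candidate]:
        return [c for c in self.candidates if c.status != STATUS_DISCARDED]

    def ortholog(self) -> Candidate | None:
        for c in self.candidates:
            if c.status == STATUS_ORTHOLOG:
                return c
        return None


# ---------------------------------------------------------------------------
# Redundancy removal (greedy global-identity clustering, longest first)

_aligner = Align.PairwiseAligner(
    mode="global", match_score=1.0, mismatch_score=0.0,
    open_gap_score=-0.5, extend_gap_score=-0.1,
)


def global_identity(a: str, b: str) -> float:
    """Matches in the best global alignment divided by the shorter length."""
    aln = _aligner.align(a, b)[0]
    matches = aln.counts().identities
    return matches / min(len(a), len(b))


def dedupe_proteome(records, threshold: float = 0.98):
    """Greedy redundancy clustering at a global-identity threshold.

    Sequences are visited longest first (ties by input order); a sequence
    joins the first existing cluster whose representative it matches at
    ``>= threshold`` identity, otherwise it founds a new cluster. Returns
    ``(representatives, cluster_map)`` with representatives in visit order.
    """
    records = list(records)
    if not records:
        raise ValueError("empty proteome")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    reps: list[SequenceRecord] = []
    cluster_map: dict[str, str] = {}
    for i in order:
        rec = records[i]
        for rep in reps:
            if global_identity(rec.residues, rep.residues) >= threshold:
                cluster_map[rec.unique_id] = rep.unique_id
                break
        else:
            reps.append(rec)
            cluster_map[rec.unique_id] = rec.unique_id
    return reps, cluster_map


# ---------------------------------------------------------------------------
# Rule chain

def collect_candidates(hits: HitTable, cfg: HarvestConfig) -> list[str]:
    """Initial priority list from the profile-HMM search.

    Targets below the significance cutoff, in significance order, truncated
    to ``max_candidates``. An empty list means the gene is skipped for this
    taxon.
    """
    sig = hits.significant(cfg.evalue_cutoff).sorted_rows()
    out: list[str] = []
    for row in sig:
        if row.target_id not in out:
            out.append(row.target_id)
        if len(out) == cfg.max_candidates:
            break
    return out


DISCARD_BACTERIAL = "bacterial_orthogroup"
DISCARD_NO_EXPECTED = "no_expected_orthogroup_hit"
DISCARD_NONRECIPROCAL = "non_reciprocal_best_hit"
DISCARD_NO_BLAST = "no_significant_blast_hit"


def orthomcl_filter(candidates: list[str], per_candidate_hits: dict[str, HitTable],
                    gene: str, groups: OrthogroupMap, cfg: HarvestConfig):
    """Screen candidates against orthogroup assignments.

    A candidate with any significant hit to a bacterial orthogroup is
    discarded (this rule dominates); a candidate with no significant hit to
    any of the gene's expected orthogroups is discarded. Survivors keep
    their relative order. Returns ``(survivors, discards)`` where discards
    are ``(seq_id, reason)`` pairs.
    """
    expected = groups.expected_for(gene)
    survivors: list[str] = []
    discards: list[tuple[str, str]] = []
    for cid in candidates:
        sig = per_candidate_hits.get(cid, HitTable()).significant(cfg.evalue_cutoff)
        ogs = {r.target_id for r in sig}
        if any(groups.is_bacterial(og) for og in ogs):
            discards.append((cid, DISCARD_BACTERIAL))
        elif not ogs & expected:
            discards.append((cid, DISCARD_NO_EXPECTED))
        else:
            survivors.append(cid)
    return survivors, discards


def database_bbh_check(candidates: list[str], db_hits: dict[str, HitTable],
                       gene: str, gene_of_target, route: str = "default"):
    """Best-hit check of each candidate against the starting database.

    ``gene_of_target`` maps a database sequence id to its gene name. Under
    the default route, a candidate whose best database hit belongs to another
    gene is discarded; under the informed route it is retained with a note,
    and a log row ``(seq_id, other_gene)`` is emitted (the on-disk log is the
    ``non-reciprocal_hits.txt`` file). A candidate with no database hit is
    treated as non-reciprocal.

    Returns ``(survivors, discards, notes, log)``.
    """
    if route not in ("default", "informed"):
        raise ValueError(f"unknown route {route!r}")
    survivors: list[str] = []
    discards: list[tuple[str, str]] = []
    notes: dict[str, str] = {}
    log: list[tuple[str, str]] = []
    for cid in candidates:
        best = db_hits.get(cid, HitTable()).best()
        best_gene = gene_of_target(best.target_id) if best else None
        if best_gene == gene:
            survivors.append(cid)
        elif route == "default":
            discards.append((cid, DISCARD_NONRECIPROCAL))
        else:
            survivors.append(cid)
            note = best_gene if best_gene is not None else "no_hit"
            notes[cid] = note
            log.append((cid, note))
    return survivors, discards, notes, log


SEED_FOUND = "seed"
SEED_FALLBACK = "fallback_to_default"


def select_seed(gene: str, meta: TaxonMeta, db: GeneDatabase,
                skip_seeds: set[str] = frozenset()):
    """Pick the first listed seed taxon that has an ortholog for ``gene``.

    ``skip_seeds`` lets the caller retry after a seed produced no significant
    BLAST hit. Returns ``(SEED_FOUND, seed_taxon, record)`` or
    ``(SEED_FALLBACK, None, None)`` when no listed taxon has the gene.
    """
    entry = db.genes.get(gene)
    for seed in meta.blast_seeds:
        if seed in skip_seeds:
            continue
        if entry is not None and seed in entry.orthologs:
            return SEED_FOUND, seed, entry.orthologs[seed]
    return SEED_FALLBACK, None, None


def informed_reprioritize(hmm_candidates: list[str], blast_hits: HitTable,
                          cfg: HarvestConfig) -> list[str] | None:
    """Rebuild the priority list from seed-BLAST significance.

    The new list is the significant BLAST targets, in BLAST order, restricted
    to sequences that were also collected by the HMM search (BLAST-only
    targets are discarded; HMM-only candidates drop off the list), truncated
    to ``max_candidates``. ``None`` signals "no significant BLAST hit" —
    the caller should try the next seed or skip the gene.
    """
    sig = blast_hits.significant(cfg.evalue_cutoff).sorted_rows()
    if not sig:
        return None
    hmm_set = set(hmm_candidates)
    out: list[str] = []
    for row in sig:
        if row.target_id in hmm_set and row.target_id not in out:
            out.append(row.target_id)
        if len(out) == cfg.max_candidates:
            break
    return out


def finalize_candidates(survivor_records: list[SequenceRecord], gene: str,
                        new_taxon: str, discards=(), notes=None) -> CandidateSet:
    """Assign ranks and statuses: rank 1 is the putative ortholog.

    An empty survivor list yields a CandidateSet with no surviving candidate
    (the gene is simply absent for the taxon). Discarded candidates are kept
    in the set for reporting.
    """
    notes = notes or {}
    cs = CandidateSet(gene=gene, taxon=new_taxon)
    for rank, rec in enumerate(survivor_records, start=1):
        status = STATUS_ORTHOLOG if rank == 1 else STATUS_PARALOG
        cs.candidates.append(Candidate(
            record=SequenceRecord(rec.unique_id, rec.residues, taxon_code=new_taxon),
            rank=rank, status=status,
            nonreciprocal_note=notes.get(rec.unique_id),
        ))
    for cid, reason in discards:
        cs.candidates.append(Candidate(
            record=SequenceRecord(cid, "X", taxon_code=new_taxon),
            status=STATUS_DISCARDED, discard_reason=reason,
        ))
    return cs


def refresh_statuses(cs: CandidateSet) -> None:
    """Recompute ranks/statuses after a reordering of survivors."""
    rank = 0
    for c in cs.candidates:
        if c.status == STATUS_DISCARDED:
            continue
        rank += 1
        c.rank = rank
        c.status = STATUS_ORTHOLOG if rank == 1 else STATUS_PARALOG


def apply_to_database(db: GeneDatabase, cs: CandidateSet) -> None:
    """Append a finalized candidate set to the database.

    The putative ortholog becomes the taxon's ortholog record; putative
    paralogs get collision-free ``<taxon>..p<k>`` ids.
    """
    entry = db.entry(cs.gene)
    for c in cs.survivors():
        if c.status == STATUS_ORTHOLOG:
            db.add_ortholog(cs.gene, cs.taxon, c.record.residues)
        else:
            db.add_paralog(cs.gene, cs.taxon, c.record.residues)


# ---------------------------------------------------------------------------
# Orthogroup assignment (database building)

def assign_orthogroups(gene_records: list[SequenceRecord],
                       orthomcl_hits: dict[str, HitTable],
                       groups: OrthogroupMap, cfg: HarvestConfig):
    """Assign orthogroups to a gene from its sequences' orthogroup hits.

    An orthogroup is assigned when at least ``orthogroup_min_fraction`` of
    the gene's sequences hit it significantly. Returns ``(assigned, usable)``;
    a gene with no assignment, or with exclusively bacterial assignments, is
    unusable in the workflow.
    """
    if not gene_records:
        raise ValueError("gene has no sequences")
    n = len(gene_records)
    counts: dict[str, int] = {}
    for rec in gene_records:
        sig = orthomcl_hits.get(rec.unique_id, HitTable()).significant(cfg.evalue_cutoff)
        for og in {r.target_id for r in sig}:
            counts[og] = counts.get(og, 0) + 1
    assigned = {og for og, c in counts.items() if c / n >= cfg.orthogroup_min_fraction}
    usable = bool(assigned) and not all(groups.is_bacterial(og) for og in assigned)
    return assigned, usable


# ---------------------------------------------------------------------------
# Per-gene driver (precomputed-hit mode)

@dataclass
class PrecomputedSearch:
    """All search results a harvest run needs, supplied up front.

    * ``hmm`` — gene -> HitTable of the profile-HMM search on the proteome.
    * ``orthomcl`` — proteome seq id -> HitTable against orthogroups.
    * ``db`` — proteome seq id -> HitTable against the starting database.
    * ``seed_blast`` — (gene, seed_taxon) -> HitTable of the seed ortholog
      BLASTed against the proteome (informed route only).
    """

    hmm: dict[str, HitTable] = field(default_factory=dict)
    orthomcl: dict[str, HitTable] = field(default_factory=dict)
    db: dict[str, HitTable] = field(default_factory=dict)
    seed_blast: dict[tuple[str, str], HitTable] = field(default_factory=dict)


def harvest_gene(gene: str, new_taxon: str, proteome: dict[str, SequenceRecord],
                 search: PrecomputedSearch, meta: TaxonMeta, db: GeneDatabase,
                 groups: OrthogroupMap, cfg: HarvestConfig | None = None,
                 gene_of_target=None) -> CandidateSet:
    """Run the full rule chain for one gene of one new taxon.

    The route is chosen from the metadata: listed blast seeds select the
    phylogenetically informed route, otherwise the default route is used.
    Tree-informed reprioritization is a separate, later step
    (:func:`phyloharvest.treecheck.tree_reprioritize`) because it needs a
    gene tree built after the candidates are aligned.
    """
    cfg = cfg or HarvestConfig()
    if gene_of_target is None:
        gene_of_target = _db_gene_lookup(db)

    hmm_candidates = collect_candidates(search.hmm.get(gene, HitTable()), cfg)
    if not hmm_candidates:
        return CandidateSet(gene=gene, taxon=new_taxon)

    route = "informed" if meta.blast_seeds else "default"
    candidates = hmm_candidates
    discards: list[tuple[str, str]] = []

    if route == "informed":
        tried: set[str] = set()
        reprioritized = None
        while True:
            verdict, seed, _seed_rec = select_seed(gene, meta, db, skip_seeds=tried)
            if verdict == SEED_FALLBACK:
                break
            tried.add(seed)
            blast = search.seed_blast.get((gene, seed), HitTable())
            reprioritized = informed_reprioritize(hmm_candidates, blast, cfg)
            if reprioritized is not None:
                break
        if not tried:
            route = "default"  # no listed seed has this gene
        elif reprioritized is None:
            # every seed's BLAST came back empty: gene skipped for this taxon
            return CandidateSet(gene=gene, taxon=new_taxon)
        else:
            dropped = [c for c in hmm_candidates if c not in reprioritized]
            discards.extend((c, DISCARD_NO_BLAST) for c in dropped)
            candidates = reprioritized

    candidates, og_discards = orthomcl_filter(
        candidates, search.orthomcl, gene, groups, cfg)
    discards.extend(og_discards)

    candidates, bbh_discards, notes, _log = database_bbh_check(
        candidates, search.db, gene, gene_of_target, route=route)
    discards.extend(bbh_discards)

    survivor_records = [proteome[cid] for cid in candidates]
    return finalize_candidates(survivor_records, gene, new_taxon,
                               discards=discards, notes=notes)


def _db_gene_lookup(db: GeneDatabase):
    index: dict[str, str] = {}
    for gene, e in db.genes.items():
        for taxon in e.orthologs:
            index[f"{gene}|{taxon}"] = gene
        for pid in e.paralogs:
            index[f"{gene}|{pid}"] = gene

    def lookup(target_id: str) -> str | None:
        return index.get(target_id)

    return lookup
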