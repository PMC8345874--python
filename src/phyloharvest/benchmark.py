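"""End-to-end ortholog-recovery benchmark on simulated gene families.

A species tree is simulated, a starting database is built from the truth
orthologs (and paralogs) of a "database" subset of taxa, and the remaining
taxa are harvested back through the full rule chain in precomputed-hit mode
(mock hit tables derived from sequence identity). Gene trees for the
tree-informed reprioritization step are built by average-linkage clustering
of pairwise mismatch distances — crude, but sufficient to place contaminant
sequences inside their donor clade.

Precision is the fraction of reported putative orthologs whose truth label
is "ortholog"; recall the fraction of surviving true orthologs reported.
Under clean conditions (no duplications, no contamination, no loss) both
are exactly 1; under the default noisy regime both stay high because
paralogs rank below orthologs in seed-BLAST identity and contaminants fail
the taxonomy nestedness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import harvest as hv
from . import synth
from .explore import _linkage_to_newick
from .seqio import GeneDatabase, TaxonMeta, read_newick
from .treecheck import tree_reprioritize


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    n_predicted: int
    n_truth: int
    n_correct: int


def _upgma_gene_tree(records):
    labels = [r.unique_id for r in records]
    n = len(labels)
    mat = np.zeros((n, n))
    enc = [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.mean(enc[i] != enc[j]))
            mat[i, j] = mat[j, i] = d
    link = linkage(squareform(mat), method="average")
    return read_newick(_linkage_to_newick(link, labels))


def run_recovery_benchmark(seed: int, n_taxa: int = 12, n_genes: int = 30,
                           dup_prob: float = 0.3, contam_rate: float = 0.1,
                           loss_rate: float = 0.1, n_new: int = 4,
                           birth_rate: float = 4.0, n_sites: int = 200,
                           use_tree_check: bool = True) -> RecoveryResult:
    """Simulate, harvest back, and score ortholog identification."""
    tree = synth.simulate_tree(n_taxa, seed=seed, birth_rate=birth_rate)
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    new_taxa = taxa[-n_new:]
    db_taxa = [t for t in taxa if t not in new_taxa]

    fams = synth.simulate_gene_families(
        tree, n_genes, dup_prob=dup_prob, contam_rate=contam_rate,
        loss_rate=loss_rate, seed=seed + 1, n_sites=n_sites,
        recipient_taxa=new_taxa)

    # starting database: truth orthologs (and paralogs) of the db taxa
    db = GeneDatabase()
    for gene, members in fams.families.items():
        for rec in members:
            if rec.taxon_code not in db_taxa:
                continue
            role = fams.truth.role(rec.unique_id)
            if role == synth.ROLE_ORTHOLOG:
                db.add_ortholog(gene, rec.taxon_code, rec.residues)
            elif role == synth.ROLE_PARALOG:
                db.add_paralog(gene, rec.taxon_code, rec.residues)

    # higher taxonomy: the two clades either side of the root split
    root_children = tree.seed_node.child_nodes()
    clade_a = {lf.taxon.label for lf in root_children[0].leaf_iter()}
    taxonomy = {t: ("CladeA" if t in clade_a else "CladeB") for t in taxa}

    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace}

    predicted: dict[tuple[str, str], str] = {}
    for new_taxon in new_taxa:
        seeds = sorted((t for t in db_taxa),
                       key=lambda t: pdm.patristic_distance(lookup[new_taxon],
                                                            lookup[t]))[:2]
        meta = TaxonMeta(unique_id=new_taxon,
                         higher_taxonomy=taxonomy[new_taxon],
                         blast_seeds=seeds)
        search, groups = synth.build_mock_search(fams, db, new_taxon, db_taxa)
        proteome = {r.unique_id: r for r in fams.proteomes[new_taxon]}
        tax_map = dict(taxonomy)
        for sid, row in fams.truth.rows.items():
            tax_map.setdefault(sid, taxonomy.get(row.taxon, "?"))

        for gene in db.genes:
            cs = hv.harvest_gene(gene, new_taxon, proteome, search, meta, db,
                                 groups)
            if use_tree_check and len(cs.survivors()) > 1:
                entry = db.genes[gene]
                members = ([entry.orthologs[t] for t in sorted(entry.orthologs)]
                           + [c.record for c in cs.survivors()])
                gtree = _upgma_gene_tree(members)
                cs = tree_reprioritize(cs, gtree, tax_map)
            orth = cs.ortholog()
            if orth is not None:
                predicted[(gene, new_taxon)] = orth.seq_id

    truth_orthologs = {
        (row.gene, row.taxon): sid
        for sid, row in fams.truth.rows.items()
        if row.role == synth.ROLE_ORTHOLOG and row.taxon in new_taxa
    }
    n_correct = sum(1 for key, sid in predicted.items()
                    if truth_orthologs.get(key) == sid)
    precision = n_correct / len(predicted) if predicted else float("nan")
    recall = (sum(1 for key, sid in truth_orthologs.items()
                  if predicted.get(key) == sid) / len(truth_orthologs)
              if truth_orthologs else float("nan"))
    return RecoveryResult(precision=precision, recall=recall,
                          n_predicted=len(predicted),
                          n_truth=len(truth_orthologs), n_correct=n_correct)
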