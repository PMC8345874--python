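"""Taxonomy-aware inspection of single-gene trees and database curation.

After candidate sequences are appended to a gene's alignment and a gene tree
is built, candidates that branch *sister to or within* a clade of taxa
sharing their own higher taxonomy are promoted over candidates that do not —
a strong signal against contaminant sequences, which typically nest inside a
foreign clade. The test is evaluated locally at the candidate's attachment
node over the adjacent subtrees, which makes it insensitive to where the
(unrooted) gene tree happens to be rooted.

Manual curation is expressed as a plain-text decision file (gene, sequence
id, ortholog/paralog/delete) applied transactionally to the database.
"""

from __future__ import annotations

import dendropy

from .seqio import GeneDatabase, DecisionRow, SequenceRecord, taxon_of
from . import harvest as hv

TaxonomyMap = dict  # sequence id or taxon code -> higher taxonomy string


def _lookup_taxonomy(tax: TaxonomyMap, leaf_label: str) -> str | None:
    if leaf_label in tax:
        return tax[leaf_label]
    return tax.get(taxon_of(leaf_label))


def _adjacent_leaf_sets(tree: dendropy.Tree, leaf_label: str) -> list[set[str]]:
    """Leaf-label sets of each subtree adjacent to the leaf's attachment node.

    The tree is treated as an unrooted graph; the attachment node is the
    node the candidate leaf hangs from, and each incident edge other than
    the one leading to the candidate defines one adjacent subtree.
    """
    target = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == leaf_label:
            target = lf
            break
    if target is None:
        raise ValueError(f"leaf {leaf_label!r} not found in tree")
    attach = target.parent_node
    if attach is None:  # single-leaf degenerate tree
        return []

    def neighbors(node):
        out = list(node.child_nodes())
        if node.parent_node is not None:
            out.append(node.parent_node)
        return out

    # A Newick bifurcating root is an artifact of rooted storage: if the
    # attachment node has degree 2 in the unrooted graph, pass through it so
    # the candidate's true attachment (and its separate adjacent subtrees)
    # is analyzed.
    blocked = target
    while True:
        nbs = [nb for nb in neighbors(attach) if nb is not blocked]
        if len(nbs) == 1 and not nbs[0].is_leaf():
            blocked, attach = attach, nbs[0]
            continue
        break

    sets = []
    for nb in neighbors(attach):
        if nb is blocked:
            continue
        # collect leaves reachable from nb without crossing attach
        leaves: set[str] = set()
        stack = [(nb, attach)]
        while stack:
            node, came_from = stack.pop()
            if node.is_leaf():
                leaves.add(node.taxon.label)
            for nxt in neighbors(node):
                if nxt is not came_from:
                    stack.append((nxt, node))
        sets.append(leaves)
    return sets


def candidate_is_taxonomically_nested(tree: dendropy.Tree, candidate_leaf: str,
                                      tax: TaxonomyMap) -> bool:
    """True iff the candidate branches sister to or within its own clade.

    At the candidate's attachment node, at least one adjacent subtree must be
    non-empty with *all* leaves sharing the candidate's higher taxonomy.
    A lone same-taxonomy sister leaf qualifies (two-leaf cherry).
    """
    own = _lookup_taxonomy(tax, candidate_leaf)
    for leaves in _adjacent_leaf_sets(tree, candidate_leaf):
        if not leaves:
            continue
        if all(_lookup_taxonomy(tax, lf) == own for lf in leaves):
            return True
    return False


def tree_reprioritize(cs: hv.CandidateSet, tree: dendropy.Tree,
                      tax: TaxonomyMap) -> hv.CandidateSet:
    """Stable partition of survivors: taxonomically nested candidates first.

    Candidates absent from the tree are treated as non-nested. Statuses and
    ranks are recomputed from the new order; discarded candidates keep their
    positions at the tail.
    """
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    survivors = cs.survivors()
    nested = [c for c in survivors if c.seq_id in present
              and candidate_is_taxonomically_nested(tree, c.seq_id, tax)]
    rest = [c for c in survivors if c not in nested]
    out = hv.CandidateSet(gene=cs.gene, taxon=cs.taxon)
    out.candidates = nested + rest + [c for c in cs.candidates
                                      if c.status == hv.STATUS_DISCARDED]
    hv.refresh_statuses(out)
    return out


# ---------------------------------------------------------------------------
# Decision-file application

def apply_decisions(db: GeneDatabase, decisions: list[DecisionRow]) -> GeneDatabase:
    """Apply curation decisions, validating everything before mutating.

    ``delete`` removes the sequence permanently; ``ortholog`` promotes a
    sequence to the taxon's ortholog slot (displacing any previous ortholog
    to the paralog set); ``paralog`` demotes an ortholog. Total sequence
    count is conserved except for delete rows.
    """
    # validation pass
    ortho_rows: set[tuple[str, str]] = set()
    for row in decisions:
        entry = db.genes.get(row.gene)
        if entry is None:
            raise ValueError(f"unknown gene {row.gene!r} in decision file")
        taxon = taxon_of(row.sequence_id)
        if row.sequence_id not in entry.paralogs and taxon not in entry.orthologs:
            raise ValueError(
                f"decision references unknown sequence {row.sequence_id!r} of gene {row.gene!r}")
        if row.decision == "ortholog":
            key = (row.gene, taxon)
            if key in ortho_rows:
                raise ValueError(f"two ortholog decisions for gene/taxon {key}")
            ortho_rows.add(key)

    out = db.copy()
    for row in decisions:
        entry = out.entry(row.gene)
        taxon = taxon_of(row.sequence_id)
        is_paralog_id = row.sequence_id in entry.paralogs
        if row.decision == "delete":
            if is_paralog_id:
                del entry.paralogs[row.sequence_id]
            elif taxon in entry.orthologs:
                del entry.orthologs[taxon]
        elif row.decision == "paralog":
            if not is_paralog_id and taxon in entry.orthologs:
                rec = entry.orthologs.pop(taxon)
                pid = entry.next_paralog_id(taxon)
                entry.paralogs[pid] = SequenceRecord(pid, rec.residues, taxon_code=taxon)
        elif row.decision == "ortholog":
            if is_paralog_id:
                rec = entry.paralogs.pop(row.sequence_id)
                if taxon in entry.orthologs:
                    old = entry.orthologs.pop(taxon)
                    pid = entry.next_paralog_id(taxon)
                    entry.paralogs[pid] = SequenceRecord(pid, old.residues, taxon_code=taxon)
                entry.orthologs[taxon] = SequenceRecord(taxon, rec.residues, taxon_code=taxon)
            # an "ortholog" row for the current ortholog is a no-op
    return out


def purge_taxa(db: GeneDatabase, taxa=(), higher_groups=(),
               metadata=None) -> GeneDatabase:
    """Permanently remove taxa (or whole higher-taxonomy groups) from every gene."""
    targets = set(taxa)
    if higher_groups:
        if metadata is None:
            raise ValueError("higher-taxonomy purge requires the metadata table")
        groups = set(higher_groups)
        for uid, m in metadata.items():
            if m.higher_taxonomy in groups:
                targets.add(uid)
    known = db.taxa()
    unknown = sorted(targets - known)
    if unknown:
        raise ValueError(f"cannot purge unknown taxa: {unknown}")
    out = db.copy()
    for entry in out.genes.values():
        for t in list(entry.orthologs):
            if t in targets:
                del entry.orthologs[t]
        for pid in list(entry.paralogs):
            if taxon_of(pid) in targets:
                del entry.paralogs[pid]
    return out


def gene_report(cs: hv.CandidateSet, tree: dendropy.Tree | None = None,
                tax: TaxonomyMap | None = None) -> str:
    """Plain-text per-gene report of candidate designations.

    Replaces an interactive viewer: leaf order (when a tree is given),
    higher-taxonomy tags and current designations, ready to be edited into a
    decision file.
    """
    lines = [f"# gene {cs.gene}  taxon {cs.taxon}"]
    order = [lf.taxon.label for lf in tree.leaf_node_iter()] if tree else None
    cands = {c.seq_id: c for c in cs.candidates}
    listed: set[str] = set()
    if order:
        for lf in order:
            c = cands.get(lf)
            tag = f"[{_lookup_taxonomy(tax or {}, lf) or '?'}]"
            if c is None:
                lines.append(f"  {lf}\t{tag}\tdatabase")
            else:
                listed.add(lf)
                lines.append(f"  {lf}\t{tag}\t{c.status}")
    for c in cs.candidates:
        if c.seq_id not in listed and order is not None:
            lines.append(f"  {c.seq_id}\t[?]\t{c.status}"
                         + (f" ({c.discard_reason})" if c.discard_reason else ""))
        elif order is None:
            lines.append(f"  {c.seq_id}\t{c.status}"
                         + (f" ({c.discard_reason})" if c.discard_reason else ""))
    return "\n".join(lines) + "\n"
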