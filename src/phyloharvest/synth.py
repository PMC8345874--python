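"""Synthetic data with ground truth for end-to-end exercise of the pipeline.

Three layers:

1. Random species trees from a Yule (pure-birth) process with exponential
   branch lengths.
2. Sequence evolution along a tree under a single-matrix amino-acid
   replacement model (LG exchangeabilities by default) with discrete-gamma
   among-site rate variation; an optional heterotachy specification rescales
   a taxon subset's branches on a random subset of sites. This simulator
   also powers the null distribution of the heterotachy utility.
3. Gene families on a species tree: one true ortholog per taxon per gene,
   optional in-paralogs (a duplication grafted at a random internal node),
   contaminant sequences copied in from a distant donor lineage, gene loss,
   and unrelated decoy sequences — every sequence carrying a truth label.

A mock-search harness converts simulated families into the engine-agnostic
hit tables the harvester consumes, using an identity-derived e-value
surrogate (``evalue = exp(-k * identity * length)``). The surrogate is a
test-harness convention, not a statistical model of search significance.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .seqio import AA_ALPHABET, Alignment, SequenceRecord, GeneDatabase, read_newick
from .harvest import HitRow, HitTable

# ---------------------------------------------------------------------------
# Substitution model

@dataclass
class SubstitutionModel:
    """Reversible 20-state model: exchangeabilities, frequencies, gamma rates."""

    exchangeabilities: np.ndarray  # 20x20 symmetric, zero diagonal
    frequencies: np.ndarray       # sums to 1, strictly positive
    alpha: float = 1.0            # gamma shape for among-site rate variation
    n_categories: int = 4

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.frequencies, float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be 20x20 symmetric")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        self.frequencies = pi / pi.sum()
        self.exchangeabilities = s
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to zero, normalized to one expected
        substitution per unit branch length at stationarity."""
        q = self.exchangeabilities * self.frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(self.frequencies, np.diag(q))
        return q / scale

    def category_rates(self) -> np.ndarray:
        """Mean-one discrete-gamma category rates (equal-probability bins)."""
        k = self.n_categories
        if k == 1:
            return np.ones(1)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), self.alpha,
                               scale=1.0 / self.alpha)
        # category rate = mean of the gamma restricted to the bin
        cdf_upper = gamma_dist.cdf(edges[1:], self.alpha + 1, scale=1.0 / self.alpha)
        cdf_lower = gamma_dist.cdf(edges[:-1], self.alpha + 1, scale=1.0 / self.alpha)
        rates = (cdf_upper - cdf_lower) * k
        return rates / np.mean(rates)


def lg_model(alpha: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    """The LG replacement model (Le & Gascuel 2008) with discrete-gamma rates.

    Exchangeabilities and stationary frequencies are bundled as a plain-text
    data file with the package.
    """
    ref = importlib.resources.files("phyloharvest").joinpath("data/lg.tsv")
    lines = [ln.split("\t") for ln in ref.read_text().strip().splitlines()]
    header = [h.strip() for h in lines[0]]
    order = [header.index(aa) for aa in AA_ALPHABET]
    rows = {ln[0].strip(): [float(x) for x in ln[1:]] for ln in lines[1:]}
    s = np.zeros((20, 20))
    for i, aa_i in enumerate(AA_ALPHABET):
        vals = rows[aa_i]
        for j, aa_j in enumerate(AA_ALPHABET):
            s[i, j] = vals[header.index(aa_j)]
    pi = np.array([rows["FREQ"][header.index(aa)] for aa in AA_ALPHABET])
    return SubstitutionModel(s, pi, alpha=alpha, n_categories=n_categories)


def poisson_model(alpha: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    """Equal-exchangeability, equal-frequency model (useful in tests)."""
    s = np.ones((20, 20))
    np.fill_diagonal(s, 0.0)
    return SubstitutionModel(s, np.full(20, 0.05), alpha=alpha,
                             n_categories=n_categories)


# ---------------------------------------------------------------------------
# Yule trees

def simulate_tree(n_taxa: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth tree with exponential waiting times.

    Starting from two lineages, each speciation interval is Exp(k * birth);
    a final Exp(n * birth) stretch extends all terminal branches so the
    expected mean branch length is 1 / (2 * birth_rate). Deterministic for
    a given seed; leaves are labeled t1..tn.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    parts = {0: None, 1: 0, 2: 0}  # node id -> parent id
    pending = {1: 0.0, 2: 0.0}
    lengths: dict[int, float] = {}
    next_id = 3
    while len(pending) < n_taxa:
        k = len(pending)
        t = rng.exponential(1.0 / (k * birth_rate))
        for nid in pending:
            pending[nid] += t
        split = rng.choice(sorted(pending))
        lengths[split] = pending.pop(split)
        for _ in range(2):
            parts[next_id] = split
            pending[next_id] = 0.0
            next_id += 1
    t = rng.exponential(1.0 / (n_taxa * birth_rate))
    for nid, acc in pending.items():
        lengths[nid] = acc + t

    children: dict[int, list[int]] = {}
    for nid, parent in parts.items():
        if parent is not None:
            children.setdefault(parent, []).append(nid)
    label_counter = [0]

    def render(nid: int) -> str:
        if nid in children:
            inner = ",".join(render(c) for c in children[nid])
            body = f"({inner})"
        else:
            label_counter[0] += 1
            body = f"t{label_counter[0]}"
        if nid == 0:
            return body + ";"
        return f"{body}:{lengths[nid]:.10f}"

    return read_newick(render(0))


# ---------------------------------------------------------------------------
# Sequence evolution

@dataclass
class HeterotachySpec:
    """Branch rescaling of a taxon subset on a random fraction of sites."""

    taxa: frozenset
    branch_scale: float = 5.0
    site_fraction: float = 0.5


def _descendant_leaves(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def simulate_alignment(tree: dendropy.Tree, model: SubstitutionModel,
                       n_sites: int, seed: int,
                       heterotachy_spec: HeterotachySpec | None = None,
                       return_internal: bool = False):
    """Evolve ``n_sites`` columns along ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies; each site gets a
    discrete-gamma rate category; transitions use the matrix exponential of
    the normalized rate matrix. With a heterotachy spec, branches whose
    descendant leaves all belong to the spec's taxon set are rescaled on a
    random site subset; the returned site mask flags those sites.

    Returns ``(alignment, het_site_mask)`` (plus the internal-node state
    table when ``return_internal``).
    """
    rng = np.random.default_rng(seed)
    q = model.rate_matrix
    pi = model.frequencies
    cat_rates = model.category_rates()
    site_cats = rng.integers(0, len(cat_rates), size=n_sites)
    het_mask = np.zeros(n_sites, dtype=bool)
    if heterotachy_spec is not None:
        n_het = int(round(heterotachy_spec.site_fraction * n_sites))
        het_mask[rng.choice(n_sites, size=n_het, replace=False)] = True

    root = tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(20, size=n_sites, p=pi)
    }
    records = []
    internal = {}

    def branch_states(parent_states, t: float) -> np.ndarray:
        out = np.empty(n_sites, dtype=np.int64)
        for c, rate in enumerate(cat_rates):
            idx = np.nonzero(site_cats == c)[0]
            if len(idx) == 0:
                continue
            p = expm(q * (t * rate)) if t > 0 else np.eye(20)
            cum = np.cumsum(p, axis=1)
            u = rng.random(len(idx))
            out[idx] = (u[:, None] < cum[parent_states[idx]]).argmax(axis=1)
        return out

    for node in tree.preorder_node_iter():
        if node is root:
            if return_internal and not node.is_leaf():
                internal[id(node)] = states[id(root)]
            continue
        t = node.edge.length or 0.0
        if not math.isfinite(t):
            raise ValueError("non-finite branch length")
        parent_states = states[id(node.parent_node)]
        scaled = (heterotachy_spec is not None
                  and _descendant_leaves(node) <= set(heterotachy_spec.taxa))
        if scaled and het_mask.any():
            plain = branch_states(parent_states, t)
            hot = branch_states(parent_states, t * heterotachy_spec.branch_scale)
            s = np.where(het_mask, hot, plain)
        else:
            s = branch_states(parent_states, t)
        states[id(node)] = s
        if node.is_leaf():
            seq = "".join(AA_ALPHABET[i] for i in s)
            records.append(SequenceRecord(node.taxon.label, seq,
                                          taxon_code=node.taxon.label))
        elif return_internal:
            internal[id(node)] = s
    aln = Alignment(records)
    if return_internal:
        return aln, het_mask, internal
    return aln, het_mask


# ---------------------------------------------------------------------------
# Gene families

ROLE_ORTHOLOG = "ortholog"
ROLE_PARALOG = "paralog"
ROLE_CONTAMINANT = "contaminant"
ROLE_DECOY = "decoy"


@dataclass(frozen=True)
class TruthRow:
    role: str
    gene: str | None
    taxon: str
    source_taxon: str | None = None
    duplication_node: str | None = None


@dataclass
class FamilyTruth:
    rows: dict[str, TruthRow] = field(default_factory=dict)

    def role(self, seq_id: str) -> str | None:
        row = self.rows.get(seq_id)
        return row.role if row else None


@dataclass
class GeneFamilySet:
    proteomes: dict[str, list[SequenceRecord]]
    families: dict[str, list[SequenceRecord]]
    truth: FamilyTruth
    species_tree: dendropy.Tree


def simulate_gene_families(species_tree: dendropy.Tree, n_genes: int,
                           dup_prob: float = 0.3, contam_rate: float = 0.1,
                           loss_rate: float = 0.1, seed: int = 0,
                           model: SubstitutionModel | None = None,
                           n_sites: int = 200, n_decoys: int = 3,
                           recipient_taxa: list[str] | None = None,
                           paralog_scale: float = 1.5,
                           paralog_stem: float = 0.4,
                           contam_extra: float = 0.2) -> GeneFamilySet:
    """Simulate gene families with labeled orthologs/paralogs/contaminants.

    Per gene: the true ortholog set evolves on the species tree; with
    probability ``dup_prob`` a duplication is grafted at a random internal
    node (the paralog copy re-descends the node's subtree with a stem branch
    of ``paralog_stem`` and branches scaled by ``paralog_scale``); with
    probability ``contam_rate`` one recipient taxon receives an extra
    sequence derived from the most distant donor lineage; with probability
    ``loss_rate`` (independently per taxon) the ortholog is deleted. Each
    taxon's proteome also receives ``n_decoys`` unrelated random sequences.

    Sequence ids are ``<taxon>@<gene>`` (ortholog), ``<taxon>@<gene>_p``
    (paralog), ``<taxon>@<gene>_c`` (contaminant), ``<taxon>@decoy<i>``.
    """
    model = model or lg_model()
    rng = np.random.default_rng(seed)
    taxa = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    recipients = recipient_taxa if recipient_taxa is not None else taxa
    proteomes: dict[str, list[SequenceRecord]] = {t: [] for t in taxa}
    families: dict[str, list[SequenceRecord]] = {}
    truth = FamilyTruth()

    internal_nodes = [nd for nd in species_tree.preorder_node_iter()
                      if not nd.is_leaf()]
    pdm = species_tree.phylogenetic_distance_matrix()
    tax_lookup = {t.label: t for t in species_tree.taxon_namespace}

    for gi in range(n_genes):
        gene = f"g{gi + 1:03d}"
        fam: list[SequenceRecord] = []
        gene_seed = int(rng.integers(0, 2**31 - 1))
        aln, _, internal = simulate_alignment(species_tree, model, n_sites,
                                              gene_seed, return_internal=True)
        lost = {t for t in taxa if rng.random() < loss_rate}
        for rec in aln.records:
            if rec.taxon in lost:
                continue
            sid = f"{rec.taxon}@{gene}"
            sr = SequenceRecord(sid, rec.residues, taxon_code=rec.taxon)
            proteomes[rec.taxon].append(sr)
            fam.append(sr)
            truth.rows[sid] = TruthRow(ROLE_ORTHOLOG, gene, rec.taxon)

        if rng.random() < dup_prob:
            node = internal_nodes[int(rng.integers(0, len(internal_nodes)))]
            dup_label = f"node{internal_nodes.index(node)}"
            sub_labels = sorted(_descendant_leaves(node))
            sub_tree = species_tree.extract_tree_with_taxa_labels(sub_labels)
            for edge in sub_tree.edges():
                if edge.length is not None:
                    edge.length *= paralog_scale
            # stem branch separating the duplicate copy from the original
            root_states = internal[id(node)]
            stem_seed = int(rng.integers(0, 2**31 - 1))
            para_aln = _evolve_from_states(sub_tree, model, root_states,
                                           paralog_stem, stem_seed)
            for rec in para_aln.records:
                if rec.taxon in lost:
                    continue
                sid = f"{rec.taxon}@{gene}_p"
                sr = SequenceRecord(sid, rec.residues, taxon_code=rec.taxon)
                proteomes[rec.taxon].append(sr)
                fam.append(sr)
                truth.rows[sid] = TruthRow(ROLE_PARALOG, gene, rec.taxon,
                                           duplication_node=dup_label)

        if rng.random() < contam_rate:
            recipient = recipients[int(rng.integers(0, len(recipients)))]
            donor = max((t for t in taxa if t != recipient),
                        key=lambda t: pdm.patristic_distance(
                            tax_lookup[recipient], tax_lookup[t]))
            donor_rec = aln.get(donor)
            if donor_rec is not None:
                contam_seed = int(rng.integers(0, 2**31 - 1))
                mutated = _mutate(donor_rec.residues, model, contam_extra,
                                  contam_seed)
                sid = f"{recipient}@{gene}_c"
                sr = SequenceRecord(sid, mutated, taxon_code=recipient)
                proteomes[recipient].append(sr)
                fam.append(sr)
                truth.rows[sid] = TruthRow(ROLE_CONTAMINANT, gene, recipient,
                                           source_taxon=donor)
        families[gene] = fam

    for t in taxa:
        for i in range(n_decoys):
            seq = "".join(AA_ALPHABET[j] for j in
                          rng.choice(20, size=n_sites, p=model.frequencies))
            sid = f"{t}@decoy{i + 1}"
            proteomes[t].append(SequenceRecord(sid, seq, taxon_code=t))
            truth.rows[sid] = TruthRow(ROLE_DECOY, None, t)

    return GeneFamilySet(proteomes=proteomes, families=families, truth=truth,
                         species_tree=species_tree)


def _evolve_from_states(tree: dendropy.Tree, model: SubstitutionModel,
                        root_states: np.ndarray, stem: float, seed: int) -> Alignment:
    """Descend a tree whose root sequence is given (plus a stem branch)."""
    rng = np.random.default_rng(seed)
    q = model.rate_matrix
    n_sites = len(root_states)

    def step(parent_states, t):
        if t <= 0:
            return parent_states.copy()
        p = expm(q * t)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n_sites)
        return (u[:, None] < cum[parent_states]).argmax(axis=1)

    states = {id(tree.seed_node): step(root_states, stem)}
    records = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = step(states[id(node.parent_node)], node.edge.length or 0.0)
        states[id(node)] = s
        if node.is_leaf():
            records.append(SequenceRecord(node.taxon.label,
                                          "".join(AA_ALPHABET[i] for i in s),
                                          taxon_code=node.taxon.label))
    return Alignment(records)


def _mutate(residues: str, model: SubstitutionModel, t: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    states = np.array([AA_ALPHABET.index(c) for c in residues])
    p = expm(model.rate_matrix * t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(states))
    out = (u[:, None] < cum[states]).argmax(axis=1)
    return "".join(AA_ALPHABET[i] for i in out)


def synthetic_supermatrix(n_taxa: int, gene_widths: list[int], seed: int):
    """Random supermatrix with the given per-gene partition widths.

    Residues are iid uniform over the 20 amino acids; every taxon is present
    in every gene. Useful for exercising column-removal arithmetic at
    realistic matrix dimensions without simulating evolution.
    """
    from .dataset import Supermatrix
    rng = np.random.default_rng(seed)
    n_cols = sum(gene_widths)
    taxa = [f"T{i + 1:02d}" for i in range(n_taxa)]
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    records = []
    for t in taxa:
        row = rng.choice(alphabet, size=n_cols)
        records.append(SequenceRecord(t, row.tobytes().decode(), taxon_code=t))
    partitions = []
    pos = 1
    for i, w in enumerate(gene_widths):
        partitions.append((f"g{i + 1:03d}", pos, pos + w - 1))
        pos += w
    presence = {(t, g): True for t in taxa for g, _, _ in partitions}
    return Supermatrix(Alignment(records), partitions, presence)


# ---------------------------------------------------------------------------
# Mock search harness (identity-derived e-value surrogate)

EVALUE_K = 0.5


def _identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("mock identity assumes equal-length (indel-free) sequences")
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(arr_a == arr_b))


def surrogate_evalue(identity: float, length: int, k: float = EVALUE_K) -> float:
    return math.exp(-k * identity * length)


def build_mock_search(fams: GeneFamilySet, db: GeneDatabase, new_taxon: str,
                      db_taxa: list[str]):
    """Precomputed hit tables for one new taxon, derived from identities.

    The profile-HMM surrogate scores every proteome sequence against a
    per-gene reference (the database ortholog of the first db taxon holding
    the gene); orthogroup hits come straight from the truth labels (family
    members hit ``OG_<gene>``; one decoy per taxon hits a bacterial group);
    database best-hit tables score family members against every gene's
    reference with target ids ``<gene>|<taxon>``; seed-BLAST tables score
    the seed's database ortholog against the proteome.
    """
    from .harvest import PrecomputedSearch, OrthogroupMap

    proteome = fams.proteomes[new_taxon]
    search = PrecomputedSearch()
    groups = OrthogroupMap()
    refs: dict[str, tuple[str, str]] = {}
    for gene in db.genes:
        entry = db.genes[gene]
        for t in db_taxa:
            if t in entry.orthologs:
                refs[gene] = (t, entry.orthologs[t].residues)
                break
        groups.expected[gene] = {f"OG_{gene}"}
        groups.domain[f"OG_{gene}"] = "non_bacterial"
    groups.domain["OG_BACT"] = "bacterial"

    for gene, (ref_taxon, ref_seq) in refs.items():
        rows = []
        for rec in proteome:
            ident = _identity(rec.residues, ref_seq)
            rows.append(HitRow(query_id=gene, target_id=rec.unique_id,
                               evalue=surrogate_evalue(ident, len(ref_seq)),
                               bitscore=ident * len(ref_seq)))
        search.hmm[gene] = HitTable(rows, engine_tag="mock-hmm")
        # seed blast: any db taxon's ortholog as query against the proteome
        for t in db_taxa:
            orth = db.genes[gene].orthologs.get(t)
            if orth is None:
                continue
            srows = [HitRow(query_id=t, target_id=rec.unique_id,
                            evalue=surrogate_evalue(
                                _identity(rec.residues, orth.residues),
                                len(orth.residues)),
                            bitscore=0.0)
                     for rec in proteome]
            search.seed_blast[(gene, t)] = HitTable(srows, engine_tag="mock-blast")

    for rec in proteome:
        row = fams.truth.rows.get(rec.unique_id)
        og_rows = []
        if row is not None and row.gene is not None:
            og_rows.append(HitRow(rec.unique_id, f"OG_{row.gene}", 1e-30, 100.0))
        elif row is not None and row.role == ROLE_DECOY and rec.unique_id.endswith("decoy1"):
            og_rows.append(HitRow(rec.unique_id, "OG_BACT", 1e-20, 80.0))
        search.orthomcl[rec.unique_id] = HitTable(og_rows, engine_tag="mock-og")

        db_rows = [HitRow(rec.unique_id, f"{gene}|{ref_taxon}",
                          surrogate_evalue(_identity(rec.residues, ref_seq),
                                           len(ref_seq)), 0.0)
                   for gene, (ref_taxon, ref_seq) in refs.items()]
        search.db[rec.unique_id] = HitTable(db_rows, engine_tag="mock-db")

    return search, groups
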