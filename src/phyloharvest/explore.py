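"""Post-construction dataset exploration.

These utilities probe a finished supermatrix (or the single-gene trees
behind it) for the classic sources of phylogenomic artifact:

* **fast sites / fast taxa** — the fastest-evolving sites are the most
  saturation-prone; removing them (or the longest-branch taxa) stepwise and
  re-inferring trees reveals signal that is robust to rate extremes.
* **heterotachy** — sites whose rate differs between a fast-evolving and a
  slow-evolving taxon set; scored as a per-site rate ratio against a null
  distribution obtained by simulating rate-homogeneous data on the same tree.
* **compositional heterogeneity** — per-taxon amino-acid frequencies,
  Euclidean distances and average-linkage clustering.
* **SR4 recoding** — the four-class amino-acid reduction of Susko & Roger
  (2007), a standard counter to substitution saturation.
* **random gene resampling** and **RTC-based gene binning** — gene-sampling
  robustness checks; internode certainty (IC) measures, per branch of an ML
  tree, how decisively the bootstrap sample prefers that bipartition over
  its best-supported conflictor.

Site rates default to a parsimony estimator (Fitch substitution counts on a
fixed tree, normalized by the number of scored leaves): the consumers only
need a ranking, and the ranking of parsimony counts tracks model-based rates
closely. Externally computed rates can be supplied as a two-column table.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .seqio import AA_ALPHABET, Alignment, SequenceRecord
from .dataset import Supermatrix, remove_columns, remove_taxa

# ---------------------------------------------------------------------------
# Site rates (vectorized Fitch parsimony over bitmask-encoded columns)

_STATE_BIT = {aa: np.uint32(1 << i) for i, aa in enumerate(AA_ALPHABET)}
_WILDCARD = np.uint32((1 << 20) - 1)  # gap / X / * constrain nothing


@dataclass
class SiteRates:
    rates: np.ndarray
    method_tag: str = "fitch"

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("site rates must be finite")


def _encode(residues: str) -> np.ndarray:
    return np.array([_STATE_BIT.get(c, _WILDCARD) for c in residues], dtype=np.uint32)


def fitch_steps(aln: Alignment, tree: dendropy.Tree) -> np.ndarray:
    """Minimum substitution count per column (Fitch, 20-state, gaps free).

    Leaves carrying a gap/X at a column contribute a wildcard state set and
    can never force a substitution. Multifurcations are scored by folding
    children left to right, which reproduces the binary-tree count on
    resolved trees and (states-1) on an all-distinct star.
    """
    by_taxon = {r.taxon: r for r in aln.records}
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaves - set(by_taxon)
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
    n_cols = aln.n_cols
    steps = np.zeros(n_cols, dtype=np.int64)

    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = _encode(by_taxon[node.taxon.label].residues)
            continue
        children = node.child_nodes()
        acc = masks.pop(id(children[0]))
        for child in children[1:]:
            other = masks.pop(id(child))
            inter = acc & other
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | other, inter)
        masks[id(node)] = acc
    return steps


def estimate_site_rates(aln: Alignment, tree: dendropy.Tree) -> SiteRates:
    """Per-site rate = Fitch substitution count / number of non-gap leaves.

    Sites with fewer than two scored leaves get rate 0.
    """
    steps = fitch_steps(aln, tree)
    counts = np.zeros(aln.n_cols, dtype=np.int64)
    for r in aln.records:
        counts += np.array([c in _STATE_BIT for c in r.residues])
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(counts >= 2, steps / np.maximum(counts, 1), 0.0)
    return SiteRates(rates, method_tag="fitch")


def read_site_rates(path) -> SiteRates:
    """Read an external two-column "site<TAB>rate" table (1-based sites)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            site, rate = line.split()[:2]
            pairs.append((int(site), float(rate)))
    pairs.sort()
    if [s for s, _ in pairs] != list(range(1, len(pairs) + 1)):
        raise ValueError("site rate table must cover sites 1..n exactly")
    return SiteRates(np.array([r for _, r in pairs]), method_tag="external")


# ---------------------------------------------------------------------------
# Stepwise removals

def _ranked_columns(values: np.ndarray) -> list[int]:
    """Column indices from highest value to lowest; ties: lower index first."""
    return sorted(range(len(values)), key=lambda i: (-values[i], i))


def _stepwise_column_removal(matrix: Supermatrix, ranking: list[int],
                             chunk: int, n_steps: int | None,
                             first_step: int | None = None) -> list[Supermatrix]:
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    out: list[Supermatrix] = []
    removed: set[int] = set()
    cursor = 0
    step = 0
    while cursor < len(ranking):
        size = first_step if (step == 0 and first_step is not None) else chunk
        batch = ranking[cursor: cursor + size]
        cursor += len(batch)
        removed.update(batch)
        step += 1
        if len(removed) >= matrix.n_cols:
            break  # exhausted; the empty matrix is not emitted
        out.append(remove_columns(matrix, removed))
        if n_steps is not None and step >= n_steps:
            break
    return out


def remove_fast_sites(matrix: Supermatrix, rates: SiteRates, chunk: int,
                      n_steps: int | None = None) -> list[Supermatrix]:
    """Stepwise removal of the fastest-evolving sites.

    Step k removes the next ``chunk`` highest-rate sites (ties broken toward
    lower column index); survivors keep their original order and partitions
    are re-tiled. Runs to exhaustion when ``n_steps`` is None.
    """
    if len(rates.rates) != matrix.n_cols:
        raise ValueError("rate vector length does not match the matrix")
    return _stepwise_column_removal(matrix, _ranked_columns(rates.rates),
                                    chunk, n_steps)


def mean_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Mean patristic tip-to-tip path length for every leaf."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out = {}
    for t1 in taxa:
        total = sum(pdm.patristic_distance(t1, t2) for t2 in taxa if t2 is not t1)
        out[t1.label] = total / (len(taxa) - 1)
    return out


def remove_fast_taxa(matrix: Supermatrix, tree: dendropy.Tree,
                     n_per_step: int, n_steps: int) -> list[Supermatrix]:
    """Stepwise removal of the longest-branch taxa (mean tip-to-tip ranking).

    The ranking is computed once; matrices are re-emitted per step without
    re-estimating anything. ``n_per_step=0`` is the identity.
    """
    if n_per_step == 0:
        return [matrix] * n_steps
    dists = mean_tip_distances(tree)
    present = [t for t in matrix.taxa() if t in dists]
    ranking = sorted(present, key=lambda t: (-dists[t], t))
    out: list[Supermatrix] = []
    removed: set[str] = set()
    for step in range(n_steps):
        batch = ranking[step * n_per_step: (step + 1) * n_per_step]
        if not batch or len(removed) + len(batch) >= len(matrix.taxa()):
            warnings.warn("fast-taxon removal stopped before removing every taxon")
            break
        removed.update(batch)
        out.append(remove_taxa(matrix, removed))
    return out


# ---------------------------------------------------------------------------
# Heterotachy

@dataclass
class HeterotachyScores:
    ratios: np.ndarray           # per-site fast/slow rate ratio
    p_values: np.ndarray | None  # empirical upper-tail p per site
    null_sample: np.ndarray | None = None
    fast_set: frozenset = frozenset()
    slow_set: frozenset = frozenset()


def split_taxa_by_rate(tree: dendropy.Tree) -> tuple[set[str], set[str]]:
    """Default fast/slow partition: upper vs lower half of the mean
    tip-to-tip distance ranking (ties broken by name)."""
    dists = mean_tip_distances(tree)
    ranked = sorted(dists, key=lambda t: (-dists[t], t))
    half = len(ranked) // 2
    return set(ranked[:half]), set(ranked[half:])


def _set_rates(aln: Alignment, tree: dendropy.Tree, taxa: set[str]) -> np.ndarray:
    """Smoothed per-site rates on the leaf restriction to ``taxa``.

    Rate = (Fitch steps + 0.5) / scored leaves on the induced subtree; the
    half-substitution pseudocount keeps ratios finite on invariant sites.
    """
    taxa = set(taxa)
    sub_aln = aln.restrict(taxa)
    if len(sub_aln.records) < 4:
        raise ValueError("need at least 4 taxa per heterotachy set")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label in taxa]
    if len(labels) < 4:
        raise ValueError("induced subtree has fewer than 4 leaves")
    sub_tree = tree.extract_tree_with_taxa_labels(labels)
    steps = fitch_steps(sub_aln, sub_tree)
    counts = np.zeros(aln.n_cols, dtype=np.int64)
    for r in sub_aln.records:
        counts += np.array([c in _STATE_BIT for c in r.residues])
    return (steps + 0.5) / np.maximum(counts, 1)


def heterotachy_ratios(aln: Alignment, tree: dendropy.Tree,
                       fast_set: set[str], slow_set: set[str]) -> np.ndarray:
    if set(fast_set) & set(slow_set):
        raise ValueError("fast and slow taxon sets must be disjoint")
    return _set_rates(aln, tree, fast_set) / _set_rates(aln, tree, slow_set)


def heterotachy_scores(aln: Alignment, tree: dendropy.Tree,
                       fast_set: set[str], slow_set: set[str],
                       null_ratios: np.ndarray | None = None,
                       randomize: bool = True,
                       seed: int | None = None) -> HeterotachyScores:
    """Per-site fast/slow rate ratios with empirical upper-tail p-values.

    p-values are computed against ``null_ratios`` (typically produced by
    :func:`simulate_null_ratios` on the same tree under a rate-homogeneous
    model). Because the parsimony ratio statistic is discrete, ties between
    an observed ratio and null atoms are resolved by seeded randomization
    (``p = (#{null > r} + U(1 + #{null == r})) / (N + 1)``), which makes the
    p-values exactly uniform under the null; ``randomize=False`` gives the
    conservative deterministic variant.
    """
    ratios = heterotachy_ratios(aln, tree, fast_set, slow_set)
    p_values = None
    if null_ratios is not None:
        null = np.sort(np.asarray(null_ratios, dtype=float))
        n = len(null)
        greater = n - np.searchsorted(null, ratios, side="right")
        equal = (n - np.searchsorted(null, ratios, side="left")) - greater
        if randomize:
            rng = np.random.default_rng(seed)
            u = rng.random(len(ratios))
        else:
            u = np.ones(len(ratios))
        p_values = (greater + u * (1 + equal)) / (n + 1)
    return HeterotachyScores(ratios=ratios, p_values=p_values,
                             null_sample=null_ratios,
                             fast_set=frozenset(fast_set),
                             slow_set=frozenset(slow_set))


def simulate_null_ratios(tree: dendropy.Tree, model, n_sites: int, seed: int,
                         fast_set: set[str], slow_set: set[str]) -> np.ndarray:
    """Null fast/slow ratio sample from rate-homogeneous simulation on ``tree``."""
    from .synth import simulate_alignment

    aln, _ = simulate_alignment(tree, model, n_sites, seed)
    return heterotachy_ratios(aln, tree, fast_set, slow_set)


def remove_heterotachous_sites(matrix: Supermatrix, scores: HeterotachyScores,
                               chunk: int, n_steps: int | None = None,
                               first_step: int | None = None) -> list[Supermatrix]:
    """Stepwise removal of the most heterotachous sites (highest ratio first).

    ``first_step`` supports an unequal first batch (e.g. 3,000 sites, then
    9,000 per subsequent step).
    """
    if len(scores.ratios) != matrix.n_cols:
        raise ValueError("score vector length does not match the matrix")
    return _stepwise_column_removal(matrix, _ranked_columns(scores.ratios),
                                    chunk, n_steps, first_step=first_step)


# ---------------------------------------------------------------------------
# Amino-acid composition

def aa_composition(matrix: Supermatrix):
    """Per-taxon amino-acid frequencies, Euclidean distances, dendrogram.

    Gaps and X are excluded from the counts; each frequency row sums to 1.
    Clustering is agglomerative with average linkage; the dendrogram is
    returned as a Newick string.
    """
    import pandas as pd

    taxa = matrix.taxa()
    rows = []
    for r in matrix.alignment.records:
        counts = Counter(c for c in r.residues if c in AA_ALPHABET)
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"taxon {r.taxon!r} has no scored residues")
        rows.append([counts.get(aa, 0) / total for aa in AA_ALPHABET])
    freqs = pd.DataFrame(rows, index=taxa, columns=list(AA_ALPHABET))
    dists = pdist(freqs.values, metric="euclidean")
    dist_df = pd.DataFrame(squareform(dists), index=taxa, columns=taxa)
    if len(taxa) < 2:
        return freqs, dist_df, f"({taxa[0]});"
    link = linkage(dists, method="average")
    newick = _linkage_to_newick(link, taxa)
    return freqs, dist_df, newick


def _linkage_to_newick(link, labels) -> str:
    node = to_tree(link)

    def render(n):
        if n.is_leaf():
            return labels[n.id]
        left = render(n.left)
        right = render(n.right)
        return (f"({left}:{n.dist - n.left.dist:.6g},"
                f"{right}:{n.dist - n.right.dist:.6g})")

    body = render(node)
    return body + ";"


# ---------------------------------------------------------------------------
# SR4 recoding

#: Susko & Roger (2007) four-class amino-acid reduction.
SR4_CLASSES = {
    "A": "AGNPST",
    "C": "CHWY",
    "G": "DEKQR",
    "T": "FILMV",
}
_SR4_MAP = {aa: cls for cls, members in SR4_CLASSES.items() for aa in members}
_SR4_MAP["-"] = "-"
_SR4_MAP["X"] = "X"


def sr4_recode_alignment(aln: Alignment) -> Alignment:
    recs = []
    for r in aln.records:
        out = []
        for pos, c in enumerate(r.residues, start=1):
            mapped = _SR4_MAP.get(c)
            if mapped is None:
                raise ValueError(
                    f"unknown residue {c!r} at {r.unique_id}:{pos} during SR4 recoding")
            out.append(mapped)
        recs.append(SequenceRecord(r.unique_id, "".join(out), taxon_code=r.taxon_code))
    return Alignment(recs, check_taxa=False)


def sr4_recode(matrix: Supermatrix) -> Supermatrix:
    """Recode a supermatrix into the SR4 four-state scheme (gap/X preserved)."""
    return Supermatrix(sr4_recode_alignment(matrix.alignment),
                       list(matrix.partitions), dict(matrix.gene_presence))


# ---------------------------------------------------------------------------
# Random gene resampling

def resample_replicate_count(n_genes: int, subset_size: int, ci: float) -> int:
    """Smallest replicate count whose union bound guarantees full coverage.

    Coverage probability that every gene appears in at least one replicate
    satisfies P >= 1 - n(1 - s/n)^R, so R = ceil(log((1-ci)/n) / log(1-s/n)).
    """
    if subset_size >= n_genes:
        return 1
    return max(1, math.ceil(math.log((1 - ci) / n_genes)
                            / math.log(1 - subset_size / n_genes)))


def random_resample(genes: list[str], step_percent: float, ci: float, seed: int):
    """Random gene subsets at each percentage step.

    For each p in {step, 2*step, ..., 100} the subset size is
    ``floor(p * n / 100)``; the number of replicates at p is chosen so every
    gene appears in at least one replicate with probability >= ``ci``.
    Returns ``[(percent, [replicate gene lists])]``; seeded and reproducible.
    """
    if not 0 < step_percent <= 100:
        raise ValueError("step_percent must be in (0, 100]")
    if not 0 < ci < 1:
        raise ValueError("ci must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    out = []
    p = step_percent
    while p <= 100 + 1e-9:
        size = int(p * n // 100)
        if size == 0:
            warnings.warn(f"subsampling step {p}% yields an empty subset; skipped")
            p += step_percent
            continue
        reps = resample_replicate_count(n, size, ci)
        replicates = [sorted(rng.choice(genes, size=size, replace=False).tolist())
                      for _ in range(reps)]
        out.append((p, replicates))
        p += step_percent
    return out


# ---------------------------------------------------------------------------
# Internode certainty / RTC

@dataclass
class RTCResult:
    ic: dict[frozenset, float]
    tc: float
    rtc: float


def _canonical_splits(tree: dendropy.Tree, leaves: frozenset) -> set[frozenset]:
    from .seqio import bipartition_sides

    anchor = min(leaves)
    out = set()
    for side in bipartition_sides(tree):
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def _conflicts(a: frozenset, b: frozenset, leaves: frozenset) -> bool:
    """Two splits conflict when all four intersections are non-empty."""
    ca, cb = leaves - a, leaves - b
    return bool(a & b) and bool(a & cb) and bool(ca & b) and bool(ca & cb)


def internode_certainty(ml_tree: dendropy.Tree,
                        bootstrap_trees: list[dendropy.Tree]) -> RTCResult:
    """IC per internal branch of the ML tree, TC and RTC.

    For a branch with bootstrap frequency f1 whose most frequent conflicting
    bipartition (among those observed in the bootstrap sample) has frequency
    f2: IC = 1 + p log2 p + q log2 q with p = f1/(f1+f2); no observed
    conflict means IC = 1. TC sums IC over internal branches; RTC divides by
    the internal branch count of an unrooted binary tree (n_leaves - 3).
    """
    from .seqio import leaf_names

    leaves = frozenset(leaf_names(ml_tree))
    if len(leaves) < 4:
        raise ValueError("internode certainty needs at least 4 leaves")
    for bt in bootstrap_trees:
        if frozenset(leaf_names(bt)) != leaves:
            raise ValueError("bootstrap trees must share the ML tree's leaf set")
    counts: Counter = Counter()
    for bt in bootstrap_trees:
        counts.update(_canonical_splits(bt, leaves))
    ic: dict[frozenset, float] = {}
    for split in _canonical_splits(ml_tree, leaves):
        f1 = counts.get(split, 0)
        f2 = 0
        for other, c in counts.items():
            if other != split and c > f2 and _conflicts(split, other, leaves):
                f2 = c
        if f2 == 0:
            ic[split] = 1.0
        else:
            p = f1 / (f1 + f2)
            q = f2 / (f1 + f2)
            val = 1.0
            if p > 0:
                val += p * math.log2(p)
            if q > 0:
                val += q * math.log2(q)
            ic[split] = val
    tc = sum(ic.values())
    return RTCResult(ic=ic, tc=tc, rtc=tc / (len(leaves) - 3))


def rtc_bin(gene_scores: dict[str, float],
            bins=(25, 50, 75)) -> dict[int, list[str]]:
    """Top-k% gene bins by RTC score (descending; count = round(k% * n)).

    Ties are broken by gene name for determinism.
    """
    ranked = sorted(gene_scores, key=lambda g: (-gene_scores[g], g))
    n = len(ranked)
    out = {}
    for k in bins:
        count = int(k * n / 100 + 0.5)
        out[k] = ranked[:count]
    return out


# ---------------------------------------------------------------------------
# Bipartition (clade) frequencies

@dataclass
class CladeQuery:
    name: str
    members: frozenset
    require_all: bool = True


def bipartition_frequency(trees: list[dendropy.Tree],
                          queries: list[CladeQuery]) -> dict[str, float]:
    """Fraction of trees in which each query clade forms one side of a split.

    Trees may have unequal leaf sets: the query is restricted to the members
    present in each tree; trees leaving fewer than two present members are
    skipped for that query (and counted in neither numerator nor
    denominator). With ``require_all`` a tree missing any member is skipped.
    """
    from .seqio import bipartition_sides, leaf_names

    out: dict[str, float] = {}
    for q in queries:
        hits = 0
        counted = 0
        for tree in trees:
            leaves = set(leaf_names(tree))
            present = q.members & leaves
            if len(present) < 2 or (q.require_all and present != q.members):
                continue
            counted += 1
            sides = {frozenset(s) for s in bipartition_sides(tree)}
            full = frozenset(leaves)
            if any(present == s or present == full - s for s in sides):
                hits += 1
        out[q.name] = hits / counted if counted else float("nan")
    return out
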