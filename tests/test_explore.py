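"""Site rates, stepwise removals, heterotachy, composition, SR4, RTC."""

import itertools

import numpy as np
import pytest

from phyloharvest import dataset as ds
from phyloharvest import explore as ex
from phyloharvest import synth
from phyloharvest.seqio import Alignment, SequenceRecord, read_newick, leaf_names


def R(uid, seq):
    return SequenceRecord(uid, seq, taxon_code=uid)


def _matrix_from(records, gene_widths):
    genes = {}
    pos = 0
    for i, w in enumerate(gene_widths):
        genes[f"g{i}"] = Alignment([R(r.unique_id, r.residues[pos:pos + w])
                                    for r in records])
        pos += w
    return ds.concatenate(genes)


# ---------------------------------------------------------------------------
# Fitch rates

def _brute_force_fitch(column, tree):
    """Exhaustive minimum-substitution count over internal assignments."""
    states = sorted(set(column.values()))
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = dict(zip([id(n) for n in internals], combo))
        cost = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            a = assign[id(nd.parent_node)]
            b = column[nd.taxon.label] if nd.is_leaf() else assign[id(nd)]
            if b == "?":
                continue
            cost += a != b
        best = cost if best is None else min(best, cost)
    return best


def test_invariant_column_rate_zero(small_tree):
    aln = Alignment([R(t, "MM") for t in ["t1", "t2", "t3", "t4"]])
    rates = ex.estimate_site_rates(aln, small_tree)
    assert np.all(rates.rates == 0)
    assert len(rates.rates) == aln.n_cols


def test_star_tree_all_distinct_gives_states_minus_one():
    star = read_newick("(t1:1,t2:1,t3:1,t4:1,t5:1);")
    aln = Alignment([R(f"t{i}", "ACDEF"[i - 1]) for i in range(1, 6)])
    steps = ex.fitch_steps(aln, star)
    assert steps[0] == 4  # 5 distinct states -> 4 substitutions


def test_fitch_matches_exhaustive_oracle(rng):
    for seed in range(15):
        tree = synth.simulate_tree(5, seed=seed, birth_rate=1.0)
        names = leaf_names(tree)
        col = {n: str(rng.choice(list("ACDG"))) for n in names}
        if rng.random() < 0.3:
            col[names[0]] = "?"  # missing datum
        aln = Alignment([R(n, col[n].replace("?", "-")) for n in names])
        assert ex.fitch_steps(aln, tree)[0] == _brute_force_fitch(col, tree)


def test_gap_leaves_never_add_steps(small_tree):
    aln = Alignment([R("t1", "M"), R("t2", "-"), R("t3", "-"), R("t4", "-")])
    rates = ex.estimate_site_rates(aln, small_tree)
    assert rates.rates[0] == 0  # fewer than 2 scored leaves


def test_external_rate_file_round_trip(tmp_path):
    p = tmp_path / "rates.tsv"
    p.write_text("1\t0.5\n2\t0.1\n3\t2.0\n")
    rates = ex.read_site_rates(p)
    assert rates.rates.tolist() == [0.5, 0.1, 2.0]
    p.write_text("1\t0.5\n3\t2.0\n")
    with pytest.raises(ValueError):
        ex.read_site_rates(p)


# ---------------------------------------------------------------------------
# fast-site removal

def test_remove_fast_sites_top3_matches_sort_oracle(rng):
    records = [R(f"t{i}", "".join(rng.choice(list("ACDEFGHIK"), size=10)))
               for i in range(4)]
    m = _matrix_from(records, [4, 6])
    vals = rng.permutation(10).astype(float)
    rates = ex.SiteRates(vals)
    [sub] = ex.remove_fast_sites(m, rates, chunk=3, n_steps=1)
    removed_oracle = set(sorted(range(10), key=lambda i: (-vals[i], i))[:3])
    kept = [i for i in range(10) if i not in removed_oracle]
    for r_old, r_new in zip(m.alignment.records, sub.alignment.records):
        assert r_new.residues == "".join(r_old.residues[i] for i in kept)


def test_remove_fast_sites_partition_conservation(rng):
    records = [R(f"t{i}", "".join(rng.choice(list("ACDEFGHIK"), size=30)))
               for i in range(4)]
    m = _matrix_from(records, [10, 12, 8])
    rates = ex.SiteRates(rng.random(30))
    for sub in ex.remove_fast_sites(m, rates, chunk=7):
        assert sum(e - s + 1 for _, s, e in sub.partitions) == sub.n_cols
        ranked = sorted(range(30), key=lambda i: (-rates.rates[i], i))
        n_removed = 30 - sub.n_cols
        removed = set(ranked[:n_removed])
        for gene, s, e in m.partitions:
            inside = sum(1 for i in removed if s - 1 <= i <= e - 1)
            new = [p for p in sub.partitions if p[0] == gene]
            new_len = (new[0][2] - new[0][1] + 1) if new else 0
            assert new_len == (e - s + 1) - inside


def test_remove_fast_sites_chunk_exceeding_matrix():
    records = [R(f"t{i}", "ACDEF") for i in range(4)]
    m = _matrix_from(records, [5])
    out = ex.remove_fast_sites(m, ex.SiteRates(np.arange(5.0)), chunk=99)
    assert out == []  # exhaustion at step 1; empty matrix not emitted


def test_removal_idempotent_on_ranking(rng):
    records = [R(f"t{i}", "".join(rng.choice(list("ACD"), size=12)))
               for i in range(4)]
    m = _matrix_from(records, [12])
    rates = ex.SiteRates(rng.random(12))
    a = ex.remove_fast_sites(m, rates, chunk=4, n_steps=2)
    b = ex.remove_fast_sites(m, rates, chunk=4, n_steps=2)
    assert [x.alignment.records[0].residues for x in a] == \
        [x.alignment.records[0].residues for x in b]


# ---------------------------------------------------------------------------
# fast-taxon removal

def test_long_branch_taxon_removed_first():
    t = read_newick("((t1:0.1,t2:0.1):0.1,(t3:0.1,t4:5.0):0.1);")
    records = [R(f"t{i}", "ACDEF") for i in range(1, 5)]
    m = _matrix_from(records, [5])
    [sub] = ex.remove_fast_taxa(m, t, n_per_step=1, n_steps=1)
    assert "t4" not in sub.taxa()


def test_mean_tip_distance_matches_all_pairs_oracle():
    for seed in range(8):
        tree = synth.simulate_tree(12, seed=seed, birth_rate=1.0)
        got = ex.mean_tip_distances(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = list(tree.taxon_namespace)
        for t1 in taxa:
            oracle = np.mean([pdm.patristic_distance(t1, t2)
                              for t2 in taxa if t2 is not t1])
            assert got[t1.label] == pytest.approx(oracle)


def test_remove_zero_taxa_is_identity(small_tree):
    records = [R(f"t{i}", "ACDEF") for i in range(1, 5)]
    m = _matrix_from(records, [5])
    out = ex.remove_fast_taxa(m, small_tree, n_per_step=0, n_steps=2)
    assert all(sub.taxa() == m.taxa() for sub in out)


# ---------------------------------------------------------------------------
# heterotachy

def test_identical_fast_slow_subalignments_ratio_one():
    tree = read_newick("(((a1:1,a2:1):1,(a3:1,a4:1):1):1,((b1:1,b2:1):1,(b3:1,b4:1):1):1);")
    seqs = ["MKLV", "MKIV", "MALV", "MKLC"]
    records = ([R(f"a{i+1}", seqs[i]) for i in range(4)]
               + [R(f"b{i+1}", seqs[i]) for i in range(4)])
    aln = Alignment(records)
    ratios = ex.heterotachy_ratios(aln, tree, {"a1", "a2", "a3", "a4"},
                                   {"b1", "b2", "b3", "b4"})
    assert np.allclose(ratios, 1.0)


def test_rescaled_subset_sites_have_higher_ratios(fast_model):
    tree = synth.simulate_tree(12, seed=9, birth_rate=2.0)
    fast, slow = ex.split_taxa_by_rate(tree)
    spec = synth.HeterotachySpec(taxa=frozenset(fast), branch_scale=5.0,
                                 site_fraction=0.5)
    aln, mask = synth.simulate_alignment(tree, fast_model, 800, seed=21,
                                         heterotachy_spec=spec)
    ratios = ex.heterotachy_ratios(aln, tree, fast, slow)
    assert np.median(ratios[mask]) > np.median(ratios[~mask])


def test_null_p_values_uniform_and_calibrated(lg):
    tree = synth.simulate_tree(16, seed=3, birth_rate=2.0)
    fast, slow = ex.split_taxa_by_rate(tree)
    aln, _ = synth.simulate_alignment(tree, lg, 2000, seed=10)
    null = ex.simulate_null_ratios(tree, lg, 2000, 11, fast, slow)
    sc = ex.heterotachy_scores(aln, tree, fast, slow, null_ratios=null, seed=12)
    frac = float(np.mean(sc.p_values < 0.05))
    tol = 3 * np.sqrt(0.05 * 0.95 / 2000)
    assert abs(frac - 0.05) <= tol
    # approximate uniformity (fixed-seed Kolmogorov-Smirnov threshold)
    from scipy.stats import kstest
    assert kstest(sc.p_values, "uniform").statistic < 0.05


def test_heterotachy_needs_four_taxa(small_tree):
    aln = Alignment([R(t, "MK") for t in ["t1", "t2", "t3", "t4"]])
    with pytest.raises(ValueError, match="4 taxa"):
        ex.heterotachy_ratios(aln, small_tree, {"t1", "t2"}, {"t3", "t4"})


def test_remove_heterotachous_unequal_first_step(rng):
    records = [R(f"t{i}", "".join(rng.choice(list("ACD"), size=20)))
               for i in range(4)]
    m = _matrix_from(records, [20])
    sc = ex.HeterotachyScores(ratios=rng.random(20), p_values=None)
    out = ex.remove_heterotachous_sites(m, sc, chunk=6, n_steps=2, first_step=3)
    assert [sub.n_cols for sub in out] == [17, 11]


# ---------------------------------------------------------------------------
# composition / SR4

def test_aa_composition_frequencies_and_distances(rng):
    records = [R("tA", "ACDE" * 5), R("tB", "ACDE" * 5),
               R("tC", "".join(rng.choice(list("KLMNP"), size=20)))]
    m = _matrix_from(records, [20])
    freqs, dists, newick = ex.aa_composition(m)
    assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)
    assert dists.loc["tA", "tB"] == 0.0
    # brute-force Euclidean oracle
    for a, b in itertools.combinations(freqs.index, 2):
        oracle = np.sqrt(((freqs.loc[a] - freqs.loc[b]) ** 2).sum())
        assert dists.loc[a, b] == pytest.approx(oracle)
    assert newick.endswith(";") and "tA" in newick
    # identical pair merges first: they form a cherry
    assert "(tA:0,tB:0)" in newick.replace(" ", "")


def test_aa_composition_empty_taxon_errors():
    m = _matrix_from([R("tA", "----"), R("tB", "MKLV")], [4])
    with pytest.raises(ValueError, match="tA"):
        ex.aa_composition(m)


def test_sr4_class_mapping():
    aln = Alignment([R("t", "AGNPST" + "CHWY" + "DEKQR" + "FILMV" + "-X")],
                    check_taxa=False)
    out = ex.sr4_recode_alignment(aln)
    assert out.records[0].residues == "A" * 6 + "C" * 4 + "G" * 5 + "T" * 5 + "-X"


def test_sr4_output_alphabet_at_most_four(rng):
    records = [R(f"t{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY-X"),
                                             size=50))) for i in range(5)]
    m = _matrix_from(records, [50])
    out = ex.sr4_recode(m)
    symbols = set("".join(r.residues for r in out.alignment.records)) - set("-X")
    assert symbols <= {"A", "C", "G", "T"}
    assert out.partitions == m.partitions


def test_sr4_unknown_residue_errors():
    aln = Alignment([R("t", "MK*")], check_taxa=False)
    with pytest.raises(ValueError, match="t:3"):
        ex.sr4_recode_alignment(aln)


# ---------------------------------------------------------------------------
# resampling

def test_resample_sizes_and_full_step():
    genes = [f"g{i}" for i in range(240)]
    out = ex.random_resample(genes, step_percent=20, ci=0.95, seed=7)
    sizes = {p: len(reps[0]) for p, reps in out}
    assert sizes[20] == 48
    assert sizes[100] == 240
    p100 = dict(out)[100]
    assert len(p100) == 1 and sorted(p100[0]) == sorted(genes)


def test_resample_deterministic_under_seed():
    genes = [f"g{i}" for i in range(30)]
    a = ex.random_resample(genes, 25, 0.9, seed=11)
    b = ex.random_resample(genes, 25, 0.9, seed=11)
    assert a == b
    c = ex.random_resample(genes, 25, 0.9, seed=12)
    assert a != c


def test_replicate_count_union_bound():
    # R is the smallest integer with n(1-s/n)^R <= 1-ci
    n, s, ci = 240, 48, 0.95
    r = ex.resample_replicate_count(n, s, ci)
    assert n * (1 - s / n) ** r <= 1 - ci
    assert n * (1 - s / n) ** (r - 1) > 1 - ci


# ---------------------------------------------------------------------------
# internode certainty / RTC

def _trees(newicks):
    return [read_newick(s) for s in newicks]


def test_ic_limit_cases():
    ml = read_newick("((a,b),(c,d));")
    boots = _trees(["((a,b),(c,d));"] * 100)
    res = ex.internode_certainty(ml, boots)
    assert list(res.ic.values()) == [1.0]
    assert res.rtc == 1.0  # one internal branch, n-3 = 1
    # balanced conflict: f1 = f2 -> IC = 0
    boots = _trees(["((a,b),(c,d));"] * 50 + ["((a,c),(b,d));"] * 50)
    res = ex.internode_certainty(ml, boots)
    assert list(res.ic.values()) == [pytest.approx(0.0)]


def test_ic_values_in_unit_interval(rng):
    ml = synth.simulate_tree(8, seed=0, birth_rate=1.0)
    boots = [synth.simulate_tree(8, seed=s, birth_rate=1.0) for s in range(30)]
    res = ex.internode_certainty(ml, boots)
    assert all(0.0 <= v <= 1.0 for v in res.ic.values())
    assert 0.0 <= res.rtc <= 1.0


def test_ic_leafset_mismatch_errors():
    ml = read_newick("((a,b),(c,d));")
    with pytest.raises(ValueError):
        ex.internode_certainty(ml, _trees(["((a,b),(c,e));"]))
    with pytest.raises(ValueError, match="4 leaves"):
        ex.internode_certainty(read_newick("(a,b,c);"), [])


def test_rtc_binning_counts():
    scores = {f"g{i}": 1.0 - i / 240 for i in range(240)}
    bins = ex.rtc_bin(scores, bins=(25, 50, 75))
    assert len(bins[75]) == 180
    assert len(bins[50]) == 120
    assert len(bins[25]) == 60
    assert bins[25] == [f"g{i}" for i in range(60)]  # highest RTC first


# ---------------------------------------------------------------------------
# bipartition frequencies

def test_clade_frequency_limits():
    trees = _trees(["((a,b),(c,d));", "((a,b),(d,c));", "(((a,b),c),d);"])
    q_yes = ex.CladeQuery("ab", frozenset({"a", "b"}))
    q_no = ex.CladeQuery("ad", frozenset({"a", "d"}))
    freq = ex.bipartition_frequency(trees, [q_yes, q_no])
    assert freq["ab"] == 1.0
    assert freq["ad"] == 0.0


def test_clade_frequency_matches_split_oracle(rng):
    from phyloharvest.seqio import bipartition_set
    trees = [synth.simulate_tree(8, seed=s, birth_rate=1.0) for s in range(50)]
    names = leaf_names(trees[0])
    members = frozenset(rng.choice(names, size=3, replace=False).tolist())
    q = ex.CladeQuery("q", members)
    freq = ex.bipartition_frequency(trees, [q])["q"]
    leaves = frozenset(names)
    oracle = np.mean([
        any(members == s or members == leaves - s for s in bipartition_set(t))
        for t in trees])
    assert freq == pytest.approx(oracle)


def test_clade_query_restriction_to_present_members():
    trees = _trees(["((a,b),(c,d));", "((a,e),(c,d));"])
    q = ex.CladeQuery("abx", frozenset({"a", "b", "x"}), require_all=False)
    freq = ex.bipartition_frequency(trees, [q])
    # second tree has only 'a' present -> skipped; first counts restricted {a,b}
    assert freq["abx"] == 1.0
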