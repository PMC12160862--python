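"""NMF program extraction, robustness selection and meta-program clustering."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stromascape as ss
from stromascape.metaprograms import GeneProgram, RobustnessParams


def _program(sample, k, f, genes, weights=None):
    genes = tuple(genes)
    if weights is None:
        weights = tuple(float(len(genes) - i) for i in range(len(genes)))
    return GeneProgram(sample_id=sample, rank_k=k, factor_index=f,
                       top_genes=genes, weights=weights)


def _gene_block(start, n=50):
    return [f"g{i:04d}" for i in range(start, start + n)]


# ---------------------------------------------------------------- NMF


def test_nmf_program_count_and_contract():
    rng = np.random.default_rng(0)
    X = rng.gamma(2, 1, size=(60, 200))
    genes = [f"g{i:04d}" for i in range(200)]
    progs = ss.fit_sample_nmf(X, genes, sample_id="s1", seed=1)
    assert len(progs) == sum(range(3, 11))  # 3+4+...+10 = 52
    for p in progs:
        assert len(set(p.top_genes)) == 50
        assert all(w >= 0 for w in p.weights)
        assert all(a >= b for a, b in zip(p.weights, p.weights[1:]))


def test_nmf_recovers_planted_modules_at_matching_k():
    """4 disjoint 50-gene modules, effect 4: at K=4 each module is matched
    by one factor with >= 45/50 of its genes."""
    rng = np.random.default_rng(2)
    n_cells, n_genes = 400, 400
    X = rng.gamma(2.0, 0.5, size=(n_cells, n_genes))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    modules = [list(range(i * 50, (i + 1) * 50)) for i in range(4)]
    for m, mod in enumerate(modules):
        on = rng.random(n_cells) < 0.5
        X[np.ix_(on, mod)] *= 4.0
    progs = [p for p in ss.fit_sample_nmf(X, genes, seed=3) if p.rank_k == 4]
    for mod in modules:
        mod_genes = {genes[i] for i in mod}
        best = max(len(mod_genes & p.gene_set) for p in progs)
        assert best >= 45


def test_nmf_rejects_degenerate_input():
    with pytest.raises(ValueError, match="all-zero"):
        ss.fit_sample_nmf(np.ones((20, 30)), [f"g{i}" for i in range(30)])
    with pytest.raises(ValueError, match="cells"):
        ss.fit_sample_nmf(np.ones((5, 30)), [f"g{i}" for i in range(30)])


# ------------------------------------------------- robustness selection


def test_robust_selection_rules():
    a = _gene_block(0)
    a_var = _gene_block(0, 40) + _gene_block(100, 10)   # 40/50 with a
    b = _gene_block(200)
    cross = _gene_block(0, 12) + _gene_block(300, 38)   # 12/50 with a
    programs = [
        _program("s1", 3, 0, a),
        _program("s1", 4, 0, a_var),       # stability partner for a
        _program("s1", 5, 0, b),           # no partner, no recurrence
        _program("s2", 3, 0, cross),       # gives a cross-sample recurrence
        _program("s2", 4, 0, cross),       # its own stability partner
    ]
    kept = ss.select_robust_programs(programs)
    kept_ids = {(p.sample_id, p.rank_k) for p in kept}
    assert ("s1", 3) in kept_ids          # stable in-sample + recurrent
    assert ("s1", 5) not in kept_ids      # unique to one K, no recurrence


def test_robust_selection_collapses_near_duplicates():
    a = _gene_block(0)
    a_dup = _gene_block(0, 48) + _gene_block(500, 2)  # 48/50 shared
    partner = _gene_block(0, 40) + _gene_block(600, 10)
    other = _gene_block(0, 15) + _gene_block(700, 35)
    programs = [
        _program("s1", 3, 0, a),
        _program("s1", 4, 0, a_dup),
        _program("s1", 5, 0, partner),
        _program("s2", 3, 0, other),
        _program("s2", 4, 0, other),
    ]
    kept = ss.select_robust_programs(programs)
    s1_near = [p for p in kept if p.sample_id == "s1" and len(p.gene_set & set(a)) >= 45]
    assert len(s1_near) == 1  # exactly one of the 48/50 twins survives


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=30), st.data())
def test_raising_inter_overlap_never_retains_more(thresh, data):
    rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
    pool = [f"g{i:04d}" for i in range(300)]
    programs = []
    for s in range(3):
        for k in (3, 4):
            for f in range(k):
                genes = rng.choice(pool, size=50, replace=False)
                programs.append(_program(f"s{s}", k, f, sorted(genes)))
    lo = ss.select_robust_programs(
        programs, RobustnessParams(intra_min_overlap=0, inter_min_overlap=thresh)
    )
    hi = ss.select_robust_programs(
        programs, RobustnessParams(intra_min_overlap=0, inter_min_overlap=min(50, thresh + 5))
    )
    assert len(hi) <= len(lo)


# ------------------------------------------------------------ Jaccard


def test_jaccard_examples():
    a = set(_gene_block(0))
    assert ss.jaccard_index(a, a) == 1.0
    assert ss.jaccard_index(a, _gene_block(100)) == 0.0
    half = _gene_block(0, 25) + _gene_block(200, 25)
    assert ss.jaccard_index(a, half) == pytest.approx(25 / 75)
    assert ss.jaccard_index(set(), set()) == 0.0


@settings(max_examples=50, deadline=None)
@given(
    st.sets(st.integers(0, 60), max_size=40),
    st.sets(st.integers(0, 60), max_size=40),
)
def test_jaccard_properties(a, b):
    a = {f"g{i}" for i in a}
    b = {f"g{i}" for i in b}
    j = ss.jaccard_index(a, b)
    assert 0.0 <= j <= 1.0
    assert j == ss.jaccard_index(b, a)
    if a:
        assert ss.jaccard_index(a, a) == 1.0


# ------------------------------------------------------- clustering


def test_clustering_separates_two_groups():
    rng = np.random.default_rng(4)
    core1, core2 = _gene_block(0), _gene_block(100)
    programs = []
    for i in range(4):  # within-group J >= 0.6, between ~0
        v1 = core1[:45] + _gene_block(500 + 10 * i, 5)
        v2 = core2[:45] + _gene_block(600 + 10 * i, 5)
        programs.append(_program(f"s{i}", 3, 0, v1))
        programs.append(_program(f"s{i}", 4, 0, v2))
    mps = ss.cluster_meta_programs(programs, min_cluster_size=3)
    assert len(mps) == 2
    consensus_sets = [set(mp.consensus_genes) for mp in mps]
    assert any(len(s & set(core1)) >= 45 for s in consensus_sets)
    assert any(len(s & set(core2)) >= 45 for s in consensus_sets)


def test_clustering_identical_programs_one_mp():
    programs = [_program(f"s{i}", 3, 0, _gene_block(0)) for i in range(4)]
    mps = ss.cluster_meta_programs(programs, min_cluster_size=2)
    assert len(mps) == 1
    assert mps[0].consensus_genes == tuple(sorted(_gene_block(0)))
    assert mps[0].n_samples == 4


def test_clustering_single_program_warns_empty():
    with pytest.warns(UserWarning, match="2 programs"):
        mps = ss.cluster_meta_programs([_program("s1", 3, 0, _gene_block(0))])
    assert mps == []


# -------------------------------------------------------- consensus


def test_consensus_identical_members():
    members = [_program(f"s{i}", 3, 0, _gene_block(0)) for i in range(3)]
    assert set(ss.consensus_gene_list(members)) == set(_gene_block(0))


def test_consensus_is_fifty_when_union_suffices():
    m1 = _program("s1", 3, 0, _gene_block(0))
    m2 = _program("s2", 3, 0, _gene_block(25))  # union = 75 genes
    consensus = ss.consensus_gene_list([m1, m2])
    assert len(consensus) == 50
    # genes in both members (25..49) outrank genes in only one
    shared = set(_gene_block(25, 25))
    assert shared <= set(consensus)


def test_consensus_frequency_beats_loading():
    everyone = _gene_block(0)
    one_member = _gene_block(200)
    m_all = [_program(f"s{i}", 3, 0, everyone) for i in range(3)]
    m_one = _program("s9", 3, 0, one_member,
                     weights=tuple(1000.0 - i for i in range(50)))
    consensus = ss.consensus_gene_list(m_all + [m_one])
    assert set(consensus) == set(everyone)


def test_consensus_small_union_warns():
    with pytest.warns(UserWarning, match="union"):
        out = ss.consensus_gene_list([_program("s1", 3, 0, _gene_block(0, 30))])
    assert len(out) == 30
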