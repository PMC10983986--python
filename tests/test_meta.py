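"""Meta-program clustering and delta-Shannon entropy."""

import itertools
import math

import numpy as np
import pytest

from lsgi.meta import (
    CatalogEntry,
    ProgramCatalog,
    cluster_meta_programs,
    delta_shannon_entropy,
    find_founder,
    grow_meta_program,
    overlap_count,
)

GENES = [f"g{i:03d}" for i in range(400)]


def entry(sample, program, gene_idx, loadings=None, study=None, tumor_type=None):
    genes = tuple(GENES[i] for i in gene_idx)
    if loadings is None:
        loadings = tuple(np.linspace(1.0, 0.5, len(genes)))
    return CatalogEntry(sample=sample, program=program, genes=genes,
                        loadings=tuple(loadings), study=study,
                        tumor_type=tumor_type)


def block(start, size):
    return list(range(start, start + size))


class TestOverlapCount:
    @pytest.mark.parametrize("a, b, want", [
        (list(range(50)), list(range(50)), 50),
        (list(range(50)), list(range(50, 100)), 0),
        ([0, 1, 2], [1, 2, 3], 2),
    ])
    def test_counts(self, a, b, want):
        assert overlap_count([GENES[i] for i in a], [GENES[i] for i in b]) == want


class TestFindFounder:
    def test_no_high_overlap_pairs_terminates(self):
        entries = [entry("s", f"p{i}", block(i * 60, 50)) for i in range(3)]
        assert find_founder(entries) is None

    def test_single_program_catalog(self):
        assert find_founder([entry("s", "p1", block(0, 50))]) is None

    def test_partner_count_then_total_overlap(self):
        # P1~P2 share 30, P1~P3 share 25, P2~P3 share 22; P4 isolated.
        # P1 and P2 tie on partner count (2); P1 wins on total 55 > 52.
        shared_all = block(0, 20)           # in P1, P2, P3
        p1p2 = block(20, 10)                # P1 and P2 only
        p1p3 = block(30, 5)                 # P1 and P3 only
        p2p3 = block(35, 2)                 # P2 and P3 only
        p1 = shared_all + p1p2 + p1p3 + block(100, 15)
        p2 = shared_all + p1p2 + p2p3 + block(120, 18)
        p3 = shared_all + p1p3 + p2p3 + block(140, 23)
        p4 = block(200, 50)
        entries = [entry("s", n, idx) for n, idx in
                   [("p1", p1), ("p2", p2), ("p3", p3), ("p4", p4)]]
        assert overlap_count(entries[0].genes, entries[1].genes) == 30
        assert overlap_count(entries[0].genes, entries[2].genes) == 25
        assert overlap_count(entries[1].genes, entries[2].genes) == 22
        founder = find_founder(entries)
        assert founder.key == ("s", "p1")


class TestGrowMetaProgram:
    def test_identical_top50_fixed_point(self):
        idx = block(0, 50)
        entries = [entry("s", f"p{i}", idx) for i in range(3)]
        mp = grow_meta_program(entries[0], entries)
        assert len(mp.members) == 3
        assert set(mp.signature_genes) == {GENES[i] for i in idx}

    def test_merge_threshold_at_least_20(self):
        founder = entry("s", "p1", block(0, 50))
        at20 = entry("s", "p2", block(30, 50))   # shares exactly 20
        at19 = entry("s", "p3", block(31, 50))   # shares exactly 19
        mp = grow_meta_program(founder, [founder, at20])
        assert ("s", "p2") in mp.members
        assert grow_meta_program(founder, [founder, at19]) is None

    def test_signature_shift_can_exclude_late_candidate(self):
        # P2 (overlap 40 with P1) merges first; the refreshed signature keeps
        # the 40 shared genes plus P2's high-loading unique genes, dropping
        # P1's low-loading tail that carried all of P3's overlap.
        shared = block(0, 40)
        p1_unique = block(40, 10)
        p2_unique = block(60, 10)
        p1 = entry("s", "p1", shared + p1_unique,
                   loadings=[1.0] * 40 + [0.2] * 10)
        p2 = entry("s", "p2", shared + p2_unique,
                   loadings=[1.0] * 40 + [0.9] * 10)
        # P3: 12 of the shared genes + 9 of P1's unique -> 21 with P1, 12 with P2
        p3 = entry("s", "p3", shared[:12] + p1_unique[:9] + block(200, 29))
        entries = [p1, p2, p3]
        founder = find_founder(entries)
        assert founder.key == ("s", "p1")
        mp = grow_meta_program(founder, entries)
        assert mp.members == [("s", "p1"), ("s", "p2")]
        sig = set(mp.signature_genes)
        assert {GENES[i] for i in p2_unique} <= sig
        assert not ({GENES[i] for i in p1_unique} & sig)


class TestClusterMetaPrograms:
    def test_disjoint_catalog_all_unclustered(self):
        entries = [entry("s", f"p{i}", block(i * 60, 50)) for i in range(4)]
        mps, unclustered = cluster_meta_programs(ProgramCatalog(entries))
        assert mps == []
        assert len(unclustered) == 4

    def test_two_cliques_recovered_exactly(self):
        cliqueA = [entry("sa", f"a{i}", block(0, 50)) for i in range(3)]
        cliqueB = [entry("sb", f"b{i}", block(100, 50)) for i in range(3)]
        mps, unclustered = cluster_meta_programs(ProgramCatalog(cliqueA + cliqueB))
        assert len(mps) == 2 and unclustered == []
        memberships = [set(mp.members) for mp in mps]
        assert {e.key for e in cliqueA} in memberships
        assert {e.key for e in cliqueB} in memberships

    def test_partition_property(self, rng):
        entries = []
        for i in range(6):
            start = int(rng.integers(0, 5)) * 15
            entries.append(entry("s", f"p{i}", block(start, 50)))
        catalog = ProgramCatalog(entries)
        mps, unclustered = cluster_meta_programs(catalog)
        assigned = [k for mp in mps for k in mp.members] + list(unclustered)
        assert sorted(assigned) == sorted(e.key for e in entries)

    def test_order_invariance_exhaustive(self):
        base = [
            entry("s", "p0", block(0, 50)),
            entry("s", "p1", block(5, 50)),
            entry("s", "p2", block(10, 50)),
            entry("s", "p3", block(300, 50)),
        ]
        reference = None
        for perm in itertools.permutations(base):
            mps, unclustered = cluster_meta_programs(ProgramCatalog(perm))
            outcome = ([tuple(mp.members) for mp in mps], tuple(unclustered))
            if reference is None:
                reference = outcome
            assert outcome == reference

    def test_signature_idempotence(self):
        from lsgi.meta import _recompute_signature

        members = [entry("s", f"p{i}", block(i * 10, 50)) for i in range(3)]
        mp = grow_meta_program(members[0], members)
        regenerated = _recompute_signature(
            [m for m in members if m.key in mp.members])
        assert regenerated == mp.signature


def _labeled_catalog(labels, genes_per=50):
    entries = []
    for i, lab in enumerate(labels):
        entries.append(entry(f"s{i}", "p", block((i % 4) * 60, genes_per),
                             study=lab, tumor_type=lab))
    return ProgramCatalog(entries)


def _mp_over(catalog, member_keys):
    from lsgi.meta import MetaProgram

    sig = [(g, 1, 1.0) for g in GENES[:50]]
    return MetaProgram(mp_id="MP_1", members=list(member_keys),
                       signature=sig, founder=member_keys[0])


class TestDeltaShannonEntropy:
    def test_half_half_composition(self):
        catalog = _labeled_catalog(["X", "X", "Y", "Y"])
        mp = _mp_over(catalog, [("s0", "p"), ("s2", "p")])
        row = delta_shannon_entropy(mp, catalog, scheme="study")
        assert row["entropy"] == pytest.approx(math.log(2))

    def test_pure_mp_has_zero_entropy_nonpositive_delta(self):
        catalog = _labeled_catalog(["X", "X", "Y", "Y", "Y", "Y"])
        mp = _mp_over(catalog, [("s0", "p"), ("s1", "p")])
        row = delta_shannon_entropy(mp, catalog, scheme="study",
                                    n_shuffle=200, seed=0)
        assert row["entropy"] == 0.0
        assert row["delta"] <= 0.0

    def test_entropy_bounded_by_log_c(self, rng):
        labels = [f"c{i % 3}" for i in range(12)]
        catalog = _labeled_catalog(labels)
        keys = [e.key for e in catalog.entries]
        mp = _mp_over(catalog, [keys[i] for i in rng.choice(12, 6, replace=False)])
        row = delta_shannon_entropy(mp, catalog, scheme="study")
        assert 0.0 <= row["entropy"] <= math.log(3) + 1e-12
        assert 0.0 <= row["mean_shuffled"] <= math.log(3) + 1e-12

    def test_uniform_null_delta_near_zero(self):
        # MP drawn uniformly from the catalog's label composition: the mean
        # delta over seeds should vanish within 3 standard errors
        deltas = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            labels = [f"c{i % 3}" for i in range(60)]
            catalog = _labeled_catalog(labels)
            keys = [e.key for e in catalog.entries]
            members = [keys[i] for i in r.choice(60, 30, replace=False)]
            mp = _mp_over(catalog, members)
            row = delta_shannon_entropy(mp, catalog, scheme="study",
                                        n_shuffle=10, seed=seed)
            deltas.append(row["delta"])
        se = np.std(deltas, ddof=1) / math.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-12

    def test_single_member_mp_entropy_zero(self):
        catalog = _labeled_catalog(["X", "Y", "Y"])
        from lsgi.meta import MetaProgram

        mp = MetaProgram(mp_id="MP_1",
                         members=[("s0", "p"), ("s1", "p")],
                         signature=[(GENES[0], 1, 1.0)], founder=("s0", "p"))
        mp.members = [("s0", "p")]  # single-member edge case
        row = delta_shannon_entropy(mp, catalog, scheme="study")
        assert row["entropy"] == 0.0

    def test_variant_flips_sign(self):
        catalog = _labeled_catalog(["X", "X", "Y", "Y"])
        mp = _mp_over(catalog, [("s0", "p"), ("s1", "p")])
        a = delta_shannon_entropy(mp, catalog, scheme="study", seed=3)
        b = delta_shannon_entropy(mp, catalog, scheme="study", seed=3,
                                  variant="max_minus_real")
        assert a["delta"] == pytest.approx(-b["delta"])
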