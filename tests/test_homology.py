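"""Local alignment, E-values, reciprocal best hits and uniqueness calls."""

import math

import numpy as np
import pytest
from oracles import gotoh_local_score

from eetcensus import synth
from eetcensus.homology import (align_local, assign_homology,
                                bidirectional_best_hits, detect_t4p,
                                estimate_evalue)


def random_protein(length, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(synth.AMINO_ACIDS), size=length))


class TestAlignLocal:
    def test_self_alignment_is_perfect(self):
        for seed in range(5):
            s = random_protein(60, seed)
            r = align_local(s, s)
            assert r.identity_percent == pytest.approx(100.0)
            assert r.query_coverage_percent == pytest.approx(100.0)

    def test_textbook_pair_score_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert align_local(a, b).score == pytest.approx(
            gotoh_local_score(a, b))

    def test_score_matches_exhaustive_dp_on_short_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = random_protein(int(rng.integers(3, 13)), rng.integers(1 << 30))
            b = random_protein(int(rng.integers(3, 13)), rng.integers(1 << 30))
            assert align_local(a, b).score == pytest.approx(
                gotoh_local_score(a, b)), (a, b)

    def test_score_is_symmetric(self):
        a, b = random_protein(80, 1), random_protein(70, 2)
        assert align_local(a, b).score == pytest.approx(align_local(b, a).score)

    def test_generated_pair_hits_target_identity(self):
        a, b, realized = synth.gen_homolog_pair(200, 50.0, seed=9)
        assert abs(align_local(a, b).identity_percent - 50.0) <= 5.0
        assert realized == pytest.approx(align_local(a, b).identity_percent)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MKV")


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        assert estimate_evalue(0, 100, 1000) == pytest.approx(
            0.041 * 100 * 1000)

    def test_linear_in_database_length(self):
        assert estimate_evalue(50, 100, 2000) == pytest.approx(
            2 * estimate_evalue(50, 100, 1000))

    def test_score_shift_by_ln2_over_lambda_halves_e(self):
        s = 80.0
        shifted = estimate_evalue(s + math.log(2) / 0.267, 100, 1000)
        assert shifted == pytest.approx(estimate_evalue(s, 100, 1000) / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_evalue(-1, 100, 100)
        with pytest.raises(ValueError):
            estimate_evalue(10, 0, 100)


def ortholog_families(n_pairs=5, n_decoys=3, identity=70.0, base_seed=50):
    """Planted ortholog pairs plus unpaired decoys, with truth labels."""
    a_prot, b_prot, pairs = [], [], []
    for i in range(n_pairs):
        a, b, _ = synth.gen_homolog_pair(150, identity, base_seed + i)
        a_prot.append((f"A_{i}", a))
        b_prot.append((f"B_{i}", b))
        pairs.append((f"A_{i}", f"B_{i}"))
    for i in range(n_decoys):
        a_prot.append((f"AD_{i}", random_protein(150, 900 + i)))
        b_prot.append((f"BD_{i}", random_protein(150, 950 + i)))
    return a_prot, b_prot, set(pairs)


class TestBBH:
    def test_proteome_vs_itself_pairs_identically(self):
        prot = [(f"p{i}", random_protein(100, i)) for i in range(4)]
        pairs = bidirectional_best_hits(prot, prot)
        assert {(p.locus_a, p.locus_b) for p in pairs} == \
            {(t, t) for t, _ in prot}
        assert all(p.identity_percent == pytest.approx(100.0) for p in pairs)

    def test_planted_ortholog_pairs_recovered_exactly(self):
        a_prot, b_prot, truth = ortholog_families()
        pairs = bidirectional_best_hits(a_prot, b_prot, 40.0, 80.0)
        assert {(p.locus_a, p.locus_b) for p in pairs} == truth

    def test_symmetry(self):
        a_prot, b_prot, _ = ortholog_families(n_pairs=3, n_decoys=2)
        ab = {(p.locus_a, p.locus_b)
              for p in bidirectional_best_hits(a_prot, b_prot)}
        ba = {(p.locus_b, p.locus_a)
              for p in bidirectional_best_hits(b_prot, a_prot)}
        assert ab == ba

    def test_low_identity_pair_gated_by_threshold(self):
        a, b, realized = synth.gen_homolog_pair(300, 30.0, seed=77)
        prots_a, prots_b = [("a0", a)], [("b0", b)]
        assert realized < 40
        assert bidirectional_best_hits(prots_a, prots_b, 40.0, 80.0) == []
        low = bidirectional_best_hits(prots_a, prots_b, 25.0, 60.0)
        assert [(p.locus_a, p.locus_b) for p in low] == [("a0", "b0")]

    def test_raising_thresholds_never_adds_pairs(self):
        a_prot, b_prot, _ = ortholog_families(identity=60.0)
        n = [len(bidirectional_best_hits(a_prot, b_prot, ident, cov))
             for ident, cov in [(20, 50), (40, 80), (70, 90), (95, 99)]]
        assert n == sorted(n, reverse=True)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            bidirectional_best_hits([], [("b", "MKV")])


class TestAssignHomology:
    def test_focal_identical_to_reference_has_no_uniques(self):
        ref = [(f"r{i}", random_protein(120, i)) for i in range(4)]
        focal = [(f"f{i}", s) for i, (_, s) in enumerate(ref)]
        out = assign_homology(focal, [("db", ref)], 40.0)
        assert not any(a.unique for a in out)
        assert all(a.best_identity_percent == pytest.approx(100.0)
                   for a in out)

    def test_random_decoy_is_unique(self):
        refs = [("db", [(f"r{i}", random_protein(150, i)) for i in range(3)])]
        [a] = assign_homology([("decoy", random_protein(150, 12345))],
                              refs, 40.0)
        assert a.unique and a.best_identity_percent < 40.0

    def test_spurious_short_fragments_do_not_mask_uniqueness(self):
        # unrelated proteins share short high-identity local fragments;
        # the significance gate must keep them from counting as homologs
        from eetcensus.homology import align_local
        refs_seqs = [(f"r{i}", random_protein(150, i)) for i in range(3)]
        decoy = random_protein(150, 12345)
        frag_identities = [align_local(decoy, s).identity_percent
                           for _, s in refs_seqs]
        assert max(frag_identities) > 40.0  # the trap is real
        [a] = assign_homology([("decoy", decoy)], [("db", refs_seqs)], 40.0)
        assert a.unique

    def test_planted_unique_count(self):
        refs_seqs = [(f"r{i}", random_protein(150, 60 + i)) for i in range(3)]
        focal = []
        for i in range(6):  # diverged copies of references: not unique
            base = refs_seqs[i % 3][1]
            focal.append((f"hom_{i}", _mutate(base, 0.25, 800 + i)))
        for i in range(4):  # unrelated: unique
            focal.append((f"uniq_{i}", random_protein(150, 7000 + i)))
        out = assign_homology(focal, [("db", refs_seqs)], 40.0)
        uniques = {a.locus_tag for a in out if a.unique}
        assert uniques == {f"uniq_{i}" for i in range(4)}

    def test_threshold_extremes(self):
        base = random_protein(100, 0)
        refs = [("db", [("r0", base)])]
        focal = [("f0", _mutate(base, 0.3, 1))]  # clear homolog of r0
        assert not assign_homology(focal, refs, 0.0)[0].unique
        assert assign_homology(focal, refs, 101.0)[0].unique

    def test_requires_a_reference(self):
        with pytest.raises(ValueError):
            assign_homology([("f", "MKV")], [], 40.0)


def _mutate(seq, fraction, seed):
    rng = np.random.default_rng(seed)
    chars = list(seq)
    for p in rng.permutation(len(chars))[: int(fraction * len(chars))]:
        options = [c for c in synth.AMINO_ACIDS if c != chars[p]]
        chars[p] = options[rng.integers(0, len(options))]
    return "".join(chars)


class TestDetectT4p:
    def _reference(self):
        names = ["PilA", "PilQ", "PilT"]
        return {n: [(f"{n}_ref", random_protein(140, 77 + i))]
                for i, n in enumerate(names)}

    def test_reference_against_itself_matches_all_names(self):
        ref = self._reference()
        proteome = [(tag, seq) for entries in ref.values()
                    for tag, seq in entries]
        table = detect_t4p(proteome, ref)
        for name, entries in ref.items():
            assert [t for t, _ in table[name]] == [entries[0][0]]
            assert table[name][0][1] == pytest.approx(100.0)

    def test_missing_family_reported_absent(self):
        ref = self._reference()
        proteome = [ref["PilA"][0], ref["PilT"][0]]
        table = detect_t4p(proteome, ref)
        assert table["PilQ"] == []

    def test_paralog_expansion_maps_to_one_name(self):
        ref = self._reference()
        base = ref["PilT"][0][1]
        proteome = [("pilT_1", _mutate(base, 0.2, 1)),
                    ("pilT_2", _mutate(base, 0.25, 2)),
                    ("other", random_protein(140, 5000))]
        table = detect_t4p(proteome, ref)
        assert {t for t, _ in table["PilT"]} == {"pilT_1", "pilT_2"}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            detect_t4p([("p", "MKV")], {})
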