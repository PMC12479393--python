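import random

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from scipy.stats import kstest

from gapfold import fixtures
from gapfold.template_engine import (
    Assignment,
    PerturbationSpec,
    assign_chains,
    build_template_features,
    merge_chains,
    perturb_template,
    sequence_identity,
)

# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of global alignments with the
# production scoring (match 1, mismatch 0, gap open/extend -0.5/-0.1)

MATCH, MISMATCH, OPEN, EXT = 1.0, 0.0, -0.5, -0.1


def _enumerate_alignments(a, b):
    results = []

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            results.append(list(cols))
            return
        if i < len(a) and j < len(b):
            cols.append((i, j)); rec(i + 1, j + 1, cols); cols.pop()
        if i < len(a):
            cols.append((i, None)); rec(i + 1, j, cols); cols.pop()
        if j < len(b):
            cols.append((None, j)); rec(i, j + 1, cols); cols.pop()

    rec(0, 0, [])
    return results


def _score_alignment(a, b, cols):
    s, prev_gap = 0.0, None
    for (i, j) in cols:
        if i is not None and j is not None:
            s += MATCH if a[i] == b[j] else MISMATCH
            prev_gap = None
        else:
            which = "b" if j is None else "a"
            s += EXT if prev_gap == which else OPEN
            prev_gap = which
    return s


def oracle_identity(a, b):
    """Max identity count over all optimal global alignments, brute force."""
    alns = _enumerate_alignments(a, b)
    best = max(_score_alignment(a, b, c) for c in alns)
    return max(
        sum(1 for (i, j) in c if i is not None and j is not None and a[i] == b[j])
        for c in alns
        if abs(_score_alignment(a, b, c) - best) < 1e-9
    ) / min(len(a), len(b))


class TestSequenceIdentity:
    def test_identical(self):
        assert sequence_identity("MKVL", "MKVL") == 1.0

    def test_disjoint_alphabets(self):
        assert sequence_identity("AAAA", "GGGG") == 0.0

    def test_fragment_case_frozen_oracle_value(self):
        # value computed by the exhaustive alignment oracle: 1.0
        assert sequence_identity("MKVLQ", "MKV") == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_short_strings(self):
        rng = random.Random(7)
        for _ in range(60):
            a = "".join(rng.choice("ACDG") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACDG") for _ in range(rng.randint(1, 6)))
            assert sequence_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_symmetric(self):
        rng = random.Random(11)
        for _ in range(30):
            a = "".join(rng.choice("ACDEFG") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("ACDEFG") for _ in range(rng.randint(1, 8)))
            assert sequence_identity(a, b) == sequence_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("", "MKV")


def greedy_oracle(identity_matrix, chain_ids):
    """Independent reimplementation of the greedy assignment rule."""
    n_targets, n_chains = identity_matrix.shape
    cells = [
        (ti, chain_ids[ci], identity_matrix[ti, ci])
        for ti in range(n_targets)
        for ci in range(n_chains)
    ]
    cells.sort(key=lambda c: (-c[2], c[0], c[1]))
    used_t, used_c, pairs = set(), set(), []
    for ti, cid, ident in cells:
        if ti in used_t or cid in used_c:
            continue
        pairs.append((ti, cid, ident))
        used_t.add(ti)
        used_c.add(cid)
    return sorted(pairs)


class TestAssignChains:
    def test_homomer_tie_break(self):
        seq = "MKVLQWERTY"
        template = fixtures.make_complex([10, 10], seed=0, sequences=[seq, seq],
                                         chain_ids=["B", "A"])
        assignment = assign_chains([seq, seq], template)
        assert assignment.pairs == [(0, "A", 1.0), (1, "B", 1.0)]
        assert not assignment.unmatched_targets
        assert not assignment.unmatched_template_chains

    def test_one_target_three_chains(self):
        seqs = ["MKVLQWERTY", "ACDEFACDEF", "HHHHHHHHHH"]
        template = fixtures.make_complex([10, 10, 10], seed=0, sequences=seqs)
        assignment = assign_chains([seqs[1]], template)
        assert assignment.pairs == [(0, "B", 1.0)]
        assert sorted(assignment.unmatched_template_chains) == ["A", "C"]

    def test_matches_greedy_oracle_on_random_matrices(self):
        # sequences engineered so pairwise identities form a random matrix:
        # identity of two equal-length gapless sequences is the fraction of
        # equal positions, so we control it by construction.
        rng = random.Random(3)
        for _ in range(30):
            n = rng.choice([3, 4])
            length = 12
            targets = ["".join(rng.choice("ACDEFGHIKL") for _ in range(length))
                       for _ in range(n)]
            chain_ids = [chr(ord("A") + i) for i in range(n)]
            chain_seqs = ["".join(rng.choice("ACDEFGHIKL") for _ in range(length))
                          for _ in range(n)]
            template = fixtures.make_complex([length] * n, seed=0,
                                             sequences=chain_seqs, chain_ids=chain_ids)
            identity = np.array([[sequence_identity(t, c) for c in chain_seqs]
                                 for t in targets])
            expected = greedy_oracle(identity, chain_ids)
            got = assign_chains(targets, template)
            assert [(t, c) for t, c, _ in got.pairs] == [(t, c) for t, c, _ in expected]
            for (_, _, gi), (_, _, ei) in zip(got.pairs, expected):
                assert gi == pytest.approx(ei)

    def test_agreement_with_hungarian_recorded_not_asserted(self, capsys):
        # informational: how often greedy equals the optimal assignment
        rng = random.Random(5)
        agree = total = 0
        for _ in range(20):
            n = 3
            mat = np.array([[rng.random() for _ in range(n)] for _ in range(n)])
            chain_ids = ["A", "B", "C"]
            greedy = {(t, c) for t, c, _ in greedy_oracle(mat, chain_ids)}
            rows, cols = linear_sum_assignment(-mat)
            optimal = {(int(r), chain_ids[int(c)]) for r, c in zip(rows, cols)}
            agree += greedy == optimal
            total += 1
        print(f"greedy equals Hungarian optimum in {agree}/{total} random 3x3 cases")

    def test_empty_targets_rejected(self, two_chain_complex):
        with pytest.raises(ValueError):
            assign_chains([], two_chain_complex)


class TestMergeChains:
    def test_paper_defaults_two_chains(self):
        merged = merge_chains(["A" * 60, "C" * 55], gap_size=200)
        assert len(merged) == 115
        assert merged.residue_index[0] == 1
        assert merged.residue_index[60] == 261  # second chain start: 60 + 200 + 1

    def test_single_chain_no_gap(self):
        merged = merge_chains(["M" * 40], gap_size=200)
        assert merged.residue_index.tolist() == list(range(1, 41))

    def test_three_chain_arithmetic(self):
        merged = merge_chains(["A" * 10, "C" * 10, "D" * 10], gap_size=5)
        starts = [merged.residue_index[off] for off in merged.chain_offsets]
        assert starts == [1, 16, 31]

    def test_boundary_jumps_exhaustive(self):
        merged = merge_chains(["A" * 7, "C" * 5, "D" * 9], gap_size=13)
        diffs = np.diff(merged.residue_index)
        boundaries = {6, 11}  # position before each chain switch
        for i, d in enumerate(diffs):
            assert d == (14 if i in boundaries else 1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            merge_chains([], gap_size=200)
        with pytest.raises(ValueError):
            merge_chains(["MKV"], gap_size=0)
        with pytest.raises(ValueError):
            merge_chains(["MKV", ""], gap_size=200)


class TestBuildTemplateFeatures:
    def test_identity_template_full_mask(self, two_chain_complex):
        seqs = [c.sequence for c in two_chain_complex.chains]
        merged = merge_chains(seqs)
        assignment = assign_chains(seqs, two_chain_complex)
        feats = build_template_features(merged, assignment, two_chain_complex)
        assert feats.mask.all()
        expected = np.concatenate([c.cb_coords for c in two_chain_complex.chains])
        np.testing.assert_array_equal(feats.positions, expected)
        assert feats.template_sequence == merged.sequence

    def test_unassigned_chain_all_false(self, two_chain_complex):
        seqs = [c.sequence for c in two_chain_complex.chains]
        extra = "W" * 30  # no template partner
        merged = merge_chains(seqs + [extra])
        assignment = assign_chains(seqs + [extra], two_chain_complex)
        feats = build_template_features(merged, assignment, two_chain_complex)
        assert 2 in assignment.unmatched_targets
        assert not feats.mask[merged.chain_slice(2)].any()
        assert feats.mask[merged.chain_slice(0)].all()

    def test_template_nterm_overhang_skipped(self):
        # template chain has 5 extra N-terminal residues absent from the
        # target; independent check: the alignment must map target position i
        # to template residue i + 5, for all i.
        target = "MKVLQWERTYACDEF"
        template_seq = "GGGGG" + target
        template = fixtures.make_complex([len(template_seq)], seed=0,
                                         sequences=[template_seq])
        merged = merge_chains([target])
        assignment = assign_chains([target], template)
        feats = build_template_features(merged, assignment, template)
        assert feats.mask.all()
        chain = template.chains[0]
        np.testing.assert_array_equal(feats.positions, chain.cb_coords[5:])
        assert feats.template_sequence == target

    def test_never_invents_coordinates(self, three_chain_complex):
        seqs = [c.sequence for c in three_chain_complex.chains]
        merged = merge_chains(seqs)
        assignment = assign_chains(seqs, three_chain_complex)
        feats = build_template_features(merged, assignment, three_chain_complex)
        all_template = np.concatenate([c.cb_coords for c in three_chain_complex.chains])
        for pos in np.nonzero(feats.mask)[0]:
            assert any(np.array_equal(feats.positions[pos], row) for row in all_template)

    def test_unknown_chain_id_rejected(self, two_chain_complex):
        seqs = [c.sequence for c in two_chain_complex.chains]
        merged = merge_chains(seqs)
        bad = Assignment(pairs=[(0, "Z", 1.0)], unmatched_targets=[1],
                         unmatched_template_chains=[])
        with pytest.raises(ValueError):
            build_template_features(merged, bad, two_chain_complex)


def _rotation_angle_deg(before, after, com, translation):
    """Recover the rotation angle from rigidly transformed coordinates."""
    x = before - com
    y = after - com - translation
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = (u @ np.diag([1, 1, d]) @ vt).T
    cos = (np.trace(r) - 1) / 2
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


class TestPerturbTemplate:
    def test_zero_spec_is_identity(self, two_chain_complex):
        spec = PerturbationSpec(max_angle=0.0, max_shift=0.0, seed=1)
        out = perturb_template(two_chain_complex, spec)
        for orig, new in zip(two_chain_complex.chains, out.chains):
            np.testing.assert_allclose(new.cb_coords, orig.cb_coords, atol=1e-9)
            np.testing.assert_allclose(new.ca_coords, orig.ca_coords, atol=1e-9)

    def test_rigidity(self, three_chain_complex):
        spec = PerturbationSpec(seed=42)
        out = perturb_template(three_chain_complex, spec)
        for orig, new in zip(three_chain_complex.chains, out.chains):
            np.testing.assert_allclose(
                pdist(new.cb_coords), pdist(orig.cb_coords), atol=1e-6
            )

    def test_same_seed_bit_reproducible(self, two_chain_complex):
        spec = PerturbationSpec(seed=9)
        a = perturb_template(two_chain_complex, spec)
        b = perturb_template(two_chain_complex, spec)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.cb_coords, cb.cb_coords)

    def test_bounds_and_uniformity_monte_carlo(self, two_chain_complex):
        spec_template = dict(max_angle=30.0, max_shift=5.0)
        angles, shifts = [], []
        for seed in range(300):
            spec = PerturbationSpec(seed=seed, **spec_template)
            out = perturb_template(two_chain_complex, spec)
            for orig, new in zip(two_chain_complex.chains, out.chains):
                translation = new.com - orig.com
                angle = _rotation_angle_deg(
                    orig.ca_coords, new.ca_coords, orig.com, translation
                )
                angles.append(angle)
                shifts.append(np.linalg.norm(translation))
        angles, shifts = np.array(angles), np.array(shifts)
        assert np.all(angles <= 30.0 + 1e-6)
        assert np.all(shifts <= 5.0 + 1e-9)
        assert kstest(angles / 30.0, "uniform").pvalue > 1e-3
        assert kstest(shifts / 5.0, "uniform").pvalue > 1e-3

    def test_chains_move_independently(self, two_chain_complex):
        # per-chain shift vectors should be uncorrelated across seeds
        shifts_a, shifts_b = [], []
        for seed in range(200):
            out = perturb_template(two_chain_complex, PerturbationSpec(seed=seed))
            shifts_a.append(out.chains[0].com - two_chain_complex.chains[0].com)
            shifts_b.append(out.chains[1].com - two_chain_complex.chains[1].com)
        shifts_a, shifts_b = np.array(shifts_a), np.array(shifts_b)
        for axis in range(3):
            corr = np.corrcoef(shifts_a[:, axis], shifts_b[:, axis])[0, 1]
            assert abs(corr) < 0.25

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(max_angle=-1.0)
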