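"""Likelihood targets, Cα extension, sequence docking and evaluation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from emtracer import fixtures, map_scaler, tracer
from emtracer.fixtures import SimulationSpec, make_ideal_helix, simulate_map
from emtracer.tracer import (
    ChainFragment,
    assign_sequence,
    ca_frame,
    coverage,
    evaluate_model,
    extend_chain,
    fragments_to_model,
    llk_score,
    merge_fragments,
    offset_ball,
    train_llk,
)
from emtracer.volio import GridMap


@pytest.fixture(scope="module")
def trained(training_model, training_map, toy_map):
    """Cα and residue-type targets trained on the independent fixture,
    scaled onto the toy map's amplitude scale."""
    scaled = map_scaler.scale_reference(training_map, toy_map, 2.5)
    return tracer.train_llk(scaled, training_model)


class TestFramesAndOffsets:
    def test_offset_ball_geometry(self):
        ball = offset_ball(radius=4.0, spacing=1.0)
        assert 200 < len(ball) < 300
        assert np.linalg.norm(ball, axis=1).max() <= 4.0

    def test_frame_orthonormal(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            prev, ca, nxt = rng.normal(scale=3.0, size=(3, 3))
            F = ca_frame(prev, ca, nxt)
            np.testing.assert_allclose(F.T @ F, np.eye(3), atol=1e-12)
            assert np.linalg.det(F) > 0

    def test_frame_follows_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        prev, ca, nxt = rng.normal(scale=3.0, size=(3, 3))
        R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        F1 = ca_frame(prev, ca, nxt)
        F2 = ca_frame(R @ prev + t, R @ ca + t, R @ nxt + t)
        np.testing.assert_allclose(F2, R @ F1, atol=1e-12)


class TestTrainLLK:
    def test_constant_map_gives_flat_target(self, training_model):
        gmap = GridMap(np.full((70, 60, 50), 2.0), voxel_size=1.0,
                       origin=np.array([-15.0, -15.0, -15.0]))
        ca_t, _ = train_llk(gmap, training_model, residue_types=False)
        inside = np.abs(ca_t.mu - 2.0) < 1e-6
        assert inside.mean() > 0.5  # offsets sampled inside the box
        assert np.all(ca_t.sigma2[inside] <= 1e-10 + 1e-12)

    def test_backbone_brighter_than_solvent(self, trained):
        ca_t, _ = trained
        r = np.linalg.norm(ca_t.offsets, axis=1)
        assert ca_t.mu[r < 1.5].mean() > 2.0 * np.abs(ca_t.mu[r > 3.5]).mean()

    def test_split_half_stability(self, training_model, training_map, toy_map):
        scaled = map_scaler.scale_reference(training_map, toy_map, 2.5)
        chains = training_model.chains
        # interleave so both halves mix helix and strand environments
        half_a = fixtures.AtomModel(chains[::2])
        half_b = fixtures.AtomModel(chains[1::2])
        ta, _ = train_llk(scaled, half_a, residue_types=False)
        tb, _ = train_llk(scaled, half_b, residue_types=False)
        corr = np.corrcoef(ta.mu, tb.mu)[0, 1]
        assert corr > 0.9

    def test_too_few_triplets_rejected(self, toy_map):
        tiny = make_ideal_helix(5)
        with pytest.raises(ValueError):
            train_llk(toy_map, tiny)


class TestLLKScore:
    def test_true_pose_beats_solvent(self, toy_model, toy_map, trained):
        ca_t, _ = trained
        true_scores = []
        for ch in toy_model.chains:
            ca = [r.ca.pos for r in ch.residues]
            for i in range(1, len(ca) - 1):
                F = ca_frame(ca[i - 1], ca[i], ca[i + 1])
                true_scores.append(llk_score(toy_map, ca_t, ca[i], F))
        rng = np.random.default_rng(3)
        tree = cKDTree(toy_model.coords())
        lo = toy_map.origin + 4.0
        hi = toy_map.origin + (np.array(toy_map.shape) - 1) * toy_map.voxel_size - 4.0
        solvent_scores = []
        while len(solvent_scores) < 200:
            p = rng.uniform(lo, hi)
            if tree.query(p)[0] > 4.0:
                F = ca_frame(p - [3.8, 0, 0], p, p + [0, 3.8, 0])
                solvent_scores.append(llk_score(toy_map, ca_t, p, F))
        ts, ss = np.array(true_scores), np.array(solvent_scores)
        pooled = np.sqrt((ts.var() + ss.var()) / 2.0)
        assert ts.mean() - ss.mean() > 3.0 * pooled
        assert ts.mean() > np.median(ss)

    def test_single_offset_reduces_to_squared_error(self):
        gmap = GridMap(np.arange(8**3, dtype=float).reshape(8, 8, 8), voxel_size=1.0)
        target = tracer.LLKTarget(
            offsets=np.zeros((1, 3)), mu=np.array([30.0]), sigma2=np.array([1.0])
        )
        positions = [np.array([2.0, 2, 2]), np.array([3.0, 3, 3]), np.array([4.0, 4, 4])]
        scores = [llk_score(gmap, target, p, np.eye(3)) for p in positions]
        from emtracer.volio import interpolate

        errors = [
            -float(((interpolate(gmap, p[None]) - 30.0) ** 2).item())
            for p in positions
        ]
        assert np.argsort(scores).tolist() == np.argsort(errors).tolist()

    def test_translation_equivariance(self, trained, toy_map, toy_model):
        ca_t, _ = trained
        shift = np.array([3.0, -2.0, 5.0])
        shifted_map = toy_map.copy()
        shifted_map.origin = toy_map.origin + shift
        ca = toy_model.chains[0].residues[3].ca.pos
        prev = toy_model.chains[0].residues[2].ca.pos
        nxt = toy_model.chains[0].residues[4].ca.pos
        F = ca_frame(prev, ca, nxt)
        a = llk_score(toy_map, ca_t, ca, F)
        b = llk_score(shifted_map, ca_t, ca + shift, F)
        assert abs(a - b) < 1e-9


class TestExtendChain:
    def test_isolated_helix_stops_at_ends(self, trained):
        """With no density beyond the helix, growth stops within a residue
        of each true terminus."""
        ca_t, _ = trained
        model = fixtures.AtomModel(
            [fixtures._place(make_ideal_helix(6), np.eye(3), np.zeros(3), chain="A")]
        )
        gmap = simulate_map(SimulationSpec(model=model, margin=10.0))
        ca = model.ca_coords()
        frag = extend_chain(gmap, ca_t, ca)
        assert len(frag) <= 6 + 2
        d, _ = cKDTree(ca).query(frag.ca)
        assert d.max() < 4.5

    def test_toy_map_coverage(self, toy_model, toy_map, trained):
        ca_t, _ = trained
        frags = []
        avoid = []
        for ch in toy_model.chains:
            ca = np.array([r.ca.pos for r in ch.residues])
            length = 6 if ch.residues[0].ss == "helix" else 4
            mid = (len(ca) - length) // 2
            seed = ca[mid : mid + length]
            frag = extend_chain(
                toy_map, ca_t, seed, avoid=np.vstack(avoid) if avoid else None
            )
            frags.append(frag)
            avoid.append(frag.ca)
        model = fragments_to_model(merge_fragments(frags))
        assert coverage(model, toy_model, cutoff=2.0) >= 70.0

    def test_geometry_invariants_enforced(self, toy_model, toy_map, trained):
        ca_t, _ = trained
        ca = np.array([r.ca.pos for r in toy_model.chains[0].residues[:6]])
        frag = extend_chain(toy_map, ca_t, ca)
        frag.check_geometry()  # raises on violation
        d = np.linalg.norm(np.diff(frag.ca, axis=0), axis=1)
        assert d.min() >= 3.0 and d.max() <= 4.2
        tree = cKDTree(frag.ca)
        for i, j in tree.query_pairs(3.0 - 1e-9):
            assert abs(i - j) == 1

    def test_short_seed_rejected(self, toy_map, trained):
        ca_t, _ = trained
        with pytest.raises(ValueError):
            extend_chain(toy_map, ca_t, np.zeros((1, 3)))


class TestMergeFragments:
    def _frag(self, ca, score=1.0):
        ca = np.asarray(ca, dtype=float)
        return ChainFragment(ca, np.full(len(ca), score))

    def test_two_halves_joined(self):
        helix = make_ideal_helix(10).ca_coords()
        a = self._frag(helix[:5])
        b = self._frag(helix[5:])
        merged = merge_fragments([a, b])
        assert len(merged) == 1 and len(merged[0]) == 10

    def test_duplicates_deduplicated(self):
        helix = make_ideal_helix(8).ca_coords()
        a = self._frag(helix, score=2.0)
        b = self._frag(helix + 0.1, score=1.0)
        merged = merge_fragments([a, b])
        assert len(merged) == 1
        np.testing.assert_array_equal(merged[0].ca, helix)

    def test_output_fragments_do_not_overlap(self):
        rng = np.random.default_rng(6)
        helix = make_ideal_helix(12).ca_coords()
        frags = []
        for k in range(6):
            start = rng.integers(0, 6)
            stop = start + rng.integers(3, 6)
            shift = rng.normal(scale=0.05, size=3)
            frags.append(self._frag(helix[start:stop] + shift, score=rng.uniform(1, 2)))
        merged = merge_fragments(frags)
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                d, _ = cKDTree(merged[j].ca).query(merged[i].ca)
                shorter = min(len(merged[i]), len(merged[j]))
                assert (d < 2.0).sum() <= 0.4 * shorter


class TestAssignSequence:
    @pytest.fixture(scope="class")
    def typed_setup(self, toy_map, training_model, training_map):
        scaled = map_scaler.scale_reference(training_map, toy_map, 2.5)
        return tracer.train_llk(scaled, training_model)

    def test_register_recovery(self, typed_setup):
        """A traced helix with distinctive large residues docks its own
        sequence at the right register."""
        _, type_targets = typed_setup
        seq = "AAWAAAFAAWAAFA"
        model = fixtures.AtomModel(
            [fixtures._place(make_ideal_helix(14, seq), np.eye(3), np.zeros(3), chain="A")]
        )
        gmap = simulate_map(SimulationSpec(model=model, margin=8.0))
        frag = ChainFragment(model.ca_coords(), np.zeros(14))
        full_seq = "GGGG" + seq + "GGGG"
        out = assign_sequence(gmap, [frag], full_seq, type_targets)
        assert out[0].residue_types is not None
        got = "".join(tracer._AA1[t] for t in out[0].residue_types)
        assert got == seq

    def test_ambiguous_polyala_not_assigned(self, typed_setup):
        _, type_targets = typed_setup
        model = fixtures.AtomModel(
            [fixtures._place(make_ideal_helix(10), np.eye(3), np.zeros(3), chain="A")]
        )
        gmap = simulate_map(SimulationSpec(model=model, margin=8.0))
        frag = ChainFragment(model.ca_coords(), np.zeros(10))
        out = assign_sequence(gmap, [frag], "A" * 30, type_targets)
        assert out[0].residue_types is None

    def test_fragment_longer_than_sequence_flagged(self, typed_setup, toy_map):
        _, type_targets = typed_setup
        frag = ChainFragment(make_ideal_helix(10).ca_coords(), np.zeros(10))
        out = assign_sequence(toy_map, [frag], "AWF", type_targets)
        assert out[0].residue_types is None


class TestEvaluateModel:
    def test_identity_is_perfect(self, toy_model):
        w1, w2, rmsd = evaluate_model(toy_model, toy_model)
        assert (w1, w2) == (100.0, 100.0)
        assert rmsd < 1e-12

    def test_uniform_offset(self, toy_model):
        shifted = toy_model.transformed(np.eye(3), np.array([1.5, 0.0, 0.0]))
        w1, w2, rmsd = evaluate_model(shifted, toy_model)
        assert w1 == 0.0
        assert w2 == 100.0
        assert abs(rmsd - 1.5) < 0.2  # nearest Cα may differ from the partner

    def test_matches_all_pairs_oracle(self, toy_model):
        rng = np.random.default_rng(8)
        jitter = toy_model.transformed(np.eye(3), np.zeros(3))
        pts = jitter.ca_coords() + rng.normal(scale=1.0, size=(74, 3))
        built = fragments_to_model([ChainFragment(pts, np.zeros(len(pts)))])
        w1, w2, rmsd = evaluate_model(built, toy_model)
        truth = toy_model.ca_coords()
        d = np.array([np.linalg.norm(truth - p, axis=1).min() for p in pts])
        assert w1 == 100.0 * (d < 1.0).mean()
        assert w2 == 100.0 * (d < 2.0).mean()
        assert abs(rmsd - np.sqrt((d**2).mean())) < 1e-12

    def test_empty_model_rejected(self, toy_model):
        with pytest.raises(ValueError):
            evaluate_model(fixtures.AtomModel([]), toy_model)
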