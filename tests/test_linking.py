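import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskertrack.config import FaceSpec
from whiskertrack.linking import (
    ChangeModel,
    CurveFeatures,
    FrameLabeling,
    N_FEATURES,
    ShapeModel,
    ThresholdHeuristic,
    TransitionModel,
    assert_valid_labeling,
    build_models,
    compute_features,
    estimate_threshold,
    heuristic_states,
    is_w,
    label_frame,
    label_name,
    link_video,
    n_states,
    state_of_label,
    transition_legal,
)
from whiskertrack.measure import FaceConfig
from whiskertrack.tracing import TracedCurve


def _curve(points):
    pts = np.asarray(points, dtype=np.float64)
    return TracedCurve(pts, np.ones(len(pts)), np.full(len(pts), 2.0))


def _polyline(p0, p1, n=120):
    t = np.linspace(0, 1, n)[:, None]
    return np.asarray(p0) + t * (np.asarray(p1, dtype=float) - np.asarray(p0))


FACE_BOTTOM = FaceConfig(face=FaceSpec(side="bottom", boundary_px=178.0))


def make_features(ap, length, angle=10.0, curv=0.001, score=500.0):
    return CurveFeatures(angle, curv, score, length, ap, ap + 5.0)


class TestComputeFeatures:
    def test_straight_curve_face_left(self):
        face = FaceConfig(face=FaceSpec(side="left", boundary_px=2.0))
        c = _curve(_polyline((5, 50), (105, 50)))
        f = compute_features(c, face)
        assert f.angle_at_face_deg == pytest.approx(0.0, abs=1e-6)
        assert f.mean_curvature_per_px == pytest.approx(0.0, abs=1e-9)
        assert f.length_px == pytest.approx(100.0)
        # a slanted curve separates the endpoint projections (face-first)
        slanted = _curve(_polyline((5, 50), (105, 62)))
        fs = compute_features(slanted, face)
        assert fs.endpoint_follicle < fs.endpoint_tip

    def test_quarter_circle_curvature(self):
        th = np.linspace(0, np.pi / 2, 160)
        pts = np.stack([10 + 100 * np.sin(th), 170 - 100 * (1 - np.cos(th))], 1)
        f = compute_features(_curve(pts), FACE_BOTTOM)
        assert f.mean_curvature_per_px == pytest.approx(0.01, rel=0.05)

    def test_synthetic_base_angle(self, bank):
        from whiskertrack.config import RunConfig
        from whiskertrack.synthdata import render_frame, single_whisker_scene
        from whiskertrack.tracing import trace_frame

        scene = single_whisker_scene(48.0, 2.0, noise_sigma=0.0, curl_px=0.0)
        frame, truth = render_frame(scene, 0)
        curves = trace_frame(frame, RunConfig(), bank)
        face = FaceConfig(face=scene.face_spec())
        f = compute_features(max(curves, key=lambda c: c.arc_length), face)
        assert abs(f.angle_at_face_deg - truth["whiskers"][0]["deflection_deg"]) <= 2.0

    def test_short_curve_fallback(self):
        c = _curve([[10, 170], [10.5, 169], [11, 168]])
        f = compute_features(c, FACE_BOTTOM)
        assert f.mean_curvature_per_px == 0.0


class TestEstimateThreshold:
    def test_spec_example_three_frames(self):
        frames = [[200.0, 210.0, 15.0]] * 3
        h = estimate_threshold(frames)
        assert h.N == 2
        assert 15.0 < h.lambda_px < 200.0
        assert h.training_frames == {0, 1, 2}

    def test_single_frame_single_curve(self):
        h = estimate_threshold([[100.0]])
        assert h.N == 1 and h.training_frames == {0}

    def test_supplied_n_excludes_bad_frames(self):
        frames = [
            [150.0, 160.0, 170.0, 140.0, 20.0],
            [150.0, 160.0, 170.0, 20.0],
            [150.0, 160.0, 170.0, 145.0, 30.0, 10.0],
        ]
        h = estimate_threshold(frames, N=4)
        # brute-force check of the definition
        lam = h.lambda_px
        for t, lens in enumerate(frames):
            n_long = sum(1 for v in lens if v > lam)
            assert (t in h.training_frames) == (n_long == 4)
        assert h.training_frames == {0, 2}

    def test_maximality_against_bruteforce_sweep(self):
        rng = np.random.default_rng(0)
        frames = [list(rng.uniform(10, 200, rng.integers(1, 7))) for _ in range(12)]
        h = estimate_threshold(frames)
        # oracle: try every candidate threshold epsilon-below each length
        best = 0
        lengths = sorted({v for f in frames for v in f})
        cands = [0.0] + [v - 1e-6 for v in lengths] + [max(lengths) + 1]
        for lam in cands:
            counts = [sum(1 for v in f if v > lam) for f in frames]
            for n in range(1, max(counts) + 1):
                best = max(best, sum(1 for c in counts if c == n))
        assert len(h.training_frames) == best

    def test_no_curves_raises(self):
        with pytest.raises(ValueError):
            estimate_threshold([[], []])

    def test_validation(self):
        with pytest.raises(ValueError):
            ThresholdHeuristic(0, 10.0, set())


class TestShapeModel:
    def test_smoothing_arithmetic_single_bin(self):
        vec = np.zeros(N_FEATURES)
        samples = np.tile(vec, (10, 1))
        other = np.tile(vec + 100.0, (5, 1))
        model = ShapeModel.fit(samples, other)
        # all W mass lands in one bin per feature: p = (10+1)/(10+32)
        ll = model.log_likelihood(vec, "W")
        assert ll == pytest.approx(N_FEATURES * np.log(11 / 42), abs=1e-9)

    def test_empty_bin_has_smoothed_mass(self):
        samples = np.tile(np.zeros(N_FEATURES), (10, 1))
        other = np.tile(np.full(N_FEATURES, 100.0), (5, 1))
        model = ShapeModel.fit(samples, other)
        mid = np.full(N_FEATURES, 50.0)
        ll = model.log_likelihood(mid, "W")
        assert ll == pytest.approx(N_FEATURES * np.log(1 / 42), abs=1e-9)

    def test_no_zero_bins(self):
        rng = np.random.default_rng(1)
        model = ShapeModel.fit(rng.normal(size=(30, 6)), rng.normal(2, 1, size=(20, 6)))
        assert np.isfinite(model.logp_w).all() and np.isfinite(model.logp_fp).all()


class TestTransitionRules:
    def test_label_names_round_trip(self):
        for s in range(9):
            assert state_of_label(label_name(s)) == s

    def test_ordering_rules(self):
        # W states never repeat; chain order never decreases
        assert transition_legal(0, 1) and transition_legal(1, 2)
        assert transition_legal(0, 0)  # F self-loop
        assert not transition_legal(1, 1)  # W repeat
        assert not transition_legal(3, 1)  # backwards
        assert transition_legal(1, 4)  # skipping ahead is fine

    def test_illegal_transitions_never_smoothed(self):
        tm = TransitionModel(2)
        tm.observe([0, 1, 2, 3, 4])
        lp = tm.log_pair
        for a in range(5):
            for b in range(5):
                if not transition_legal(a, b):
                    assert lp[a, b] == -np.inf
                else:
                    assert np.isfinite(lp[a, b])
        # outgoing probabilities sum to 1
        for a in range(5):
            assert np.exp(lp[a][np.isfinite(lp[a])]).sum() == pytest.approx(1.0)


def _random_models(rng, N):
    """Hand-built random models for oracle comparisons."""
    n_train_w = int(rng.integers(5, 20))
    shape = ShapeModel.fit(
        rng.normal(0, 1, (n_train_w, N_FEATURES)) * [10, 0.01, 100, 30, 40, 40]
        + [10, 0.02, 500, 150, 100, 110],
        rng.normal(0, 1, (int(rng.integers(5, 20)), N_FEATURES))
        * [20, 0.02, 50, 10, 60, 60]
        + [0, 0.05, 150, 40, 100, 105],
    )
    tm = TransitionModel(N)
    for _ in range(int(rng.integers(3, 10))):
        states = []
        s = 0
        for _ in range(int(rng.integers(1, 6))):
            choices = [b for b in range(n_states(N)) if transition_legal(s, b)] if states else list(range(n_states(N)))
            s = int(rng.choice(choices))
            states.append(s)
        tm.observe(states)
    return shape, tm


def _enumerate_labelings(M, N):
    S = n_states(N)

    def rec(prefix):
        if len(prefix) == M:
            yield list(prefix)
            return
        for s in range(S):
            if not prefix or transition_legal(prefix[-1], s):
                yield from rec(prefix + [s])

    yield from rec([])


def _oracle_best(features, shape, tm, change=None, neighbor=None):
    """Brute-force enumeration over all legal label sequences."""
    M = len(features)
    vecs = [f.vector() for f in features]
    nb_w = {}
    if neighbor is not None:
        lab, nf = neighbor
        for l, f in zip(lab.labels, nf):
            if l.startswith("W"):
                nb_w[state_of_label(l)] = f.vector()
    best = None
    for states in _enumerate_labelings(M, tm.N):
        total = tm.log_start[states[0]]
        ok = True
        for a, b in zip(states[:-1], states[1:]):
            total += tm.log_pair[a, b]
        for ci, s in enumerate(states):
            kind = "W" if is_w(s) else "FP"
            total += shape.log_likelihood(vecs[ci], kind)
            if change is not None and neighbor is not None:
                if is_w(s):
                    if s in nb_w:
                        total += change.log_likelihood(vecs[ci] - nb_w[s], "W")
                    else:
                        total += change.missing_log_mass("W")
                else:
                    total += change.missing_log_mass("FP")
        if not np.isfinite(total):
            continue
        if best is None or total > best[0]:
            best = (total, states)
    return best


class TestLabelFrame:
    def test_empty_frame(self):
        tm = TransitionModel(2)
        tm.observe([1, 3])
        lab = label_frame([], ShapeModel.fit(np.empty((0, 6)), np.empty((0, 6))), tm)
        assert lab.labels == []

    def test_structural_uniqueness(self):
        rng = np.random.default_rng(3)
        shape, tm = _random_models(rng, 3)
        feats = [make_features(ap, 150.0) for ap in (10, 40, 70, 100)]
        lab = label_frame(feats, shape, tm)
        assert_valid_labeling(lab.labels, 3)
        w = [l for l in lab.labels if l.startswith("W")]
        assert len(w) == len(set(w))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(1, 4))
        M = int(rng.integers(1, 6))
        shape, tm = _random_models(rng, N)
        feats = [
            make_features(
                float(rng.uniform(0, 200)),
                float(rng.uniform(10, 200)),
                float(rng.uniform(-30, 60)),
                float(rng.uniform(0, 0.05)),
                float(rng.uniform(50, 700)),
            )
            for _ in range(M)
        ]
        feats.sort(key=lambda f: f.endpoint_follicle)
        lab = label_frame(feats, shape, tm)
        oracle = _oracle_best(feats, shape, tm)
        got = sum(
            [tm.log_start[lab.states[0]]]
            + [tm.log_pair[a, b] for a, b in zip(lab.states[:-1], lab.states[1:])]
            + [
                shape.log_likelihood(f.vector(), "W" if is_w(s) else "FP")
                for f, s in zip(feats, lab.states)
            ]
        )
        assert got == pytest.approx(oracle[0], abs=1e-9)

    def test_neighbor_correspondence_prefers_near_curve(self):
        rng = np.random.default_rng(11)
        # shape model that clearly marks both test curves as whiskers
        w_samples = np.array(
            [make_features(rng.uniform(80, 160), 150 + rng.normal(0, 1)).vector() for _ in range(40)]
        )
        fp_samples = np.array(
            [make_features(rng.uniform(0, 200), rng.uniform(20, 40), score=200.0).vector() for _ in range(40)]
        )
        shape = ShapeModel.fit(w_samples, fp_samples)
        tm = TransitionModel(1)
        for _ in range(10):
            tm.observe([1, 2])
        # change model concentrated on tiny frame-to-frame changes
        small = rng.normal(0, 0.5, (40, N_FEATURES))
        change = ChangeModel.fit(small, np.empty((0, N_FEATURES)))
        nb_feat = make_features(100.0, 150.0)
        nb = (FrameLabeling(0, ["W1"], 0.0), [nb_feat])
        near = make_features(101.0, 150.5)
        far = make_features(141.0, 150.5)
        lab = label_frame([near, far], shape, tm, change, neighbor=nb, frame_index=1)
        assert lab.labels[0] == "W1"
        assert lab.labels[1] != "W1"
        oracle = _oracle_best([near, far], shape, tm, change, nb)
        assert lab.states == oracle[1]


def _toy_video(T=10, N=3, seed=0, drop=None):
    """Feature-level synthetic video: N whiskers + variable hairs."""
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(T):
        feats = []
        for i in range(N):
            ap = 30.0 * (i + 1) + 3 * np.sin(0.3 * t + i)
            if drop and drop[0] <= t < drop[1] and i == drop[2]:
                continue
            feats.append(
                make_features(ap, 150.0 + i + rng.normal(0, 0.5), 10 + 5 * np.sin(0.3 * t))
            )
        for j in range(int(rng.integers(1, 4))):
            feats.append(make_features(rng.uniform(0, 120), rng.uniform(20, 40), score=200.0))
        feats.sort(key=lambda f: f.endpoint_follicle)
        frames.append(feats)
    return frames


class TestBuildModels:
    def test_heuristic_states_and_models(self):
        feats = [
            make_features(10, 30.0),
            make_features(40, 150.0),
            make_features(70, 151.0),
            make_features(100, 29.0),
        ]
        states = heuristic_states(feats, 100.0, 2)
        assert [label_name(s) for s in states] == ["F0", "W1", "W2", "F2"]
        with pytest.raises(ValueError):
            heuristic_states(feats, 100.0, 3)

    def test_loglik_ratio_positive_for_whiskers(self):
        frames = _toy_video(T=12, seed=2)
        h = estimate_threshold([[f.length_px for f in fr] for fr in frames])
        model = build_models(frames, h)
        for t in sorted(h.training_frames):
            for f in frames[t]:
                if f.length_px > h.lambda_px:
                    w = model.shape.log_likelihood(f.vector(), "W")
                    fp = model.shape.log_likelihood(f.vector(), "FP")
                    assert w > fp


class TestLinkVideoFeatures:
    """link_video drives label_frame over feature-level synthetic videos."""

    def _link(self, frames, N=None):
        # wrap features in stub curves: link_video computes features from
        # curves, so instead test the lower-level pipeline pieces here
        return frames

    def test_error_in_one_frame_does_not_propagate(self, bank):
        from whiskertrack.config import RunConfig
        from whiskertrack.synthdata import default_scene, render_frame
        from whiskertrack.tracing import trace_frame

        scene = default_scene(seed=31, noise_sigma=1.0)
        face = FaceConfig(face=scene.face_spec())
        curves = []
        for t in range(12):
            frame, _ = render_frame(scene, t)
            curves.append(trace_frame(frame, RunConfig(), bank))
        labelings, model, orders = link_video(curves, face)
        # corrupt frame 6: delete one whisker curve
        corrupted = [list(c) for c in curves]
        lengths = [c.arc_length for c in corrupted[6]]
        corrupted[6].pop(int(np.argmax(lengths)))
        labelings2, model2, orders2 = link_video(corrupted, face, N=4)
        same = sum(
            labelings[t].labels == labelings2[t].labels for t in range(12) if t != 6
        )
        assert same >= 10

    def test_single_frame_video(self, bank):
        from whiskertrack.config import RunConfig
        from whiskertrack.synthdata import default_scene, render_frame
        from whiskertrack.tracing import trace_frame

        scene = default_scene(seed=32, noise_sigma=1.0)
        face = FaceConfig(face=scene.face_spec())
        frame, _ = render_frame(scene, 0)
        curves = [trace_frame(frame, RunConfig(), bank)]
        labelings, model, orders = link_video(curves, face)
        assert len(labelings) == 1
        assert_valid_labeling(labelings[0].labels, model.heuristic.N)

    def test_smooth_video_links_perfectly(self, bank):
        from whiskertrack.config import RunConfig
        from whiskertrack.evaluate import identity_accuracy
        from whiskertrack.synthdata import default_scene, render_frame
        from whiskertrack.tracing import trace_frame

        scene = default_scene(seed=33, noise_sigma=1.0)
        face = FaceConfig(face=scene.face_spec())
        curves, truths = [], []
        for t in range(10):
            frame, tr = render_frame(scene, t)
            curves.append(trace_frame(frame, RunConfig(), bank))
            truths.append(tr)
        labelings, model, orders = link_video(curves, face)
        acc, ncorr, nvis = identity_accuracy(truths, curves, labelings, orders)
        assert model.heuristic.N == 4
        assert ncorr == nvis == 40
        for lab in labelings:
            assert_valid_labeling(lab.labels, 4)

    def test_reversed_frame_order_symmetric(self, bank):
        from whiskertrack.config import RunConfig
        from whiskertrack.synthdata import default_scene, render_frame
        from whiskertrack.tracing import trace_frame

        scene = default_scene(seed=34, noise_sigma=1.0)
        face = FaceConfig(face=scene.face_spec())
        curves = []
        for t in range(8):
            frame, _ = render_frame(scene, t)
            curves.append(trace_frame(frame, RunConfig(), bank))
        fwd, _, _ = link_video(curves, face)
        rev, _, _ = link_video(curves[::-1], face)
        assert [l.labels for l in fwd] == [l.labels for l in rev][::-1]
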