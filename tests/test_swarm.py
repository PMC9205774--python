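"""Swarm protocol: schedules, merging, election, lockstep equivalences."""

import numpy as np
import pytest

from swarmpath.classifier import Hyperparams, init_model, train_full
from swarmpath.swarm import (
    elect_merger,
    make_schedule,
    merge_params,
    run_swarm,
)


@pytest.fixture
def hp():
    return Hyperparams(batch_size=16, learning_rate=0.01)


def _peer_table(rng, n, dim=12):
    return rng.normal(size=(n, dim)), (rng.random(n) > 0.5).astype(int)


class TestSchedule:
    def test_basic_schedule_equal_epochs_equal_weights(self, hp):
        s = make_schedule([500, 1000, 2000], "basic", hp, sync_interval=4)
        assert s.epochs == (5, 5, 5)
        np.testing.assert_allclose(s.merge_weights, [1 / 3] * 3)
        # checkpoints tied to the smallest and second-smallest cohorts
        assert s.checkpoint_rounds["b-chkpt1"] == s.finish_rounds[0]
        assert s.checkpoint_rounds["b-chkpt2"] == s.finish_rounds[1]
        assert s.checkpoint_rounds["b-chkpt1"] < s.checkpoint_rounds["b-chkpt2"]

    def test_weighted_schedule_epochs_and_weights(self, hp):
        # epochs scale inversely with cohort size; weights proportional to it
        s = make_schedule([100, 200, 400], "weighted", hp, sync_interval=4)
        assert s.epochs == (20, 10, 5)
        np.testing.assert_allclose(s.merge_weights, [1 / 7, 2 / 7, 4 / 7])
        # equal total tile throughput: e_i * N_i constant
        throughput = [e * n for e, n in zip(s.epochs, s.tile_counts)]
        assert len(set(throughput)) == 1

    def test_weighted_with_equal_cohorts_degenerates_to_basic(self, hp):
        b = make_schedule([300, 300, 300], "basic", hp, 4)
        w = make_schedule([300, 300, 300], "weighted", hp, 4)
        assert w.epochs == b.epochs
        np.testing.assert_allclose(w.merge_weights, b.merge_weights)
        assert list(w.checkpoint_rounds) == ["w-chkpt"]

    def test_fewer_than_two_peers_rejected(self, hp):
        with pytest.raises(ValueError):
            make_schedule([100], "basic", hp, 4)

    def test_weight_normalization_invariant(self, hp):
        s = make_schedule([123, 456, 789], "weighted", hp, 4)
        assert abs(sum(s.merge_weights) - 1.0) < 1e-12


class TestMerge:
    def test_identical_params_any_weights_identity(self):
        m = init_model(0, feature_dim=6)
        out = merge_params([m, m, m], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(out.flatten(), m.flatten())

    def test_two_point_average(self):
        m = init_model(0, feature_dim=4)
        a = m.unflatten(np.full(m.n_params, 0.0))
        b = m.unflatten(np.full(m.n_params, 4.0))
        a.weights[0][0, 0], a.weights[0][0, 1] = 0.0, 2.0
        b.weights[0][0, 0], b.weights[0][0, 1] = 4.0, 6.0
        out = merge_params([a, b], [0.5, 0.5])
        assert out.weights[0][0, 0] == pytest.approx(2.0)
        assert out.weights[0][0, 1] == pytest.approx(4.0)

    def test_tile_proportional_weights(self):
        # counts 100 and 300 -> weights 0.25/0.75; values 1 and 5 -> 4
        counts = np.array([100, 300])
        w = counts / counts.sum()
        np.testing.assert_allclose(w, [0.25, 0.75])
        m = init_model(0, feature_dim=4)
        a = m.unflatten(np.full(m.n_params, 1.0))
        b = m.unflatten(np.full(m.n_params, 5.0))
        out = merge_params([a, b], w)
        np.testing.assert_allclose(out.flatten(), 4.0)

    def test_merge_conserves_linear_functionals(self, rng):
        # f(merge(thetas, w)) = sum w_i f(theta_i) for linear f
        m = init_model(0, feature_dim=8)
        ps = [m.unflatten(rng.normal(size=m.n_params)) for _ in range(3)]
        w = np.array([0.2, 0.5, 0.3])
        f = rng.normal(size=m.n_params)
        lhs = merge_params(ps, w).flatten() @ f
        rhs = sum(wi * (p.flatten() @ f) for wi, p in zip(w, ps))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_invalid_weights_rejected(self):
        m = init_model(0, feature_dim=4)
        with pytest.raises(ValueError):
            merge_params([m, m], [0.7, 0.7])
        with pytest.raises(ValueError):
            merge_params([m, m], [1.5, -0.5])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_params([init_model(0, 4), init_model(0, 5)], [0.5, 0.5])


class TestElection:
    def test_round_robin_over_active_peers(self):
        peers = ["A", "B", "C"]
        assert [elect_merger(r, peers) for r in range(4)] == ["A", "B", "C", "A"]

    def test_single_active_peer(self):
        assert elect_merger(17, ["Z"]) == "Z"


class TestRunSwarm:
    def test_identical_data_degenerates_to_local_run(self, hp, rng):
        # every merge of identical peers is an identity, so checkpoints
        # coincide with one single-trainer run
        X, y = _peer_table(rng, 64)
        local = train_full(X, y, hp.epochs_base, hp, seed=3)
        for S in (1, 4, 16):
            sched = make_schedule([64] * 3, "basic", hp, S)
            ckpts, events = run_swarm([(X, y)] * 3, sched, hp, seed=3)
            for name in ("b-chkpt1", "b-chkpt2"):
                np.testing.assert_allclose(
                    ckpts[name].params.flatten(), local.flatten(), atol=1e-12
                )
            wsched = make_schedule([64] * 3, "weighted", hp, S)
            wck, _ = run_swarm([(X, y)] * 3, wsched, hp, seed=3)
            np.testing.assert_allclose(
                wck["w-chkpt"].params.flatten(), local.flatten(), atol=1e-12
            )

    def test_sync_interval_one_equals_centralized_sgd(self, hp, rng):
        # with S=1, equal batch sizes and batch-proportional weights, each
        # swarm round equals one centralized SGD step on the concatenated
        # batch (independently re-simulated here)
        from swarmpath.classifier import (
            data_fingerprint,
            epoch_order,
            steps_per_epoch,
            train_steps,
        )

        datas = [_peer_table(rng, 48) for _ in range(3)]
        sched = make_schedule([48] * 3, "basic", hp, sync_interval=1)
        ckpts, events = run_swarm(datas, sched, hp, seed=7)

        spe = steps_per_epoch(48, hp.batch_size)
        fps = [data_fingerprint(X, y) for X, y in datas]

        def batch(p, it):
            X, y = datas[p]
            ep, j = divmod(it, spe)
            order = epoch_order(7, ep, fps[p], 48)
            sel = order[j * hp.batch_size : (j + 1) * hp.batch_size]
            return X[sel], y[sel]

        central = init_model(7, feature_dim=datas[0][0].shape[1])
        n_rounds = len(events)
        assert n_rounds == 5 * spe
        for r in range(n_rounds):
            Xc = np.concatenate([batch(p, r)[0] for p in range(3)])
            yc = np.concatenate([batch(p, r)[1] for p in range(3)])
            central = train_steps(central, iter([(Xc, yc)]), 1, hp)
        final = ckpts["b-chkpt2"].params.flatten()
        ref = central.flatten()
        assert np.abs(final - ref).max() / np.abs(ref).max() < 1e-5

    def test_basic_checkpoint_ordering_and_dropout(self, hp, rng):
        # small < mid < large: chk1 round < chk2 round, one deactivation between
        datas = [_peer_table(rng, n) for n in (32, 64, 128)]
        sched = make_schedule([32, 64, 128], "basic", hp, 4)
        ckpts, events = run_swarm(datas, sched, hp, seed=0)
        r1 = ckpts["b-chkpt1"].round_index
        r2 = ckpts["b-chkpt2"].round_index
        assert r1 < r2
        # between the checkpoints exactly the smallest peer is absent
        mid_events = [e for e in events if r1 < e.round_index <= r2]
        assert all(set(e.participants) == {"peer1", "peer2"} for e in mid_events)
        # run ends at b-chkpt2 (fewer than two active peers remain)
        assert events[-1].round_index == r2

    def test_checkpoints_invariant_to_peer_ordering(self, hp, rng):
        datas = [_peer_table(rng, n) for n in (32, 48, 80)]
        sched = make_schedule([32, 48, 80], "weighted", hp, 4)
        ck1, _ = run_swarm(datas, sched, hp, seed=2)
        perm = [2, 0, 1]
        sched_p = make_schedule([80, 32, 48], "weighted", hp, 4,
                                peer_ids=["peer2", "peer0", "peer1"])
        ck2, _ = run_swarm([datas[i] for i in perm], sched_p, hp, seed=2)
        np.testing.assert_allclose(
            ck1["w-chkpt"].params.flatten(), ck2["w-chkpt"].params.flatten(), atol=1e-12
        )

    def test_event_digests_replay_exactly(self, hp, rng):
        datas = [_peer_table(rng, n) for n in (32, 64)]
        sched = make_schedule([32, 64], "basic", hp, 4)
        _, ev1 = run_swarm(datas, sched, hp, seed=9)
        _, ev2 = run_swarm(datas, sched, hp, seed=9)
        assert [e.digest for e in ev1] == [e.digest for e in ev2]
        assert [e.merger for e in ev1] == [e.merger for e in ev2]

    def test_schedule_data_mismatch_rejected(self, hp, rng):
        datas = [_peer_table(rng, 32), _peer_table(rng, 64)]
        sched = make_schedule([32, 65], "basic", hp, 4)
        with pytest.raises(ValueError):
            run_swarm(datas, sched, hp, seed=0)

    def test_weighted_run_emits_single_terminal_checkpoint(self, hp, rng):
        datas = [_peer_table(rng, n) for n in (24, 40, 56)]
        sched = make_schedule([24, 40, 56], "weighted", hp, 2)
        ckpts, events = run_swarm(datas, sched, hp, seed=1)
        assert set(ckpts.checkpoints) == {"w-chkpt"}
        assert ckpts["w-chkpt"].round_index == events[-1].round_index
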