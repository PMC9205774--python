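"""Decentralized training protocol (swarm learning) simulator.

Peers hold physically separate tile tables and train the shared classifier
in lockstep rounds: each active peer runs ``S`` local optimizer iterations
(the sync interval), then all active peers' parameters are merged by
weighted averaging and broadcast back. Merge leadership rotates round-robin
over the active peers, standing in for the blockchain-based merger election
of a production deployment; because averaging is leader-independent, the
elected merger affects only the audit log, never the result.

Two schedules are supported:

* **basic** — every peer trains the same number of epochs with equal merge
  weights. Peers with less data finish earlier; a checkpoint is emitted at
  the merge where the smallest cohort finishes its final epoch (b-chkpt1)
  and another where the second-smallest finishes (b-chkpt2), at which point
  fewer than the minimum number of active peers remain and the run ends.
* **weighted** — smaller cohorts train proportionally more epochs so all
  peers finish together, and merge weights are strictly proportional to
  each peer's (post-balancing) tile count; a single terminal checkpoint
  (w-chkpt) is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import (
    Hyperparams,
    ModelParams,
    _AdamState,
    data_fingerprint,
    epoch_order,
    init_model,
    steps_per_epoch,
    train_steps,
)

__all__ = [
    "PeerState",
    "SwarmSchedule",
    "SyncEvent",
    "CheckpointSet",
    "make_schedule",
    "merge_params",
    "elect_merger",
    "run_swarm",
]


@dataclass
class PeerState:
    """Mutable per-peer training state during a swarm run."""

    peer_id: str
    n_tiles: int  # post-balancing training tile count N_i
    model: ModelParams
    iteration: int = 0
    epochs_done: int = 0
    active: bool = True


@dataclass(frozen=True)
class SwarmSchedule:
    """Static description of one swarm run.

    ``epochs`` and ``merge_weights`` are per-peer (aligned with
    ``peer_ids``); ``finish_rounds`` maps each peer to the lockstep round at
    which it completes its final epoch.
    """

    mode: str  # "basic" | "weighted"
    peer_ids: tuple[str, ...]
    tile_counts: tuple[int, ...]
    sync_interval: int
    base_epochs: int
    epochs: tuple[int, ...]
    merge_weights: tuple[float, ...]
    finish_rounds: tuple[int, ...]
    checkpoint_rounds: dict[str, int]  # {"b-chkpt1": r, "b-chkpt2": r} or {"w-chkpt": r}
    min_active_peers: int = 2

    def __post_init__(self) -> None:
        if abs(sum(self.merge_weights) - 1.0) > 1e-12:
            raise ValueError("merge weights must sum to 1")
        if self.sync_interval < 1:
            raise ValueError("sync interval must be >= 1")


@dataclass(frozen=True)
class SyncEvent:
    """Audit record of one merge round."""

    round_index: int
    participants: tuple[str, ...]
    merger: str
    weights: tuple[float, ...]
    digest: str


@dataclass(frozen=True)
class Checkpoint:
    name: str
    params: ModelParams
    round_index: int
    digest: str


@dataclass
class CheckpointSet:
    """The swarm run's output models with provenance.

    Basic mode yields exactly two checkpoints (b-chkpt1, b-chkpt2);
    weighted mode yields exactly one (w-chkpt).
    """

    mode: str
    checkpoints: dict[str, Checkpoint] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Checkpoint:
        return self.checkpoints[name]

    def validate(self) -> None:
        want = {"basic": {"b-chkpt1", "b-chkpt2"}, "weighted": {"w-chkpt"}}[self.mode]
        if set(self.checkpoints) != want:
            raise ValueError(f"mode {self.mode}: expected checkpoints {want}, got {set(self.checkpoints)}")


def make_schedule(
    tile_counts: Sequence[int],
    mode: str,
    hp: Hyperparams,
    sync_interval: int = 4,
    peer_ids: Sequence[str] | None = None,
    min_active_peers: int = 2,
) -> SwarmSchedule:
    """Derive per-peer epochs, merge weights and checkpoint rounds.

    basic:    e_i = E, w_i = 1/P; checkpoints tied to the rounds where the
              smallest and second-smallest cohorts finish epoch E.
    weighted: w_i = N_i / sum(N); e_i = round(E * max(N) / N_i) (>= 1), so
              every peer's total tile throughput is approximately E*max(N)
              and all peers stop at (nearly) the same round.
    """
    counts = [int(n) for n in tile_counts]
    if len(counts) < 2:
        raise ValueError("at least two partners are required")
    if any(n < 1 for n in counts):
        raise ValueError("every peer needs at least one training tile")
    if peer_ids is None:
        peer_ids = [f"peer{i}" for i in range(len(counts))]
    if len(set(peer_ids)) != len(counts):
        raise ValueError("peer ids must be distinct and match tile_counts")
    P = len(counts)
    E = hp.epochs_base
    if mode == "basic":
        epochs = [E] * P
        weights = [1.0 / P] * P
    elif mode == "weighted":
        total = sum(counts)
        weights = [n / total for n in counts]
        epochs = [max(1, round(E * max(counts) / n)) for n in counts]
    else:
        raise ValueError(f"unknown schedule mode {mode!r}")

    total_iters = [e * steps_per_epoch(n, hp.batch_size) for e, n in zip(epochs, counts)]
    finish_rounds = [-(-t // sync_interval) for t in total_iters]

    if mode == "basic":
        # order of finishing: fewer total iterations first; ties by tile count then id
        order = sorted(range(P), key=lambda i: (finish_rounds[i], counts[i], str(peer_ids[i])))
        checkpoint_rounds = {
            "b-chkpt1": finish_rounds[order[0]],
            "b-chkpt2": finish_rounds[order[1]],
        }
    else:
        checkpoint_rounds = {"w-chkpt": max(finish_rounds)}

    return SwarmSchedule(
        mode=mode,
        peer_ids=tuple(str(p) for p in peer_ids),
        tile_counts=tuple(counts),
        sync_interval=int(sync_interval),
        base_epochs=E,
        epochs=tuple(epochs),
        merge_weights=tuple(weights),
        finish_rounds=tuple(finish_rounds),
        checkpoint_rounds=checkpoint_rounds,
        min_active_peers=min_active_peers,
    )


def merge_params(params_list: Sequence[ModelParams], weights: Sequence[float]) -> ModelParams:
    """Element-wise weighted average of every tensor across peers."""
    if len(params_list) != len(weights) or len(params_list) == 0:
        raise ValueError("need one weight per parameter set")
    w = np.asarray(weights, dtype=np.float64)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    ref = params_list[0]
    for p in params_list[1:]:
        if [a.shape for a in p.weights] != [a.shape for a in ref.weights]:
            raise ValueError("parameter shape mismatch between peers")
    out = ref.copy()
    for i in range(len(out.weights)):
        out.weights[i] = sum(wi * p.weights[i] for wi, p in zip(w, params_list))
        out.biases[i] = sum(wi * p.biases[i] for wi, p in zip(w, params_list))
    return out


def elect_merger(round_index: int, active_peers: Sequence[str]) -> str:
    """Deterministic round-robin leader election over the active peers."""
    if len(active_peers) == 0:
        raise ValueError("no active peers")
    ordered = sorted(str(p) for p in active_peers)
    return ordered[round_index % len(ordered)]


class _Peer:
    """Internal trainer: one peer's data, shuffle stream and step counter."""

    def __init__(self, peer_id: str, X: np.ndarray, y: np.ndarray, epochs: int, hp: Hyperparams, seed: int):
        self.peer_id = peer_id
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.int64)
        self.hp = hp
        self.seed = seed
        self.fp = data_fingerprint(self.X, self.y)
        self.spe = steps_per_epoch(len(self.y), hp.batch_size)
        self.total_iters = epochs * self.spe
        self.iteration = 0
        self.adam = None

    @property
    def remaining(self) -> int:
        return self.total_iters - self.iteration

    def _batches_from(self, iteration: int):
        while True:
            ep, j0 = divmod(iteration, self.spe)
            order = epoch_order(self.seed, ep, self.fp, len(self.y))
            for j in range(j0, self.spe):
                sel = order[j * self.hp.batch_size : (j + 1) * self.hp.batch_size]
                yield self.X[sel], self.y[sel]
            iteration = (ep + 1) * self.spe

    def step(self, model: ModelParams, k: int) -> ModelParams:
        if self.hp.optimizer == "adaptive" and self.adam is None:
            self.adam = _AdamState(model)
        out = train_steps(model, self._batches_from(self.iteration), k, self.hp, adam_state=self.adam)
        self.iteration += k
        return out


def run_swarm(
    peer_data: Sequence[tuple[np.ndarray, np.ndarray]],
    schedule: SwarmSchedule,
    hp: Hyperparams,
    seed: int,
) -> tuple[CheckpointSet, list[SyncEvent]]:
    """Execute a swarm run in strict lockstep rounds.

    Every peer starts from the shared ``init_model(seed)``. Each round, every
    active peer with remaining work performs up to ``sync_interval`` local
    optimizer steps on its own shuffled tile stream; then the parameters of
    the peers that trained this round are averaged with the schedule weights
    (renormalized over the participants) and broadcast to all peers still in
    the run. Checkpoints and peer deactivation follow the schedule mode.
    """
    if len(peer_data) != len(schedule.peer_ids):
        raise ValueError("peer_data length does not match schedule")
    for (X, y), n in zip(peer_data, schedule.tile_counts):
        if len(y) != n or len(X) != n:
            raise ValueError("schedule tile counts do not match the provided data")

    feature_dim = np.asarray(peer_data[0][0]).shape[1]
    global_model = init_model(seed, feature_dim=feature_dim)
    peers = [
        _Peer(pid, X, y, e, hp, seed)
        for pid, (X, y), e in zip(schedule.peer_ids, peer_data, schedule.epochs)
    ]
    active = {p.peer_id: True for p in peers}
    events: list[SyncEvent] = []
    ckpts = CheckpointSet(mode=schedule.mode)
    S = schedule.sync_interval
    wmap = dict(zip(schedule.peer_ids, schedule.merge_weights))
    finish_order = sorted(
        range(len(peers)),
        key=lambda i: (schedule.finish_rounds[i], schedule.tile_counts[i], schedule.peer_ids[i]),
    )
    finishers_seen = 0
    round_index = 0

    while True:
        trained: list[_Peer] = []
        models: list[ModelParams] = []
        for p in peers:
            if not active[p.peer_id] or p.remaining <= 0:
                continue
            k = min(S, p.remaining)
            models.append(p.step(global_model, k))
            trained.append(p)
        if not trained:
            break
        w = np.array([wmap[p.peer_id] for p in trained])
        w = w / w.sum()
        merged = merge_params(models, w)
        merger = elect_merger(round_index, [p.peer_id for p in trained])
        events.append(
            SyncEvent(
                round_index=round_index,
                participants=tuple(p.peer_id for p in trained),
                merger=merger,
                weights=tuple(float(x) for x in w),
                digest=merged.digest(),
            )
        )
        global_model = merged

        finished_now = [p for p in trained if p.remaining <= 0]
        # deterministic ordering of simultaneous finishers
        finished_now.sort(key=lambda p: (p.total_iters, len(p.y), p.peer_id))
        if schedule.mode == "basic":
            for p in finished_now:
                finishers_seen += 1
                if finishers_seen == 1:
                    ckpts.checkpoints["b-chkpt1"] = Checkpoint(
                        "b-chkpt1", merged.copy(), round_index, merged.digest()
                    )
                elif finishers_seen == 2:
                    ckpts.checkpoints["b-chkpt2"] = Checkpoint(
                        "b-chkpt2", merged.copy(), round_index, merged.digest()
                    )
                active[p.peer_id] = False
            if sum(active.values()) < schedule.min_active_peers:
                if "b-chkpt2" not in ckpts.checkpoints:
                    ckpts.checkpoints["b-chkpt2"] = Checkpoint(
                        "b-chkpt2", merged.copy(), round_index, merged.digest()
                    )
                break
        else:  # weighted: idle finished peers keep receiving the merged state
            if all(p.remaining <= 0 for p in peers):
                ckpts.checkpoints["w-chkpt"] = Checkpoint(
                    "w-chkpt", merged.copy(), round_index, merged.digest()
                )
                break
        round_index += 1

    ckpts.validate()
    return ckpts, events
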