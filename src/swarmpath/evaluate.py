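"""Patient-level evaluation harness: AUROC, replicates, comparisons, grids.

The primary metric is the patient-level AUROC (Mann-Whitney formulation:
the probability that a random positive patient outscores a random negative
one, ties half-credited). Every experiment is repeated with several random
seeds (default 5); a model type's replicate AUROCs are summarized as
mean +/- sample s.d. and compared across model types with a two-sided
unpaired t-test without multiple-testing correction.

Model types follow the multi-site study design: one *local* model per
training cohort, a *merged* model trained on the concatenated cohorts by a
single trainer, and the swarm checkpoints *b-chkpt1*, *b-chkpt2* (basic
schedule) and *w-chkpt* (weighted schedule). Data-efficiency experiments
rerun the grid on stratified subsets of each cohort; the sync-interval
sweep reruns a simple swarm model across a range of merge frequencies.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .classifier import (
    Hyperparams,
    ModelParams,
    PatientBag,
    bags_to_tile_table,
    balance_by_undersampling,
    predict_patients,
    train_full,
)
from .swarm import make_schedule, run_swarm
from .synthetic import SyntheticConfig, generate_feature_cohorts, generate_test_pool

__all__ = [
    "ExperimentResult",
    "ExperimentSpec",
    "patient_auroc",
    "stratified_subsample",
    "train_model_suite",
    "replicate_experiment",
    "compare_auroc",
    "sync_sweep",
    "run_experiment_grid",
    "MODEL_TYPES",
]

MODEL_TYPES = ("local", "merged", "b-chkpt1", "b-chkpt2", "w-chkpt")


def patient_auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Patient-level AUROC (ties half-credited)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUROC")
    return float(roc_auc_score(labels, scores))


def stratified_subsample(
    patients: Sequence[PatientBag], n: int, seed: int
) -> list[PatientBag]:
    """Random subset of ``n`` patients preserving class proportions.

    Class quotas use largest-remainder rounding of ``n * class fraction``
    so they always sum to ``n`` exactly. Deterministic under ``seed``.
    """
    total = len(patients)
    if n > total:
        raise ValueError(f"cannot sample {n} from {total} patients")
    labels = np.array([p.label for p in patients])
    classes = np.unique(labels)
    if n < len(classes):
        raise ValueError("n must be at least the number of classes")
    if n == total:
        return list(patients)
    quotas = {}
    fracs = {}
    for c in classes:
        exact = n * (labels == c).sum() / total
        quotas[c] = int(np.floor(exact))
        fracs[c] = exact - np.floor(exact)
    short = n - sum(quotas.values())
    # largest remainder; ties broken toward the larger class, then label order
    order = sorted(classes, key=lambda c: (-fracs[c], -(labels == c).sum(), c))
    for c in order[:short]:
        quotas[c] += 1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57A7]))
    keep: list[int] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        keep.extend(np.sort(rng.choice(idx, size=quotas[c], replace=False)))
    return [patients[i] for i in sorted(keep)]


@dataclass(frozen=True)
class ExperimentResult:
    """Replicate AUROCs of one model type on one test cohort."""

    model_type: str
    test_cohort: str
    aurocs: tuple[float, ...]
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= a <= 1.0 for a in self.aurocs):
            raise ValueError("AUROC values must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.aurocs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aurocs, ddof=1)) if len(self.aurocs) > 1 else 0.0


def compare_auroc(a: ExperimentResult, b: ExperimentResult, welch: bool = False) -> float:
    """Two-sided unpaired t-test p-value between two replicate AUROC lists."""
    xa, xb = np.asarray(a.aurocs), np.asarray(b.aurocs)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least two replicates per model for a t-test")
    if xa.std(ddof=1) < 1e-12 and xb.std(ddof=1) < 1e-12:
        warnings.warn("zero variance in both replicate lists; p-value by convention")
        return 1.0 if np.isclose(xa.mean(), xb.mean()) else 0.0
    res = stats.ttest_ind(xa, xb, equal_var=not welch)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# training suites


def _derive(seed: int, *tags: int) -> int:
    h = hashlib.sha256(np.array([seed, *tags], dtype=np.int64).tobytes()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def train_model_suite(
    train_bags: dict[str, list[PatientBag]],
    hp: Hyperparams,
    seed: int,
    model_types: Sequence[str] = MODEL_TYPES,
    sync_interval: int = 4,
) -> dict[str, ModelParams]:
    """Train the requested local / merged / swarm models on one seed.

    Balancing is applied per cohort for local and swarm training (each peer
    balances its own tiles) and on the pooled table for the merged model.
    Returns ``{model_type: params}`` with local models keyed
    ``local:<cohort_id>``.
    """
    cohort_ids = sorted(train_bags)
    tables = {}
    for i, cid in enumerate(cohort_ids):
        X, y = bags_to_tile_table(train_bags[cid])
        tables[cid] = balance_by_undersampling(X, y, _derive(seed, 1, i))
    models: dict[str, ModelParams] = {}
    if "local" in model_types:
        for cid in cohort_ids:
            Xb, yb = tables[cid]
            models[f"local:{cid}"] = train_full(Xb, yb, hp.epochs_base, hp, seed)
    if "merged" in model_types:
        X, y = bags_to_tile_table([b for cid in cohort_ids for b in train_bags[cid]])
        Xm, ym = balance_by_undersampling(X, y, _derive(seed, 2))
        models["merged"] = train_full(Xm, ym, hp.epochs_base, hp, seed)
    peer_data = [tables[cid] for cid in cohort_ids]
    counts = [len(t[1]) for t in peer_data]
    if "b-chkpt1" in model_types or "b-chkpt2" in model_types:
        sched = make_schedule(counts, "basic", hp, sync_interval, peer_ids=cohort_ids)
        ckpts, _ = run_swarm(peer_data, sched, hp, seed)
        for name in ("b-chkpt1", "b-chkpt2"):
            if name in model_types:
                models[name] = ckpts[name].params
    if "w-chkpt" in model_types:
        sched = make_schedule(counts, "weighted", hp, sync_interval, peer_ids=cohort_ids)
        ckpts, _ = run_swarm(peer_data, sched, hp, seed)
        models["w-chkpt"] = ckpts["w-chkpt"].params
    return models


def evaluate_model(model: ModelParams, test_bags: Sequence[PatientBag], rule: str = "mean") -> float:
    labels, scores = predict_patients(model, test_bags, rule=rule)
    return patient_auroc(labels, scores)


@dataclass(frozen=True)
class ExperimentSpec:
    """Description of one replicated experiment on synthetic cohorts."""

    config: SyntheticConfig
    subset_size: int | None = None  # patients per cohort, None = all
    model_types: tuple[str, ...] = MODEL_TYPES
    sync_interval: int = 4
    hp: Hyperparams = field(default_factory=Hyperparams)
    test_patients_per_cohort: int = 100
    aggregation: str = "mean"

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "config": self.config.__dict__,
                "subset": self.subset_size,
                "models": list(self.model_types),
                "S": self.sync_interval,
                "hp": self.hp.__dict__,
                "test_n": self.test_patients_per_cohort,
                "agg": self.aggregation,
            },
            default=str,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_one_seed(spec: ExperimentSpec, seed: int, test_bags: list[PatientBag]) -> dict[str, float]:
    train_bags, _ = generate_feature_cohorts(spec.config, split="train")
    if spec.subset_size is not None:
        train_bags = {
            cid: stratified_subsample(bags, spec.subset_size, _derive(seed, 3, i))
            for i, (cid, bags) in enumerate(sorted(train_bags.items()))
        }
    _check_no_overlap(train_bags, test_bags)
    models = train_model_suite(
        train_bags, spec.hp, seed, model_types=spec.model_types, sync_interval=spec.sync_interval
    )
    return {
        name: evaluate_model(m, test_bags, rule=spec.aggregation) for name, m in models.items()
    }


def _check_no_overlap(train_bags: dict[str, list[PatientBag]], test_bags: Sequence[PatientBag]) -> None:
    train_ids = {b.patient_id for bags in train_bags.values() for b in bags}
    test_ids = {b.patient_id for b in test_bags}
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"train/test patient overlap: {sorted(overlap)[:5]} ...")


def replicate_experiment(
    spec: ExperimentSpec,
    seeds: Sequence[int],
    cache_dir: str | Path | None = None,
) -> dict[str, ExperimentResult]:
    """Run one full train+test per seed and collect per-model AUROC replicates.

    The seed controls model init, tile shuffling, balancing and subsampling.
    Results are cached by the content hash of (spec, seed) when ``cache_dir``
    is given, making large grids resumable.
    """
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds in replicate list")
    test_bags = generate_test_pool(spec.config, spec.test_patients_per_cohort)
    per_seed: list[dict[str, float]] = []
    for seed in seeds:
        cached = None
        key = f"{spec.content_hash()}_{seed}.json"
        if cache_dir is not None and (Path(cache_dir) / key).exists():
            cached = json.loads((Path(cache_dir) / key).read_text())
        if cached is None:
            cached = _run_one_seed(spec, seed, test_bags)
            if cache_dir is not None:
                Path(cache_dir).mkdir(parents=True, exist_ok=True)
                (Path(cache_dir) / key).write_text(json.dumps(cached))
        per_seed.append(cached)
    out = {}
    for name in per_seed[0]:
        out[name] = ExperimentResult(
            model_type=name,
            test_cohort="pool",
            aurocs=tuple(d[name] for d in per_seed),
            seeds=tuple(seeds),
        )
    return out


def sync_sweep(
    config: SyntheticConfig,
    intervals: Sequence[int],
    n_patients: int,
    seeds: Sequence[int],
    hp: Hyperparams | None = None,
    test_patients_per_cohort: int = 100,
) -> pd.DataFrame:
    """AUROC of a simple (basic-schedule) swarm model across sync intervals.

    One swarm run per (interval, seed) on a stratified subset of
    ``n_patients`` per cohort; the final basic checkpoint is evaluated on
    the pooled test set. Returns a tidy table (interval, seed, auroc).
    """
    if any(i < 1 for i in intervals):
        raise ValueError("sync intervals must be >= 1")
    hp = hp or Hyperparams()
    rows = []
    for interval in intervals:
        spec = ExperimentSpec(
            config=config,
            subset_size=n_patients,
            model_types=("b-chkpt2",),
            sync_interval=int(interval),
            hp=hp,
            test_patients_per_cohort=test_patients_per_cohort,
        )
        res = replicate_experiment(spec, seeds)["b-chkpt2"]
        for seed, auroc in zip(res.seeds, res.aurocs):
            rows.append({"interval": int(interval), "seed": seed, "auroc": auroc})
    return pd.DataFrame(rows)


def run_experiment_grid(
    config: SyntheticConfig,
    subset_sizes: Sequence[int | None],
    seeds: Sequence[int],
    model_types: Sequence[str] = MODEL_TYPES,
    hp: Hyperparams | None = None,
    sync_interval: int = 4,
    test_patients_per_cohort: int = 100,
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Local / merged / swarm comparison across subset sizes and seeds.

    Returns a tidy table with columns (test_cohort, model_type, subset_size,
    seed, auroc); ``subset_size`` is the per-cohort patient count (0 = all).
    """
    hp = hp or Hyperparams()
    rows = []
    for size in subset_sizes:
        spec = ExperimentSpec(
            config=config,
            subset_size=size,
            model_types=tuple(model_types),
            sync_interval=sync_interval,
            hp=hp,
            test_patients_per_cohort=test_patients_per_cohort,
        )
        results = replicate_experiment(spec, seeds, cache_dir=cache_dir)
        for name, res in results.items():
            for seed, auroc in zip(res.seeds, res.aurocs):
                rows.append(
                    {
                        "test_cohort": res.test_cohort,
                        "model_type": name,
                        "subset_size": 0 if size is None else int(size),
                        "seed": seed,
                        "auroc": auroc,
                    }
                )
    return pd.DataFrame(rows)


def ttest_matrix(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    """Pairwise two-sided t-test p-values between all model types."""
    names = sorted(results)
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                p = compare_auroc(results[a], results[b])
                mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def plot_results_box(df: pd.DataFrame, out_path: str | Path, title: str = "") -> None:
    """Box plot of replicate AUROCs per model type (one panel per subset size)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = sorted(df["subset_size"].unique())
    fig, axes = plt.subplots(1, len(sizes), figsize=(4 * len(sizes), 4), squeeze=False)
    for ax, size in zip(axes[0], sizes):
        sub = df[df["subset_size"] == size]
        order = sorted(sub["model_type"].unique())
        data = [sub[sub["model_type"] == m]["auroc"].values for m in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel("patient-level AUROC")
        ax.set_title(f"{size or 'all'} patients/cohort")
        ax.tick_params(axis="x", rotation=45)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
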