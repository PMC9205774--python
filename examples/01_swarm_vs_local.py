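"""Swarm vs local vs merged training on synthetic multi-site cohorts.

Generates three feature-mode cohorts of unequal size with a cohort-specific
site effect, trains every model type with two replicate seeds, and prints
patient-level AUROCs on a held-out multi-site test pool. Expect the local
models (trained on one site each) to trail the weighted swarm checkpoint,
which in turn tracks the centrally merged model.
"""

from swarmpath.evaluate import ExperimentSpec, replicate_experiment
from swarmpath.synthetic import SyntheticConfig

# smaller cohorts than the package defaults so this demo runs in ~30 s
config = SyntheticConfig(patients_per_cohort=(50, 150, 75), seed=0)
spec = ExperimentSpec(config=config, test_patients_per_cohort=60)

results = replicate_experiment(spec, seeds=[0, 1])
print(f"{'model':<16}{'mean AUROC':>12}{'sd':>9}")
for name, res in sorted(results.items()):
    print(f"{name:<16}{res.mean:>12.4f}{res.sd:>9.4f}")

w, m = results["w-chkpt"].mean, results["merged"].mean
best_local = max(v.mean for k, v in results.items() if k.startswith("local:"))
print(
    f"\nweighted swarm {w:.4f} vs best local {best_local:.4f} "
    f"(gap {w - best_local:+.4f}); vs merged {m:.4f} (gap {w - m:+.4f})"
)
print("A positive gap over local models with a near-zero gap to the merged")
print("model is the collaborative-training benefit without data pooling.")
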