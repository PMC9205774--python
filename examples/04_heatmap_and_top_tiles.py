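"""Model examination: slide prediction heatmap and top-tile export.

Trains a merged model on small synthetic cohorts, scores one test
patient's tiles, renders the whole-slide heatmap (linear interpolation of
tile-level probabilities over the slide grid, nearest-value fill outside
the scored hull) and lists the highest-scoring tiles of the
highest-scoring patients — the tiles a pathologist would review.
"""

import numpy as np
import pandas as pd

from swarmpath.classifier import Hyperparams, predict_tiles
from swarmpath.evaluate import train_model_suite
from swarmpath.explain import slide_heatmap, top_tiles
from swarmpath.synthetic import SyntheticConfig, generate_feature_cohorts, generate_test_pool

config = SyntheticConfig(patients_per_cohort=(30, 60, 40), seed=2)
train_bags, _ = generate_feature_cohorts(config)
models = train_model_suite(train_bags, Hyperparams(), seed=0, model_types=("merged",))
model = models["merged"]

test_bags = generate_test_pool(config, patients_per_cohort=20)

# pretend the first positive patient's bag came from an 8x4 tile grid
patient = next(b for b in test_bags if b.label == 1)
scores = predict_tiles(model, patient.features)
tile = 32
positions = [((i % 8) * tile, (i // 8) * tile) for i in range(len(scores))]
hm = slide_heatmap(positions, scores, slide_shape=(4 * tile, 8 * tile),
                   tile_size=tile, slide_id=patient.patient_id)
print(f"heatmap for {patient.patient_id} (true label {patient.label}):")
print(np.array2string(hm.raster, precision=2, suppress_small=True))
print(f"patient-level score (mean of tiles): {scores.mean():.3f}")

# top 3 tiles from the top 2 patients across the pool
rows, patient_scores = [], {}
for bag in test_bags:
    s = predict_tiles(model, bag.features)
    patient_scores[bag.patient_id] = float(s.mean())
    for i, sc in enumerate(s):
        rows.append({"patient_id": bag.patient_id, "slide_id": f"{bag.patient_id}_s0",
                     "x": (i % 8) * tile, "y": (i // 8) * tile, "score": float(sc)})
table = top_tiles(patient_scores, pd.DataFrame(rows), M=2, N=3)
print("\ntop 3 tiles of the top 2 patients (for qualitative review):")
print(table.to_string(index=False))
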