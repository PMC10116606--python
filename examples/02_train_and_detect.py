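"""Train a small detector and localize selected variants on held-out images.

Uses a reduced population size (N = 1,000) and a small image budget so the
whole script runs in about a minute; the study-scale settings live in
``paintscan.pipeline.PROFILES``.

Run:  python examples/02_train_and_detect.py
"""

import numpy as np

from paintscan import pipeline, scenarios
from paintscan.detector import DetectorConfig, fit_detector, predict

model = scenarios.baseline_model(N0=1_000)

print("simulating 60 training images (20% neutral) ...")
train = pipeline.generate_examples(model, 60, fraction_neutral=0.2, seed=1)
print("simulating 15 held-out images ...")
held_out = pipeline.generate_examples(model, 15, fraction_neutral=0.2, seed=1,
                                      index_offset=60)

config = DetectorConfig(epochs=5, seed=1)
detector = fit_detector([(ex.image.pixels, ex.variant_pixel) for ex in train], config)
print(f"training loss: {detector.training_log[0]:.3f} -> {detector.training_log[-1]:.3f}")

hits = misses = neutral_boxes = 0
for ex in held_out:
    boxes = predict(detector, ex.image.pixels, threshold=0.5)
    if ex.variant_pixel is None:
        neutral_boxes += len(boxes)
        continue
    found = any(b.contains_x(ex.variant_pixel) for b in boxes)
    hits += found
    misses += not found
    tag = "hit " if found else "MISS"
    shown = f"[{boxes[0].x_min}, {boxes[0].x_max}) score {boxes[0].score:.2f}" if boxes else "none"
    print(f"  s={ex.s:.2f} variant at pixel {ex.variant_pixel:3d}: {tag} {shown}")

print(f"\nlocalized {hits}/{hits + misses} selected variants; "
      f"{neutral_boxes} boxes on neutral images")
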