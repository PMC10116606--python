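"""Evaluate a detector with pooled pixel metrics and a threshold sweep.

Shows the reporting conventions: every x-pixel of every image is a binary
test (an 11-pixel target on a 200-pixel image = 11 positives, 189
negatives, pooled across images), plus the bbox detection rate and the
precision-recall curve swept over 10,000 score thresholds.

Run:  python examples/03_evaluate_and_thresholds.py
"""

from paintscan import pipeline, scenarios
from paintscan.detector import DetectorConfig, fit_detector, predict_batch
from paintscan.evaluation import evaluate_detections, pr_curve_auc

model = scenarios.baseline_model(N0=1_000)
print("simulating and training (small scale) ...")
train = pipeline.generate_examples(model, 60, fraction_neutral=0.2, seed=3)
val = pipeline.generate_examples(model, 20, fraction_neutral=0.2, seed=3, index_offset=60)
detector = fit_detector([(ex.image.pixels, ex.variant_pixel) for ex in train],
                        DetectorConfig(epochs=5, seed=3))

images = [ex.image.pixels for ex in val]
targets = [ex.target for ex in val]
vpix = [ex.variant_pixel for ex in val]
width = detector.image_shape[1]

for threshold in (0.3, 0.5, 0.7, 0.9):
    detections = predict_batch(detector, images, threshold)
    report = evaluate_detections(detections, targets, vpix, width, compute_auc=False)
    print(f"threshold {threshold:.1f}: precision {report.precision:.3f} "
          f"recall {report.recall:.3f} "
          f"boxes/image {report.count_mean:.2f} "
          f"detection rate {report.bbox_detection_rate}")

scored = predict_batch(detector, images, 0.0)
auc, precision, recall = pr_curve_auc(scored, targets, width, n_thresholds=10_000)
print(f"\nPR-curve AUC over 10,000 thresholds: {auc:.3f} "
      f"({len(precision)} operating points)")
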