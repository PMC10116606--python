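"""Experiment plumbing: simulate -> paint -> (train) -> detect -> evaluate.

Everything here is deterministic given a configuration and a base seed.
Per-image randomness comes from ``numpy`` sequence seeding with
``(base_seed, image_index)``, so manifests and images are byte-identical
across reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import scenarios, tractio
from .detector import DetectorConfig, DetectorModel, fit_detector, predict_batch, save_model
from .evaluation import EvalReport, evaluate_detections
from .painting import (
    AimPanel,
    AncestryImage,
    BBox,
    CoordinateMap,
    draw_aim_panel,
    rasterize_aims,
    rasterize_full,
    target_bbox,
)
from .simulate import (
    DemographicModel,
    SelectionModel,
    config_hash,
    run_simulation,
    sample_haplotypes,
)

__all__ = [
    "ImageExample",
    "simulate_image",
    "generate_examples",
    "assemble_training_set",
    "evaluate_model",
    "run_experiment",
    "PROFILES",
]

# Study-scale and desk-scale experiment profiles.  The paper-scale profile
# mirrors the published setup (8,000 training images, 30 epochs); the desk
# profile is sized for a single CPU.
PROFILES = {
    "paper": {"n_train": 8000, "n_val": 2000, "epochs": 30},
    "desk": {"n_train": 400, "n_val": 100, "epochs": 10},
}


@dataclass
class ImageExample:
    """One simulated, painted image with its annotation and provenance."""

    image: AncestryImage
    target: BBox | None
    variant_pixel: int | None
    s: float | None
    variant_position: float | None
    seed: tuple[int, int]


def simulate_image(
    model: DemographicModel,
    selection: SelectionModel,
    seed,
    n_haplotypes: int = 200,
    width: int = 200,
    mode: str = "full",
    panel: AimPanel | None = None,
    coords: str = "physical",
    half_width: int = 5,
    chromosome: int = 0,
) -> tuple[AncestryImage, BBox | None]:
    """Simulate one replicate and paint it; returns the image and, if the
    replicate has a selected site on the painted chromosome, its target box."""
    rng = np.random.default_rng(seed)
    result = run_simulation(model, selection, rng=rng)
    samples = sample_haplotypes(result, n_haplotypes, rng)
    rmap = model.chromosomes[chromosome]
    cmap = (
        CoordinateMap.genetic(rmap, width)
        if coords == "genetic"
        else CoordinateMap.physical(rmap.length, width)
    )
    if mode == "aims":
        if panel is None:
            raise ValueError("AIM mode requires a marker panel")
        image = rasterize_aims(samples, panel, cmap, chromosome)
    else:
        image = rasterize_full(samples, cmap, chromosome)
    target = None
    on_chrom = [site for site in selection.sites if site.chromosome == chromosome]
    if on_chrom:
        target = target_bbox(on_chrom[0].position, cmap, half_width, n_haplotypes)
    return image, target


def generate_examples(
    model: DemographicModel,
    n_images: int,
    fraction_neutral: float = 0.0,
    seed: int = 0,
    mode: str = "full",
    panel: AimPanel | None = None,
    width: int = 200,
    n_haplotypes: int = 200,
    half_width: int = 5,
    selection_factory=None,
    index_offset: int = 0,
) -> list[ImageExample]:
    """Generate a seeded set of painted images under the study conditions.

    The first ``round(n_images * fraction_neutral)`` indices are neutral
    (no selected site, no target box); the rest draw s ~ U(0, 0.5) and a
    uniformly placed variant.  ``selection_factory(rng, model)`` can
    override how selection is drawn (e.g. the FST = 0 scenario).
    """
    if not 0 <= fraction_neutral < 1:
        raise ValueError("fraction_neutral must be in [0, 1)")
    if mode == "aims" and panel is None:
        panel = draw_aim_panel(model.chromosomes[0].length, 100, seed=seed + 977)
    n_neutral = round(n_images * fraction_neutral)
    examples = []
    for i in range(n_images):
        idx = index_offset + i
        rng = np.random.default_rng((seed, idx))
        if i < n_neutral:
            selection = scenarios.neutral_selection()
        elif selection_factory is not None:
            selection = selection_factory(rng, model)
        else:
            selection = scenarios.draw_selection(rng, model)
        image, target = simulate_image(
            model, selection, rng, n_haplotypes, width, mode, panel, half_width=half_width
        )
        site = selection.sites[0] if selection.sites else None
        vpix = (
            int(image.cmap.position_to_pixel(site.position))
            if site is not None and site.chromosome == 0
            else None
        )
        examples.append(
            ImageExample(
                image,
                target,
                vpix,
                site.s if site else None,
                site.position if site else None,
                (seed, idx),
            )
        )
    return examples


def _manifest_record(i: int, ex: ImageExample) -> dict:
    return {
        "id": i,
        "file_name": f"img_{i:05d}.png",
        "s": ex.s,
        "variant_position": ex.variant_position,
        "variant_pixel": ex.variant_pixel,
        "neutral": ex.target is None,
        "seed": list(ex.seed),
    }


def _write_split(examples: list[ImageExample], out: Path, width: int, height: int) -> None:
    (out / "images").mkdir(parents=True, exist_ok=True)
    entries = []
    records = []
    for i, ex in enumerate(examples):
        rec = _manifest_record(i, ex)
        records.append(rec)
        tractio.write_image(ex.image, out / "images" / rec["file_name"])
        entries.append((i, rec["file_name"], [ex.target] if ex.target else []))
    tractio.write_annotations(entries, out / "annotations.json", width, height)
    manifest = {"images": records}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def assemble_training_set(
    model: DemographicModel,
    n_train: int,
    n_val: int,
    fraction_neutral: float,
    seed: int,
    out_dir,
    mode: str = "full",
    panel: AimPanel | None = None,
    width: int = 200,
    n_haplotypes: int = 200,
    half_width: int = 5,
) -> Path:
    """Simulate, paint and write a train/val image set with COCO annotations
    and a reproducibility manifest.  Selection images carry exactly one
    target box; neutral images carry none."""
    if n_train < 1 or n_val < 1:
        raise ValueError("n_train and n_val must be >= 1")
    out_dir = Path(out_dir)
    if mode == "aims" and panel is None:
        panel = draw_aim_panel(model.chromosomes[0].length, 100, seed=seed + 977)
    train_ex = generate_examples(
        model, n_train, fraction_neutral, seed, mode, panel, width, n_haplotypes, half_width
    )
    val_ex = generate_examples(
        model, n_val, fraction_neutral, seed, mode, panel, width, n_haplotypes, half_width,
        index_offset=n_train,
    )
    _write_split(train_ex, out_dir / "train", width, n_haplotypes)
    _write_split(val_ex, out_dir / "val", width, n_haplotypes)
    meta = {
        "config_hash": config_hash(model, scenarios.neutral_selection()),
        "seed": seed,
        "mode": mode,
        "fraction_neutral": fraction_neutral,
        "n_train": n_train,
        "n_val": n_val,
        "panel": panel.positions.tolist() if panel is not None else None,
    }
    (out_dir / "dataset.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out_dir


def evaluate_model(
    detector: DetectorModel,
    examples: list[ImageExample],
    threshold: float | None = None,
    n_thresholds: int = 10_000,
) -> EvalReport:
    """Run inference on painted examples and compute the pooled metrics."""
    images = [ex.image.pixels for ex in examples]
    detections = predict_batch(detector, images, threshold)
    # the threshold sweep needs unfiltered scores
    scored = predict_batch(detector, images, 0.0)
    targets = [ex.target for ex in examples]
    vpix = [ex.variant_pixel for ex in examples]
    report = evaluate_detections(detections, targets, vpix, detector.image_shape[1],
                                 compute_auc=False)
    from .evaluation import pr_curve_auc

    auc, _, _ = pr_curve_auc(scored, targets, detector.image_shape[1], n_thresholds)
    report.auc = auc
    return report


def run_experiment(
    out_dir,
    profile: str = "desk",
    seed: int = 0,
    model: DemographicModel | None = None,
    fraction_neutral: float = 0.0,
    mode: str = "full",
    threshold: float = 0.5,
) -> dict:
    """End-to-end pipeline: training-set generation, training, inference on
    the validation split, metric report.  Writes all artifacts under
    ``out_dir`` and returns the report dict."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    prof = PROFILES[profile]
    if model is None:
        model = scenarios.baseline_model()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = draw_aim_panel(model.chromosomes[0].length, 100, seed=seed + 977) if mode == "aims" else None
    train_ex = generate_examples(model, prof["n_train"], fraction_neutral, seed, mode, panel)
    val_ex = generate_examples(
        model, prof["n_val"], fraction_neutral, seed, mode, panel, index_offset=prof["n_train"]
    )
    config = DetectorConfig(epochs=prof["epochs"], threshold=threshold, seed=seed)
    detector = fit_detector([(ex.image.pixels, ex.variant_pixel) for ex in train_ex], config)
    save_model(detector, out_dir / "model.joblib")
    report = evaluate_model(detector, val_ex, threshold)
    payload = {
        "profile": profile,
        "seed": seed,
        "mode": mode,
        "config": dataclasses.asdict(config),
        "metrics": report.to_dict(),
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return payload
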