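"""File formats: BED-like ancestry tracts, HapMap-style genetic maps,
grayscale PNG images and COCO-style bounding-box annotations.

Tract files are tab-delimited with columns
``sample_id  haplotype  chrom  start  end  ancestry``
using 0-based half-open intervals; each (sample_id, haplotype, chrom) group
must tile the chromosome exactly.  PNG images are 8-bit grayscale with
0 = black = ancestry 1 and 255 = white = ancestry 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .painting import AncestryImage, BBox, CoordinateMap
from .simulate import HaplotypeTractSet, RecombinationMap, SampleSet

__all__ = [
    "write_tracts",
    "read_tracts",
    "read_genetic_map",
    "write_image",
    "read_image",
    "write_annotations",
    "read_annotations",
]

TRACT_COLUMNS = ["sample_id", "haplotype", "chrom", "start", "end", "ancestry"]


def write_tracts(samples: SampleSet, path) -> None:
    rows = []
    for i, hap in enumerate(samples.haplotypes):
        sample_id, hap_id = i // 2, i % 2
        for c, (ends, anc) in enumerate(hap.tracts):
            starts = np.concatenate(([0.0], ends[:-1]))
            for s, e, a in zip(starts, ends, anc):
                rows.append((sample_id, hap_id, c, int(s), int(e), int(a)))
    df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_tracts(path, chrom_lengths=None) -> SampleSet:
    """Parse a tract file back into a SampleSet, validating the tiling.

    Malformed rows or non-tiling tract groups raise ValueError naming the
    offending file line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"ancestry": int})
    except Exception as exc:  # noqa: BLE001 - reraise with context
        raise ValueError(f"{path}: cannot parse tract file: {exc}") from exc
    missing = [c for c in TRACT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not set(np.unique(df["ancestry"])) <= {0, 1}:
        bad = df.index[~df["ancestry"].isin([0, 1])][0] + 2  # header + 1-based
        raise ValueError(f"{path}: line {bad}: ancestry must be 0 or 1")
    chroms = sorted(df["chrom"].unique())
    if chrom_lengths is None:
        chrom_lengths = tuple(float(df.loc[df["chrom"] == c, "end"].max()) for c in chroms)
    haplotypes = []
    df = df.sort_values(["sample_id", "haplotype", "chrom", "start"], kind="stable")
    grouped = df.groupby(["sample_id", "haplotype"], sort=True)
    for (sid, hid), grp in grouped:
        tracts = []
        for c, L in zip(chroms, chrom_lengths):
            sub = grp[grp["chrom"] == c]
            if sub.empty:
                raise ValueError(f"{path}: sample {sid} hap {hid} missing chrom {c}")
            starts = sub["start"].to_numpy(float)
            ends = sub["end"].to_numpy(float)
            anc = sub["ancestry"].to_numpy(np.int8)
            if starts[0] != 0 or ends[-1] != L or np.any(starts[1:] != ends[:-1]):
                line = sub.index[0] + 2
                raise ValueError(
                    f"{path}: line {line}: tracts for sample {sid} hap {hid} "
                    f"chrom {c} do not tile [0, {L:g})"
                )
            # merge any adjacent same-ancestry tracts on read
            keep = np.concatenate((anc[1:] != anc[:-1], [True]))
            tracts.append((ends[keep], anc[keep]))
        haplotypes.append(HaplotypeTractSet(tracts))
    n = len(haplotypes)
    return SampleSet(haplotypes, tuple(chrom_lengths), np.arange(n // 2), {"source": str(path)})


def read_genetic_map(path, length: float | None = None) -> RecombinationMap:
    """Read a HapMap-format recombination map:
    columns chrom, position (bp), rate (cM/Mb), cumulative map (cM)."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (chrom, pos, rate, cM)")
    pos = df.iloc[:, 1].to_numpy(float)
    cm = df.iloc[:, 3].to_numpy(float)
    cm = cm - cm[0]
    if pos[0] > 0:
        # extend to position 0 using the first interval's rate
        slope = (cm[1] - cm[0]) / (pos[1] - pos[0])
        pos = np.concatenate(([0.0], pos))
        cm = np.concatenate(([0.0], cm + slope * pos[1]))
    table = np.column_stack([pos, cm])
    L = float(length) if length is not None else float(pos[-1])
    return RecombinationMap(length=L, table=table)


def write_image(image: AncestryImage, path) -> None:
    arr = np.where(image.pixels == 1, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_image(path, cmap: CoordinateMap | None = None) -> AncestryImage:
    arr = np.asarray(Image.open(path).convert("L"))
    pixels = (arr < 128).astype(np.uint8)
    if cmap is None:
        cmap = CoordinateMap(0.0, float(pixels.shape[1]), pixels.shape[1])
    return AncestryImage(pixels, cmap)


def write_annotations(entries, path, width: int = 200, height: int = 200) -> None:
    """COCO-style annotation JSON for one category ("selected_variant").

    ``entries`` is a sequence of ``(image_id, file_name, [BBox, ...])``; box
    geometry is stored as [x, y, width, height] with the half-open pixel
    convention (width = x_max - x_min).
    """
    images, annotations = [], []
    ann_id = 1
    for image_id, file_name, boxes in entries:
        images.append(
            {"id": int(image_id), "file_name": str(file_name), "width": width, "height": height}
        )
        for box in boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": int(image_id),
                    "category_id": 1,
                    "bbox": [box.x_min, box.y_min, box.width, box.y_max - box.y_min],
                    "area": box.width * (box.y_max - box.y_min),
                    "iscrowd": 0,
                    **({"score": box.score} if box.score is not None else {}),
                }
            )
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "selected_variant"}],
        "info": {"box_convention": "half-open pixels; bbox = [x_min, y_min, width, height]"},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> dict[int, list[BBox]]:
    """Boxes per image id from a COCO-style annotation file."""
    payload = json.loads(Path(path).read_text())
    out: dict[int, list[BBox]] = {img["id"]: [] for img in payload["images"]}
    for ann in payload["annotations"]:
        x, y, w, h = ann["bbox"]
        out[ann["image_id"]].append(
            BBox(int(x), int(y), int(x + w), int(y + h), ann.get("score"))
        )
    return out
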