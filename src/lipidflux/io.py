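"""Reading and writing fields, masks and ground truth on disk.

Layout per dataset directory::

    fields/<name>.tif         single-channel float32 lipid image
    fields/<name>.json        sidecar metadata (probe_id, chase_time, condition, seed)
    masks/<name>.tif          multi-page float32 masks: PM, Endo, Golgi, ER, cell
    truth.csv                 optional ground truth (time_min, compartment, fraction)

The same reader accepts externally produced probability maps as long as
they follow the page order above.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import COMPARTMENTS, FractionTimeSeries
from .scene import FieldImage, OrganelleMaskSet, SyntheticDataset

__all__ = ["write_dataset", "read_dataset", "field_name"]

_MASK_PAGES = (*COMPARTMENTS, "cell")


def field_name(image: FieldImage, index: int) -> str:
    cond = "uv" if image.condition == "UV" else "nouv"
    return f"{image.probe_id}_t{image.chase_time:g}_{cond}_{index:04d}"


def write_field(
    fields_dir: Path, masks_dir: Path, image: FieldImage, masks: OrganelleMaskSet,
    index: int,
) -> str:
    name = field_name(image, index)
    tifffile.imwrite(fields_dir / f"{name}.tif", image.pixels.astype(np.float32))
    pages = np.stack(
        [masks.masks[c] for c in COMPARTMENTS] + [masks.cell_mask.astype(np.float32)]
    ).astype(np.float32)
    tifffile.imwrite(masks_dir / f"{name}.tif", pages)
    meta = {
        "probe_id": image.probe_id,
        "chase_time": image.chase_time,
        "condition": image.condition,
        "seed": image.seed,
        "mask_pages": list(_MASK_PAGES),
    }
    (fields_dir / f"{name}.json").write_text(json.dumps(meta, indent=1))
    return name


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a synthetic dataset (fields, masks, ground-truth CSV) to disk."""
    out = Path(out_dir)
    fields_dir = out / "fields"
    masks_dir = out / "masks"
    fields_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    for i, (image, masks) in enumerate(dataset.fields):
        write_field(fields_dir, masks_dir, image, masks, i)
    truth = dataset.truth_series
    rows = [
        {"time_min": t, "compartment": c, "fraction": truth.fractions[i, j]}
        for i, t in enumerate(truth.times)
        for j, c in enumerate(COMPARTMENTS)
    ]
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
    return out


def read_dataset(in_dir: str | Path) -> list[tuple[FieldImage, OrganelleMaskSet]]:
    """Load every field (image + masks + metadata) from a dataset directory."""
    root = Path(in_dir)
    fields_dir, masks_dir = root / "fields", root / "masks"
    out = []
    for meta_path in sorted(fields_dir.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        name = meta_path.stem
        pixels = tifffile.imread(fields_dir / f"{name}.tif").astype(np.float64)
        pages = tifffile.imread(masks_dir / f"{name}.tif").astype(np.float32)
        page_order = meta.get("mask_pages", list(_MASK_PAGES))
        masks = {c: pages[page_order.index(c)] for c in COMPARTMENTS}
        cell = pages[page_order.index("cell")] > 0.5
        out.append(
            (
                FieldImage(
                    pixels=pixels,
                    probe_id=meta["probe_id"],
                    chase_time=float(meta["chase_time"]),
                    condition=meta["condition"],
                    seed=int(meta["seed"]),
                ),
                OrganelleMaskSet(masks=masks, cell_mask=cell),
            )
        )
    if not out:
        raise FileNotFoundError(f"no fields found under {root}")
    return out


def read_truth(in_dir: str | Path) -> FractionTimeSeries:
    df = pd.read_csv(Path(in_dir) / "truth.csv")
    wide = df.pivot(index="time_min", columns="compartment", values="fraction")
    times = wide.index.to_numpy(dtype=float)
    fractions = wide[list(COMPARTMENTS)].to_numpy()
    return FractionTimeSeries(times=times, fractions=fractions)
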