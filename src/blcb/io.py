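"""Image/mask readers and writers and DRIVE-style dataset indexing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "DatasetEntry",
    "DatasetIndex",
    "read_image",
    "read_mask",
    "write_image",
    "write_probability_map",
    "load_dataset",
]

_FORMATS = {".png", ".tif", ".tiff", ".gif", ".jpg", ".jpeg"}


def read_image(path) -> np.ndarray:
    """Read an image as RGB uint8 (H, W, 3) or grayscale.

    Grayscale images come back as 2-D arrays; 16-bit grayscale (e.g.
    stored probability maps) is rescaled to float [0, 1]. Alpha channels
    are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(f"unsupported image format: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[0] in (1,):  # some GIFs: (frames, H, W)
        arr = arr[0]
    if arr.ndim == 2 and arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr


def read_mask(path) -> np.ndarray:
    """Read a binary mask; 8-bit values above 127 count as foreground."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.dtype == np.float64:  # came from 16-bit storage
        return (arr > 0.5).astype(np.uint8)
    return (arr > 127).astype(np.uint8)


def write_image(path, arr: np.ndarray) -> None:
    """Write an 8-bit image (binary masks are scaled to {0, 255})."""
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        if arr.max(initial=0) <= 1:
            arr = (arr.astype(np.float64) * 255).round().astype(np.uint8)
        else:
            arr = arr.astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_probability_map(path, pmap: np.ndarray) -> None:
    """Store a [0, 1] probability map losslessly-enough as 16-bit PNG."""
    arr = np.clip(np.asarray(pmap, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


@dataclass(frozen=True)
class DatasetEntry:
    stem: str
    image: Path
    gt: Path
    fov: Path | None = None
    thick: Path | None = None
    thin: Path | None = None


@dataclass
class DatasetIndex:
    root: Path
    entries: list[DatasetEntry] = field(default_factory=list)
    split: str = ""

    def __len__(self) -> int:
        return len(self.entries)


def _stem_map(folder: Path) -> dict[str, Path]:
    if not folder.is_dir():
        return {}
    return {
        p.stem.replace("_training", "").replace("_test", "").replace("_manual1", ""): p
        for p in sorted(folder.iterdir())
        if p.suffix.lower() in _FORMATS
    }


def load_dataset(root, split: str = "", check_dims: bool = True) -> DatasetIndex:
    """Index a DRIVE-style directory (images/, 1st_manual/, mask/ ...).

    Entries are paired by filename stem; unpaired or dimension-mismatched
    files are reported in one aggregated error.
    """
    root = Path(root)
    images = _stem_map(root / "images")
    gts = _stem_map(root / "1st_manual")
    fovs = _stem_map(root / "mask")
    thicks = _stem_map(root / "thick")
    thins = _stem_map(root / "thin")
    if not images:
        raise FileNotFoundError(f"no images/ folder with images under {root}")
    problems = []
    entries = []
    for stem in sorted(set(images) | set(gts)):
        if stem not in images:
            problems.append(f"{stem}: ground truth without image")
            continue
        if stem not in gts:
            problems.append(f"{stem}: image without ground truth")
            continue
        entry = DatasetEntry(
            stem=stem,
            image=images[stem],
            gt=gts[stem],
            fov=fovs.get(stem),
            thick=thicks.get(stem),
            thin=thins.get(stem),
        )
        if check_dims:
            img = read_image(entry.image)
            hw = img.shape[:2]
            for name, p in (("gt", entry.gt), ("fov", entry.fov),
                            ("thick", entry.thick), ("thin", entry.thin)):
                if p is not None and read_mask(p).shape != hw:
                    problems.append(f"{stem}: {name} mask dimensions differ from image")
        entries.append(entry)
    if problems:
        raise ValueError("dataset validation failed:\n  " + "\n  ".join(problems))
    return DatasetIndex(root=root, entries=entries, split=split)
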