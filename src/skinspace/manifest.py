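"""Dataset manifests pairing images with masks and train/test split tags."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ManifestRow", "Manifest", "split_manifest"]

_VALID_SPLITS = ("train", "test", "")


@dataclass(frozen=True)
class ManifestRow:
    image: str
    mask: str
    split: str = ""

    def __post_init__(self) -> None:
        if self.split not in _VALID_SPLITS:
            raise ValueError(f"invalid split tag {self.split!r}; valid: train/test")


@dataclass(frozen=True)
class Manifest:
    rows: tuple[ManifestRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, split: str) -> "Manifest":
        return Manifest(tuple(r for r in self.rows if r.split == split))

    @classmethod
    def load(cls, path: str | Path, check_paths: bool = True) -> "Manifest":
        path = Path(path)
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                row = ManifestRow(
                    image=rec["image"], mask=rec["mask"], split=rec.get("split", "") or ""
                )
                if check_paths:
                    for p in (row.image, row.mask):
                        if not Path(p).exists():
                            raise FileNotFoundError(f"manifest references missing file {p}")
                rows.append(row)
        return cls(tuple(rows))

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "mask", "split"])
            for r in self.rows:
                writer.writerow([r.image, r.mask, r.split])

    def load_pairs(self, split: str | None = None):
        """Yield (RgbImage, SkinMask) pairs, optionally restricted to a split."""
        from .colorspaces import load_image, load_mask

        rows = self.rows if split is None else self.subset(split).rows
        for r in rows:
            yield load_image(r.image), load_mask(r.mask)


def split_manifest(
    manifest: Manifest, train_fraction: float = 0.75, seed: int = 0
) -> Manifest:
    """Assign image-level train/test tags by a seeded random permutation.

    The train count is ``round(n * train_fraction)`` with half-up rounding;
    both sides must end up non-empty.
    """
    n = len(manifest)
    if n < 2:
        raise ValueError("need at least 2 manifest rows to split")
    n_train = int(np.floor(n * train_fraction + 0.5))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty side for n={n}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    rows = tuple(
        ManifestRow(r.image, r.mask, "train" if i in train_idx else "test")
        for i, r in enumerate(manifest.rows)
    )
    return Manifest(rows)
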