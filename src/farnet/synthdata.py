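"""Synthetic multilabel jujube-defect images with a census-exact label table.

The real multilabel jujube dataset behind this architecture was never
deposited, so this module emulates it: 8 surface-condition labels — normal
(n), russeting (r), mild rot (mr), severe rot (sr), cracking (c), shriveled
(s), peeling (p), bird pecking (bp) — and the published sample census of 15
label combinations totalling 1930 images (660 single-, 1200 double- and 70
triple-label).  Each image is a disc-shaped "fruit" on a dark background with
one geometrically distinct motif per label, so a small CNN can learn the
label-wise channel hypothesis at desk scale.  Generation is a pure function
of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_LABELS",
    "TABLE_COMBOS",
    "LabelVocabulary",
    "DatasetSpec",
    "LabeledImage",
    "DatasetIndex",
    "make_default_spec",
    "render_sample",
    "generate_dataset",
    "split_dataset",
    "dataset_stats",
]

DEFAULT_LABELS = ("n", "r", "mr", "sr", "c", "s", "p", "bp")

#: Published sample census: (label combination, count).  Singles sum to 660,
#: doubles to 1200, triples to 70; grand total 1930.
TABLE_COMBOS: tuple[tuple[tuple[str, ...], int], ...] = (
    (("n",), 100),
    (("r",), 80),
    (("mr",), 80),
    (("sr",), 80),
    (("c",), 80),
    (("s",), 80),
    (("p",), 80),
    (("bp",), 80),
    (("r", "p"), 200),
    (("r", "c"), 200),
    (("mr", "p"), 200),
    (("mr", "c"), 200),
    (("bp", "p"), 200),
    (("s", "p"), 200),
    (("r", "p", "mr"), 20),
    (("r", "p", "c"), 20),
    (("mr", "c", "p"), 15),
    (("bp", "sr", "c"), 15),
)


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered label identifiers; the order fixes the index of every target
    vector and of every label-wise feature channel downstream."""

    names: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("a label vocabulary needs at least 2 labels")
        if len(set(self.names)) != len(self.names):
            raise ValueError("label names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}; vocabulary is {list(self.names)}") from None

    def multi_hot(self, combo: Iterable[str]) -> np.ndarray:
        y = np.zeros(len(self.names), dtype=np.int8)
        for label in combo:
            y[self.index(label)] = 1
        return y


# Per-label motif rendering parameters: shape family, colour, size as a
# fraction of the fruit radius.  Values chosen to keep motifs visually and
# geometrically distinct at 64 px.
DEFAULT_MOTIF_PARAMS: dict[str, dict] = {
    "n": {},
    "r": {"color": (0.74, 0.56, 0.36), "speck_radius": 0.055, "n_specks": 14, "spread": 0.45},
    "mr": {"color": (0.26, 0.13, 0.06), "radius": 0.30},
    "sr": {"color": (0.07, 0.04, 0.02), "radius": 0.55},
    "c": {"color": (0.10, 0.05, 0.04), "width": 0.045, "n_points": 6},
    "s": {"depth": 0.16, "rings": 5.0},
    "p": {"color": (0.88, 0.78, 0.52), "radius": 0.34},
    "bp": {"color": (0.05, 0.03, 0.02), "radius": 0.14, "rim_color": (0.80, 0.62, 0.40)},
}


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for a synthetic dataset: which label combinations, how many of
    each, the image side in pixels, motif parameters and the master seed."""

    combos: tuple[tuple[tuple[str, ...], int], ...]
    image_size: int = 64
    motif_params: Mapping[str, dict] = field(default_factory=lambda: DEFAULT_MOTIF_PARAMS)
    seed: int = 0
    vocabulary: LabelVocabulary = field(default_factory=LabelVocabulary)

    def __post_init__(self) -> None:
        for combo, count in self.combos:
            if not combo:
                raise ValueError("every label combination must be nonempty")
            for label in combo:
                self.vocabulary.index(label)
            if count <= 0:
                raise ValueError(f"count for combo {combo} must be positive, got {count}")

    @property
    def total(self) -> int:
        return sum(count for _, count in self.combos)

    def scaled(self, factor: float) -> "DatasetSpec":
        """Shrink every combination count by ``factor`` (≥1 kept per combo)."""
        combos = tuple(
            (combo, max(1, int(round(count * factor)))) for combo, count in self.combos
        )
        return replace(self, combos=combos)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "combos": [["+".join(c), int(n)] for c, n in self.combos],
            "image_size": self.image_size,
            "seed": self.seed,
            "labels": list(self.vocabulary.names),
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetSpec":
        payload = yaml.safe_load(Path(path).read_text())
        vocab = LabelVocabulary(tuple(payload.get("labels", DEFAULT_LABELS)))
        combos = tuple((tuple(c.split("+")), int(n)) for c, n in payload["combos"])
        return cls(
            combos=combos,
            image_size=int(payload.get("image_size", 64)),
            seed=int(payload.get("seed", 0)),
            vocabulary=vocab,
        )


@dataclass
class LabeledImage:
    pixels: np.ndarray  # H×W×3 floats in [0, 1]
    y: np.ndarray  # multi-hot {0,1}^C
    id: str


class DatasetIndex:
    """Annotation table: one row per image with id, multi-hot labels and an
    optional train/val/test split tag."""

    def __init__(self, frame: pd.DataFrame, vocabulary: LabelVocabulary | None = None):
        self.vocabulary = vocabulary or LabelVocabulary(
            tuple(c for c in frame.columns if c not in ("id", "split", "combo"))
        )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        return self.frame[list(self.vocabulary.names)].to_numpy(dtype=np.int8)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    def combo_strings(self) -> pd.Series:
        labels = list(self.vocabulary.names)
        y = self.frame[labels].to_numpy(dtype=bool)
        return pd.Series(
            ["+".join(l for l, on in zip(labels, row) if on) for row in y],
            index=self.frame.index,
        )

    def subset(self, split: str) -> "DatasetIndex":
        if "split" not in self.frame.columns:
            raise ValueError("index has no split assignment; call split_dataset first")
        return DatasetIndex(
            self.frame[self.frame["split"] == split].copy(), self.vocabulary
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetIndex":
        return cls(pd.read_csv(path))


# --------------------------------------------------------------------- render


def _disc_mask(size: int, yy: np.ndarray, xx: np.ndarray, rng: np.random.Generator):
    cy = 0.5 + rng.uniform(-0.02, 0.02)
    cx = 0.5 + rng.uniform(-0.02, 0.02)
    radius = 0.42 + rng.uniform(-0.02, 0.02)
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return r < radius, (cy, cx, radius, r)


def _soft_blob(yy, xx, cy, cx, radius, rng, lobes: int = 3):
    """Irregular blob: a disc whose radius is modulated by a few random lobes."""
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = np.ones_like(theta)
    for _ in range(lobes):
        k = rng.integers(2, 6)
        wobble += 0.25 * rng.uniform(-1, 1) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return r < radius * wobble


def _paint(img: np.ndarray, mask: np.ndarray, color: Sequence[float], alpha: float = 1.0):
    img[mask] = (1 - alpha) * img[mask] + alpha * np.asarray(color)


def render_sample(
    combo: Sequence[str],
    motif_params: Mapping[str, dict] | None = None,
    rng: np.random.Generator | int = 0,
    image_size: int = 64,
    vocabulary: LabelVocabulary | None = None,
    sample_id: str = "",
) -> LabeledImage:
    """Draw one fruit disc with one motif per label in ``combo``.

    Deterministic given the rng state: the same (combo, seed) yields a
    bit-identical image.  Unknown labels raise ``KeyError`` naming the label.
    """
    if not combo:
        raise ValueError("combo must contain at least one label")
    vocab = vocabulary or LabelVocabulary()
    params = dict(DEFAULT_MOTIF_PARAMS)
    if motif_params:
        for k, v in motif_params.items():
            params[k] = {**params.get(k, {}), **v}
    y = vocab.multi_hot(combo)  # validates labels, raising KeyError if unknown
    for label in combo:
        if label not in params:
            raise KeyError(f"no motif parameters for label {label!r}")

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    size = image_size
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    img = np.empty((size, size, 3))
    img[...] = (0.16, 0.15, 0.13)
    disc, (cy, cx, radius, r) = _disc_mask(size, yy, xx, rng)

    # fruit body: reddish-brown with radial shading and fine speckle
    shade = 1.0 - 0.55 * (r / radius) ** 2
    base = np.array([0.58, 0.19, 0.12])
    body = base[None, None, :] * shade[..., None]
    img[disc] = body[disc]
    img += rng.normal(0.0, 0.012, size=img.shape)

    def random_point_in_disc(max_frac: float = 0.7):
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * max_frac * np.sqrt(rng.uniform(0, 1))
        return cy + rad * np.sin(ang), cx + rad * np.cos(ang)

    for label in combo:
        p = params[label]
        if label == "n":
            continue
        elif label == "r":  # russeting: cluster of small tan specks
            ky, kx = random_point_in_disc(0.5)
            spread = p["spread"] * radius
            for _ in range(p["n_specks"]):
                sy = ky + rng.normal(0, spread)
                sx = kx + rng.normal(0, spread)
                sr_ = p["speck_radius"] * radius * rng.uniform(0.6, 1.4)
                m = ((yy - sy) ** 2 + (xx - sx) ** 2 < sr_**2) & disc
                _paint(img, m, p["color"], alpha=0.9)
        elif label in ("mr", "sr"):  # rot: dark irregular blob (severe = larger/darker)
            ky, kx = random_point_in_disc(0.45 if label == "sr" else 0.6)
            blob = _soft_blob(yy, xx, ky, kx, p["radius"] * radius * rng.uniform(0.85, 1.15), rng)
            _paint(img, blob & disc, p["color"], alpha=0.95)
        elif label == "c":  # cracking: thin dark polyline across the fruit
            pts = []
            ang = rng.uniform(0, 2 * np.pi)
            start = (cy + 0.85 * radius * np.sin(ang), cx + 0.85 * radius * np.cos(ang))
            end = (cy - 0.85 * radius * np.sin(ang) + rng.normal(0, 0.1 * radius),
                   cx - 0.85 * radius * np.cos(ang) + rng.normal(0, 0.1 * radius))
            ctrl = np.linspace(start, end, p["n_points"])
            ctrl[1:-1] += rng.normal(0, 0.08 * radius, size=(p["n_points"] - 2, 2))
            dense = []
            for a, b in zip(ctrl[:-1], ctrl[1:]):
                t = np.linspace(0, 1, 24)[:, None]
                dense.append(a * (1 - t) + b * t)
            dense = np.concatenate(dense)
            d2 = ((yy[..., None] - dense[:, 0]) ** 2 + (xx[..., None] - dense[:, 1]) ** 2).min(-1)
            width = p["width"] * radius
            _paint(img, (d2 < width**2) & disc, p["color"], alpha=0.9)
        elif label == "s":  # shriveled: concentric wrinkle rings
            phase = rng.uniform(0, 2 * np.pi)
            rings = np.sin(2 * np.pi * p["rings"] * (r / radius) + phase)
            img[disc] *= (1.0 + p["depth"] * rings[disc])[:, None]
        elif label == "p":  # peeling: bright irregular patch of exposed flesh
            ky, kx = random_point_in_disc(0.55)
            blob = _soft_blob(yy, xx, ky, kx, p["radius"] * radius * rng.uniform(0.85, 1.15), rng)
            _paint(img, blob & disc, p["color"], alpha=0.92)
        elif label == "bp":  # bird pecking: small deep hole with a bright rim
            ky, kx = random_point_in_disc(0.55)
            hole_r = p["radius"] * radius * rng.uniform(0.8, 1.2)
            d = np.sqrt((yy - ky) ** 2 + (xx - kx) ** 2)
            _paint(img, (d < hole_r * 1.4) & (d >= hole_r) & disc, p["rim_color"], alpha=0.8)
            _paint(img, (d < hole_r) & disc, p["color"], alpha=1.0)
        else:  # pragma: no cover - vocabulary already validated
            raise KeyError(f"no renderer for label {label!r}")

    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(pixels=img, y=y, id=sample_id or "+".join(combo))


# ------------------------------------------------------------------- generate


def make_default_spec(image_size: int = 64, seed: int = 0) -> DatasetSpec:
    """The published census: 15 label combinations, 1930 samples in total."""
    return DatasetSpec(combos=TABLE_COMBOS, image_size=image_size, seed=seed)


def generate_dataset(
    spec: DatasetSpec,
    out_dir: str | Path | None = None,
    return_images: bool = True,
) -> tuple[DatasetIndex, dict[str, np.ndarray]]:
    """Render one image per census count unit.

    When ``out_dir`` is given, images are written as PNG and the annotation
    table as ``annotations.csv`` (header ``id,n,r,mr,sr,c,s,p,bp``, 0/1
    cells).  Images are also returned in memory unless ``return_images`` is
    False.  Fully deterministic given ``spec.seed``.
    """
    vocab = spec.vocabulary
    rows = []
    images: dict[str, np.ndarray] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
    idx = 0
    for combo, count in spec.combos:
        combo_str = "+".join(combo)
        for k in range(count):
            sample_id = f"{combo_str}_{k:04d}"
            sample = render_sample(
                combo,
                spec.motif_params,
                rng=np.random.default_rng([spec.seed, idx]),
                image_size=spec.image_size,
                vocabulary=vocab,
                sample_id=sample_id,
            )
            rows.append({"id": sample_id, **dict(zip(vocab.names, sample.y.tolist()))})
            if return_images:
                images[sample_id] = sample.pixels
            if out_dir is not None:
                from PIL import Image

                arr = (sample.pixels * 255).round().astype(np.uint8)
                Image.fromarray(arr).save(img_dir / f"{sample_id}.png")
            idx += 1
    frame = pd.DataFrame(rows, columns=["id", *vocab.names])
    index = DatasetIndex(frame, vocab)
    if out_dir is not None:
        index.to_csv(out_dir / "annotations.csv")
    return index, images


def split_dataset(
    index: DatasetIndex,
    ratio: Sequence[float] = (3, 1, 1),
    seed: int = 0,
) -> DatasetIndex:
    """Assign train/val/test tags, stratified by label combination.

    Within each combination the split is an exact largest-remainder
    apportionment of the ratio (so sizes are within ±1 of exact per combo) and
    the assignment is a seeded permutation.  A combination with fewer records
    than split parts goes entirely to train, with a warning.
    """
    ratio = np.asarray(ratio, dtype=float)
    if (ratio <= 0).any():
        raise ValueError("all ratio components must be positive")
    names = ("train", "val", "test")
    rng = np.random.default_rng(seed)
    frame = index.frame.copy()
    frame["split"] = ""
    combos = index.combo_strings()
    for combo_str in sorted(combos.unique()):
        rows = np.flatnonzero((combos == combo_str).to_numpy())
        n = len(rows)
        if n < len(ratio):
            warnings.warn(
                f"combination {combo_str!r} has only {n} record(s), fewer than "
                f"{len(ratio)} split parts; assigning all to train"
            )
            frame.iloc[rows, frame.columns.get_loc("split")] = "train"
            continue
        exact = n * ratio / ratio.sum()
        base = np.floor(exact).astype(int)
        remainder = exact - base
        for j in np.argsort(-remainder, kind="stable")[: n - base.sum()]:
            base[j] += 1
        perm = rng.permutation(rows)
        tags = np.repeat(names, base)
        frame.iloc[perm, frame.columns.get_loc("split")] = tags
    return DatasetIndex(frame, index.vocabulary)


def dataset_stats(index: DatasetIndex) -> dict:
    """Census summary: total, per-cardinality counts, multilabel fraction and
    per-label frequency, percentages reported to one decimal."""
    if len(index) == 0:
        raise ValueError("cannot summarize an empty dataset index")
    y = index.y
    total = len(index)
    cardinality = y.sum(axis=1)
    card_counts = {int(k): int((cardinality == k).sum()) for k in np.unique(cardinality)}
    multilabel = int((cardinality >= 2).sum())
    per_label = {
        name: round(float(y[:, i].sum()) / total * 100, 1)
        for i, name in enumerate(index.vocabulary.names)
    }
    return {
        "total": total,
        "cardinality_counts": card_counts,
        "multilabel_count": multilabel,
        "multilabel_pct": round(multilabel / total * 100, 1),
        "per_label_pct": per_label,
    }
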