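"""Synthetic slides with planted, class-discriminative lesions.

These fixtures emulate the structure of a 3-class slide-level task (normal
tissue vs two tumour types) at desk scale: each "slide" is a tiled texture
raster with a one-patch-wide white margin (so background filtering is
exercised), a pinkish tissue texture everywhere else, and — for tumour
classes — a contiguous rectangular-ish lesion of a class-specific texture
covering roughly ``lesion_fraction`` of the tissue area.  A pixel-level
ground-truth lesion mask accompanies every slide, which makes saliency
localisation a measurable connected-region-recovery problem.

The three texture families are deliberately crude (plain, blob-dense,
striped); they make no claim of histologic realism, only of separability, so
an end-to-end failure on them points at a model bug rather than at the data.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tiling import SlideImage

__all__ = [
    "SyntheticSlideSpec",
    "generate_slide",
    "generate_cohort",
    "CLASS_NAMES",
]

CLASS_NAMES = ("normal", "tumor_A", "tumor_B")

# base tissue colour: pink, clearly above the saturation threshold and with
# min-channel well below the near-white threshold of the background rule
_TISSUE_RGB = np.array([228, 168, 198], dtype=np.float64)
_BLOB_RGB = np.array([118, 58, 138], dtype=np.float64)  # dark purple nuclei-like blobs
_STRIPE_RGB = np.array([70, 132, 120], dtype=np.float64)  # teal fibrous stripes


@dataclass(frozen=True)
class SyntheticSlideSpec:
    slide_id: str
    n_rows: int
    n_cols: int
    patch_size: int
    class_label: str  # one of CLASS_NAMES
    lesion_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"class_label must be one of {CLASS_NAMES}")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.class_label != "normal" and not (0.0 < self.lesion_fraction < 1.0):
            raise ValueError("lesion_fraction must lie in (0, 1) for tumor classes")

    @property
    def label_index(self) -> int:
        return CLASS_NAMES.index(self.class_label)

    @property
    def tissue_patch_count(self) -> int:
        """Number of full-tissue patches the background filter should keep."""
        return self.n_rows * self.n_cols


def _tissue_texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    base = np.broadcast_to(_TISSUE_RGB, (h, w, 3)).copy()
    base += rng.normal(0.0, 9.0, size=(h, w, 3))
    # coarse luminance mottling so patches are not i.i.d. noise
    coarse = rng.normal(0.0, 14.0, size=(h // 8 + 1, w // 8 + 1))
    base += np.kron(coarse, np.ones((8, 8)))[:h, :w, None]
    return base


def _paint_blobs(rng: np.random.Generator, img: np.ndarray, region: tuple[slice, slice]):
    ys, xs = region
    h = ys.stop - ys.start
    w = xs.stop - xs.start
    n_blobs = max(1, int(h * w / 110))
    yy, xx = np.mgrid[0:h, 0:w]
    sub = img[ys, xs]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(3.0, 7.0)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        sub[mask] = _BLOB_RGB + rng.normal(0.0, 6.0, size=3)


def _paint_stripes(rng: np.random.Generator, img: np.ndarray, region: tuple[slice, slice]):
    ys, xs = region
    h = ys.stop - ys.start
    w = xs.stop - xs.start
    yy, xx = np.mgrid[0:h, 0:w]
    period = rng.uniform(9.0, 13.0)
    phase = rng.uniform(0, period)
    stripe = ((yy + xx + phase) % period) < period * 0.45
    sub = img[ys, xs]
    sub[stripe] = _STRIPE_RGB + rng.normal(0.0, 6.0, size=(int(stripe.sum()), 3))


def _lesion_rectangle(
    rng: np.random.Generator, n_rows: int, n_cols: int, lesion_fraction: float
) -> tuple[int, int, int, int]:
    """(r0, c0, h, w) of a lesion block of ~lesion_fraction of the grid."""
    target = max(1, int(round(lesion_fraction * n_rows * n_cols)))
    h = int(round(np.sqrt(target)))
    h = int(np.clip(h, 1, n_rows))
    w = int(np.clip(int(round(target / h)), 1, n_cols))
    r0 = int(rng.integers(0, n_rows - h + 1))
    c0 = int(rng.integers(0, n_cols - w + 1))
    return r0, c0, h, w


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideImage, np.ndarray, int]:
    """Render one synthetic slide.

    Returns ``(slide, lesion_mask, label_index)`` where ``lesion_mask`` is a
    boolean (H, W) raster marking lesion pixels (all-zero for normal slides).
    The raster has a one-patch white margin on every side, so its tiled grid
    is (n_rows+2) x (n_cols+2) with the tissue block at rows/cols 1..n.
    """
    rng = np.random.default_rng(spec.seed)
    ps = spec.patch_size
    H = (spec.n_rows + 2) * ps
    W = (spec.n_cols + 2) * ps
    img = np.full((H, W, 3), 255.0)
    tissue = (slice(ps, ps + spec.n_rows * ps), slice(ps, ps + spec.n_cols * ps))
    img[tissue] = _tissue_texture(rng, spec.n_rows * ps, spec.n_cols * ps)

    mask = np.zeros((H, W), dtype=bool)
    if spec.class_label != "normal":
        r0, c0, h, w = _lesion_rectangle(rng, spec.n_rows, spec.n_cols, spec.lesion_fraction)
        region = (
            slice((r0 + 1) * ps, (r0 + 1 + h) * ps),
            slice((c0 + 1) * ps, (c0 + 1 + w) * ps),
        )
        if spec.class_label == "tumor_A":
            _paint_blobs(rng, img, region)
        else:
            _paint_stripes(rng, img, region)
        mask[region] = True

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    slide = SlideImage(slide_id=spec.slide_id, pixels=pixels)
    return slide, mask, spec.label_index


@dataclass
class Cohort:
    """A balanced synthetic cohort: specs plus convenience accessors."""

    specs: list[SyntheticSlideSpec]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label_index for s in self.specs])

    def __len__(self):
        return len(self.specs)

    def __iter__(self):
        for spec in self.specs:
            yield generate_slide(spec)

    def manifest_rows(self):
        return [
            {
                "slide_id": s.slide_id,
                "label": s.class_label,
                "n_rows": s.n_rows,
                "n_cols": s.n_cols,
                "patch_size": s.patch_size,
                "seed": s.seed,
            }
            for s in self.specs
        ]


def generate_cohort(
    n_per_class: int = 40,
    grid_range: tuple[int, int] = (8, 12),
    patch_size: int = 64,
    lesion_fraction: float = 0.25,
    seed: int = 0,
) -> Cohort:
    """Balanced 3-class cohort with variable grid sizes.

    Grid dimensions are drawn uniformly from ``grid_range`` (inclusive) per
    slide, emulating the variable patch counts of real slides.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    lo, hi = grid_range
    if lo < 2 or hi < lo:
        raise ValueError("invalid grid_range")
    rng = np.random.default_rng(seed)
    specs = []
    for cls in CLASS_NAMES:
        for i in range(n_per_class):
            nr = int(rng.integers(lo, hi + 1))
            nc = int(rng.integers(lo, hi + 1))
            slide_seed = int(rng.integers(0, 2**31 - 1))
            specs.append(
                SyntheticSlideSpec(
                    slide_id=f"{cls}_{i:03d}",
                    n_rows=nr,
                    n_cols=nc,
                    patch_size=patch_size,
                    class_label=cls,
                    lesion_fraction=lesion_fraction,
                    seed=slide_seed,
                )
            )
    return Cohort(specs)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write slides/masks as PNGs plus a TSV manifest; returns the manifest path."""
    from PIL import Image
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in cohort.specs:
        slide, mask, _ = generate_slide(spec)
        slide_path = out_dir / f"{spec.slide_id}.png"
        mask_path = out_dir / f"{spec.slide_id}_mask.png"
        Image.fromarray(slide.pixels).save(slide_path)
        Image.fromarray((mask * 255).astype(np.uint8)).save(mask_path)
        rows.append(
            {
                "slide_id": spec.slide_id,
                "label": spec.class_label,
                "path": slide_path.name,
                "mask_path": mask_path.name,
                "seed": spec.seed,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def raster_digest(pixels: np.ndarray) -> str:
    """Stable content hash of a raster (used to detect duplicate renders)."""
    return hashlib.sha256(np.ascontiguousarray(pixels).tobytes()).hexdigest()
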