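"""Self-supervised contrastive pre-training of the patch feature extractor.

Two independently augmented views of each patch in a mini-batch form a
positive pair; every other augmented patch in the batch is a negative.  With
2K augmented views, projected to latent vectors z, the loss for the ordered
positive pair (i, j) is the normalised-temperature cross entropy

    l_ij = -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]

with cosine similarity sim and temperature tau; the batch loss averages l_ij
over all 2K ordered pairs.  After training, the projection head is discarded
and the backbone's pooled features become the graph node features.

Augmentations follow the usual contrastive recipe for images: random crop
with resize back to the original size, random colour distortion, and random
Gaussian blur.  No-op settings (strength 0, unit crop scale) reproduce the
input exactly, which the determinism tests rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .autograd import Tensor
from .nn import Adam, MLP, Module, ResNetBackbone, cosine_annealing_lr
from .tiling import PatchGrid

__all__ = [
    "AugmentationPolicy",
    "EmbeddingBatch",
    "FeatureExtractor",
    "augment_patch",
    "augment_pair",
    "cosine_sim",
    "nt_xent_loss",
    "PretrainConfig",
    "pretrain",
    "extract_features",
]

# fixed input normalisation for the backbone
_PIX_MEAN, _PIX_STD = 0.5, 0.25


@dataclass(frozen=True)
class AugmentationPolicy:
    color_distortion_strength: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)
    blur_probability: float = 0.5
    crop_scale_range: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self):
        if self.crop_scale_range[0] > self.crop_scale_range[1]:
            raise ValueError("degenerate crop range: min > max")
        if self.blur_sigma_range[0] > self.blur_sigma_range[1]:
            raise ValueError("degenerate blur range: min > max")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(color_distortion_strength=0.0, blur_sigma_range=(0.0, 0.0),
                   blur_probability=0.0, crop_scale_range=(1.0, 1.0))


def _color_jitter(img: np.ndarray, s: float, rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter with a single strength scalar."""
    # brightness and contrast in [1 - 0.8s, 1 + 0.8s]
    img = img * rng.uniform(1 - 0.8 * s, 1 + 0.8 * s)
    mean = img.mean()
    img = (img - mean) * rng.uniform(1 - 0.8 * s, 1 + 0.8 * s) + mean
    # saturation: blend with per-pixel grey
    grey = img.mean(axis=2, keepdims=True)
    img = grey + (img - grey) * rng.uniform(1 - 0.8 * s, 1 + 0.8 * s)
    # hue: small rotation of the colour channels around grey
    theta = rng.uniform(-0.2 * s, 0.2 * s) * np.pi
    c, sn = np.cos(theta), np.sin(theta)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    u, v = r - g, (r + g) / 2 - b
    u2, v2 = c * u - sn * v, sn * u + c * v
    lum = img.mean(axis=2)
    img = np.stack([lum + u2 / 2 + v2 / 3, lum - u2 / 2 + v2 / 3, lum - 2 * v2 / 3], axis=2)
    return img


def augment_patch(patch: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator) -> np.ndarray:
    """One augmented view (uint8 in, uint8 out, same size)."""
    size = patch.shape[0]
    img = patch.astype(np.float64)
    # random crop + resize back
    lo, hi = policy.crop_scale_range
    scale = rng.uniform(lo, hi)
    crop = max(8, int(round(size * np.sqrt(scale))))
    if crop < size:
        y = int(rng.integers(0, size - crop + 1))
        x = int(rng.integers(0, size - crop + 1))
        img = resize(img[y : y + crop, x : x + crop], (size, size),
                     order=1, mode="reflect", anti_aliasing=False)
    if policy.color_distortion_strength > 0:
        img = _color_jitter(img, policy.color_distortion_strength, rng)
    if policy.blur_probability > 0 and rng.uniform() < policy.blur_probability:
        sigma = rng.uniform(*policy.blur_sigma_range)
        if sigma > 0:
            img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    return np.clip(img, 0, 255).astype(np.uint8)


def augment_pair(
    patch: np.ndarray, policy: AugmentationPolicy, rng_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one patch; reproducible by seed."""
    rng = np.random.default_rng(rng_seed)
    return augment_patch(patch, policy, rng), augment_patch(patch, policy, rng)


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("undefined similarity for zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class EmbeddingBatch:
    """2K augmented items: backbone features f, projected z, positive pairing."""

    f: np.ndarray | None
    z: Tensor | np.ndarray
    pair_index: np.ndarray  # pair_index[i] = index of i's positive partner

    def __post_init__(self):
        z = self.z.data if isinstance(self.z, Tensor) else np.asarray(self.z)
        n = z.shape[0]
        if n < 2 or n % 2:
            raise ValueError("an embedding batch holds 2K >= 2 items")
        pi = np.asarray(self.pair_index)
        if (pi.shape != (n,) or not np.array_equal(pi[pi], np.arange(n))
                or (pi == np.arange(n)).any()):
            raise ValueError("pair_index must pair every item with one partner")
        self.pair_index = pi

    @classmethod
    def interleaved(cls, z, f=None) -> "EmbeddingBatch":
        """Pairing convention (0,1), (2,3), ...: views of one patch adjacent."""
        n = (z.data if isinstance(z, Tensor) else z).shape[0]
        pairs = np.arange(n).reshape(-1, 2)[:, ::-1].ravel()
        return cls(f=f, z=z, pair_index=pairs)


def nt_xent_loss(batch: EmbeddingBatch | Tensor | np.ndarray, tau: float = 0.5,
                 pair_index: np.ndarray | None = None) -> Tensor:
    """Mean contrastive loss over all 2K ordered positive pairs.

    Accepts an :class:`EmbeddingBatch`, or a raw (2K, d) array/tensor with
    ``pair_index`` (interleaved pairing assumed when omitted).  Returns a
    scalar :class:`Tensor` so the loss is differentiable when ``z`` is.
    """
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    if isinstance(batch, EmbeddingBatch):
        z, pair_index = batch.z, batch.pair_index
    else:
        z = batch
        if pair_index is None:
            n = (z.data if isinstance(z, Tensor) else np.asarray(z)).shape[0]
            pair_index = np.arange(n).reshape(-1, 2)[:, ::-1].ravel()
    if not isinstance(z, Tensor):
        z = Tensor(np.asarray(z))
    n = z.shape[0]
    norms_sq = (z * z).sum(axis=1, keepdims=True)
    if (norms_sq.data <= 0).any():
        raise ValueError("undefined similarity for zero vector")
    zn = z / norms_sq.sqrt()
    sims = (zn @ zn.T) * (1.0 / tau)
    # exclude k == i from the denominator by masking the diagonal
    masked = sims + Tensor(np.where(np.eye(n, dtype=bool), -1e9, 0.0))
    logp = masked.log_softmax(axis=-1)
    picked = logp[np.arange(n), pair_index]
    return -picked.mean()


class FeatureExtractor(Module):
    """Residual-CNN backbone (+ optional projection head during pre-training)."""

    def __init__(self, backbone: ResNetBackbone, projection_head: MLP | None = None,
                 preset: str = "tiny"):
        super().__init__()
        self.backbone = backbone
        if projection_head is not None:
            self.projection_head = projection_head
        else:
            object.__setattr__(self, "projection_head", None)
        self.preset = preset
        self.feature_dim = backbone.feature_dim

    @classmethod
    def create(cls, preset: str, rng: np.random.Generator,
               with_projection: bool = True, projection_dim: int | None = None):
        backbone = ResNetBackbone.preset(preset, rng)
        head = None
        if with_projection:
            d = backbone.feature_dim
            proj_out = projection_dim or (128 if d >= 128 else d)
            head = MLP(d, d, proj_out, rng, activation="relu")
        return cls(backbone, head, preset=preset)

    @staticmethod
    def preprocess(patches: np.ndarray) -> Tensor:
        """uint8 (B, H, W, 3) → normalised float tensor (B, 3, H, W)."""
        x = np.asarray(patches, dtype=np.float32) / 255.0
        x = (x - _PIX_MEAN) / _PIX_STD
        return Tensor(x.transpose(0, 3, 1, 2))

    def forward(self, patches: np.ndarray) -> Tensor:
        """Backbone features only — the projection head never appears here."""
        return self.backbone(self.preprocess(patches))

    def project(self, patches: np.ndarray) -> tuple[Tensor, Tensor]:
        if self.projection_head is None:
            raise RuntimeError("extractor has no projection head (inference-only)")
        f = self.forward(patches)
        return f, self.projection_head(f)

    def extract(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference-mode embedding of a stack of patches."""
        patches = np.asarray(patches)
        out = []
        for i in range(0, len(patches), batch_size):
            out.append(self.forward(patches[i : i + batch_size]).data.copy())
        return np.concatenate(out, axis=0)

    def strip_projection_head(self) -> "FeatureExtractor":
        return FeatureExtractor(self.backbone, None, preset=self.preset)

    # ------------------------------------------------------------- checkpoints
    def save(self, path: str | Path, meta: dict | None = None):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.backbone.state_dict())
        sidecar = {
            "preset": self.preset,
            "feature_dim": self.feature_dim,
            "stage_channels": list(self.backbone.stage_channels),
            "blocks_per_stage": list(self.backbone.blocks_per_stage),
        }
        sidecar.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureExtractor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        backbone = ResNetBackbone(
            sidecar["stage_channels"], sidecar["blocks_per_stage"], np.random.default_rng(0)
        )
        with np.load(path.with_suffix(".npz")) as data:
            backbone.load_state_dict(dict(data))
        return cls(backbone, None, preset=sidecar.get("preset", "custom"))


@dataclass
class PretrainConfig:
    steps: int = 100
    batch_size: int = 32          # K source patches per step
    lr: float = 1e-4
    tau: float = 0.5
    seed: int = 0
    backbone: str = "tiny"
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)


def pretrain(patches: list[np.ndarray] | np.ndarray, config: PretrainConfig
             ) -> tuple[FeatureExtractor, list[float]]:
    """Contrastive pre-training; returns (extractor without head, loss log).

    ``patches`` is the pool of uint8 RGB tiles sampled from at each step.
    Optimised with Adam under cosine-annealed learning rate.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("empty patch stream")
    rng = np.random.default_rng(config.seed)
    model = FeatureExtractor.create(config.backbone, rng, with_projection=True)
    opt = Adam(model.parameters(), lr=config.lr)
    losses: list[float] = []
    for step in range(config.steps):
        opt.lr = cosine_annealing_lr(step, config.steps, config.lr)
        idx = rng.integers(0, len(patches), size=min(config.batch_size, len(patches)))
        views = []
        for i in idx:
            a, b = augment_pair(patches[i], config.policy, int(rng.integers(0, 2**31 - 1)))
            views.extend([a, b])
        f, z = model.project(np.stack(views))
        loss = nt_xent_loss(EmbeddingBatch.interleaved(z, f=f.data), tau=config.tau)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return model.strip_projection_head(), losses


def extract_features(extractor: FeatureExtractor, patch_grid: PatchGrid,
                     batch_size: int = 64) -> np.ndarray:
    """Node feature matrix F (N, D); row i embeds patch i of the grid."""
    return extractor.extract(np.stack(patch_grid.patches), batch_size=batch_size)
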