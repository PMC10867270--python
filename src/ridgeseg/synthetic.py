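"""Synthetic farmland ridge scenes.

The real drone imagery this package targets is not publicly deposited, so
this module synthesises image/mask pairs with the same gross statistics:
thin, narrow, roughly axis-aligned ridge strips of bare yellow-brown soil
crossing a green crop canopy, with irregular edge texture and — on the hard
setting — small bright "vacancy" speckles inside the crop that resemble
ridge fragments but are labelled background. Every other module of the
package is testable against these scenes without any download.

Determinism contract: an identical :class:`SceneSpec` (including its seed)
produces bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .raster import read_image, read_mask, write_image, write_mask

__all__ = ["SceneSpec", "Scene", "DatasetIndex", "DatasetEntry",
           "generate_scene", "render_scene", "generate_dataset",
           "generate_large_scene"]

# Base colours (RGB) of the three scene materials; per-pixel noise is added.
CROP_COLOR = np.array([62, 112, 48], dtype=np.float32)     # green canopy
RIDGE_COLOR = np.array([168, 138, 82], dtype=np.float32)   # bare-soil strip
VACANCY_COLOR = np.array([214, 206, 178], dtype=np.float32)  # bright bare patch

ORIENTATIONS = ("horizontal", "vertical", "mixed")
DIFFICULTIES = ("easy", "hard")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``edge_roughness`` is the standard deviation (pixels) of the smoothed
    per-row/column jitter applied to each ridge boundary; ``vacancy_density``
    is the expected fraction of crop (label-0) area covered by vacancy
    speckles, whose diameters are drawn from ``vacancy_size_range``.
    """

    height: int = 512
    width: int = 512
    orientation: str = "mixed"
    n_ridges: int = 4
    ridge_width_range: tuple[int, int] = (10, 26)
    edge_roughness: float = 2.5
    vacancy_density: float = 0.02
    vacancy_size_range: tuple[int, int] = (2, 6)
    background_noise_sd: float = 12.0
    difficulty: str = "hard"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @classmethod
    def preset(cls, difficulty: str, **overrides) -> "SceneSpec":
        """The two study conditions: ``easy`` (clean axis-aligned stripes,
        no distractors) and ``hard`` (rough edges, vacancy speckles)."""
        if difficulty == "easy":
            base = dict(edge_roughness=0.0, vacancy_density=0.0,
                        background_noise_sd=8.0, difficulty="easy")
        elif difficulty == "hard":
            base = dict(edge_roughness=2.5, vacancy_density=0.02,
                        background_noise_sd=12.0, difficulty="hard")
        else:
            raise ValueError(f"difficulty must be one of {DIFFICULTIES}, got {difficulty!r}")
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}, "
                             f"got {self.orientation!r}")
        if self.difficulty not in DIFFICULTIES:
            raise ValueError(f"difficulty must be one of {DIFFICULTIES}")
        if self.height < 1 or self.width < 1:
            raise ValueError("scene dimensions must be positive")
        wmin, wmax = self.ridge_width_range
        if wmin < 1 or wmax < wmin:
            raise ValueError(f"invalid ridge_width_range {self.ridge_width_range}")
        if self.n_ridges < 0:
            raise ValueError("n_ridges must be non-negative")
        if self.n_ridges > 0 and wmax >= min(self.height, self.width) / self.n_ridges:
            raise ValueError(
                f"stripes cannot fit: max ridge width {wmax} must be below "
                f"min(height, width)/n_ridges = {min(self.height, self.width) / self.n_ridges:.1f}")
        if not 0.0 <= self.vacancy_density <= 1.0:
            raise ValueError("vacancy_density must lie in [0, 1]")
        if self.edge_roughness < 0:
            raise ValueError("edge_roughness must be non-negative")
        vmin, vmax = self.vacancy_size_range
        if vmin < 1 or vmax < vmin:
            raise ValueError(f"invalid vacancy_size_range {self.vacancy_size_range}")

    def replace(self, **changes) -> "SceneSpec":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Scene:
    """A rendered scene: image, label mask, and the vacancy footprint."""

    image: np.ndarray        # H x W x 3 uint8
    mask: np.ndarray         # H x W uint8 in {0, 1}
    vacancy_mask: np.ndarray  # H x W bool, True where a vacancy speckle sits
    spec: SceneSpec


def _smooth_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Correlated boundary jitter: white noise smoothed with a Hanning
    window, rescaled so its sample std equals ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, 1.0, n)
    win = np.hanning(9)
    win /= win.sum()
    sm = np.convolve(raw, win, mode="same")
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def _paint_ridges(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    wmin, wmax = spec.ridge_width_range
    for i in range(spec.n_ridges):
        if spec.orientation == "mixed":
            orient = "vertical" if rng.random() < 0.5 else "horizontal"
        else:
            orient = spec.orientation
        # a vertical ridge spans all rows; its centre sits in slot i across W
        across = spec.width if orient == "vertical" else spec.height
        along = spec.height if orient == "vertical" else spec.width
        centre = (i + 0.5) * across / spec.n_ridges
        w = int(rng.integers(wmin, wmax + 1))
        jit_lo = _smooth_jitter(rng, along, spec.edge_roughness)
        jit_hi = _smooth_jitter(rng, along, spec.edge_roughness)
        lo = np.rint(centre - w / 2 + jit_lo).astype(np.intp)
        hi = lo + w + np.rint(jit_hi - jit_lo).astype(np.intp)
        hi = np.maximum(hi, lo + 1)  # never collapse below 1 px
        lo = np.clip(lo, 0, across - 1)
        hi = np.clip(hi, 1, across)
        pos = np.arange(across)
        band = (pos[None, :] >= lo[:, None]) & (pos[None, :] < hi[:, None])
        if orient == "vertical":
            mask |= band.astype(np.uint8)
        else:
            mask |= band.T.astype(np.uint8)
    return mask


def _paint_vacancies(spec: SceneSpec, mask: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    vac = np.zeros_like(mask, dtype=bool)
    if spec.vacancy_density <= 0:
        return vac
    background = mask == 0
    target = spec.vacancy_density * background.sum()
    vmin, vmax = spec.vacancy_size_range
    placed = 0.0
    mean_area = np.pi * ((vmin + vmax) / 4.0) ** 2
    max_tries = int(10 * target / max(mean_area, 1.0)) + 100
    for _ in range(max_tries):
        if placed >= target:
            break
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        a = max(rng.uniform(vmin, vmax) / 2.0, 0.5)
        b = max(rng.uniform(vmin, vmax) / 2.0, 0.5)
        # evaluate the ellipse only on its bounding-box window
        y0, y1 = max(int(cy - a), 0), min(int(cy + a) + 2, spec.height)
        x0, x1 = max(int(cx - b), 0), min(int(cx + b) + 2, spec.width)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None]
        xx = np.arange(x0, x1)[None, :]
        blob = (((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2) <= 1.0
        blob &= background[y0:y1, x0:x1] & ~vac[y0:y1, x0:x1]
        n_new = int(blob.sum())
        if n_new:
            vac[y0:y1, x0:x1] |= blob
            placed += n_new
    return vac


def _render_image(spec: SceneSpec, mask: np.ndarray, vac: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = CROP_COLOR
    img[mask == 1] = RIDGE_COLOR
    img[vac] = VACANCY_COLOR
    # low-frequency canopy brightness variation plus per-pixel noise
    fy = rng.uniform(1.0, 3.0)
    fx = rng.uniform(1.0, 3.0)
    field = 6.0 * np.outer(np.sin(2 * np.pi * fy * np.arange(h) / max(h, 1) + rng.uniform(0, 2 * np.pi)),
                           np.cos(2 * np.pi * fx * np.arange(w) / max(w, 1) + rng.uniform(0, 2 * np.pi)))
    img += field[:, :, None].astype(np.float32)
    if spec.background_noise_sd > 0:
        img += rng.normal(0.0, spec.background_noise_sd, img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_scene(spec: SceneSpec) -> Scene:
    """Render a full scene, including the vacancy footprint."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = _paint_ridges(spec, rng)
    vac = _paint_vacancies(spec, mask, rng)
    img = _render_image(spec, mask, vac, rng)
    return Scene(image=img, mask=mask, vacancy_mask=vac, spec=spec)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, mask) pair from ``spec``."""
    sc = render_scene(spec)
    return sc.image, sc.mask


def generate_large_scene(height: int, width: int,
                         spec_template: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene at arbitrary (>= 512) size with the template's look.

    The ridge count is scaled with the raster size so the stripe density
    matches the template's.
    """
    if height < 512 or width < 512:
        raise ValueError(f"large scenes must be at least 512x512, got {height}x{width}")
    scale = min(height, width) / min(spec_template.height, spec_template.width)
    n = max(1, int(round(spec_template.n_ridges * scale)))
    spec = spec_template.replace(height=height, width=width, n_ridges=n)
    return generate_scene(spec)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetEntry:
    image: str  # path relative to the dataset root
    mask: str
    split: str  # "train" or "val"


@dataclass
class DatasetIndex:
    """Manifest of a generated tile dataset (paths relative to ``root``)."""

    root: Path
    entries: list[DatasetEntry]
    tile_size: int
    split_ratio: tuple[int, int]

    def __post_init__(self):
        self.root = Path(self.root)
        splits = {e.split for e in self.entries}
        if not splits <= {"train", "val"}:
            raise ValueError(f"unknown split tags: {splits - {'train', 'val'}}")

    def split_entries(self, split: str) -> list[DatasetEntry]:
        return [e for e in self.entries if e.split == split]

    def load_pairs(self, split: str) -> list[tuple[np.ndarray, np.ndarray]]:
        """Read all (image, mask) arrays of one split into memory."""
        return [(read_image(self.root / e.image), read_mask(self.root / e.mask))
                for e in self.split_entries(split)]

    def save(self, path: Path | None = None) -> Path:
        path = Path(path) if path else self.root / "index.json"
        payload = {
            "tile_size": self.tile_size,
            "split_ratio": list(self.split_ratio),
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: Path) -> "DatasetIndex":
        path = Path(path)
        if path.is_dir():
            path = path / "index.json"
        payload = json.loads(path.read_text())
        return cls(root=path.parent,
                   entries=[DatasetEntry(**e) for e in payload["entries"]],
                   tile_size=payload["tile_size"],
                   split_ratio=tuple(payload["split_ratio"]))


def split_sizes(n_tiles: int, split_ratio: tuple[int, int]) -> tuple[int, int]:
    """Train/val counts for a ratio like 5:1.

    When ``n_tiles`` is not divisible by the ratio sum, the remainder goes to
    the training split, so the validation fraction never exceeds its nominal
    share.
    """
    a, b = split_ratio
    if a < 1 or b < 1:
        raise ValueError("split ratio parts must be positive")
    unit = n_tiles // (a + b)
    n_val = unit * b
    return n_tiles - n_val, n_val


def tile_seed(master_seed: int, index: int) -> int:
    """Deterministic, well-separated per-tile seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_tiles: int, split_ratio: tuple[int, int], root: Path,
                     spec_template: SceneSpec) -> DatasetIndex:
    """Write ``n_tiles`` image/mask PNG pairs plus an index manifest.

    Per-tile seeds derive deterministically from the template's seed, so the
    same call reproduces the same dataset byte for byte.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be positive")
    root = Path(root)
    try:
        (root / "images").mkdir(parents=True, exist_ok=True)
        (root / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset root {root}: {exc}") from exc
    n_train, _ = split_sizes(n_tiles, split_ratio)
    entries = []
    for i in range(n_tiles):
        spec = spec_template.replace(seed=tile_seed(spec_template.seed, i))
        img, mask = generate_scene(spec)
        rel_img = f"images/tile_{i:05d}.png"
        rel_mask = f"masks/tile_{i:05d}.png"
        write_image(img, root / rel_img)
        write_mask(mask, root / rel_mask)
        entries.append(DatasetEntry(image=rel_img, mask=rel_mask,
                                    split="train" if i < n_train else "val"))
    index = DatasetIndex(root=root, entries=entries,
                         tile_size=spec_template.height, split_ratio=tuple(split_ratio))
    index.save()
    return index
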