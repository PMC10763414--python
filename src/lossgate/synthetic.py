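"""Seeded synthetic patch corpora for noisy-pool active-learning experiments.

Real histopathology pools mix clean tissue patches with artifact ("noisy")
patches that an annotator cannot label: near-empty tiles picked up around the
tissue, foreign substances, out-of-focus regions, air bubbles, tissue folds.
This module renders a desk-scale stand-in: three colour/texture classes that
play the role of benign / dysplasia / malignant tissue, plus a small fraction
of noisy patches drawn from two artifact families,

* ``empty_foreign`` — near-uniform pale background with at most a few coloured
  specks (almost no class signal; low colour saturation), and
* ``capture_artifact`` — a clean patch degraded by an occluding bubble disc or
  a dark fold band and then defocused with a Gaussian blur (corrupted class
  signal; low high-frequency energy).

Classes are separable by simple colour statistics, so a small classifier can
learn the task, while the artifact families are statistically distinguishable
from clean tissue "in principle" — mirroring what makes the real problem
well-posed without attempting visual realism.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pathlib import Path
from PIL import Image
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "NOISY",
    "Patch",
    "ClassTexture",
    "NoiseParams",
    "CorpusSpec",
    "Corpus",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
    "mean_saturation",
    "high_freq_energy",
]

CLASS_NAMES = ("benign", "dysplasia", "malignant")
NOISY = "noisy"
NOISE_TYPES = ("none", "empty_foreign", "capture_artifact")

MANIFEST_COLUMNS = ["id", "filename", "oracle_answer", "noise_type", "split"]


class CorpusError(ValueError):
    """Invalid corpus configuration or on-disk corpus."""


@dataclass(frozen=True)
class Patch:
    """One patch image together with its hidden oracle answer.

    ``oracle_answer`` is what a pathologist-oracle would reply when asked to
    label the patch: one of the three tissue classes, or ``"noisy"`` meaning
    the patch cannot be labelled.  Everything outside the oracle simulator and
    the metrics treats this field as hidden.
    """

    id: str
    image: np.ndarray  # (H, W, 3) float64 in [0, 1]
    oracle_answer: str
    noise_type: str
    split: str  # "pool" | "test"

    def __post_init__(self) -> None:
        clean = self.oracle_answer in CLASS_NAMES
        if clean != (self.noise_type == "none"):
            raise CorpusError(
                f"patch {self.id}: noise_type={self.noise_type!r} inconsistent "
                f"with oracle_answer={self.oracle_answer!r}"
            )


@dataclass(frozen=True)
class ClassTexture:
    """Generative texture parameters for one clean class."""

    base_color: tuple[float, float, float]
    blob_color: tuple[float, float, float]
    blob_density: float  # expected blob count on a 32x32 patch (scales with area)
    blob_scale: float  # mean blob radius in pixels at patch_size 32


@dataclass(frozen=True)
class NoiseParams:
    """Generative parameters of the two artifact families."""

    blank_level: float = 0.94  # background intensity of empty/foreign patches
    max_specks: int = 3
    blur_sigma: float = 2.0  # defocus strength for capture artifacts
    occlusion_fraction: float = 0.35  # bubble-disc area fraction of the patch
    empty_foreign_share: float = 0.5  # relative frequency of the two families


DEFAULT_TEXTURES: dict[str, ClassTexture] = {
    # Hues loosely evoke an H&E palette; densities differ so that texture, not
    # only mean colour, carries class information.
    "benign": ClassTexture((0.93, 0.76, 0.84), (0.78, 0.36, 0.55), 6.0, 2.6),
    "dysplasia": ClassTexture((0.80, 0.70, 0.90), (0.48, 0.28, 0.66), 13.0, 2.0),
    "malignant": ClassTexture((0.68, 0.74, 0.92), (0.24, 0.30, 0.58), 24.0, 1.5),
}


@dataclass(frozen=True)
class CorpusSpec:
    """Declarative recipe for one synthetic corpus.

    Defaults mirror the corpus structure the method targets at desk scale:
    a pool of 3,000 clean patches (1,000 per class) plus ~5.8% noisy patches,
    and a balanced clean-only test split of 300.
    """

    n_clean_per_class: int = 1000
    noise_fraction: float = 0.058
    patch_size: int = 32
    n_test_per_class: int = 100
    class_texture_params: dict[str, ClassTexture] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clean_per_class < 1:
            raise CorpusError("n_clean_per_class must be >= 1")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise CorpusError("noise_fraction must be in [0, 1)")
        if self.patch_size < 8:
            raise CorpusError("patch_size must be >= 8")
        if self.n_test_per_class < 0:
            raise CorpusError("n_test_per_class must be >= 0")
        if set(self.class_texture_params) != set(CLASS_NAMES):
            raise CorpusError(f"class_texture_params must cover {CLASS_NAMES}")
        if not (0.0 <= self.noise_params.empty_foreign_share <= 1.0):
            raise CorpusError("empty_foreign_share must be in [0, 1]")

    @property
    def n_noisy(self) -> int:
        """Noisy pool count so that noisy/(clean+noisy) ~= noise_fraction."""
        n_clean = self.n_clean_per_class * len(CLASS_NAMES)
        return int(round(self.noise_fraction * n_clean / (1.0 - self.noise_fraction)))


class Corpus:
    """An in-memory corpus: patches plus indexed access by id and split."""

    def __init__(self, patches: list[Patch], spec: CorpusSpec | None = None):
        self.patches = list(patches)
        self.spec = spec
        self._by_id = {p.id: p for p in self.patches}
        if len(self._by_id) != len(self.patches):
            raise CorpusError("duplicate patch ids")

    def __len__(self) -> int:
        return len(self.patches)

    def __getitem__(self, patch_id: str) -> Patch:
        return self._by_id[patch_id]

    def __contains__(self, patch_id: str) -> bool:
        return patch_id in self._by_id

    @property
    def pool_ids(self) -> list[str]:
        return [p.id for p in self.patches if p.split == "pool"]

    @property
    def test_ids(self) -> list[str]:
        return [p.id for p in self.patches if p.split == "test"]

    def images(self, ids: list[str]) -> np.ndarray:
        """Stack images for ``ids`` into an (n, H, W, 3) array."""
        return np.stack([self._by_id[i].image for i in ids])

    def labels(self, ids: list[str]) -> np.ndarray:
        """Integer class labels for clean ids (error on noisy ids)."""
        out = np.empty(len(ids), dtype=np.int64)
        for k, i in enumerate(ids):
            ans = self._by_id[i].oracle_answer
            if ans == NOISY:
                raise CorpusError(f"patch {i} is noisy and has no class label")
            out[k] = CLASS_NAMES.index(ans)
        return out

    def manifest(self) -> pd.DataFrame:
        rows = [
            (p.id, f"{p.id}.png", p.oracle_answer, p.noise_type, p.split)
            for p in self.patches
        ]
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# rendering


def _quantize(img: np.ndarray) -> np.ndarray:
    # keep images exactly representable as 8-bit PNG so disk round-trips are
    # lossless
    return np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0


def _disc_mask(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _render_clean(tex: ClassTexture, size: int, rng: np.random.Generator) -> np.ndarray:
    area_scale = (size / 32.0) ** 2
    img = np.empty((size, size, 3))
    img[:] = np.asarray(tex.base_color) + rng.normal(0.0, 0.035, size=3)
    n_blobs = max(1, rng.poisson(tex.blob_density * area_scale))
    r_mean = tex.blob_scale * size / 32.0
    blob = np.asarray(tex.blob_color)
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, size=2)
        r = max(0.8, rng.normal(r_mean, 0.3 * r_mean))
        mask = _disc_mask(size, cx, cy, r)
        img[mask] = blob + rng.normal(0.0, 0.04, size=3)
    img += rng.normal(0.0, 0.03, size=img.shape)
    return _quantize(img)


def _render_empty_foreign(
    textures: dict[str, ClassTexture],
    params: NoiseParams,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    # near-blank background carrying a faint, class-ambiguous stain tint
    # (smeared dye, dust): enough colour to confuse, far too little to carry
    # class signal — mean saturation stays well below any clean class
    bases = np.array([textures[c].base_color for c in CLASS_NAMES])
    mix = rng.dirichlet(np.ones(len(CLASS_NAMES))) @ bases
    w = rng.uniform(0.02, 0.10)
    img = np.full((size, size, 3), params.blank_level) * (1 - w) + w * mix
    img += rng.normal(0.0, 0.01, size=img.shape)  # faint scanner grain
    for _ in range(rng.integers(0, params.max_specks + 1)):
        cx, cy = rng.uniform(0, size, size=2)
        r = rng.uniform(0.8, 0.06 * size)
        speck = rng.uniform(0.2, 0.8, size=3)
        img[_disc_mask(size, cx, cy, r)] = speck
    return _quantize(img)


def _render_capture_artifact(
    textures: dict[str, ClassTexture],
    params: NoiseParams,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    # capture failures typically straddle tissue boundaries, so start from a
    # pixelwise blend of two classes' textures (class-ambiguous by
    # construction), then corrupt it
    a, b = rng.choice(len(CLASS_NAMES), size=2, replace=False)
    w = rng.uniform(0.3, 0.7)
    img = (
        w * _render_clean(textures[CLASS_NAMES[a]], size, rng)
        + (1 - w) * _render_clean(textures[CLASS_NAMES[b]], size, rng)
    )
    kind = rng.integers(3)  # 0 = defocus only, 1 = bubble discs, 2 = fold band
    if kind == 1:
        target = params.occlusion_fraction * size * size
        covered = 0.0
        while covered < target:
            cx, cy = rng.uniform(0, size, size=2)
            r = rng.uniform(0.15, 0.3) * size
            mask = _disc_mask(size, cx, cy, r)
            img[mask] = 0.97 + rng.normal(0.0, 0.01, size=3)
            covered += mask.sum()
    elif kind == 2:
        width = max(2, int(round(size / 6)))
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:size, 0:size]
        d = (xx - size / 2) * np.cos(theta) + (yy - size / 2) * np.sin(theta)
        offset = rng.uniform(-size / 4, size / 4)
        img[np.abs(d - offset) <= width / 2] *= 0.25
    # every capture artifact is also defocused: out-of-focus scanning is the
    # dominant failure mode, and it is what suppresses high-frequency energy
    sigma = params.blur_sigma * size / 32.0
    img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0.0))
    return _quantize(img)


# ---------------------------------------------------------------------------
# image statistics used by the artifact invariants


def mean_saturation(img: np.ndarray) -> float:
    """Mean HSV-style saturation, (max-min)/max per pixel."""
    mx = img.max(axis=-1)
    mn = img.min(axis=-1)
    return float(np.mean((mx - mn) / np.maximum(mx, 1e-8)))


def high_freq_energy(img: np.ndarray) -> float:
    """Mean squared Laplacian of the grayscale image (defocus indicator)."""
    gray = img.mean(axis=-1)
    return float(np.mean(ndimage.laplace(gray) ** 2))


# ---------------------------------------------------------------------------
# generation and I/O


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Render a corpus from ``spec``; identical spec+seed gives identical bits.

    The pool holds ``3 * n_clean_per_class`` clean patches plus ``spec.n_noisy``
    noisy ones; the test split holds ``n_test_per_class`` clean patches per
    class and no noisy patches.  Clean, test and noisy patches are drawn from
    independent child streams of ``spec.seed``, so setting ``noise_fraction=0``
    leaves every clean patch bit-identical — that is what makes matched
    noisy/clean corpus pairs possible.
    """
    ss = np.random.SeedSequence([int(spec.seed), 0x10553A7E])
    rng_clean, rng_test, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    size = spec.patch_size
    textures = spec.class_texture_params
    patches: list[Patch] = []

    # id families (c=clean pool, n=noisy pool, t=test) are numbered
    # independently so matched corpora that differ only in noise_fraction
    # share ids for every common patch
    counter = 0
    for cls in CLASS_NAMES:
        for _ in range(spec.n_clean_per_class):
            patches.append(
                Patch(
                    id=f"c{counter:06d}",
                    image=_render_clean(textures[cls], size, rng_clean),
                    oracle_answer=cls,
                    noise_type="none",
                    split="pool",
                )
            )
            counter += 1
    counter = 0
    for _ in range(spec.n_noisy):
        if rng_noise.uniform() < spec.noise_params.empty_foreign_share:
            img = _render_empty_foreign(textures, spec.noise_params, size, rng_noise)
            ntype = "empty_foreign"
        else:
            img = _render_capture_artifact(textures, spec.noise_params, size, rng_noise)
            ntype = "capture_artifact"
        patches.append(
            Patch(
                id=f"n{counter:06d}",
                image=img,
                oracle_answer=NOISY,
                noise_type=ntype,
                split="pool",
            )
        )
        counter += 1
    counter = 0
    for cls in CLASS_NAMES:
        for _ in range(spec.n_test_per_class):
            patches.append(
                Patch(
                    id=f"t{counter:06d}",
                    image=_render_clean(textures[cls], size, rng_test),
                    oracle_answer=cls,
                    noise_type="none",
                    split="test",
                )
            )
            counter += 1
    return Corpus(patches, spec=spec)


def clean_twin(spec: CorpusSpec) -> CorpusSpec:
    """The matched noise-free spec: same seed, same clean patches, no noise."""
    return replace(spec, noise_fraction=0.0)


def write_corpus(corpus: Corpus, directory: str | Path) -> Path:
    """Write one 8-bit RGB PNG per patch plus ``manifest.csv``; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in corpus.patches:
        arr = np.round(p.image * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(directory / f"{p.id}.png")
    manifest = corpus.manifest()
    path = directory / "manifest.csv"
    with io.open(path, "w", encoding="utf-8", newline="\n") as fh:
        manifest.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_corpus(directory: str | Path) -> Corpus:
    """Read a corpus written by :func:`write_corpus`.

    Raises :class:`CorpusIOError` naming the offending patch id when a PNG
    listed in the manifest is missing or malformed.
    """
    directory = Path(directory)
    path = directory / "manifest.csv"
    if not path.exists():
        raise CorpusIOError(f"no manifest.csv in {directory}")
    manifest = pd.read_csv(path, dtype=str)
    if list(manifest.columns) != MANIFEST_COLUMNS:
        raise CorpusIOError(f"manifest columns {list(manifest.columns)} unexpected")
    patches = []
    for row in manifest.itertuples(index=False):
        png = directory / row.filename
        if not png.exists():
            raise CorpusIOError(f"patch {row.id}: missing image file {row.filename}")
        try:
            arr = np.asarray(Image.open(png).convert("RGB"), dtype=np.float64) / 255.0
        except Exception as exc:  # pragma: no cover - PIL error text varies
            raise CorpusIOError(f"patch {row.id}: unreadable PNG {row.filename}") from exc
        patches.append(
            Patch(
                id=row.id,
                image=arr,
                oracle_answer=row.oracle_answer,
                noise_type=row.noise_type,
                split=row.split,
            )
        )
    return Corpus(patches)


class CorpusIOError(IOError):
    """On-disk corpus is missing files or inconsistent with its manifest."""
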