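"""Synthetic particle-crop image generator.

Backgrounded-membrane imaging yields small grayscale crops of individual
subvisible particles: dark, roughly convex blobs on a near-white membrane
background.  This module renders controllable stand-ins for such crops so
that every downstream stage (standardization, CNN training, fingerprinting,
goodness-of-fit testing) can be exercised and validated without instrument
data.

Each particle class is a :class:`ClassSpec`: a star-shaped region whose
boundary radius is a truncated-Fourier perturbation of a circle,

    R(theta) = r * (1 + roughness * sum_k a_k cos(k * theta + phi_k)),

filled with a configurable interior intensity plus speckle texture, ringed
by an edge band, and embedded in additive pixel noise.  The radial-Fourier
blob (rather than, say, thresholded filtered noise) keeps the rendered area
analytically checkable: with roughness 0 the particle is an exact disc.

Intensity convention: particles are dark on a light background (membrane
imaging).  This is the single place where the convention lives; invert the
rendered array to flip it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "ClassSpec",
    "ParticleImage",
    "DatasetManifest",
    "render_particle",
    "generate_dataset",
    "perturb_spec",
    "load_manifest",
]

#: rendered side lengths are clipped to this range (pixels); keeps crops in
#: a plausible > 2 um particle regime while exercising both the padding
#: (< 32 px) and cropping (> 32 px) branches downstream.
SIDE_RANGE = (8, 64)

SPLITS = ("train", "val", "test", "none")


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class ClassSpec:
    """Morphology recipe for one synthetic particle class.

    Parameters
    ----------
    name
        Class label.
    mean_radius_px
        Mean particle radius in pixels (> 0).
    radius_cv
        Coefficient of variation of the particle radius, in [0, 1).
    boundary_roughness
        Amplitude of the radial Fourier perturbation (>= 0; 0 = exact disc).
    boundary_harmonics
        Number of radial Fourier modes (>= 1).
    interior_level
        Mean interior intensity in [0, 1] (0 = black).
    edge_level
        Intensity of the boundary ring, in [0, 1].
    edge_width_px
        Width of the boundary ring in pixels (>= 0; 0 = no ring).
    texture_sd
        Standard deviation of interior speckle noise (>= 0).
    background_level
        Background (membrane) intensity, near white.
    noise_sd
        Standard deviation of global additive pixel noise (>= 0).
    """

    name: str
    mean_radius_px: float = 8.0
    radius_cv: float = 0.15
    boundary_roughness: float = 0.1
    boundary_harmonics: int = 4
    interior_level: float = 0.35
    edge_level: float = 0.2
    edge_width_px: float = 1.5
    texture_sd: float = 0.05
    background_level: float = 0.92
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.mean_radius_px <= 0:
            raise ParameterError("mean_radius_px must be positive")
        if not (0 <= self.radius_cv < 1):
            raise ParameterError("radius_cv must be in [0, 1)")
        if self.boundary_roughness < 0:
            raise ParameterError("boundary_roughness must be >= 0")
        if int(self.boundary_harmonics) < 1:
            raise ParameterError("boundary_harmonics must be >= 1")
        for attr in ("interior_level", "edge_level", "background_level"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{attr} must be in [0, 1], got {v}")
        for attr in ("edge_width_px", "texture_sd", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ParameterError(f"{attr} must be >= 0")


@dataclass
class ParticleImage:
    """One grayscale particle crop.

    ``pixels`` holds intensities in [0, 1] as float64; 8-bit conversion
    happens only at the PNG boundary.
    """

    pixels: np.ndarray
    id: str = ""
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2D array")
        h, w = self.pixels.shape
        if h < 4 or w < 4:
            raise ParameterError("images must be at least 4x4 pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)

    @classmethod
    def from_uint8(cls, arr: np.ndarray, id: str = "", label: str = "unlabeled") -> "ParticleImage":
        return cls(np.asarray(arr, dtype=float) / 255.0, id=id, label=label)

    def save_png(self, path: Path | str) -> None:
        Image.fromarray(self.to_uint8(), mode="L").save(path)

    @classmethod
    def load_png(cls, path: Path | str, label: str = "unlabeled") -> "ParticleImage":
        arr = np.asarray(Image.open(path).convert("L"))
        return cls.from_uint8(arr, id=Path(path).stem, label=label)


@dataclass
class DatasetManifest:
    """Index of a generated dataset: (path, label, split) records.

    ``root`` is the directory the relative paths in ``records`` resolve
    against; ``spec_summary`` maps each label to its generator parameters.
    """

    records: pd.DataFrame
    root: Path
    seed: int
    spec_summary: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"path", "label", "split"}
        if not required.issubset(self.records.columns):
            raise ParameterError(f"manifest needs columns {sorted(required)}")
        bad = set(self.records["split"]) - set(SPLITS)
        if bad:
            raise ParameterError(f"unknown split tags: {sorted(bad)}")
        missing = set(self.records["label"]) - set(self.spec_summary)
        if self.spec_summary and missing:
            raise ParameterError(f"labels missing from spec summary: {sorted(missing)}")

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]

    def load_images(self, split: str | None = None) -> list[ParticleImage]:
        rows = self.records if split is None else self.subset(split)
        return [
            ParticleImage.load_png(Path(self.root) / r.path, label=r.label)
            for r in rows.itertuples()
        ]

    def save(self) -> None:
        root = Path(self.root)
        self.records.to_csv(root / "manifest.csv", index=False)
        meta = {"seed": int(self.seed), "specs": self.spec_summary}
        (root / "specs.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_manifest(root: Path | str) -> DatasetManifest:
    root = Path(root)
    records = pd.read_csv(root / "manifest.csv")
    meta = yaml.safe_load((root / "specs.yaml").read_text())
    return DatasetManifest(records=records, root=root, seed=int(meta["seed"]),
                           spec_summary=meta["specs"])


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _draw_radius(spec: ClassSpec, rng: np.random.Generator) -> float:
    r = spec.mean_radius_px * (1.0 + spec.radius_cv * rng.standard_normal())
    return max(r, 2.0)


def render_particle(spec: ClassSpec, rng_seed: int) -> ParticleImage:
    """Render one particle crop; bit-identical for identical (spec, seed).

    The side length is ``round(2 r) + 12`` (clipped to ``SIDE_RANGE``) for a
    particle radius ``r`` drawn from the class size distribution, so larger
    particles produce larger crops.
    """
    rng = np.random.default_rng(rng_seed)
    r = _draw_radius(spec, rng)
    side = int(np.clip(round(2.0 * r) + 12, *SIDE_RANGE))

    n_h = int(spec.boundary_harmonics)
    # per-harmonic amplitudes decay as 1/k so low modes dominate, as for
    # gently lobed particles; boundary_roughness sets the overall scale.
    amps = rng.uniform(-1.0, 1.0, size=n_h) / np.arange(1, n_h + 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_h)

    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - c, xx - c
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    pert = np.zeros_like(theta)
    for k in range(1, n_h + 1):
        pert += amps[k - 1] * np.cos(k * theta + phases[k - 1])
    radius = r * (1.0 + spec.boundary_roughness * pert)
    radius = np.maximum(radius, 1.0)

    inside = dist <= radius
    interior = dist <= (radius - spec.edge_width_px)
    edge = inside & ~interior

    img = np.full((side, side), spec.background_level, dtype=float)
    img[edge] = spec.edge_level
    img[interior] = spec.interior_level
    if spec.texture_sd > 0:
        texture = rng.normal(0.0, spec.texture_sd, size=img.shape)
        img[interior] += texture[interior]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return ParticleImage(img, id=f"{spec.name}-{rng_seed}", label=spec.name)


def perturb_spec(spec: ClassSpec, brightness_shift: float) -> ClassSpec:
    """Copy ``spec`` with interior and edge intensity shifted, geometry intact.

    This constructs a "subtle pair": two classes with identical shapes whose
    particles merely appear slightly brighter or darker — the hard case for
    any morphology-based classifier.
    """
    new_interior = spec.interior_level + brightness_shift
    new_edge = spec.edge_level + brightness_shift
    for v, attr in ((new_interior, "interior_level"), (new_edge, "edge_level")):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(
                f"brightness_shift {brightness_shift} pushes {attr} to {v}, outside [0, 1]"
            )
    return dataclasses.replace(spec, interior_level=new_interior, edge_level=new_edge)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _split_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n into len(fractions) buckets."""
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ParameterError("split fractions must be 3 nonnegative values summing to 1")
    raw = fr * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base.tolist()


def _image_seed(master: int, class_idx: int, img_idx: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(class_idx, img_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    split_fractions: tuple[float, float, float],
    seed: int,
    out_dir: Path | str,
) -> DatasetManifest:
    """Render ``n_per_class`` images per spec, write PNGs + manifest CSV.

    Split tags are assigned per class by a seeded shuffle with exact
    largest-remainder counts, so every class is represented in every
    nonempty split.  Identical arguments reproduce a byte-identical dataset.
    """
    if len(specs) == 0:
        raise ParameterError("need at least one class spec")
    if n_per_class <= 0:
        raise ParameterError("n_per_class must be positive")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ParameterError("class spec names must be unique")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, spec in enumerate(specs):
        cls_dir = out_dir / spec.name
        cls_dir.mkdir(exist_ok=True)
        counts = _split_counts(n_per_class, split_fractions)
        tags = np.repeat(["train", "val", "test"], counts)
        shuffler = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ci,)))
        tags = tags[shuffler.permutation(n_per_class)]
        for ii in range(n_per_class):
            img = render_particle(spec, _image_seed(seed, ci, ii))
            rel = f"{spec.name}/{spec.name}_{ii:05d}.png"
            img.save_png(out_dir / rel)
            rows.append({"path": rel, "label": spec.name, "split": tags[ii]})

    records = pd.DataFrame(rows, columns=["path", "label", "split"])
    summary = {s.name: dataclasses.asdict(s) for s in specs}
    manifest = DatasetManifest(records=records, root=out_dir, seed=int(seed),
                               spec_summary=summary)
    manifest.save()
    return manifest


def render_class(spec: ClassSpec, n: int, seed: int, class_idx: int = 0) -> list[ParticleImage]:
    """Render ``n`` images of one class in memory (no disk round-trip)."""
    return [render_particle(spec, _image_seed(seed, class_idx, i)) for i in range(n)]


# ---------------------------------------------------------------------------
# Preset class recipes (the canonical study conditions)
# ---------------------------------------------------------------------------

def default_study_specs() -> list[ClassSpec]:
    """Four well-separated classes with disjoint size/brightness/texture
    regimes, loosely modeled on an abraded-polymer protein surrogate, two
    protein particle populations, and a fatty-acid particle population."""
    return [
        ClassSpec("etfe", mean_radius_px=14, radius_cv=0.35, boundary_roughness=0.25,
                  boundary_harmonics=5, interior_level=0.15, edge_level=0.10,
                  edge_width_px=2.0, texture_sd=0.08, noise_sd=0.02),
        ClassSpec("protein_a", mean_radius_px=9, radius_cv=0.25, boundary_roughness=0.45,
                  boundary_harmonics=6, interior_level=0.55, edge_level=0.35,
                  edge_width_px=1.0, texture_sd=0.10, noise_sd=0.02),
        ClassSpec("protein_b", mean_radius_px=7, radius_cv=0.20, boundary_roughness=0.15,
                  boundary_harmonics=3, interior_level=0.40, edge_level=0.60,
                  edge_width_px=3.0, texture_sd=0.05, noise_sd=0.02),
        ClassSpec("fa_pal", mean_radius_px=5, radius_cv=0.15, boundary_roughness=0.05,
                  boundary_harmonics=2, interior_level=0.70, edge_level=0.50,
                  edge_width_px=1.0, texture_sd=0.03, noise_sd=0.02),
    ]


def fa_panel_specs() -> list[ClassSpec]:
    """Six fatty-acid-like classes: gradual changes in size, darkness and
    roughness, mimicking particles of increasing carbon chain length plus
    two mixed-composition samples."""
    out = []
    for name, r, lvl, rough in [
        ("laua", 4.0, 0.72, 0.06), ("myra", 5.0, 0.62, 0.12),
        ("pala", 6.0, 0.52, 0.18), ("stea", 7.0, 0.42, 0.24),
        ("mix_i", 6.5, 0.35, 0.35), ("mix_ii", 5.5, 0.47, 0.30),
    ]:
        out.append(ClassSpec(name, mean_radius_px=r, radius_cv=0.2,
                             boundary_roughness=rough, boundary_harmonics=4,
                             interior_level=lvl, edge_level=max(lvl - 0.15, 0.0),
                             edge_width_px=1.5, texture_sd=0.05, noise_sd=0.03))
    return out


def subtle_pair_specs(shift: float = 0.08) -> list[ClassSpec]:
    """A brightness-only "subtle pair": identical geometry, the second
    class shifted ``shift`` brighter — the hard, mix-versus-mix case."""
    base = ClassSpec("mix_i", mean_radius_px=7, radius_cv=0.25,
                     boundary_roughness=0.30, boundary_harmonics=5,
                     interior_level=0.40, edge_level=0.28, edge_width_px=1.5,
                     texture_sd=0.06, noise_sd=0.03)
    brighter = dataclasses.replace(perturb_spec(base, shift), name="mix_ii")
    return [base, brighter]
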