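"""Procedural generator of labelled droplet-like images and synthetic embeddings.

The images are geometric caricatures of crystallisation-droplet inspections,
not photorealistic micrographs: a circular drop on a styled background whose
interior carries a class-specific signature (clear = featureless, crystal =
bright elongated polygons, precipitate = granular high-frequency texture,
other = irregular blob/ring).  A minority "bolus" contaminant type stands in
for lipidic-cubic-phase images.  The generator plants the structures the
curation algorithms are designed to find: controllable class frequencies,
several imaging "source" styles, timecourse groups of near-duplicate images,
and a contaminant fraction.

All generation is a pure function of (config, seed): per-image random streams
are derived by hashing the record identity together with the global seed, so
insertion order never changes an individual image.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from xtalcurate.apportion import largest_remainder
from xtalcurate.embedding import EmbeddingSet
from xtalcurate.manifest import (
    CLASS_LABELS,
    ClassDistribution,
    DatasetManifest,
    ImageRecord,
    write_manifest,
)

CONTAMINANT = "bolus"  # rendering signature of the LCP-like contaminant


@dataclass(frozen=True)
class StyleConfig:
    """One imaging style (laboratory / imager combination).

    ``background_level`` is the plate background grey level in [0, 1];
    ``vignette_strength`` darkens image corners; ``noise_sd`` is per-pixel
    Gaussian sensor noise; ``drop_radius_range`` bounds the drop radius as a
    fraction of the image width.
    """

    source_name: str
    background_level: float = 0.55
    vignette_strength: float = 0.25
    noise_sd: float = 0.02
    drop_radius_range: tuple[float, float] = (0.28, 0.38)

    def __post_init__(self) -> None:
        lo, hi = self.drop_radius_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("drop_radius_range must satisfy 0 < min <= max <= 0.5")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level must lie in [0, 1]")
        if self.vignette_strength < 0 or self.noise_sd < 0:
            raise ValueError("vignette_strength and noise_sd must be >= 0")


#: Three default styles whose background/contrast differences dominate class differences,
#: mimicking multi-laboratory collections where imaging style is the largest
#: source of variation.
DEFAULT_STYLES: tuple[StyleConfig, ...] = (
    StyleConfig("imagerA", background_level=0.50, vignette_strength=0.15, noise_sd=0.025),
    StyleConfig("imagerB", background_level=0.42, vignette_strength=0.45, noise_sd=0.03),
    StyleConfig("imagerC", background_level=0.58, vignette_strength=0.05, noise_sd=0.02),
)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic image dataset.

    Records are grouped into timecourses of ``duplicate_group_size`` images
    sharing a ``well_id``; each group is rendered from one base scene with a
    per-timepoint translation of at most ``duplicate_jitter * image_size``
    pixels and a brightness shift of at most ``duplicate_jitter``, so images
    within a well are near-duplicates.  ``contaminant_fraction`` of the images
    are re-rendered as irregular boluses (keeping their nominal label) to
    emulate a hidden minority contaminant type.
    """

    n_images: int
    class_dist: ClassDistribution
    image_size: int = 48
    styles: tuple[StyleConfig, ...] = DEFAULT_STYLES
    style_weights: Optional[tuple[float, ...]] = None
    duplicate_group_size: int = 1
    duplicate_jitter: float = 0.01
    contaminant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images <= 0 or self.image_size <= 0:
            raise ValueError("n_images and image_size must be positive")
        if self.duplicate_group_size < 1:
            raise ValueError("duplicate_group_size must be >= 1")
        if self.duplicate_jitter < 0:
            raise ValueError("duplicate_jitter must be >= 0")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if self.style_weights is not None:
            w = np.asarray(self.style_weights, dtype=float)
            if len(w) != len(self.styles):
                raise ValueError("style_weights must match styles")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("style_weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        if self.style_weights is None:
            return np.full(len(self.styles), 1.0 / len(self.styles))
        return np.asarray(self.style_weights, dtype=float)


def _rng_for(seed: int, key: str) -> np.random.Generator:
    """Deterministic per-entity stream: hash (seed, key) into a SeedSequence."""
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return np.random.default_rng(np.random.SeedSequence([seed, int.from_bytes(digest, "big")]))


# ---------------------------------------------------------------------------
# Scene sampling and rendering
# ---------------------------------------------------------------------------


@dataclass
class _Scene:
    """Resolution-independent description of one droplet image."""

    label: str
    cx: float  # drop centre, fraction of width
    cy: float
    radius: float  # fraction of width
    features: dict = field(default_factory=dict)


def _sample_scene(label: str, style: StyleConfig, rng: np.random.Generator) -> _Scene:
    lo, hi = style.drop_radius_range
    radius = rng.uniform(lo, hi)
    cx = 0.5 + rng.uniform(-0.05, 0.05)
    cy = 0.5 + rng.uniform(-0.05, 0.05)
    feats: dict = {}
    # Per-well appearance fingerprint, constant across the timecourse: every
    # droplet/plate position has its own illumination ramp and grey offsets,
    # which keeps distinct wells well separated in embedding space relative
    # to the small re-imaging jitter within a timecourse.
    feats["bg_offset"] = rng.uniform(-0.05, 0.05)
    feats["ramp_angle"] = rng.uniform(0, 2 * np.pi)
    feats["ramp_strength"] = rng.uniform(-0.04, 0.04)
    feats["drop_offset"] = rng.uniform(-0.05, 0.05)
    # faint coarse mottle of the plate/well surface: a high-dimensional
    # per-well fingerprint, so even featureless (clear) wells are mutually
    # distinguishable while re-imaging jitter stays comparatively tiny
    feats["plate_seed"] = int(rng.integers(0, 2**31))
    feats["plate_amp"] = rng.uniform(0.06, 0.12)
    feats["contrast"] = rng.uniform(0.90, 1.10)
    feats["drop_shade"] = rng.uniform(-0.08, 0.08)
    if label == "crystal":
        n_xtal = int(rng.integers(1, 6))
        xtals = []
        for k in range(n_xtal):
            r = rng.uniform(0.0, 0.5) * radius
            theta = rng.uniform(0, 2 * np.pi)
            # the first crystal is always sizeable so the class signature is
            # present even in a single-crystal drop
            length = rng.uniform(0.85 if k == 0 else 0.5, 1.2) * radius
            width = length * rng.uniform(0.22 if k == 0 else 0.12, 0.30)
            angle = rng.uniform(0, np.pi)
            xtals.append(
                dict(
                    x=cx + r * np.cos(theta),
                    y=cy + r * np.sin(theta),
                    length=length,
                    width=width,
                    angle=angle,
                    bright=rng.uniform(0.95, 1.0),
                )
            )
        feats["crystals"] = xtals
    elif label == "precipitate":
        feats["grain_seed"] = int(rng.integers(0, 2**31))
        feats["grain_amp"] = rng.uniform(0.20, 0.30)
        # coarse per-well blotch pattern: visible to mean-pooled features,
        # giving every precipitate well a distinct identity
        feats["blotch_seed"] = int(rng.integers(0, 2**31))
        feats["blotch_amp"] = rng.uniform(0.10, 0.16)
    elif label == "other":
        feats["ring_radius"] = rng.uniform(0.35, 0.75) * radius
        feats["ring_width"] = rng.uniform(0.06, 0.12) * radius
        feats["blob_radius"] = rng.uniform(0.30, 0.50) * radius
        feats["blob_phase"] = rng.uniform(0, 2 * np.pi)
        feats["blob_dark"] = rng.uniform(0.25, 0.35)
    elif label == CONTAMINANT:
        # irregular bolus filling > 60% of the drop, unlike any class signature
        feats["bolus_radius"] = 0.82 * radius
        feats["bolus_phase"] = rng.uniform(0, 2 * np.pi)
        feats["bolus_bright"] = rng.uniform(0.25, 0.35)
        feats["swirl_seed"] = int(rng.integers(0, 2**31))
    elif label != "clear":
        raise ValueError(f"unknown render label {label!r}")
    return _Scene(label=label, cx=cx, cy=cy, radius=radius, features=feats)


def _render_scene(
    scene: _Scene,
    style: StyleConfig,
    size: int,
    rng: np.random.Generator,
    offset: tuple[float, float] = (0.0, 0.0),
    brightness: float = 0.0,
) -> np.ndarray:
    """Rasterise a scene to an 8-bit grayscale image.

    ``offset`` shifts the drop (in pixels) and ``brightness`` adds a global
    grey-level shift; both model timecourse re-imaging jitter.  Sensor noise
    is drawn from ``rng`` so identical (scene, style, rng state) renders are
    bit-identical.
    """
    ax = (np.arange(size) + 0.5) / size
    xx, yy = np.meshgrid(ax, ax)
    cx = scene.cx + offset[0] / size
    cy = scene.cy + offset[1] / size

    feats = scene.features

    # styled background with radial vignette, plus the per-well fingerprint
    # (grey offset and a linear illumination ramp)
    r2 = (xx - 0.5) ** 2 + (yy - 0.5) ** 2
    img = style.background_level * (1.0 - style.vignette_strength * 2.0 * r2)
    img = img + feats.get("bg_offset", 0.0)
    ang = feats.get("ramp_angle", 0.0)
    img = img + feats.get("ramp_strength", 0.0) * (
        (xx - 0.5) * np.cos(ang) + (yy - 0.5) * np.sin(ang)
    )

    # Anti-aliased coverage masks: edges blend over ~1 pixel so that the
    # sub-pixel translations of timecourse jitter change pixel values
    # smoothly instead of flipping whole pixels in and out of features.
    px = 1.0 / size

    def soft_inside(signed_dist):  # 1 well inside, 0 well outside
        return np.clip(0.5 - signed_dist / px, 0.0, 1.0)

    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    inside = soft_inside(dist - scene.radius)
    rim = np.exp(-(((dist - scene.radius) / (1.2 * px)) ** 2))
    drop_level = (
        (style.background_level + feats.get("bg_offset", 0.0)) * 0.92
        + 0.04
        + feats.get("drop_offset", 0.0)
    )
    img = img * (1 - inside) + drop_level * inside
    # gentle radial shading of the drop interior (per-well lensing)
    img = img + feats.get("drop_shade", 0.0) * (dist / scene.radius) * inside
    img = img * (1 - rim) + img * 0.55 * rim

    if "plate_seed" in feats:
        # plate mottle is visible both beside and through the drop; it gives
        # every well a high-dimensional appearance fingerprint
        mottle_rng = np.random.default_rng(feats["plate_seed"])
        coarse = mottle_rng.uniform(-1.0, 1.0, size=(6, 6))
        mottle = np.kron(coarse, np.ones((size // 6 + 1, size // 6 + 1)))[:size, :size]
        img = img + feats["plate_amp"] * mottle

    if scene.label == "crystal":
        for x in feats["crystals"]:
            u = np.array([np.cos(x["angle"]), np.sin(x["angle"])])
            v = np.array([-u[1], u[0]])
            dx, dy = xx - x["x"], yy - x["y"]
            along = np.abs(dx * u[0] + dy * u[1])
            across = np.abs(dx * v[0] + dy * v[1])
            body = (
                soft_inside(along - x["length"] / 2)
                * soft_inside(across - x["width"] / 2)
                * inside
            )
            # lengthwise shading keeps the highlight spread over several
            # grey levels rather than one flat value
            value = x["bright"] - 0.15 * (along / (x["length"] / 2 + 1e-9))
            img = img * (1 - body) + value * body
    elif scene.label == "precipitate":
        grain_rng = np.random.default_rng(feats["grain_seed"])
        # grain darkens more than it brightens, as dense precipitate does;
        # keeps its bright tail out of the crystal-highlight intensity range
        grain = grain_rng.uniform(-1.0, 0.4, size=(size, size))
        img = img + inside * feats["grain_amp"] * grain
        # coarse blotches: a 6x6 random field upsampled to image size
        blotch_rng = np.random.default_rng(feats["blotch_seed"])
        coarse = blotch_rng.uniform(-1.0, 1.0, size=(6, 6))
        blotch = np.kron(coarse, np.ones((size // 6 + 1, size // 6 + 1)))[:size, :size]
        img = img + inside * feats["blotch_amp"] * blotch
    elif scene.label == "other":
        ring = np.exp(-(((dist - feats["ring_radius"]) / feats["ring_width"]) ** 2)) * inside
        img = img * (1 - ring) + img * 0.5 * ring
        theta = np.arctan2(yy - cy, xx - cx)
        blob_r = feats["blob_radius"] * (1.0 + 0.35 * np.sin(3 * theta + feats["blob_phase"]))
        blob = soft_inside(dist - blob_r) * inside
        img = img - feats["blob_dark"] * blob
    elif scene.label == CONTAMINANT:
        theta = np.arctan2(yy - cy, xx - cx)
        bol_r = feats["bolus_radius"] * (
            1.0 + 0.18 * np.sin(4 * theta + feats["bolus_phase"]) + 0.1 * np.sin(7 * theta)
        )
        bolus = soft_inside(dist - bol_r) * inside
        swirl_rng = np.random.default_rng(feats["swirl_seed"])
        swirl = swirl_rng.uniform(-1.0, 1.0, size=(size, size))
        # low-frequency-ish swirl: average 3x-coarse noise
        swirl = (swirl + np.roll(swirl, 1, axis=0) + np.roll(swirl, 1, axis=1)) / 3.0
        img = img + bolus * (feats["bolus_bright"] + 0.06 * swirl)

    if style.noise_sd > 0:
        img = img + rng.normal(0.0, style.noise_sd, size=(size, size))
    # per-well contrast stretch about mid-grey, then timecourse brightness shift
    img = 0.5 + feats.get("contrast", 1.0) * (img - 0.5)
    img = img + brightness
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def render_droplet(
    label: str, style: StyleConfig, rng: np.random.Generator, size: int = 48
) -> np.ndarray:
    """Render a single droplet image with the given class signature.

    ``label`` is one of the four outcome classes or :data:`CONTAMINANT`.
    Deterministic: the same (label, style, rng state) renders bit-identically.
    """
    scene = _sample_scene(label, style, rng)
    return _render_scene(scene, style, size, rng)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write a synthetic image dataset and its manifest to ``out_dir``.

    Class counts follow ``cfg.class_dist`` exactly via largest-remainder
    apportionment.  Within each class, images are chunked into timecourses of
    ``duplicate_group_size`` sharing a ``well_id`` (the final chunk of a class
    may be shorter); a timecourse is rendered from one base scene with
    per-timepoint jitter.  Contaminant images keep their nominal label but are
    rendered as boluses, get a ``+lcp`` source-tag suffix, and are listed in a
    ``contaminants.txt`` sidecar.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    counts = largest_remainder(cfg.class_dist.as_array(), cfg.n_images)
    n_cont_target = int(round(cfg.contaminant_fraction * cfg.n_images))

    # Build the well layout: per class, consecutive chunks of group size.
    wells: list[tuple[str, str, int]] = []  # (well_id, label, n_timepoints)
    widx = 0
    for ci, label in enumerate(CLASS_LABELS):
        remaining = int(counts[ci])
        while remaining > 0:
            g = min(cfg.duplicate_group_size, remaining)
            wells.append((f"w{widx:05d}", label, g))
            widx += 1
            remaining -= g

    # Choose contaminant wells (whole timecourses) until the image target is
    # covered; an LCP-like experiment contaminates its entire timecourse.
    cont_wells: set[str] = set()
    if n_cont_target > 0:
        layout_rng = _rng_for(cfg.seed, "contaminant-layout")
        order = layout_rng.permutation(len(wells))
        covered = 0
        for wi in order:
            if covered >= n_cont_target:
                break
            cont_wells.add(wells[wi][0])
            covered += wells[wi][2]

    records: list[ImageRecord] = []
    contaminant_ids: list[str] = []
    weights = cfg.weights
    for well_id, label, n_t in wells:
        well_rng = _rng_for(cfg.seed, f"well:{well_id}")
        style_i = int(well_rng.choice(len(cfg.styles), p=weights))
        style = cfg.styles[style_i]
        render_label = CONTAMINANT if well_id in cont_wells else label
        scene = _sample_scene(render_label, style, well_rng)
        for t in range(n_t):
            record_id = f"{well_id}-t{t}"
            img_rng = _rng_for(cfg.seed, f"img:{record_id}")
            if cfg.duplicate_jitter > 0:
                offset = tuple(
                    img_rng.uniform(-1.0, 1.0, 2) * cfg.duplicate_jitter * cfg.image_size
                )
                brightness = float(img_rng.uniform(-1.0, 1.0) * cfg.duplicate_jitter)
            else:
                offset, brightness = (0.0, 0.0), 0.0
            noise_rng = _rng_for(cfg.seed, f"noise:{well_id}")  # shared: near-duplicates
            img = _render_scene(
                scene, style, cfg.image_size, noise_rng, offset=offset, brightness=brightness
            )
            rel = f"images/{record_id}.png"
            Image.fromarray(img, mode="L").save(out_dir / rel)
            source = style.source_name + ("+lcp" if well_id in cont_wells else "")
            if well_id in cont_wells:
                contaminant_ids.append(record_id)
            records.append(
                ImageRecord(
                    record_id=record_id,
                    image_path=rel,
                    label=label,
                    source=source,
                    well_id=well_id,
                    timepoint=t,
                )
            )

    manifest = DatasetManifest(records=records, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    if contaminant_ids:
        (out_dir / "contaminants.txt").write_text("\n".join(contaminant_ids) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic embeddings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingSynthConfig:
    """Gaussian-cluster embeddings with separate class and source structure.

    Each vector is class-centre + source-offset + isotropic noise.  Class
    centres are mutually ``class_separation`` apart and source offsets
    mutually ``source_separation`` apart, so the ratio of the two separations
    controls whether clustering recovers classes or sources — the knob used to
    emulate collections where imaging origin dominates semantic content.
    """

    n_per_class: int
    dim: int = 16
    class_separation: float = 4.0
    source_separation: float = 0.0
    n_sources: int = 1
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if self.class_separation < 0 or self.source_separation < 0:
            raise ValueError("separations must be >= 0")


def _mutually_separated_centres(
    k: int, dim: int, sep: float, rng: np.random.Generator, axis_offset: int
) -> np.ndarray:
    """k centres pairwise ``sep`` apart (exact on orthogonal axes, expected otherwise)."""
    if sep == 0 or k == 1:
        return np.zeros((k, dim))
    if axis_offset + k <= dim:
        centres = np.zeros((k, dim))
        for i in range(k):
            centres[i, axis_offset + i] = sep / np.sqrt(2.0)
        return centres
    dirs = rng.normal(size=(k, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * sep / np.sqrt(2.0)


def generate_embeddings(
    cfg: EmbeddingSynthConfig,
) -> tuple[EmbeddingSet, np.ndarray, np.ndarray]:
    """Draw synthetic embedding vectors; returns (embeddings, labels, sources).

    ``labels`` and ``sources`` are integer arrays aligned to the embedding
    rows.  Sources are assigned round-robin within each class so every
    class/source cell is populated.
    """
    rng = np.random.default_rng(cfg.seed)
    class_centres = _mutually_separated_centres(4, cfg.dim, cfg.class_separation, rng, 0)
    source_offsets = _mutually_separated_centres(
        cfg.n_sources, cfg.dim, cfg.source_separation, rng, 4
    )
    n = 4 * cfg.n_per_class
    vectors = np.empty((n, cfg.dim))
    labels = np.empty(n, dtype=np.int64)
    sources = np.empty(n, dtype=np.int64)
    ids = []
    row = 0
    for c in range(4):
        for j in range(cfg.n_per_class):
            s = j % cfg.n_sources
            vectors[row] = (
                class_centres[c] + source_offsets[s] + rng.normal(0.0, cfg.within_sd, cfg.dim)
            )
            labels[row] = c
            sources[row] = s
            ids.append(f"e{row:06d}")
            row += 1
    return (
        EmbeddingSet(vectors=vectors, record_ids=ids, provider_name="synthetic-gaussian"),
        labels,
        sources,
    )
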