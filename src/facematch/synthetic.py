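"""Seeded generators for synthetic facebases, clinician ratings and face sketches.

The embedding generator is a three-level isotropic Gaussian hierarchy:

* cohort prototype  ``mu_s ~ N(0, sigma_b^2 I_d)``
* individual centre ``c_i ~ N(mu_s, sigma_w^2 I_d)``
* image vector      ``x_ij ~ N(c_i, sigma_e^2 I_d)``

Controls are drawn from the zero-centred marginal
``N(0, (sigma_b^2 + sigma_w^2 + sigma_e^2) I_d)`` — heterogeneous unaffected
faces rather than a cluster of their own.  All rows are L2-normalised.
With ``sigma_b = 0`` every image is i.i.d. isotropic, so rankings are
exchangeable and retrieval carries no cohort signal (the calibration
regime); increasing ``sigma_b`` tightens cohorts on the sphere.

The default layout (:func:`reference_config`) mirrors a staged 10-syndrome
database: 3145 images at stage 1, 3432 at stage 2 and 3681 at stage 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .errors import ConfigError
from .facebase import CONTROL, Facebase, ImageRecord
from .ratings import RatingTable

__all__ = [
    "CohortSpec",
    "GeneratorConfig",
    "RatingModel",
    "reference_config",
    "generate_embedding_facebase",
    "generate_clinician_scores",
    "FaceParams",
    "sample_face_params",
    "generate_face_image",
]


@dataclass(frozen=True)
class CohortSpec:
    """Composition of one syndrome cohort (or one staged tranche of it).

    ``multi_image_fraction`` is the probability that an individual
    contributes 2–3 images instead of 1 (same person at different ages);
    image totals are exact, individual counts fall out of the draw.
    """

    name: str
    n_images: int
    stage: int = 1
    multi_image_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ConfigError(f"cohort {self.name!r}: n_images must be >= 0")
        if not 0.0 <= self.multi_image_fraction <= 1.0:
            raise ConfigError(f"cohort {self.name!r}: multi_image_fraction in [0,1]")
        if self.name == CONTROL:
            raise ConfigError(f"{CONTROL!r} is reserved; use n_controls")


@dataclass(frozen=True)
class GeneratorConfig:
    cohorts: tuple[CohortSpec, ...]
    n_controls: int = 0
    d: int = 16
    sigma_b: float = 1.0
    sigma_w: float = 0.5
    sigma_e: float = 0.25
    seed: int = 0
    control_stage: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        if self.d < 2:
            raise ConfigError("embedding dimension d must be >= 2")
        if min(self.sigma_b, self.sigma_w, self.sigma_e) < 0:
            raise ConfigError("all scales must be >= 0")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be >= 0")
        if self.sigma_b == self.sigma_w == self.sigma_e == 0:
            raise ConfigError("at least one scale must be positive")

    @property
    def cohort_names(self) -> list[str]:
        out: list[str] = []
        for spec in self.cohorts:
            if spec.name not in out:
                out.append(spec.name)
        return out


#: Staged composition of the emulated database: (name, images, entry stage).
#: Stage-1 total is 3145 images, stage-2 3432, stage-3 3681 + 249 = 3681.
_REFERENCE_LAYOUT: tuple[tuple[str, int, int], ...] = (
    ("Williams", 183, 1),
    ("Rubinstein-Taybi", 155, 1),
    ("Floating Harbor", 61, 1),
    ("Coffin Lowry", 154, 1),
    ("Kabuki", 195, 1),
    ("Smith Magenis", 124, 1),
    ("Cornelia de Lange", 192, 1),
    ("PACS1", 39, 2),
    ("Kleefstra", 128, 2),
    ("Koolen-de Vries", 120, 2),
    ("Cornelia de Lange", 249, 3),
)

_REFERENCE_CONTROLS = 2081

#: Stage at which each syndrome cohort was analysed.
REFERENCE_ANALYSIS_STAGE: Mapping[str, int] = {
    "Williams": 1,
    "Rubinstein-Taybi": 1,
    "Floating Harbor": 1,
    "Coffin Lowry": 1,
    "Kabuki": 1,
    "Smith Magenis": 1,
    "PACS1": 2,
    "Kleefstra": 2,
    "Koolen-de Vries": 2,
    "Cornelia de Lange": 3,
}


def reference_config(
    d: int = 64,
    sigma_b: float = 1.0,
    sigma_w: float = 0.5,
    sigma_e: float = 0.25,
    seed: int = 0,
    multi_image_fraction: float = 0.05,
) -> GeneratorConfig:
    """Default staged 10-cohort layout (N=3145/3432/3681 at stages 1/2/3)."""
    cohorts = tuple(
        CohortSpec(name, n, stage, multi_image_fraction)
        for name, n, stage in _REFERENCE_LAYOUT
    )
    return GeneratorConfig(
        cohorts=cohorts,
        n_controls=_REFERENCE_CONTROLS,
        d=d,
        sigma_b=sigma_b,
        sigma_w=sigma_w,
        sigma_e=sigma_e,
        seed=seed,
    )


def _partition_images(
    n_images: int, multi_fraction: float, rng: np.random.Generator
) -> list[int]:
    """Split an exact image total into per-individual image counts."""
    counts: list[int] = []
    remaining = n_images
    while remaining > 0:
        if remaining >= 2 and rng.random() < multi_fraction:
            k = min(int(rng.integers(2, 4)), remaining)
        else:
            k = 1
        counts.append(k)
        remaining -= k
    return counts


def generate_embedding_facebase(cfg: GeneratorConfig) -> Facebase:
    """Draw a labelled facebase with clustered unit-norm embeddings.

    Deterministic for a fixed config (including ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed)
    prototypes = {
        name: rng.normal(0.0, cfg.sigma_b, size=cfg.d) for name in cfg.cohort_names
    }
    records: list[ImageRecord] = []
    rows: list[np.ndarray] = []
    individual_serial: dict[str, int] = {}
    for spec in cfg.cohorts:
        slug = "".join(w[0] for w in spec.name.split()).upper() + spec.name.replace(" ", "")[1:3]
        mu = prototypes[spec.name]
        for n_imgs in _partition_images(spec.n_images, spec.multi_image_fraction, rng):
            serial = individual_serial.get(spec.name, 0) + 1
            individual_serial[spec.name] = serial
            individual_id = f"{slug}-{serial:04d}"
            centre = mu + rng.normal(0.0, cfg.sigma_w, size=cfg.d)
            for j in range(1, n_imgs + 1):
                records.append(
                    ImageRecord(
                        image_id=f"{individual_id}.{j}",
                        individual_id=individual_id,
                        cohort=spec.name,
                        stage=spec.stage,
                    )
                )
                rows.append(centre + rng.normal(0.0, cfg.sigma_e, size=cfg.d))
    control_scale = float(
        np.sqrt(cfg.sigma_b**2 + cfg.sigma_w**2 + cfg.sigma_e**2)
    )
    for i in range(1, cfg.n_controls + 1):
        individual_id = f"CTRL-{i:05d}"
        records.append(
            ImageRecord(
                image_id=f"{individual_id}.1",
                individual_id=individual_id,
                cohort=CONTROL,
                stage=cfg.control_stage,
            )
        )
        rows.append(rng.normal(0.0, control_scale, size=cfg.d))
    embeddings = np.vstack(rows) if rows else np.empty((0, cfg.d))
    return Facebase(records, embeddings)


# ---------------------------------------------------------------------------
# clinician rating generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingModel:
    """Per-cohort score distribution for the three simulated raters.

    ``p_definite``/``p_possible`` map cohort name to the probability of a
    score of 1 / 3; the residual mass goes to score 2.  Scalars broadcast to
    every cohort.  ``rater_correlation`` is the probability a rater reuses
    the image's shared latent draw instead of an independent one, which
    induces agreement between raters without changing the marginals.
    """

    p_definite: Mapping[str, float] | float
    p_possible: Mapping[str, float] | float = 0.0
    rater_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rater_correlation <= 1.0:
            raise ConfigError("rater_correlation must lie in [0,1]")

    def probs(self, cohort: str) -> tuple[float, float]:
        p1 = self._lookup(self.p_definite, cohort)
        p3 = self._lookup(self.p_possible, cohort)
        if p1 < 0 or p3 < 0 or p1 + p3 > 1.0 + 1e-12:
            raise ConfigError(
                f"cohort {cohort!r}: p_definite + p_possible must be <= 1"
            )
        return p1, p3

    @staticmethod
    def _lookup(value: Mapping[str, float] | float, cohort: str) -> float:
        if isinstance(value, Mapping):
            try:
                return float(value[cohort])
            except KeyError:
                raise ConfigError(f"cohort {cohort!r} missing from rating model")
        return float(value)


def generate_clinician_scores(
    fb: Facebase, model: RatingModel, seed: int
) -> RatingTable:
    """Simulate three rater scores for every syndrome image.

    A score of 1 is drawn with the cohort's ``p_definite``, 3 with
    ``p_possible``, 2 otherwise.  Controls receive no rows.  Deterministic
    per seed.
    """
    if len(fb) == 0:
        raise ConfigError("facebase is empty")
    rng = np.random.default_rng(seed)
    scores: dict[str, tuple[int, int, int]] = {}
    for rec in fb.records:
        if rec.is_control:
            continue
        p1, p3 = model.probs(rec.cohort)
        shared = rng.random()
        triple = []
        for _ in range(3):
            u = shared if rng.random() < model.rater_correlation else rng.random()
            if u < p1:
                triple.append(1)
            elif u < p1 + p3:
                triple.append(3)
            else:
                triple.append(2)
        scores[rec.image_id] = tuple(triple)
    return RatingTable(scores)


# ---------------------------------------------------------------------------
# procedural face sketches (fixture generator for the descriptor)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FaceParams:
    """Latent geometry of a sketched face; every field lies in [0, 1]."""

    head_width: float = 0.5
    head_height: float = 0.5
    eye_spacing: float = 0.5
    eye_size: float = 0.5
    eye_height: float = 0.5
    nose_length: float = 0.5
    mouth_width: float = 0.5
    mouth_height: float = 0.5

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.head_width,
                self.head_height,
                self.eye_spacing,
                self.eye_size,
                self.eye_height,
                self.nose_length,
                self.mouth_width,
                self.mouth_height,
            ]
        )


def sample_face_params(rng: np.random.Generator) -> FaceParams:
    vals = rng.uniform(0.15, 0.85, size=8)
    return FaceParams(*map(float, vals))


def generate_face_image(
    individual_params: FaceParams,
    age_scale: float = 1.0,
    noise_seed: int = 0,
    size: int = 64,
    noise_sigma: float = 4.0,
    shade_amp: float = 18.0,
) -> np.ndarray:
    """Render a parametric grayscale face sketch as a ``(size, size)`` uint8 array.

    The same individual at a different ``age_scale`` has globally scaled
    geometry.  A stationary low-frequency shading field (complexion /
    lighting stand-in, parameters derived from the latent vector) does not
    scale with age, so identity survives an age change in the descriptor's
    low-frequency view.  Pixel noise is deterministic per ``noise_seed``.
    """
    if size < 32:
        raise ConfigError("canvas must be at least 32x32")
    p = individual_params
    img = Image.new("L", (size, size), color=32)
    draw = ImageDraw.Draw(img)
    cx = cy = size / 2.0

    def scaled(dx: float, dy: float) -> tuple[float, float]:
        return cx + dx * age_scale, cy + dy * age_scale

    half_w = size * (0.22 + 0.18 * p.head_width)
    half_h = size * (0.26 + 0.18 * p.head_height)
    draw.ellipse(
        [scaled(-half_w, -half_h), scaled(half_w, half_h)], fill=200, outline=255, width=2
    )
    eye_dx = half_w * (0.25 + 0.5 * p.eye_spacing)
    eye_dy = -half_h * (0.15 + 0.35 * p.eye_height)
    eye_r = size * (0.02 + 0.04 * p.eye_size)
    for sign in (-1, 1):
        ex, ey = scaled(sign * eye_dx, eye_dy)
        r = eye_r * age_scale
        draw.ellipse([ex - r, ey - r, ex + r, ey + r], fill=16)
    nose_len = half_h * (0.2 + 0.4 * p.nose_length)
    draw.line([scaled(0, -nose_len * 0.2), scaled(0, nose_len * 0.8)], fill=64, width=2)
    mouth_hw = half_w * (0.2 + 0.5 * p.mouth_width)
    mouth_dy = half_h * (0.35 + 0.3 * p.mouth_height)
    draw.arc(
        [scaled(-mouth_hw, mouth_dy - mouth_hw * 0.6), scaled(mouth_hw, mouth_dy + mouth_hw * 0.6)],
        start=20,
        end=160,
        fill=48,
        width=2,
    )
    arr = np.asarray(img, dtype=np.float64)
    if shade_amp:
        yy, xx = np.mgrid[0:size, 0:size] / size
        fx = 0.5 + 2.0 * p.eye_spacing
        fy = 0.5 + 2.0 * p.mouth_height
        phase = 2.0 * np.pi * p.nose_length
        arr = arr + shade_amp * np.sin(2.0 * np.pi * (fx * xx + fy * yy) + phase)
    noise = np.random.default_rng(noise_seed).normal(0.0, noise_sigma, arr.shape)
    return np.clip(arr + noise, 0, 255).astype(np.uint8)
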