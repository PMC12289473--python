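"""Synthetic syndrome-structured embedding galleries and cohorts.

Real next-generation-phenotyping galleries cluster hierarchically: images of
one subject are nearly identical, subjects sharing a syndrome cluster around
a syndrome-specific facial gestalt, and ensemble members of one image differ
only by model/augmentation jitter.  The generator reproduces that geometry on
the unit hypersphere with a Gaussian-perturb-then-normalize scheme (not exact
von Mises–Fisher sampling, but the same qualitative concentration structure):

* syndrome centre  mu_s ~ uniform on S^(d-1)
* subject centre   normalize(mu_s + sigma_subject * g)
* image vector     normalize(subject + sigma_image * g)
* ensemble member  normalize(image + sigma_ensemble * g_k)

Ids are systematic (``S001_P01_I01``) so syndrome/subject ground truth is
recoverable from the id alone.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import Cohort
from .embeddings import EmbeddingSet, Gallery, ValidationError

__all__ = [
    "SyntheticConfig",
    "generate_gallery",
    "generate_cohort",
    "sample_cross_syndrome_cohort",
]


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the hierarchical sphere model.

    Defaults emulate a small labelled gallery (50 syndromes x 3 subjects x 2
    images) with the ensemble geometry of a 12-model, 512-dimensional
    embedding stack; spreads are fractions of the unit radius.
    """

    n_syndromes: int = 50
    subjects_per_syndrome: int = 3
    images_per_subject: int | tuple[int, int] = 2
    d: int = 512
    E: int = 12
    sigma_subject: float = 0.2
    sigma_image: float = 0.1
    sigma_ensemble: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_syndromes < 1 or self.subjects_per_syndrome < 1:
            raise ValidationError("need >= 1 syndrome and >= 1 subject per syndrome")
        if self.d < 2:
            raise ValidationError("embedding dimension d must be >= 2")
        if self.E < 1:
            raise ValidationError("ensemble size E must be >= 1")
        for name in ("sigma_subject", "sigma_image", "sigma_ensemble"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perturb(center: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(center + sigma * rng.standard_normal(center.shape))


def _images_for_subject(
    spec: int | tuple[int, int], rng: np.random.Generator
) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _make_embedding(
    image_id: str,
    subject_id: str,
    label: str,
    subject_center: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> EmbeddingSet:
    image_vec = _perturb(subject_center, cfg.sigma_image, rng)
    members = np.stack(
        [_perturb(image_vec, cfg.sigma_ensemble, rng) for _ in range(cfg.E)]
    )
    return EmbeddingSet(
        image_id=image_id, subject_id=subject_id, vectors=members, syndrome_label=label
    )


def generate_gallery(
    config: SyntheticConfig, *, return_centers: bool = False
) -> Gallery | tuple[Gallery, dict[str, np.ndarray]]:
    """Generate a labelled gallery under the hierarchical sphere model.

    With ``return_centers=True`` the syndrome centres are returned as well
    (useful for attaching a synthetic cohort to an existing syndrome).
    """
    rng = np.random.default_rng(config.seed)
    items: list[EmbeddingSet] = []
    centers: dict[str, np.ndarray] = {}
    for s in range(config.n_syndromes):
        label = f"S{s + 1:03d}"
        mu = _unit(rng.standard_normal(config.d))
        centers[label] = mu
        for p in range(config.subjects_per_syndrome):
            subject_id = f"{label}_P{p + 1:02d}"
            subject_center = _perturb(mu, config.sigma_subject, rng)
            for i in range(_images_for_subject(config.images_per_subject, rng)):
                items.append(
                    _make_embedding(
                        f"{subject_id}_I{i + 1:02d}", subject_id, label,
                        subject_center, config, rng,
                    )
                )
    gallery = Gallery(items)
    return (gallery, centers) if return_centers else gallery


def _constrained_counts(
    n_subjects: int,
    per_subject: tuple[int, int],
    total: int | None,
    rng: np.random.Generator,
) -> list[int]:
    lo, hi = per_subject
    if total is None:
        return [int(rng.integers(lo, hi + 1)) for _ in range(n_subjects)]
    if not n_subjects * lo <= total <= n_subjects * hi:
        raise ValidationError(
            f"total_images={total} infeasible for {n_subjects} subjects in [{lo}, {hi}]"
        )
    counts = [lo] * n_subjects
    remainder = total - n_subjects * lo
    while remainder > 0:
        open_slots = [i for i, c in enumerate(counts) if c < hi]
        counts[open_slots[int(rng.integers(len(open_slots)))]] += 1
        remainder -= 1
    return counts


def generate_cohort(
    config: SyntheticConfig,
    n_subjects: int = 4,
    images_per_subject: tuple[int, int] = (1, 3),
    total_images: int | None = 7,
    attach_to: np.ndarray | None = None,
    label: str = "QUERY",
) -> Cohort:
    """Generate a held-out test cohort around one (new or given) syndrome centre.

    Defaults emulate a small clinical photo series: four subjects contributing
    seven images in total, one to three per subject.  ``attach_to`` plants the
    cohort on an existing gallery syndrome centre for recovery experiments;
    otherwise a fresh centre (a syndrome absent from the gallery) is drawn.
    The cohort carries the held-out ``label``.
    """
    if n_subjects < 2:
        raise ValidationError("a cohort needs >= 2 subjects")
    rng = np.random.default_rng([config.seed, 17])
    mu = _unit(np.asarray(attach_to, dtype=np.float64)) if attach_to is not None else _unit(
        rng.standard_normal(config.d)
    )
    counts = _constrained_counts(n_subjects, images_per_subject, total_images, rng)
    items: list[EmbeddingSet] = []
    for p in range(n_subjects):
        subject_id = f"{label}_P{p + 1:02d}"
        subject_center = _perturb(mu, config.sigma_subject, rng)
        for i in range(counts[p]):
            items.append(
                _make_embedding(
                    f"{subject_id}_I{i + 1:02d}", subject_id, label,
                    subject_center, config, rng,
                )
            )
    return Cohort(items)


def sample_cross_syndrome_cohort(
    gallery: Gallery, n_subjects: int = 4, seed: int = 0, *, rename: bool = True
) -> Cohort:
    """Assemble a negative-control cohort from subjects of distinct syndromes.

    Each chosen subject keeps all of its images; by default items are re-id'd
    with a ``RANDOMC`` prefix so the cohort is disjoint from the gallery by id
    (the underlying vectors are shared, which is intentional for control
    cohorts drawn from the gallery itself — exclude them via
    :func:`gestaltcohort.embeddings.Gallery.without` when building nulls).
    """
    rng = np.random.default_rng([seed, 23])
    index = gallery.syndrome_index
    if len(index) < n_subjects:
        raise ValidationError(
            f"need {n_subjects} distinct syndromes, gallery has {len(index)}"
        )
    syndromes = rng.choice(sorted(index), size=n_subjects, replace=False)
    items: list[EmbeddingSet] = []
    sources: list[str] = []
    for j, syndrome in enumerate(syndromes):
        subject = index[syndrome][int(rng.integers(len(index[syndrome])))]
        image_ids = gallery.subject_index[subject]
        for i, iid in enumerate(image_ids):
            src = gallery.get(iid)
            sources.append(iid)
            if rename:
                items.append(
                    EmbeddingSet(
                        image_id=f"RANDOMC_P{j + 1:02d}_I{i + 1:02d}",
                        subject_id=f"RANDOMC_P{j + 1:02d}",
                        vectors=src.vectors,
                        syndrome_label="RANDOMC",
                    )
                )
            else:
                items.append(src)
    cohort = Cohort(items)
    cohort.source_image_ids = sources  # type: ignore[attr-defined]
    return cohort
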