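"""Resampled mean-pairwise-distance distributions for cohort similarity.

The cohort-level analysis asks whether a small patient cohort is more
self-similar in embedding space than chance: the cohort's mean pairwise
distance, resampled one image per subject, is compared with two null
distributions drawn from a large labelled gallery — sub-cohorts constrained
to a single syndrome ("same") and unconstrained sub-cohorts ("random").
Resampling never places two images of one subject in the same sub-cohort.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSet, Gallery, ValidationError, distance_matrix

__all__ = [
    "Cohort",
    "DistributionSet",
    "sample_subcohort",
    "mean_pairwise_distance",
    "resample_test_distribution",
    "build_same_distribution",
    "build_random_distribution",
    "compute_distribution_set",
]


class Cohort:
    """A test cohort: >= 2 subjects, each image belonging to exactly one subject."""

    def __init__(self, items: Sequence[EmbeddingSet]):
        self._gallery = Gallery(items)  # reuse uniqueness/shape validation
        if len(self.subjects) < 2:
            raise ValidationError("cohort needs >= 2 distinct subjects")

    @property
    def items(self) -> list[EmbeddingSet]:
        return self._gallery.items

    @property
    def subjects(self) -> dict[str, list[str]]:
        """subject_id -> sorted image_ids."""
        return self._gallery.subject_index

    @property
    def ids(self) -> list[str]:
        return self._gallery.ids

    @property
    def n_members(self) -> int:
        return self._gallery.n_members

    @property
    def dim(self) -> int:
        return self._gallery.dim

    def get(self, image_id: str) -> EmbeddingSet:
        return self._gallery.get(image_id)

    def __len__(self) -> int:
        return len(self._gallery)

    def __iter__(self):
        return iter(self._gallery)


@dataclasses.dataclass
class DistributionSet:
    """The three resampled mean-pairwise-distance arrays of one analysis."""

    test: np.ndarray
    same: np.ndarray
    random: np.ndarray
    n_resamples: int
    subcohort_size: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Long format: columns ``distribution``, ``draw_index``, ``value``."""
        parts = []
        for name, arr in (("test", self.test), ("same", self.same), ("random", self.random)):
            parts.append(
                pd.DataFrame(
                    {
                        "distribution": name,
                        "draw_index": np.arange(len(arr)),
                        "value": arr,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def sample_subcohort(cohort: Cohort, rng: np.random.Generator) -> list[str]:
    """Draw one image id per subject, uniformly among that subject's images.

    Guarantees no two images of the same subject co-occur in a draw.
    """
    ids = []
    for subject, images in cohort.subjects.items():
        if not images:
            raise ValidationError(f"subject {subject!r} has no images")
        ids.append(images[int(rng.integers(len(images)))])
    return ids


def mean_pairwise_distance(
    ids: Sequence[str], source, *, members: str = "aligned"
) -> float:
    """Arithmetic mean of pair distances over all unordered id pairs."""
    ids = list(ids)
    if len(ids) < 2:
        raise ValidationError("mean_pairwise_distance needs >= 2 image ids")
    items = [source.get(i) for i in ids]
    dist = distance_matrix(items, members=members)
    iu = np.triu_indices(len(ids), k=1)
    return float(dist[iu].mean())


def resample_test_distribution(
    cohort: Cohort,
    n: int = 100,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    members: str = "aligned",
) -> np.ndarray:
    """``n`` mean pairwise distances of independent one-image-per-subject draws."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = mean_pairwise_distance(sample_subcohort(cohort, rng), cohort, members=members)
    return out


def _labelled_subjects(gallery: Gallery) -> dict[str, dict[str, list[str]]]:
    """syndrome -> subject -> image_ids, restricted to fully labelled items."""
    tree: dict[str, dict[str, list[str]]] = {}
    for it in gallery:
        if it.syndrome_label is None:
            continue
        tree.setdefault(it.syndrome_label, {}).setdefault(it.subject_id, []).append(
            it.image_id
        )
    return {
        s: {p: sorted(v) for p, v in sorted(subs.items())} for s, subs in sorted(tree.items())
    }


def _draw_one_image_each(
    subjects: dict[str, list[str]], chosen: Sequence[str], rng: np.random.Generator
) -> list[str]:
    return [subjects[s][int(rng.integers(len(subjects[s])))] for s in chosen]


def build_same_distribution(
    gallery: Gallery,
    size: int,
    n: int = 100,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    members: str = "aligned",
) -> np.ndarray:
    """Null distribution of mean pairwise distance within single syndromes.

    Per draw: a syndrome with >= 2 subjects is chosen uniformly, then
    ``min(size, available)`` distinct subjects of it (one image each).
    Syndromes smaller than ``size`` contribute smaller sub-cohorts rather than
    being excluded, mirroring the many small cohorts of real galleries.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    tree = _labelled_subjects(gallery)
    eligible = [s for s, subs in tree.items() if len(subs) >= 2]
    if not eligible:
        raise ValidationError("no syndrome with >= 2 subjects in the gallery")
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        syndrome = eligible[int(rng.integers(len(eligible)))]
        subs = tree[syndrome]
        m = min(size, len(subs))
        chosen = rng.choice(sorted(subs), size=max(2, m), replace=False)
        ids = _draw_one_image_each(subs, chosen, rng)
        out[i] = mean_pairwise_distance(ids, gallery, members=members)
    return out


def build_random_distribution(
    gallery: Gallery,
    size: int,
    n: int = 100,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    members: str = "aligned",
) -> np.ndarray:
    """Null distribution over sub-cohorts sampled without syndrome constraint."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    subjects = gallery.subject_index
    if len(subjects) < 2:
        raise ValidationError("gallery needs >= 2 subjects for the random null")
    names = sorted(subjects)
    m = min(size, len(names))
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        chosen = rng.choice(names, size=max(2, m), replace=False)
        ids = _draw_one_image_each(subjects, chosen, rng)
        out[i] = mean_pairwise_distance(ids, gallery, members=members)
    return out


def compute_distribution_set(
    cohort: Cohort,
    gallery: Gallery,
    *,
    n_resamples: int = 100,
    size: int | None = None,
    seed: int = 0,
    members: str = "aligned",
) -> DistributionSet:
    """Test distribution plus both nulls, with leakage-safe gallery handling.

    Any cohort image present in the gallery is removed before the nulls are
    built.  ``size`` defaults to the cohort's subject count.  The three stages
    use child generators spawned from ``seed`` so each is independently
    reproducible.
    """
    size = size if size is not None else len(cohort.subjects)
    pool = gallery.without(cohort.ids) if any(i in gallery for i in cohort.ids) else gallery
    rng_test = np.random.default_rng([seed, 1])
    rng_same = np.random.default_rng([seed, 2])
    rng_rand = np.random.default_rng([seed, 3])
    test = resample_test_distribution(cohort, n_resamples, rng=rng_test, members=members)
    same = build_same_distribution(pool, size, n_resamples, rng=rng_same, members=members)
    random = build_random_distribution(pool, size, n_resamples, rng=rng_rand, members=members)
    return DistributionSet(
        test=test,
        same=same,
        random=random,
        n_resamples=n_resamples,
        subcohort_size=size,
        seed=seed,
    )
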