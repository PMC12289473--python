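"""Leave-one-out gallery rank retrieval and top-k syndrome matching.

For each cohort image used as a probe query ("test image"), the remaining
cohort images are inserted into the labelled gallery and every image in that
augmented pool is ranked by ascending ensemble distance.  The rank a cohort
image attains relative to another quantifies individual-level similarity
against the background of the full gallery.  Ties in distance are broken by
lexicographic image id so ranks are deterministic across platforms.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .embeddings import EmbeddingSet, Gallery, ValidationError

__all__ = [
    "RankMatrix",
    "SyndromeMatchTable",
    "rank_images",
    "pairwise_rank_matrix",
    "top_k_matches",
]


def _distances_to_pool(
    test: EmbeddingSet, pool: Sequence[EmbeddingSet], members: str
) -> np.ndarray:
    stack = np.stack([p.vectors for p in pool])  # (n, E, d)
    e = test.n_members
    if members == "aligned":
        cos = np.einsum("kd,nkd->n", test.vectors, stack) / e
    elif members == "all_pairs":
        cos = np.einsum("ad,nbd->n", test.vectors, stack) / (e * stack.shape[1])
    else:
        raise ValueError(f"unknown member pairing {members!r}")
    return np.clip(1.0 - cos, 0.0, 2.0)


def rank_images(
    test: EmbeddingSet, pool: Sequence[EmbeddingSet], *, members: str = "aligned"
) -> list[tuple[str, float, int]]:
    """Sort a pool by ascending distance to ``test``; 1-based ranks.

    Returns ``(image_id, distance, rank)`` triples.  The test image must not
    itself be in the pool.
    """
    pool = list(pool)
    if not pool:
        raise ValidationError("pool must be non-empty")
    ids = [p.image_id for p in pool]
    if test.image_id in ids:
        raise ValidationError(f"test image {test.image_id!r} present in pool")
    dist = _distances_to_pool(test, pool, members)
    order = sorted(range(len(pool)), key=lambda i: (dist[i], ids[i]))
    return [(ids[i], float(dist[i]), r + 1) for r, i in enumerate(order)]


@dataclasses.dataclass
class RankMatrix:
    """Pairwise leave-one-out ranks of cohort images against an augmented gallery.

    ``ranks[i, j]`` is the rank of probe image ``probe_image_ids[i]`` within
    the pool gallery + (cohort minus test image) when ``test_image_ids[j]`` is
    the query; the self diagonal is 0 (undefined).  ``same_subject[i, j]``
    flags probe/test pairs from one subject so self-similarity can be filtered
    out of summaries.
    """

    test_image_ids: list[str]
    probe_image_ids: list[str]
    ranks: np.ndarray
    same_subject: np.ndarray
    gallery_size: int

    def to_frame(self) -> pd.DataFrame:
        """Rows = probes, columns = test images, <NA> on the diagonal."""
        df = pd.DataFrame(
            self.ranks, index=self.probe_image_ids, columns=self.test_image_ids
        ).astype("Int64")
        return df.mask(df == 0)


def pairwise_rank_matrix(
    cohort: Cohort, gallery: Gallery, *, members: str = "aligned"
) -> RankMatrix:
    """Leave-one-out rank of every cohort image relative to every other.

    For each test image the pool is the gallery plus the remaining cohort
    images (same-subject probes included but flagged).
    """
    overlap = [i for i in cohort.ids if i in gallery]
    if overlap:
        raise ValidationError(f"cohort images present in gallery: {overlap[:3]}")
    ids = cohort.ids
    n = len(ids)
    ranks = np.zeros((n, n), dtype=np.int64)
    same_subject = np.zeros((n, n), dtype=bool)
    subj = {it.image_id: it.subject_id for it in cohort}
    for j, test_id in enumerate(ids):
        test = cohort.get(test_id)
        probes = [cohort.get(i) for i in ids if i != test_id]
        pool = list(gallery.items) + probes
        ranked = {iid: rank for iid, _, rank in rank_images(test, pool, members=members)}
        for i, probe_id in enumerate(ids):
            if probe_id == test_id:
                continue
            ranks[i, j] = ranked[probe_id]
            same_subject[i, j] = subj[probe_id] == subj[test_id]
    return RankMatrix(
        test_image_ids=list(ids),
        probe_image_ids=list(ids),
        ranks=ranks,
        same_subject=same_subject,
        gallery_size=len(gallery),
    )


@dataclasses.dataclass
class SyndromeMatchTable:
    """Tallies of syndrome labels among each image's k nearest gallery neighbours.

    ``per_image`` maps image_id -> Counter over syndrome labels (counts sum to
    k); ``per_subject`` sums the tallies over each subject's images;
    ``modal_syndrome`` gives each subject's most frequent match (ties broken
    lexicographically).
    """

    k: int
    per_image: dict[str, Counter]
    per_subject: dict[str, Counter]
    modal_syndrome: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subject, tally in sorted(self.per_subject.items()):
            for label, count in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
                rows.append(
                    {
                        "subject_id": subject,
                        "syndrome_label": label,
                        "count": count,
                        "modal": label == self.modal_syndrome[subject],
                    }
                )
        return pd.DataFrame(rows, columns=["subject_id", "syndrome_label", "count", "modal"])


def top_k_matches(
    cohort: Cohort, gallery: Gallery, k: int = 30, *, members: str = "aligned"
) -> SyndromeMatchTable:
    """Per-image top-k syndrome tallies against the gallery, summed per subject.

    Only gallery images count toward the tallies (cohort probes are excluded
    from the neighbourhood); every gallery image must carry a syndrome label.
    """
    unlabelled = [it.image_id for it in gallery if it.syndrome_label is None]
    if unlabelled:
        raise ValidationError(f"unlabelled gallery images: {unlabelled[:3]}")
    if not 1 <= k <= len(gallery):
        raise ValidationError(f"k={k} out of range for gallery of {len(gallery)}")
    labels = {it.image_id: it.syndrome_label for it in gallery}
    per_image: dict[str, Counter] = {}
    for it in cohort:
        ranked = rank_images(it, gallery.items, members=members)
        per_image[it.image_id] = Counter(labels[iid] for iid, _, rank in ranked[:k])
    per_subject: dict[str, Counter] = {}
    for it in cohort:
        per_subject.setdefault(it.subject_id, Counter()).update(per_image[it.image_id])
    modal = {
        s: min(t.items(), key=lambda kv: (-kv[1], kv[0]))[0] for s, t in per_subject.items()
    }
    return SyndromeMatchTable(
        k=k, per_image=per_image, per_subject=per_subject, modal_syndrome=modal
    )
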