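"""Ensemble facial-embedding containers and cosine-distance arithmetic.

A face image analysed by a next-generation phenotyping ensemble is represented
by ``E`` unit vectors of dimension ``d`` (one per model / test-time
augmentation).  Facial similarity between two images is the cosine distance
averaged across ensemble members.  This module provides the
:class:`EmbeddingSet` / :class:`Gallery` containers, the distance arithmetic,
and plain-text (TSV) plus array-archive (npz) readers and writers that
round-trip float64 values exactly.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "EmbeddingSet",
    "Gallery",
    "normalize_rows",
    "cosine_distance",
    "pair_distance",
    "distance_matrix",
    "load_embeddings",
    "save_gallery",
]


class ValidationError(ValueError):
    """An embedding or gallery violates a structural invariant."""


class FormatError(ValueError):
    """An on-disk embedding file is malformed or internally inconsistent."""


def normalize_rows(vectors: np.ndarray, image_id: str | None = None) -> np.ndarray:
    """L2-normalize each row of an ``E x d`` matrix.

    Zero rows cannot be normalized and are rejected; the offending image id
    (if known) is named in the error message.
    """
    arr = np.array(vectors, dtype=np.float64, copy=True)
    if arr.ndim != 2:
        raise ValidationError(f"embedding matrix must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 2:
        raise ValidationError(
            f"embedding matrix needs E >= 1 members and d >= 2 dims, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite embedding values in image {image_id!r}")
    norms = np.linalg.norm(arr, axis=1)
    if np.any(norms == 0.0):
        raise ValidationError(f"zero-norm ensemble row in image {image_id!r}")
    # bitwise no-op on rows already unit: normalization is idempotent and
    # saved/reloaded galleries round-trip exactly
    off = np.abs(norms - 1.0) > 1e-12
    if off.any():
        arr[off] /= norms[off, None]
    return arr


@dataclasses.dataclass(frozen=True)
class EmbeddingSet:
    """One image's ensemble embedding: ``E`` unit rows of dimension ``d``.

    Parameters
    ----------
    image_id, subject_id
        Identifiers; ``image_id`` must be unique within a gallery, several
        images may share a ``subject_id``.
    vectors
        ``E x d`` real matrix; rows are L2-normalized on construction.
    syndrome_label
        Optional diagnostic label (empty string is treated as absent).
    """

    image_id: str
    subject_id: str
    vectors: np.ndarray
    syndrome_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "vectors", normalize_rows(self.vectors, self.image_id))
        if self.syndrome_label == "":
            object.__setattr__(self, "syndrome_label", None)

    @property
    def n_members(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class Gallery:
    """A labelled collection of :class:`EmbeddingSet` with shared ``E`` and ``d``.

    Provides syndrome -> subjects and subject -> images indices used by the
    null-distribution builders and the rank analysis.
    """

    def __init__(self, items: Sequence[EmbeddingSet]):
        items = list(items)
        if not items:
            raise ValidationError("gallery must contain at least one item")
        e, d = items[0].n_members, items[0].dim
        by_id: dict[str, EmbeddingSet] = {}
        for it in items:
            if it.image_id in by_id:
                raise ValidationError(f"duplicate image_id {it.image_id!r}")
            if (it.n_members, it.dim) != (e, d):
                raise FormatError(
                    f"image {it.image_id!r} has shape {(it.n_members, it.dim)}, "
                    f"expected {(e, d)}"
                )
            by_id[it.image_id] = it
        self.items: list[EmbeddingSet] = items
        self._by_id = by_id

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[EmbeddingSet]:
        return iter(self.items)

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._by_id

    def get(self, image_id: str) -> EmbeddingSet:
        return self._by_id[image_id]

    @property
    def ids(self) -> list[str]:
        return [it.image_id for it in self.items]

    @property
    def n_members(self) -> int:
        return self.items[0].n_members

    @property
    def dim(self) -> int:
        return self.items[0].dim

    # -- indices ------------------------------------------------------------------
    @property
    def subject_index(self) -> dict[str, list[str]]:
        """subject_id -> sorted image_ids."""
        idx: dict[str, list[str]] = {}
        for it in self.items:
            idx.setdefault(it.subject_id, []).append(it.image_id)
        return {s: sorted(v) for s, v in sorted(idx.items())}

    @property
    def syndrome_index(self) -> dict[str, list[str]]:
        """syndrome_label -> sorted subject_ids (unlabelled items excluded)."""
        idx: dict[str, set[str]] = {}
        for it in self.items:
            if it.syndrome_label is not None:
                idx.setdefault(it.syndrome_label, set()).add(it.subject_id)
        return {s: sorted(v) for s, v in sorted(idx.items())}

    def without(self, image_ids: Iterable[str]) -> "Gallery":
        """A new gallery with the given image ids removed."""
        drop = set(image_ids)
        kept = [it for it in self.items if it.image_id not in drop]
        return Gallery(kept)


# ---------------------------------------------------------------------------
# distance arithmetic
# ---------------------------------------------------------------------------

def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - <u, v>`` for unit vectors; in ``[0, 2]``."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.clip(1.0 - u @ v, 0.0, 2.0))


def pair_distance(a: EmbeddingSet, b: EmbeddingSet, *, members: str = "aligned") -> float:
    """Mean cosine distance between two images across ensemble members.

    ``members="aligned"`` (default) compares member ``k`` of ``a`` with member
    ``k`` of ``b`` (one distance per model/augmentation).  ``members="all_pairs"``
    averages the full ``E x E`` grid of member distances.
    """
    if (a.n_members, a.dim) != (b.n_members, b.dim):
        raise ValidationError(
            f"shape mismatch: {a.image_id!r} {(a.n_members, a.dim)} vs "
            f"{b.image_id!r} {(b.n_members, b.dim)}"
        )
    if members == "aligned":
        cos = np.einsum("kd,kd->k", a.vectors, b.vectors).mean()
    elif members == "all_pairs":
        cos = (a.vectors @ b.vectors.T).mean()
    else:
        raise ValueError(f"unknown member pairing {members!r}")
    return float(np.clip(1.0 - cos, 0.0, 2.0))


def distance_matrix(items: Sequence[EmbeddingSet], *, members: str = "aligned") -> np.ndarray:
    """Symmetric matrix of :func:`pair_distance` values with a zero diagonal."""
    items = list(items)
    if len(items) < 2:
        raise ValidationError("distance_matrix needs at least 2 items")
    e, d = items[0].n_members, items[0].dim
    for it in items:
        if (it.n_members, it.dim) != (e, d):
            raise ValidationError(f"shape mismatch for {it.image_id!r}")
    stack = np.stack([it.vectors for it in items])  # (n, E, d)
    if members == "aligned":
        cos = np.einsum("ikd,jkd->ij", stack, stack) / e
    elif members == "all_pairs":
        cos = np.einsum("iad,jbd->ij", stack, stack) / (e * e)
    else:
        raise ValueError(f"unknown member pairing {members!r}")
    dist = np.clip(1.0 - cos, 0.0, 2.0)
    dist = (dist + dist.T) / 2.0  # kill fp asymmetry
    np.fill_diagonal(dist, 0.0)
    return dist


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"#\s*ensemble-embeddings\s+E=(\d+)\s+d=(\d+)")
_META_COLS = ("image_id", "subject_id", "syndrome_label")


def save_gallery(gallery: Gallery, path: str | Path, *, format: str | None = None) -> Path:
    """Write a gallery as a TSV with inline vectors or as an npz archive.

    The format is inferred from the suffix (``.npz`` -> archive, otherwise
    delimited table) unless given explicitly.  Both writers round-trip float64
    values exactly.
    """
    path = Path(path)
    fmt = format or ("archive" if path.suffix == ".npz" else "table")
    if fmt == "table":
        _save_table(gallery, path)
    elif fmt == "archive":
        _save_archive(gallery, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _save_table(gallery: Gallery, path: Path) -> None:
    e, d = gallery.n_members, gallery.dim
    vec_cols = [f"v{i + 1}" for i in range(e * d)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# ensemble-embeddings E={e} d={d}\n")
        fh.write("\t".join(_META_COLS + tuple(vec_cols)) + "\n")
        for it in gallery:
            flat = it.vectors.reshape(-1)  # row-major by member
            vals = "\t".join(f"{x:.17g}" for x in flat)
            label = it.syndrome_label or ""
            fh.write(f"{it.image_id}\t{it.subject_id}\t{label}\t{vals}\n")


def _save_archive(gallery: Gallery, path: Path) -> None:
    arrays: dict[str, np.ndarray] = {
        "image_ids": np.array(gallery.ids, dtype=str),
        "subject_ids": np.array([it.subject_id for it in gallery], dtype=str),
        "syndrome_labels": np.array(
            [it.syndrome_label or "" for it in gallery], dtype=str
        ),
    }
    for it in gallery:
        arrays[f"vectors/{it.image_id}"] = it.vectors
    np.savez(path, **arrays)


def load_embeddings(path: str | Path, *, format: str | None = None) -> Gallery:
    """Read a gallery written by :func:`save_gallery`.

    ``format`` is ``"table"`` or ``"archive"``; by default it is inferred from
    the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding file not found: {path}")
    fmt = format or ("archive" if path.suffix == ".npz" else "table")
    if fmt == "table":
        return _load_table(path)
    if fmt == "archive":
        return _load_archive(path)
    raise ValueError(f"unknown format {format!r}")


def _load_table(path: Path) -> Gallery:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    m = _HEADER_RE.match(first)
    if not m:
        raise FormatError(
            f"{path}: missing '# ensemble-embeddings E=.. d=..' header line"
        )
    e, d = int(m.group(1)), int(m.group(2))
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={c: str for c in _META_COLS},
        float_precision="round_trip",
    )
    for col in _META_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing metadata column {col!r}")
    vec_cols = [f"v{i + 1}" for i in range(e * d)]
    missing = [c for c in vec_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: expected {e * d} vector columns, missing {missing[:3]}...")
    mat = df[vec_cols].to_numpy(dtype=np.float64)
    items = []
    for i, row in enumerate(df.itertuples(index=False)):
        label = getattr(row, "syndrome_label")
        if label is None or (isinstance(label, float) and np.isnan(label)):
            label = ""
        items.append(
            EmbeddingSet(
                image_id=str(row.image_id),
                subject_id=str(row.subject_id),
                vectors=mat[i].reshape(e, d),
                syndrome_label=str(label),
            )
        )
    return Gallery(items)


def _load_archive(path: Path) -> Gallery:
    with np.load(path) as npz:
        image_ids = [str(x) for x in npz["image_ids"]]
        subject_ids = [str(x) for x in npz["subject_ids"]]
        labels = [str(x) for x in npz["syndrome_labels"]]
        if not (len(image_ids) == len(subject_ids) == len(labels)):
            raise FormatError(f"{path}: metadata arrays have inconsistent lengths")
        items = []
        for iid, sid, lab in zip(image_ids, subject_ids, labels):
            key = f"vectors/{iid}"
            if key not in npz:
                raise FormatError(f"{path}: missing vectors for image {iid!r}")
            items.append(
                EmbeddingSet(image_id=iid, subject_id=sid, vectors=npz[key], syndrome_label=lab)
            )
    return Gallery(items)
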