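"""Per-residue feature construction: embedding backends, one-hot encoding,
and assembly into the flattened residue dataset.

An *embedding backend* is anything that deterministically maps a sequence
of length L to an L×D real matrix.  Protein language models (pLMs) such as
ProtTrans (D=1024) and ESM-2 650M (D=1280) are the backends of scientific
interest; they are optional, heavyweight externals.  The package ships two
self-contained backends — ``onehot`` (D=21) and a seeded ``synthetic``
Gaussian embedder — so the full pipeline runs and tests offline.

The final feature vector of a residue is its embedding row concatenated
with the 21-column one-hot encoding of its amino acid (configurable off).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .records import CANONICAL_AA, ProteinRecord
from .splits import SplitAssignment

__all__ = [
    "EmbeddingMatrix",
    "ResidueDataset",
    "one_hot_encode",
    "OneHotBackend",
    "SyntheticBackend",
    "register_backend",
    "get_backend",
    "list_backends",
    "embed",
    "assemble_dataset",
    "save_embeddings",
    "load_embeddings",
]

# fixed alphabetical column order, unknown symbol last
_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
N_ONEHOT = len(CANONICAL_AA) + 1  # 21


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a sequence as an L×21 binary matrix.

    Columns are the 20 canonical amino acids in alphabetical order
    (A, C, D, ..., Y) followed by one unknown column; every row sums to 1.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    out = np.zeros((len(sequence), N_ONEHOT), dtype=np.float32)
    for i, aa in enumerate(sequence.upper()):
        out[i, _AA_INDEX.get(aa, N_ONEHOT - 1)] = 1.0
    return out


@dataclass
class EmbeddingMatrix:
    """L×D per-residue feature matrix for one protein from a named backend."""

    protein_id: str
    backend_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError(
                f"{self.protein_id!r}: embedding must be 2-D, "
                f"got shape {self.values.shape}"
            )

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]


class OneHotBackend:
    """The one-hot encoder exposed as an embedding backend (D = 21)."""

    name = "onehot"
    dimension = N_ONEHOT

    def __call__(self, sequence: str) -> np.ndarray:
        return one_hot_encode(sequence)


class SyntheticBackend:
    """Deterministic pseudo-random embedder for offline pipelines.

    Each residue's vector is drawn from a Gaussian whose stream is seeded
    by (seed, amino acid, position), so identical sequences always embed
    identically while carrying no membrane-interaction signal.  For
    label-correlated synthetic embeddings see :mod:`ibspred.synthetic`.
    """

    name = "synthetic"

    def __init__(self, dimension: int = 32, seed: int = 0):
        if dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.dimension = dimension
        self.seed = seed

    def __call__(self, sequence: str) -> np.ndarray:
        out = np.empty((len(sequence), self.dimension), dtype=np.float32)
        for i, aa in enumerate(sequence):
            rng = np.random.default_rng(
                [self.seed, ord(aa), i % 4096]
            )
            out[i] = rng.standard_normal(self.dimension)
        return out


BackendFactory = Callable[..., Callable[[str], np.ndarray]]
_REGISTRY: dict[str, BackendFactory] = {}


def register_backend(name: str, factory: BackendFactory) -> None:
    _REGISTRY[name] = factory


def _esm_factory(**kwargs):  # pragma: no cover - needs external weights
    try:
        import esm  # type: ignore  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "the 'esm' backend needs the optional fair-esm dependency and "
            "downloaded weights; offline backends: "
            + ", ".join(sorted(_REGISTRY))
        ) from exc
    raise NotImplementedError("plug an ESM wrapper in via register_backend")


def _prottrans_factory(**kwargs):  # pragma: no cover - needs external weights
    try:
        import transformers  # type: ignore  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "the 'prottrans' backend needs the optional transformers "
            "dependency and downloaded weights; offline backends: "
            + ", ".join(sorted(_REGISTRY))
        ) from exc
    raise NotImplementedError("plug a ProtTrans wrapper in via register_backend")


register_backend("onehot", OneHotBackend)
register_backend("synthetic", SyntheticBackend)
register_backend("esm", _esm_factory)
register_backend("prottrans", _prottrans_factory)


def list_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(name: str, **kwargs) -> Callable[[str], np.ndarray]:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; registered backends: "
            + ", ".join(sorted(_REGISTRY))
        ) from None
    return factory(**kwargs)


def embed(backend, sequence: str, protein_id: str = "") -> EmbeddingMatrix:
    """Run one sequence through a backend (by name or instance)."""
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    if isinstance(backend, str):
        backend = get_backend(backend)
    values = np.asarray(backend(sequence), dtype=np.float32)
    name = getattr(backend, "name", type(backend).__name__)
    if values.shape[0] != len(sequence):
        raise ValueError(
            f"backend {name!r} returned {values.shape[0]} rows for a "
            f"length-{len(sequence)} sequence"
        )
    return EmbeddingMatrix(protein_id, name, values)


def embed_records(
    backend, records: Sequence[ProteinRecord]
) -> dict[str, EmbeddingMatrix]:
    if isinstance(backend, str):
        backend = get_backend(backend)
    return {r.id: embed(backend, r.sequence, r.id) for r in records}


@dataclass
class ResidueDataset:
    """Flattened (protein, position) → feature vector + label table.

    ``meta`` has one row per residue with columns ``protein_id``,
    ``position`` (0-based), ``label`` and ``split``; ``X`` is the aligned
    feature matrix.  Row order is sorted by (protein_id, position).
    """

    X: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.X) != len(self.meta):
            raise ValueError("feature matrix and metadata row counts differ")
        if self.meta.duplicated(["protein_id", "position"]).any():
            raise ValueError("duplicate (protein_id, position) rows")

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=np.int8)

    def subset(self, split: str) -> "ResidueDataset":
        mask = (self.meta["split"] == split).to_numpy()
        return ResidueDataset(self.X[mask], self.meta[mask].reset_index(drop=True))

    def subset_proteins(self, protein_ids: Sequence[str]) -> "ResidueDataset":
        mask = self.meta["protein_id"].isin(set(protein_ids)).to_numpy()
        return ResidueDataset(self.X[mask], self.meta[mask].reset_index(drop=True))


def assemble_dataset(
    records: Sequence[ProteinRecord],
    embeddings: Mapping[str, EmbeddingMatrix],
    split: SplitAssignment | None = None,
    include_one_hot: bool = True,
) -> ResidueDataset:
    """Flatten labeled proteins into one residue-level dataset.

    Feature vector = embedding row (++ one-hot row when enabled); one row
    per residue; split tags copied from the protein-level assignment.
    """
    blocks: list[np.ndarray] = []
    meta_rows: list[pd.DataFrame] = []
    dims = set()
    for rec in sorted(records, key=lambda r: r.id):
        if rec.labels is None:
            raise ValueError(f"record {rec.id!r} has no labels")
        try:
            emb = embeddings[rec.id]
        except KeyError:
            raise KeyError(f"no embedding for protein {rec.id!r}") from None
        if len(emb) != len(rec.sequence):
            raise ValueError(
                f"protein {rec.id!r}: embedding rows {len(emb)} != "
                f"sequence length {len(rec.sequence)}"
            )
        feats = emb.values
        if include_one_hot:
            feats = np.hstack([feats, one_hot_encode(rec.sequence)])
        dims.add(feats.shape[1])
        blocks.append(feats)
        meta_rows.append(
            pd.DataFrame(
                {
                    "protein_id": rec.id,
                    "position": np.arange(len(rec.sequence)),
                    "label": rec.labels.astype(np.int8),
                    "split": split[rec.id] if split is not None else "train",
                }
            )
        )
    if not blocks:
        raise ValueError("no records to assemble")
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature lengths across proteins: {dims}")
    X = np.vstack(blocks).astype(np.float32)
    meta = pd.concat(meta_rows, ignore_index=True)
    return ResidueDataset(X, meta)


def save_dataset(path: str | Path, dataset: ResidueDataset) -> None:
    """Persist a residue dataset as a compressed .npz archive."""
    np.savez_compressed(
        path,
        X=dataset.X.astype(np.float32),
        protein_id=dataset.meta["protein_id"].to_numpy(dtype=str),
        position=dataset.meta["position"].to_numpy(dtype=np.int64),
        label=dataset.meta["label"].to_numpy(dtype=np.int8),
        split=dataset.meta["split"].to_numpy(dtype=str),
    )


def load_dataset(path: str | Path) -> ResidueDataset:
    with np.load(path, allow_pickle=False) as archive:
        meta = pd.DataFrame(
            {
                "protein_id": archive["protein_id"],
                "position": archive["position"],
                "label": archive["label"],
                "split": archive["split"],
            }
        )
        return ResidueDataset(archive["X"], meta)


def save_embeddings(path: str | Path, matrices: Mapping[str, EmbeddingMatrix]) -> None:
    """Write an HDF5 container: one dataset per protein id, homogeneous backend."""
    if not matrices:
        raise ValueError("nothing to save")
    names = {m.backend_name for m in matrices.values()}
    if len(names) != 1:
        raise ValueError(f"mixed backends in one container: {sorted(names)}")
    dims = {m.dimension for m in matrices.values()}
    if len(dims) != 1:
        raise ValueError(f"mixed dimensions in one container: {sorted(dims)}")
    with h5py.File(path, "w") as fh:
        fh.attrs["backend_name"] = names.pop()
        fh.attrs["dimension"] = dims.pop()
        for pid, mat in matrices.items():
            fh.create_dataset(pid, data=mat.values.astype(np.float32))


def load_embeddings(
    path: str | Path, protein_ids: Sequence[str] | None = None
) -> dict[str, EmbeddingMatrix]:
    try:
        fh = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise OSError(f"cannot open embedding container {path}: {exc}") from exc
    with fh:
        backend = str(fh.attrs["backend_name"])
        keys = list(fh.keys())
        if protein_ids is not None:
            missing = set(protein_ids) - set(keys)
            if missing:
                raise KeyError(
                    f"container {path} lacks proteins: {sorted(missing)}"
                )
            keys = list(protein_ids)
        return {
            pid: EmbeddingMatrix(pid, backend, fh[pid][()]) for pid in keys
        }
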