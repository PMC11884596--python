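"""Global and residue-level sequence context from a pluggable embedder.

The working backend is a deterministic mock: every residue embeds as the
unit-normalized sum of a letter vector and a scaled position-bucket vector,
both drawn from seeded generators.  Identical residues in the same coarse
position bucket embed identically, the same letter in different buckets
stays strongly similar, and different letters are near-orthogonal — a
caricature of the locality structure a protein language model produces,
sufficient to train and test the whole pipeline offline.

A ``plm`` backend slot exists for a real protein language model (ESM-2
class, 2560-dim per residue); requesting it without the model installed
raises an explicit error rather than silently falling back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CROP_WINDOW = 1022
_CONTEXT_SCALE = 0.5  # weight of the position-bucket component in mock rows
_BUCKET_SIZE = 32     # residues per coarse position bucket


class EmbedderBackendError(RuntimeError):
    """Raised when the requested embedding backend cannot run."""


@dataclass
class EmbedderConfig:
    backend: str = "mock"            # "mock" | "plm"
    mock_dim: int = 64
    crop_window: int = DEFAULT_CROP_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("mock", "plm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.mock_dim <= 0:
            raise ValueError("mock_dim must be positive")
        if self.crop_window < 1:
            raise ValueError("crop_window must be positive")


@dataclass
class EmbeddingMatrix:
    """L×D per-residue representations plus their global mean vector."""

    per_residue: np.ndarray   # (L, D)
    global_vector: np.ndarray  # (D,) == column mean of per_residue
    backend_tag: str

    @property
    def dim(self) -> int:
        return self.per_residue.shape[1]

    def __len__(self) -> int:
        return self.per_residue.shape[0]


def _mock_row(letter: str, bucket: int, dim: int, seed: int) -> np.ndarray:
    letter_vec = np.random.default_rng([seed, 1, ord(letter)]).standard_normal(dim)
    bucket_vec = np.random.default_rng([seed, 2, bucket]).standard_normal(dim)
    row = letter_vec / np.linalg.norm(letter_vec) + _CONTEXT_SCALE * (
        bucket_vec / np.linalg.norm(bucket_vec)
    )
    return row / np.linalg.norm(row)


def embed_sequence(sequence: str, config: EmbedderConfig | None = None) -> EmbeddingMatrix:
    """Embed a sequence into an L×D matrix plus a mean-pooled global vector."""
    config = config or EmbedderConfig()
    if not sequence:
        raise ValueError("sequence is empty")
    if config.backend == "plm":
        raise EmbedderBackendError(
            "the 'plm' backend needs a pretrained protein language model, "
            "which is not installed; use backend='mock'"
        )
    # cache rows per (letter, bucket): identical contexts embed identically
    cache: dict[tuple[str, int], np.ndarray] = {}
    rows = np.empty((len(sequence), config.mock_dim))
    for i, letter in enumerate(sequence):
        key = (letter, i // _BUCKET_SIZE)
        if key not in cache:
            cache[key] = _mock_row(letter, key[1], config.mock_dim, config.seed)
        rows[i] = cache[key]
    return EmbeddingMatrix(
        per_residue=rows,
        global_vector=rows.mean(axis=0),
        backend_tag=config.backend,
    )


def crop_to_window(
    sequence: str, site_index: int, window: int
) -> tuple[str, int, int]:
    """Center-crop an over-long sequence around a 0-based site index.

    Returns (cropped sequence, site index within the crop, crop start).
    Sequences already within the window are returned unchanged.
    """
    if not 0 <= site_index < len(sequence):
        raise IndexError(f"site index {site_index} outside sequence")
    if len(sequence) <= window:
        return sequence, site_index, 0
    start = site_index - window // 2
    start = max(0, min(start, len(sequence) - window))
    return sequence[start : start + window], site_index - start, start


def project_embeddings(
    matrix: EmbeddingMatrix | np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Row-wise affine map D→C of per-residue embeddings."""
    per_residue = matrix.per_residue if isinstance(matrix, EmbeddingMatrix) else matrix
    if per_residue.shape[1] != weights.shape[0]:
        raise ValueError(
            f"embedding dim {per_residue.shape[1]} does not match weights "
            f"{weights.shape}"
        )
    out = per_residue @ weights
    if bias is not None:
        out = out + bias
    return out


def build_query(
    matrix: np.ndarray,
    site_index: int,
    mode: str = "global_site",
    window: int = 15,
) -> np.ndarray:
    """Assemble the cross-attention query token matrix for one site.

    ``global_site`` (default): two tokens, the mean-pooled global vector and
    the site residue's own row.  ``window``: the global token followed by a
    fixed-width window of rows centered on the site, indices clamped at the
    chain ends so the token count is constant.
    """
    L = matrix.shape[0]
    if not 0 <= site_index < L:
        raise IndexError(f"site index {site_index} outside 0..{L - 1}")
    global_token = matrix.mean(axis=0)
    if mode == "global_site":
        return np.stack([global_token, matrix[site_index]])
    if mode == "window":
        half = window // 2
        idx = np.clip(np.arange(site_index - half, site_index - half + window), 0, L - 1)
        return np.vstack([global_token[None, :], matrix[idx]])
    raise ValueError(f"unknown query mode {mode!r}")


def query_token_count(mode: str = "global_site", window: int = 15) -> int:
    if mode == "global_site":
        return 2
    if mode == "window":
        return window + 1
    raise ValueError(f"unknown query mode {mode!r}")
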