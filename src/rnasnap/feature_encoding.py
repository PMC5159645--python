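"""Windowed feature encoding of per-position base vectors.

Each sequence position carries a 4-vector: either a ±1 one-hot over A,C,G,U
(sequence mode) or the normalized profile row (profile mode).  The feature
row for position i concatenates the vectors at positions i−w … i+w, giving
4×(2w+1) features; positions falling off either end of the sequence are
filled with the padding vector (−1,−1,−1,−1).  With the default window
w = 40 this yields 324 features — comparable to the 340 = 20×(2×8+1) of a
window-8 encoding over the 20-letter protein alphabet, compensating the
lower per-position information content of a 4-letter alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RNA_ALPHABET = "ACGU"


@dataclass(frozen=True)
class EncoderConfig:
    """Window half-width, encoding mode, and padding vector."""

    window: int = 40
    mode: str = "seq"  # "seq" (one-hot) or "prof" (profile rows)
    alphabet: str = RNA_ALPHABET

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.mode not in ("seq", "prof"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_features(self) -> int:
        return len(self.alphabet) * (2 * self.window + 1)

    @property
    def pad_vector(self) -> np.ndarray:
        return -np.ones(len(self.alphabet))


def encode_onehot(sequence: str, alphabet: str = RNA_ALPHABET) -> np.ndarray:
    """±1 one-hot rows: +1 at the position's base, −1 elsewhere.

    T is read as U; symbols outside the alphabet encode as the all −1
    vector (identical to the terminal padding vector, keeping the feature
    alphabet closed).
    """
    if not sequence:
        raise ValueError("empty sequence")
    index = {b: k for k, b in enumerate(alphabet)}
    out = -np.ones((len(sequence), len(alphabet)))
    for i, c in enumerate(sequence.upper()):
        if alphabet == RNA_ALPHABET and c == "T":
            c = "U"
        j = index.get(c)
        if j is not None:
            out[i, j] = 1.0
    return out


def window_features(vectors: np.ndarray, cfg: EncoderConfig | None = None) -> np.ndarray:
    """Concatenate each position's neighbourhood into one feature row.

    ``vectors`` is (L, A); the result is (L, A×(2w+1)), rows ordered by
    position, window positions left to right, padding where the window
    overhangs the sequence ends.
    """
    cfg = cfg or EncoderConfig()
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be 2-D (positions × alphabet)")
    L, A = vectors.shape
    if A != len(cfg.alphabet):
        raise ValueError(
            f"vector width {A} does not match alphabet size {len(cfg.alphabet)}"
        )
    if L == 0:
        raise ValueError("need at least one position")
    w = cfg.window
    padded = np.concatenate(
        [np.tile(cfg.pad_vector, (w, 1)), vectors, np.tile(cfg.pad_vector, (w, 1))]
    )
    # row i = padded[i : i + 2w+1] flattened
    rows = np.lib.stride_tricks.sliding_window_view(padded, (2 * w + 1, A))
    return rows.reshape(L, cfg.n_features).copy()


def encode_sequence(sequence: str, cfg: EncoderConfig | None = None) -> np.ndarray:
    """One-hot + windowing in one call (sequence mode)."""
    cfg = cfg or EncoderConfig()
    return window_features(encode_onehot(sequence, cfg.alphabet), cfg)


def encode_profile(norm_profile: np.ndarray, cfg: EncoderConfig | None = None) -> np.ndarray:
    """Windowing of normalized profile rows (profile mode)."""
    cfg = cfg or EncoderConfig(mode="prof")
    return window_features(norm_profile, cfg)
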