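"""Sequence profiles from multiple sequence alignments.

A profile summarises, for every query position i and base j ∈ {A,C,G,U},
how often j is observed among aligned homologs.  Counts receive asymmetric
pseudocounts (9.0 for the query's own base, 0.3 for the other three) to
avoid zero frequencies, are converted to negative log frequencies

    P[i][j] = −log( N'[i][j] / Σ_j N'[i][j] ),

and finally min–max mapped onto (−1, 1) for use as regression features.
The map's anchors (p_lo, p_hi) are fitted on the training set and persisted
with the model; at prediction time out-of-range values are clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGU"
BASE_INDEX = {b: k for k, b in enumerate(BASES)}

# IUPAC ambiguity codes → compatible bases (fractional counts split equally).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class PseudocountConfig:
    """Additive count corrections: s_query for the query's base, s_other else."""

    s_query: float = 9.0
    s_other: float = 0.3

    def __post_init__(self) -> None:
        if self.s_query < 0 or self.s_other < 0:
            raise ValueError("pseudocounts must be non-negative")


@dataclass
class AlignmentCounts:
    """Observed base counts per query position.

    counts : (L, 4) array over A,C,G,U; query : ungapped query sequence.
    """

    counts: np.ndarray
    query: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (L, 4)")
        if self.counts.shape[0] != len(self.query):
            raise ValueError("query length must equal number of count rows")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class SeqProfile:
    """Raw −log-frequency profile and its (−1,1)-normalized form."""

    query: str
    raw: np.ndarray
    norm: np.ndarray | None = None
    bounds: tuple[float, float] | None = None


def _norm_char(c: str) -> str:
    return c.upper().replace("T", "U")


def count_alignment_columns(
    alignment: list[str], query: str | None = None
) -> AlignmentCounts:
    """Count bases per query position over aligned rows (query row included).

    ``alignment[0]`` is the query row in alignment coordinates; columns where
    it carries a gap are skipped, so counts live in ungapped query
    coordinates.  Gap characters contribute to no base; IUPAC ambiguity codes
    contribute fractional counts split among their compatible bases.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    for k, row in enumerate(alignment):
        if len(row) != width:
            raise ValueError(
                f"alignment row {k} has length {len(row)}, expected {width}"
            )
    query_row = alignment[0]
    query_cols = [c for c in range(width) if query_row[c] not in GAP_CHARS]
    qseq = "".join(_norm_char(query_row[c]) for c in query_cols)
    if query is not None and _norm_char_seq(query) != qseq:
        raise ValueError("supplied query does not match alignment's first row")

    counts = np.zeros((len(query_cols), 4))
    for row in alignment:
        for i, c in enumerate(query_cols):
            ch = _norm_char(row[c])
            if ch in GAP_CHARS:
                continue
            bases = IUPAC.get(ch)
            if bases is None:
                continue  # unknown symbol: contributes nothing
            w = 1.0 / len(bases)
            for b in bases:
                counts[i, BASE_INDEX[b]] += w
    return AlignmentCounts(counts=counts, query=qseq)


def _norm_char_seq(s: str) -> str:
    return "".join(_norm_char(c) for c in s)


def apply_pseudocounts(
    counts: AlignmentCounts, cfg: PseudocountConfig | None = None
) -> np.ndarray:
    """Corrected counts: + s_query at the query base, + s_other elsewhere.

    A query base outside {A,C,G,U} gets the uniform s_other at every base
    (no query bonus).
    """
    cfg = cfg or PseudocountConfig()
    out = counts.counts + cfg.s_other
    for i, b in enumerate(counts.query):
        j = BASE_INDEX.get(_norm_char(b))
        if j is None:
            out[i] = counts.counts[i] + cfg.s_other
        else:
            out[i, j] = counts.counts[i, j] + cfg.s_query
    return out


def counts_to_profile(corrected: np.ndarray, query: str) -> SeqProfile:
    """Negative natural-log frequencies per column."""
    corrected = np.asarray(corrected, dtype=float)
    sums = corrected.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("zero column sum; apply pseudocounts first")
    raw = -np.log(corrected / sums)
    return SeqProfile(query=_norm_char_seq(query), raw=raw)


def normalize_profile(
    profile: SeqProfile, bounds: tuple[float, float] | None = None
) -> SeqProfile:
    """Affine-map raw values onto [−1, 1], clamping outside stored bounds.

    Without ``bounds`` the map anchors are the min/max of the input profile
    and are stored on the returned profile for reuse at prediction time.
    """
    raw = profile.raw
    if bounds is None:
        p_lo, p_hi = float(raw.min()), float(raw.max())
    else:
        p_lo, p_hi = bounds
    if p_hi == p_lo:
        logger.warning("degenerate profile bounds (p_lo == p_hi); norm set to 0")
        norm = np.zeros_like(raw)
    else:
        norm = np.clip(2.0 * (raw - p_lo) / (p_hi - p_lo) - 1.0, -1.0, 1.0)
    return SeqProfile(query=profile.query, raw=raw, norm=norm, bounds=(p_lo, p_hi))


def profile_from_alignment(
    alignment: list[str],
    pseudo: PseudocountConfig | None = None,
    bounds: tuple[float, float] | None = None,
) -> SeqProfile:
    """Alignment → counts → pseudocounts → raw profile → normalized profile."""
    counts = count_alignment_columns(alignment)
    corrected = apply_pseudocounts(counts, pseudo)
    prof = counts_to_profile(corrected, counts.query)
    return normalize_profile(prof, bounds)


# ---------------------------------------------------------------------------
# I/O adapters.  Upstream homology search (e.g. BLASTN vs NT, E < 0.001,
# ≤ 50,000 homologs) is run externally; these adapters consume its output.


def read_aligned_fasta(path: str) -> list[str]:
    """Aligned FASTA, query first; returns rows in alignment coordinates."""
    from Bio import SeqIO

    rows = [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return rows


def read_counts_tsv(path: str) -> AlignmentCounts:
    """Pre-tabulated counts TSV with columns: position, base, nA, nC, nG, nU."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    counts = df[["nA", "nC", "nG", "nU"]].to_numpy(dtype=float)
    query = "".join(_norm_char(b) for b in df["base"])
    return AlignmentCounts(counts=counts, query=query)


def write_profile_tsv(path: str, profile: SeqProfile) -> None:
    """TSV: position, base, raw P per base, normalized value per base."""
    import pandas as pd

    cols = {"position": np.arange(len(profile.query)), "base": list(profile.query)}
    for k, b in enumerate(BASES):
        cols[f"P_{b}"] = profile.raw[:, k]
    if profile.norm is not None:
        for k, b in enumerate(BASES):
            cols[f"norm_{b}"] = profile.norm[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")
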