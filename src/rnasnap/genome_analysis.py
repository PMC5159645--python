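"""Downstream genome-scale procedures built on predicted accessibility.

Three analyses:

* DMS reactivity normalization — raw read counts per mRNA and condition
  (denature / in vitro / in vivo) are scaled by each condition's per-mRNA
  maximum (removing abundance effects), averaged over non-overlapping
  50-base fragments, and reported as the compare/denature ratio per
  fragment (removing position-dependent bias); fragments with a zero
  denature or compare mean are dropped.

* MAF-bin association — single-nucleotide variants are sorted by predicted
  accessibility at the mutation site and split into (by default) 100
  equal-occupancy bins; the Pearson r between bin-mean predicted value and
  bin-mean log10(minor allele frequency) quantifies the accessibility /
  allele-frequency association, optionally stratified by region class or
  mutation type.

* Transcript boundary profiles — per-base predicted accessibility averaged
  over transcripts at offsets −50…+49 around each region boundary
  (5'UTR|CDS, CDS|intron, intron|CDS, CDS|3'UTR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation_metrics import pearson

logger = logging.getLogger(__name__)

DMS_FRAGMENT_LENGTH = 50
DMS_CONDITIONS = ("denature", "invitro", "vivo")
REGION_CLASSES = ("synonymous", "nonsynonymous", "3UTR", "5UTR", "ncRNA")
BOUNDARY_TYPES = ("5UTR|CDS", "CDS|intron", "intron|CDS", "CDS|3UTR")
DEFAULT_FLANK = 50
MIN_REGION_LENGTH = 100


@dataclass
class DmsTrack:
    """Raw per-base read counts for one mRNA under each probing condition."""

    mrna_id: str
    counts: dict[str, np.ndarray]
    fragment_length: int = DMS_FRAGMENT_LENGTH

    def __post_init__(self) -> None:
        self.counts = {c: np.asarray(v, dtype=float) for c, v in self.counts.items()}
        lengths = {v.shape[0] for v in self.counts.values()}
        if len(lengths) != 1:
            raise ValueError("all condition tracks must have the same length")
        for c, v in self.counts.items():
            if np.any(v < 0):
                raise ValueError(f"negative read count in condition {c!r}")

    @property
    def length(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    def n_reacted(self, condition: str = "denature") -> int:
        return int(np.count_nonzero(self.counts[condition]))


def filter_tracks_by_reacted(
    tracks: list[DmsTrack], min_reacted: int = 4000, condition: str = "denature"
) -> list[DmsTrack]:
    """Keep mRNAs with at least ``min_reacted`` nonzero-count bases."""
    return [t for t in tracks if t.n_reacted(condition) >= min_reacted]


def normalize_dms(track: DmsTrack, compare: str = "vivo") -> pd.DataFrame:
    """Per-fragment normalized reactivity of ``compare`` relative to denature.

    Steps, in order: (1) divide each condition by its own per-mRNA maximum
    read; (2) average over consecutive non-overlapping fragments (a trailing
    partial fragment is dropped); (3) drop fragments whose denature or
    compare mean is zero; (4) ratio = compare / denature per survivor.
    """
    if compare not in track.counts:
        raise ValueError(f"condition {compare!r} not in track")
    if "denature" not in track.counts:
        raise ValueError("track lacks a denature condition")
    den_raw = track.counts["denature"]
    cmp_raw = track.counts[compare]
    if den_raw.max() == 0 or cmp_raw.max() == 0:
        raise ValueError("zero maximum read count; cannot normalize")

    L = track.length
    flen = track.fragment_length
    n_frag = L // flen
    if n_frag == 0:
        logger.warning("%s shorter than one fragment; empty result", track.mrna_id)
        return pd.DataFrame(
            columns=["mrna_id", "fragment_index", "denature", "compare", "ratio"]
        )

    den = (den_raw / den_raw.max())[: n_frag * flen].reshape(n_frag, flen).mean(axis=1)
    cmp_ = (cmp_raw / cmp_raw.max())[: n_frag * flen].reshape(n_frag, flen).mean(axis=1)
    keep = (den > 0) & (cmp_ > 0)
    if not keep.any():
        logger.warning("%s: all fragments dropped (null counts)", track.mrna_id)
    idx = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "mrna_id": track.mrna_id,
            "fragment_index": idx,
            "denature": den[idx],
            "compare": cmp_[idx],
            "ratio": cmp_[idx] / den[idx],
        }
    )


# ---------------------------------------------------------------------------
# MAF binning


@dataclass
class BinSummary:
    """One equal-occupancy bin of SNVs sorted by predicted accessibility."""

    bin_index: int
    mean_predicted: float
    mean_log_maf: float
    n: int


def _check_snv_frame(snvs: pd.DataFrame) -> pd.DataFrame:
    required = {"predicted_asa", "maf"}
    missing = required - set(snvs.columns)
    if missing:
        raise ValueError(f"SNV table lacks columns: {sorted(missing)}")
    bad = ~(snvs["maf"] > 0)
    if bad.any():
        logger.warning("rejecting %d SNVs with MAF <= 0", int(bad.sum()))
        snvs = snvs[~bad]
    return snvs


def bin_association(
    snvs: pd.DataFrame, n_bins: int = 100
) -> tuple[list[BinSummary], float]:
    """Equal-occupancy binning by predicted value; r over (bin means).

    Stable sort by predicted value ascending (ties keep input order); bin
    sizes are ⌊n/n_bins⌋ with the first n mod n_bins bins one record larger.
    Returns the bins and the Pearson r between bin-mean predicted value and
    bin-mean log10(MAF).
    """
    snvs = _check_snv_frame(snvs)
    n = len(snvs)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} SNVs, got {n}")
    order = np.argsort(snvs["predicted_asa"].to_numpy(), kind="stable")
    pred = snvs["predicted_asa"].to_numpy()[order]
    log_maf = np.log10(snvs["maf"].to_numpy()[order])

    base, extra = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:extra] += 1
    edges = np.concatenate(([0], np.cumsum(sizes)))
    bins = [
        BinSummary(
            bin_index=b,
            mean_predicted=float(pred[edges[b]:edges[b + 1]].mean()),
            mean_log_maf=float(log_maf[edges[b]:edges[b + 1]].mean()),
            n=int(sizes[b]),
        )
        for b in range(n_bins)
    ]
    r = pearson([b.mean_predicted for b in bins], [b.mean_log_maf for b in bins])
    return bins, r


def stratified_bin_association(
    snvs: pd.DataFrame,
    stratify_by: str = "region",
    n_bins: int = 100,
    min_stratum: int | None = None,
) -> dict[str, tuple[list[BinSummary], float]]:
    """bin_association per stratum; strata below ``min_stratum`` (default
    n_bins) records are skipped with a warning."""
    if stratify_by not in snvs.columns:
        raise ValueError(f"no column {stratify_by!r} in SNV table")
    min_stratum = n_bins if min_stratum is None else min_stratum
    out: dict[str, tuple[list[BinSummary], float]] = {}
    for name, group in snvs.groupby(stratify_by, sort=False):
        if len(group) < min_stratum:
            logger.warning(
                "stratum %r has %d records (< %d); skipped", name, len(group), min_stratum
            )
            continue
        out[str(name)] = bin_association(group, n_bins=n_bins)
    return out


# ---------------------------------------------------------------------------
# Transcript boundary profiles


@dataclass
class TranscriptAsa:
    """Per-base predicted accessibility plus an ordered region annotation.

    ``regions`` is a list of (label, start, end) with 0-based half-open
    coordinates covering the transcript in order, labels from
    {5UTR, CDS, intron, 3UTR}.
    """

    transcript_id: str
    asa: np.ndarray
    regions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.asa = np.asarray(self.asa, dtype=float)
        pos = 0
        for label, start, end in self.regions:
            if start != pos or end <= start:
                raise ValueError(
                    f"{self.transcript_id}: regions must be ordered, contiguous, non-empty"
                )
            pos = end
        if pos != len(self.asa):
            raise ValueError(f"{self.transcript_id}: regions must cover the transcript")

    def min_region_length(self) -> int:
        return min(end - start for _, start, end in self.regions)

    def boundaries(self) -> list[tuple[str, int]]:
        """(boundary_type, position) for each adjacent region pair."""
        out = []
        for (la, _, end_a), (lb, start_b, _) in zip(self.regions, self.regions[1:]):
            out.append((f"{la}|{lb}", start_b))
        return out


def boundary_profile(
    transcripts: list[TranscriptAsa],
    flank: int = DEFAULT_FLANK,
    min_region_length: int = MIN_REGION_LENGTH,
) -> tuple[dict[str, np.ndarray], int]:
    """Mean accessibility at offsets −flank…+flank−1 around each boundary type.

    Transcripts with any region shorter than ``min_region_length`` are
    excluded (their count is returned).  Offset 0 is the first base of the
    downstream region.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    n_excluded = 0
    for tr in transcripts:
        if tr.min_region_length() < min_region_length:
            n_excluded += 1
            continue
        for btype, pos in tr.boundaries():
            window = tr.asa[pos - flank: pos + flank]
            if window.shape[0] != 2 * flank:
                continue  # boundary too close to a transcript end
            if btype not in sums:
                sums[btype] = np.zeros(2 * flank)
                counts[btype] = 0
            sums[btype] += window
            counts[btype] += 1
    profiles = {b: sums[b] / counts[b] for b in sums}
    return profiles, n_excluded


# ---------------------------------------------------------------------------
# I/O adapters (pre-annotated TSV in, TSV out)


def read_dms_tsv(path: str, fragment_length: int = DMS_FRAGMENT_LENGTH) -> list[DmsTrack]:
    """TSV columns: mrna_id, position, denature, invitro, vivo."""
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for mid, group in df.groupby("mrna_id", sort=False):
        group = group.sort_values("position")
        tracks.append(
            DmsTrack(
                mrna_id=str(mid),
                counts={c: group[c].to_numpy(dtype=float) for c in DMS_CONDITIONS},
                fragment_length=fragment_length,
            )
        )
    return tracks


def read_snv_tsv(path: str) -> pd.DataFrame:
    """TSV columns: id, region, mutation_type, predicted_asa, maf."""
    return pd.read_csv(path, sep="\t")


def read_transcripts(pred_tsv: str, regions_tsv: str) -> list[TranscriptAsa]:
    """Per-base prediction TSV (transcript_id, position, asa_norm) plus a
    BED-like region TSV (transcript_id, region, start, end; 0-based half-open)."""
    preds = pd.read_csv(pred_tsv, sep="\t")
    regions = pd.read_csv(regions_tsv, sep="\t")
    out = []
    for tid, group in preds.groupby("transcript_id", sort=False):
        asa = group.sort_values("position")["asa_norm"].to_numpy(dtype=float)
        reg = regions[regions["transcript_id"] == tid].sort_values("start")
        out.append(
            TranscriptAsa(
                transcript_id=str(tid),
                asa=asa,
                regions=[
                    (str(r.region), int(r.start), int(r.end))
                    for r in reg.itertuples()
                ],
            )
        )
    return out
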