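"""Seeded synthetic data generators with planted, recoverable structure.

Every input class the package consumes can be emulated here: toy RNA
coordinate sets (for the accessibility pipeline), mutated-homolog
alignments (for profiles), windowed-signal regression sets (for the SVR),
SNV tables with a planted accessibility–allele-frequency link, and DMS
read tracks with a shared positional bias plus an in-vivo-only exposure
signal.  All outputs are fully determined by an integer seed
(integer-state RNG, no time or locale dependence).

Geometry is deliberately simple — residues along a self-avoiding random
walk with ~8 named heavy atoms each, no base pairing or helices — enough
to exercise area quadrature, completeness filtering and aggregation, not
to mimic real RNA folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemdata import VDW_RADII
from .feature_encoding import EncoderConfig, encode_onehot, window_features
from .genome_analysis import DmsTrack
from .structure_asa import AtomSet

BASES = "ACGU"

# Simplified per-base heavy-atom inventories (~8 atoms), standing in for the
# full nucleotide chemistry.
SIMPLE_INVENTORY: dict[str, tuple[str, ...]] = {
    "A": ("P", "O5'", "C4'", "C1'", "N9", "C8", "N1", "C2"),
    "G": ("P", "O5'", "C4'", "C1'", "N9", "C8", "N1", "O6"),
    "C": ("P", "O5'", "C4'", "C1'", "N1", "C2", "N4", "O2"),
    "U": ("P", "O5'", "C4'", "C1'", "N1", "C2", "O4", "O2"),
}

MIN_ATOM_SPACING = 1.5  # Å, enforced global minimum pairwise distance


def simple_expected_inventories(sequence: str) -> list[frozenset[str]]:
    """Expected (simplified) inventory per residue of a fixture chain."""
    return [frozenset(SIMPLE_INVENTORY[b]) for b in sequence]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_synthetic_chain(
    seed: int,
    n_residues: int = 8,
    delete_atoms: list[tuple[int, str]] | None = None,
    step: float = 6.0,
    jitter: float = 2.2,
    max_retries: int = 200,
) -> tuple[AtomSet, str]:
    """Sterically plausible toy chain: residue centres on a random walk,
    atoms jittered around each centre, global min spacing ≥ 1.5 Å.

    ``delete_atoms`` removes named atoms from given residues to exercise the
    completeness filter.  Returns (AtomSet, sequence).
    """
    rng = np.random.default_rng(seed)
    sequence = random_sequence(rng, n_residues)
    deleted = set(delete_atoms or [])

    centers = [np.zeros(3)]
    for _ in range(1, n_residues):
        d = rng.normal(size=3)
        centers.append(centers[-1] + step * d / np.linalg.norm(d))

    names, elements, radii, coords, ridx, rbase = [], [], [], [], [], []
    placed: list[np.ndarray] = []
    for i, base in enumerate(sequence):
        for atom_name in SIMPLE_INVENTORY[base]:
            if (i, atom_name) in deleted:
                continue
            for attempt in range(max_retries):
                pos = centers[i] + rng.uniform(-jitter, jitter, size=3)
                if all(np.linalg.norm(pos - q) >= MIN_ATOM_SPACING for q in placed[-60:]):
                    break
            else:
                raise RuntimeError(
                    f"could not place atom {atom_name} of residue {i} "
                    f"with spacing >= {MIN_ATOM_SPACING} Å"
                )
            element = atom_name[0]
            names.append(atom_name)
            elements.append(element)
            radii.append(VDW_RADII[element])
            coords.append(pos)
            ridx.append(i)
            rbase.append(base)
            placed.append(pos)
    atoms = AtomSet(
        names, elements, np.array(radii), np.array(coords), np.array(ridx), rbase
    )
    return atoms, sequence


# ---------------------------------------------------------------------------
# Regression fixtures


@dataclass
class RegressionSet:
    """Chains with sequences and planted normalized-ASA targets."""

    sequences: dict[str, str]
    targets: dict[str, np.ndarray]
    alignments: dict[str, list[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def chain_features(
        self, cfg: EncoderConfig
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Encode every chain in sequence mode: {chain: (X, y)}."""
        return {
            c: (window_features(encode_onehot(seq, cfg.alphabet), cfg), self.targets[c])
            for c, seq in self.sequences.items()
        }


def make_asa_regression_set(
    seed: int,
    n_chains: int = 60,
    length_range: tuple[int, int] = (40, 70),
    signal_halfwidth: int = 3,
    noise_sd: float = 0.08,
    target_mean: float = 0.35,
    target_sd: float = 0.15,
) -> RegressionSet:
    """Chains whose targets are a fixed random linear map of the local
    one-hot window (half-width ``signal_halfwidth``) plus Gaussian noise.

    The linear map's output is standardized across the set to the stated
    mean/sd before noise, then clipped to [0, 1] — the scale of
    400 Å²-normalized accessibilities.
    """
    rng = np.random.default_rng(seed)
    h = signal_halfwidth
    W = rng.normal(size=4 * (2 * h + 1))
    enc = EncoderConfig(window=h)

    sequences, raw = {}, {}
    for c in range(n_chains):
        cid = f"chain{c:03d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = random_sequence(rng, L)
        sequences[cid] = seq
        raw[cid] = window_features(encode_onehot(seq), enc) @ W

    pooled = np.concatenate(list(raw.values()))
    mu, sd = pooled.mean(), pooled.std()
    targets = {}
    for cid, r in raw.items():
        z = (r - mu) / sd
        t = target_mean + target_sd * z + rng.normal(0, noise_sd, size=r.shape)
        targets[cid] = np.clip(t, 0.0, 1.0)
    return RegressionSet(
        sequences=sequences,
        targets=targets,
        meta={
            "seed": seed,
            "signal_halfwidth": h,
            "noise_sd": noise_sd,
            "target_mean": target_mean,
            "target_sd": target_sd,
        },
    )


def shuffle_targets(dataset: RegressionSet, seed: int) -> RegressionSet:
    """Null dataset: targets permuted across all positions (signal destroyed)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([dataset.targets[c] for c in sorted(dataset.targets)])
    rng.shuffle(pooled)
    targets, k = {}, 0
    for c in sorted(dataset.targets):
        n = len(dataset.targets[c])
        targets[c] = pooled[k: k + n]
        k += n
    return RegressionSet(
        sequences=dict(dataset.sequences),
        targets=targets,
        alignments=dict(dataset.alignments),
        meta={**dataset.meta, "shuffled_with_seed": seed},
    )


def make_synthetic_alignment(
    query: str,
    seed: int,
    n_homologs: int = 30,
    mutation_rate: float = 0.2,
    gap_rate: float = 0.02,
    conserved: frozenset[int] | set[int] = frozenset(),
) -> list[str]:
    """Homologs = query with i.i.d. substitutions and occasional gaps;
    columns in ``conserved`` mutate at rate 0.  Query row first; homolog
    gaps only (alignment coordinates = query coordinates)."""
    rng = np.random.default_rng(seed)
    rows = [query]
    qlist = list(query)
    for _ in range(n_homologs):
        row = []
        for i, b in enumerate(qlist):
            if i not in conserved and rng.random() < gap_rate:
                row.append("-")
            elif i not in conserved and rng.random() < mutation_rate:
                row.append(rng.choice([x for x in BASES if x != b]))
            else:
                row.append(b)
        rows.append("".join(row))
    return rows


def make_conservation_regression_set(
    seed: int,
    n_chains: int = 40,
    length: int = 60,
    burial_prob: float = 0.4,
    burial_effect: float = 0.30,
    base_effect: float = 0.05,
    noise_sd: float = 0.05,
    n_homologs: int = 30,
    mutation_rate: float = 0.3,
) -> RegressionSet:
    """Chains where homolog alignments carry signal beyond the sequence.

    A latent per-position burial indicator lowers the target accessibility
    by ``burial_effect`` and freezes the column in the alignment
    (conserved), while exposed columns mutate freely; the sequence itself
    carries only a weak base-identity effect.  A profile encoder can read
    the burial off conservation, a one-hot encoder cannot.
    """
    rng = np.random.default_rng(seed)
    base_shift = {"A": base_effect, "C": base_effect / 2,
                  "G": -base_effect / 2, "U": -base_effect}
    sequences, targets, alignments = {}, {}, {}
    for c in range(n_chains):
        cid = f"chain{c:03d}"
        seq = random_sequence(rng, length)
        buried = rng.random(length) < burial_prob
        t = (
            0.55
            - burial_effect * buried
            + np.array([base_shift[b] for b in seq])
            + rng.normal(0, noise_sd, size=length)
        )
        sequences[cid] = seq
        targets[cid] = np.clip(t, 0.0, 1.0)
        alignments[cid] = make_synthetic_alignment(
            seq,
            seed=int(rng.integers(2**31)),
            n_homologs=n_homologs,
            mutation_rate=mutation_rate,
            conserved=frozenset(np.flatnonzero(buried).tolist()),
        )
    return RegressionSet(
        sequences=sequences,
        targets=targets,
        alignments=alignments,
        meta={"seed": seed, "burial_prob": burial_prob, "burial_effect": burial_effect},
    )


# ---------------------------------------------------------------------------
# Downstream-analysis fixtures


def make_snv_table(
    seed: int,
    n: int = 200,
    log_maf_intercept: float = -3.0,
    log_maf_slope: float = 2.2,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """SNVs with a planted accessibility → allele-frequency link.

    log10(MAF) = intercept + slope × predicted_asa, times a lognormal
    noise factor of spread ``noise_sd`` (in log10 units).  Region classes
    and mutation types are assigned at random.
    """
    rng = np.random.default_rng(seed)
    pred = rng.uniform(0.0, 1.0, size=n)
    log_maf = log_maf_intercept + log_maf_slope * pred
    if noise_sd > 0:
        log_maf = log_maf + rng.normal(0, noise_sd, size=n)
    maf = np.minimum(10.0 ** log_maf, 0.5)
    return pd.DataFrame(
        {
            "id": [f"snv{i:06d}" for i in range(n)],
            "region": rng.choice(
                ["synonymous", "nonsynonymous", "3UTR", "5UTR", "ncRNA"], size=n
            ),
            "mutation_type": rng.choice(["transition", "transversion"], size=n),
            "predicted_asa": pred,
            "maf": maf,
        }
    )


@dataclass
class DmsFixture:
    """Synthetic DMS tracks plus the ground-truth exposure they encode."""

    tracks: list[DmsTrack]
    exposure: dict[str, np.ndarray]


def make_dms_tracks(
    seed: int,
    n_mrnas: int = 20,
    length: int = 1000,
    depth: float = 60.0,
    bias_sd: float = 0.5,
    vivo_baseline: float = 0.3,
) -> DmsFixture:
    """Read tracks with a shared positional bias in all conditions and an
    exposure-proportional signal in vivo only.

    Per position: bias ~ lognormal(0, bias_sd) multiplies every condition
    (mimicking sequence/position-dependent read-out efficiency); the in
    vivo rate is additionally scaled by (baseline + exposure), exposure
    ~ U(0,1).  Counts are Poisson at mean depth × rate."""
    rng = np.random.default_rng(seed)
    tracks, exposure = [], {}
    for m in range(n_mrnas):
        mid = f"mrna{m:04d}"
        bias = rng.lognormal(0.0, bias_sd, size=length)
        expo = rng.uniform(0.0, 1.0, size=length)
        counts = {
            "denature": rng.poisson(depth * bias).astype(float),
            "invitro": rng.poisson(depth * bias).astype(float),
            "vivo": rng.poisson(depth * bias * (vivo_baseline + expo)).astype(float),
        }
        tracks.append(DmsTrack(mrna_id=mid, counts=counts))
        exposure[mid] = expo
    return DmsFixture(tracks=tracks, exposure=exposure)


def make_boundary_transcripts(
    seed: int,
    n_transcripts: int = 30,
    region_length: int = 120,
    intron_level: float = 0.8,
    exon_level: float = 0.3,
    noise_sd: float = 0.05,
):
    """Transcripts with a step-function accessibility profile: introns high,
    exonic regions low; layout 5UTR–CDS–intron–CDS–3UTR."""
    from .genome_analysis import TranscriptAsa

    rng = np.random.default_rng(seed)
    layout = ["5UTR", "CDS", "intron", "CDS", "3UTR"]
    out = []
    for t in range(n_transcripts):
        regions, asa, pos = [], [], 0
        for label in layout:
            level = intron_level if label == "intron" else exon_level
            asa.append(
                np.clip(rng.normal(level, noise_sd, size=region_length), 0, 1)
            )
            regions.append((label, pos, pos + region_length))
            pos += region_length
        out.append(
            TranscriptAsa(
                transcript_id=f"tx{t:04d}",
                asa=np.concatenate(asa),
                regions=regions,
            )
        )
    return out
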