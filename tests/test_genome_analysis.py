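"""DMS normalization walk-throughs, equal-occupancy MAF binning, and
transcript boundary profiles."""

import numpy as np
import pandas as pd
import pytest

from rnasnap.evaluation_metrics import pearson
from rnasnap.genome_analysis import (
    DmsTrack,
    TranscriptAsa,
    bin_association,
    boundary_profile,
    filter_tracks_by_reacted,
    normalize_dms,
    stratified_bin_association,
)


def _track(den, cmp_, flen=50):
    return DmsTrack(
        mrna_id="m1",
        counts={"denature": np.asarray(den, float),
                "invitro": np.asarray(den, float),
                "vivo": np.asarray(cmp_, float)},
        fragment_length=flen,
    )


def test_identical_tracks_give_unit_ratios():
    rng = np.random.default_rng(0)
    counts = rng.poisson(20, size=250).astype(float)
    out = normalize_dms(_track(counts, counts), compare="vivo")
    assert len(out) == 5
    np.testing.assert_allclose(out["ratio"], 1.0)


def test_hand_walk_two_fragment_example():
    """100-base mRNA; after max-normalization the denature fragment means
    are (0.5, 0) and the compare means (0.4, 0.2): one survivor, ratio 0.8."""
    den = np.zeros(100)
    den[:50:2] = 1.0  # 25 ones in fragment 1 -> mean 0.5; fragment 2 all zero
    cmp_ = np.zeros(100)
    cmp_[:20] = 1.0   # fragment 1 mean 0.4
    cmp_[50:60] = 1.0  # fragment 2 mean 0.2
    out = normalize_dms(_track(den, cmp_), compare="vivo")
    assert len(out) == 1
    assert out["fragment_index"].tolist() == [0]
    assert out["denature"].iloc[0] == pytest.approx(0.5)
    assert out["compare"].iloc[0] == pytest.approx(0.4)
    assert out["ratio"].iloc[0] == pytest.approx(0.8)


def test_partial_trailing_fragment_dropped():
    den = np.ones(149)
    out = normalize_dms(_track(den, den), compare="vivo")
    assert len(out) == 2  # trailing 49 bases ignored


def test_scale_invariance_of_normalization():
    rng = np.random.default_rng(1)
    den = rng.poisson(30, size=200).astype(float) + 1
    cmp_ = rng.poisson(30, size=200).astype(float) + 1
    a = normalize_dms(_track(den, cmp_), compare="vivo")
    b = normalize_dms(_track(den * 7.0, cmp_ * 0.3), compare="vivo")
    np.testing.assert_allclose(a["ratio"], b["ratio"])


def test_zero_maximum_rejected_and_reacted_filter():
    with pytest.raises(ValueError, match="zero maximum"):
        normalize_dms(_track(np.zeros(100), np.ones(100)), compare="vivo")
    tracks = [_track(np.ones(100), np.ones(100))]
    assert filter_tracks_by_reacted(tracks, min_reacted=50) == tracks
    assert filter_tracks_by_reacted(tracks, min_reacted=101) == []


# --- MAF binning -----------------------------------------------------------


def _snvs(pred, maf, region=None):
    df = pd.DataFrame({"predicted_asa": pred, "maf": maf})
    df["region"] = region if region is not None else "3UTR"
    return df


def test_200_snvs_give_100_bins_of_two():
    rng = np.random.default_rng(2)
    bins, _ = bin_association(_snvs(rng.uniform(size=200), rng.uniform(0.01, 0.5, 200)))
    assert len(bins) == 100
    assert all(b.n == 2 for b in bins)
    assert sum(b.n for b in bins) == 200


def test_planted_log_affine_relation_gives_r_one():
    rng = np.random.default_rng(3)
    pred = rng.uniform(size=200)
    maf = 10.0 ** (-3.0 + 2.0 * pred)  # log10(maf) affine in pred
    _, r = bin_association(_snvs(pred, maf))
    assert r == pytest.approx(1.0, abs=1e-9)


def test_shuffled_snvs_below_permutation_null_p95():
    rng = np.random.default_rng(4)
    pred = rng.uniform(size=300)
    maf = 10.0 ** (-3.0 + 2.0 * pred)
    shuffled = _snvs(pred, rng.permutation(maf))
    _, r_obs = bin_association(shuffled)
    null = []
    for _ in range(1000):
        _, r = bin_association(_snvs(pred, rng.permutation(maf)))
        null.append(abs(r))
    assert abs(r_obs) <= np.quantile(null, 0.95) + 0.05
    # and far from the planted relation's r = 1
    assert abs(r_obs) < 0.9


def test_nonpositive_maf_rejected_and_small_n_errors():
    df = _snvs([0.1, 0.2], [0.0, 0.1])
    with pytest.raises(ValueError, match="at least 100"):
        bin_association(df)
    bins, _ = bin_association(
        _snvs(np.linspace(0, 1, 150), np.linspace(0.01, 0.4, 150)), n_bins=100
    )
    assert sum(b.n for b in bins) == 150  # first 50 bins take the extra record
    assert [b.n for b in bins[:50]] == [2] * 50
    assert [b.n for b in bins[50:]] == [1] * 50


def test_sort_is_stable_for_tied_predictions():
    # pairs of tied predictions: within each pair input order is preserved
    pred = np.repeat(np.arange(50.0), 2)
    maf = np.linspace(0.01, 0.5, 100)
    bins, _ = bin_association(_snvs(pred, maf), n_bins=50)
    for b in range(50):
        assert bins[b].mean_log_maf == pytest.approx(
            np.log10(maf[2 * b: 2 * b + 2]).mean()
        )


def test_stratified_single_stratum_matches_plain():
    rng = np.random.default_rng(5)
    df = _snvs(rng.uniform(size=200), rng.uniform(0.01, 0.5, 200), region="5UTR")
    plain_bins, plain_r = bin_association(df)
    out = stratified_bin_association(df, "region")
    assert set(out) == {"5UTR"}
    assert out["5UTR"][1] == pytest.approx(plain_r)


def test_stratified_recovers_opposite_sign_relations():
    rng = np.random.default_rng(6)
    pred = rng.uniform(size=400)
    up = _snvs(pred[:200], 10.0 ** (-3 + 2 * pred[:200]), region="3UTR")
    down = _snvs(pred[200:], 10.0 ** (-1 - 2 * pred[200:]), region="5UTR")
    df = pd.concat([up, down], ignore_index=True)
    out = stratified_bin_association(df, "region")
    assert out["3UTR"][1] == pytest.approx(1.0, abs=1e-9)
    assert out["5UTR"][1] == pytest.approx(-1.0, abs=1e-9)
    assert sum(sum(b.n for b in bins) for bins, _ in out.values()) == 400


def test_small_stratum_skipped():
    rng = np.random.default_rng(7)
    df = pd.concat(
        [
            _snvs(rng.uniform(size=150), rng.uniform(0.01, 0.5, 150), region="3UTR"),
            _snvs(rng.uniform(size=20), rng.uniform(0.01, 0.5, 20), region="ncRNA"),
        ],
        ignore_index=True,
    )
    out = stratified_bin_association(df, "region")
    assert set(out) == {"3UTR"}


# --- boundary profiles -----------------------------------------------------


def _transcript(tid, levels, region_length=120):
    labels = ["5UTR", "CDS", "intron", "CDS", "3UTR"]
    asa, regions, pos = [], [], 0
    for label, level in zip(labels, levels):
        asa.append(np.full(region_length, level))
        regions.append((label, pos, pos + region_length))
        pos += region_length
    return TranscriptAsa(tid, np.concatenate(asa), regions)


def test_constant_transcript_gives_flat_profile():
    profiles, n_exc = boundary_profile([_transcript("t", [0.5] * 5)])
    assert n_exc == 0
    assert set(profiles) == {"5UTR|CDS", "CDS|intron", "intron|CDS", "CDS|3UTR"}
    for prof in profiles.values():
        np.testing.assert_allclose(prof, 0.5)


def test_two_transcripts_average():
    profiles, _ = boundary_profile(
        [_transcript("a", [0.2] * 5), _transcript("b", [0.8] * 5)]
    )
    for prof in profiles.values():
        np.testing.assert_allclose(prof, 0.5)


def test_step_function_appears_at_boundary():
    tr = _transcript("t", [0.3, 0.3, 0.8, 0.3, 0.3])
    profiles, _ = boundary_profile([tr], flank=50)
    step = profiles["CDS|intron"]
    np.testing.assert_allclose(step[:50], 0.3)  # upstream of boundary: exon
    np.testing.assert_allclose(step[50:], 0.8)  # downstream: intron
    # direct per-offset oracle
    b = tr.boundaries()[1][1]
    np.testing.assert_allclose(step, tr.asa[b - 50: b + 50])


def test_short_region_transcript_excluded():
    ok = _transcript("ok", [0.5] * 5, region_length=120)
    short = _transcript("short", [0.5] * 5, region_length=60)
    profiles, n_exc = boundary_profile([ok, short], min_region_length=100)
    assert n_exc == 1
    for prof in profiles.values():
        np.testing.assert_allclose(prof, 0.5)


def test_profile_means_bounded_by_contributions():
    rng = np.random.default_rng(8)
    transcripts = [
        _transcript(f"t{i}", rng.uniform(0.1, 0.9, size=5)) for i in range(5)
    ]
    profiles, _ = boundary_profile(transcripts)
    lo = min(t.asa.min() for t in transcripts)
    hi = max(t.asa.max() for t in transcripts)
    for prof in profiles.values():
        assert np.all(prof >= lo) and np.all(prof <= hi)
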