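"""Self-contained fixture experiments: planted-signal recovery harnesses.

Each function generates a seeded synthetic dataset, runs the corresponding
part of the pipeline end to end, and returns the measured statistics.
They are used both by the test suite and by the results-reproduction
script, so the numbers reported there are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .evaluation_metrics import pearson
from .feature_encoding import EncoderConfig, window_features
from .genome_analysis import bin_association, normalize_dms
from .msa_profile import counts_to_profile, normalize_profile, profile_from_alignment
from .svr_model import SvrConfig, chain_kfold_split, cross_validate, predict, train


def cv_recovery(seed: int, n_chains: int = 60, window: int = 40) -> dict:
    """Chain-level fivefold CV on the planted window-local regression set,
    plus the shuffled-target null.  Returns pooled r for both."""
    ds = synthetic.make_asa_regression_set(seed=seed, n_chains=n_chains)
    enc = EncoderConfig(window=window)
    chains = ds.chain_features(enc)
    cfg = SvrConfig(seed=seed)
    result = cross_validate(chains, k=5, seed=seed, cfg=cfg)
    null = synthetic.shuffle_targets(ds, seed=seed + 1)
    null_result = cross_validate(null.chain_features(enc), k=5, seed=seed, cfg=cfg)
    n = sum(len(y) for _, y in chains.values())
    return {
        "pooled_r": result.pooled_r,
        "null_r": null_result.pooled_r,
        "n_positions": n,
        "cv": result,
    }


def prof_vs_seq(seed: int, n_chains: int = 40, window: int = 40) -> dict:
    """Pooled CV r of profile-mode vs sequence-mode features on the
    conservation-bearing fixture (profiles read burial off conservation).

    Profile normalization bounds are fitted on each fold's training chains
    and applied, with clamping, to its test chains — the same persisted-
    bounds convention used for a deployed model.
    """
    ds = synthetic.make_conservation_regression_set(seed=seed, n_chains=n_chains)
    enc = EncoderConfig(window=window)
    cfg = SvrConfig(seed=seed)
    r_seq = cross_validate(ds.chain_features(enc), k=5, seed=seed, cfg=cfg).pooled_r

    raw = {cid: profile_from_alignment(aln).raw for cid, aln in ds.alignments.items()}
    fold_of_chain = chain_kfold_split(sorted(raw), 5, seed)
    preds, targs = [], []
    for fold in range(5):
        train_ids = [c for c, f in fold_of_chain.items() if f != fold]
        test_ids = [c for c, f in fold_of_chain.items() if f == fold]
        pooled_raw = np.concatenate([raw[c] for c in train_ids])
        bounds = (float(pooled_raw.min()), float(pooled_raw.max()))

        def encode(cid: str) -> np.ndarray:
            from .msa_profile import SeqProfile

            prof = normalize_profile(
                SeqProfile(query=ds.sequences[cid], raw=raw[cid]), bounds
            )
            return window_features(prof.norm, EncoderConfig(window=window, mode="prof"))

        X_tr = np.concatenate([encode(c) for c in train_ids])
        y_tr = np.concatenate([ds.targets[c] for c in train_ids])
        model = train(X_tr, y_tr, cfg, mode="prof", profile_bounds=bounds)
        for c in test_ids:
            norm, _ = predict(model, encode(c))
            preds.append(norm)
            targs.append(ds.targets[c])
    r_prof = pearson(np.concatenate(preds), np.concatenate(targs))
    n = sum(len(t) for t in ds.targets.values())
    return {"r_seq": r_seq, "r_prof": r_prof, "n_positions": n}


def dms_recovery(seed: int, n_mrnas: int = 20, length: int = 1000) -> dict:
    """Normalize the synthetic DMS tracks and correlate per-fragment
    reactivity with the planted per-fragment exposure, for the in vivo and
    the in vitro condition."""
    fx = synthetic.make_dms_tracks(seed=seed, n_mrnas=n_mrnas, length=length)
    out = {}
    for condition in ("vivo", "invitro"):
        ratios, exposures = [], []
        for track in fx.tracks:
            frags = normalize_dms(track, compare=condition)
            expo = fx.exposure[track.mrna_id]
            flen = track.fragment_length
            for idx, ratio in zip(frags["fragment_index"], frags["ratio"]):
                ratios.append(ratio)
                exposures.append(expo[idx * flen: (idx + 1) * flen].mean())
        out[f"r_{condition}"] = pearson(ratios, exposures)
        out[f"n_fragments_{condition}"] = len(ratios)
    return out


def maf_recovery(seed: int, n: int = 200, n_permutations: int = 1000) -> dict:
    """Bin-mean association on a noise-free planted monotone SNV table,
    plus a permutation null (predicted values shuffled against MAF)."""
    snvs = synthetic.make_snv_table(seed=seed, n=n, noise_sd=0.0)
    _, r_planted = bin_association(snvs)
    rng = np.random.default_rng(seed + 1)
    null_rs = []
    for _ in range(n_permutations):
        shuffled = snvs.copy()
        shuffled["maf"] = rng.permutation(shuffled["maf"].to_numpy())
        _, r = bin_association(shuffled)
        null_rs.append(abs(r))
    null_rs = np.array(null_rs)
    shuffled = snvs.copy()
    shuffled["maf"] = np.random.default_rng(seed + 2).permutation(
        shuffled["maf"].to_numpy()
    )
    _, r_null_draw = bin_association(shuffled)
    return {
        "r_planted": r_planted,
        "r_null_draw": r_null_draw,
        "null_abs_p95": float(np.quantile(null_rs, 0.95)),
        "n": n,
    }
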