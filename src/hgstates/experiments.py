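"""Canonical study runs on synthetic data.

Each function assembles one complete analysis at desk scale — generate the
study conditions, run the pipeline stage under test, and measure the result —
and returns plain dicts of numbers.  The numbered analysis drivers, the test
suite, and the acceptance script all call these, so the conditions are defined
exactly once.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import subspace_angles
from scipy.stats import multivariate_normal

from . import classifiers, features, gpfa, pipeline, preprocess, synthetic, validation

#: 30-s epochs per balanced class from the published per-class minutes:
#: four states (275/40/90/470 min) and three states (75/130/165 min)
CLASS_MINUTES_4 = (275, 40, 90, 470)
CLASS_MINUTES_3 = (75, 130, 165)


def published_chance_levels(alpha: float = 0.05) -> dict:
    """Finite binomial chance levels for the published class-duration tables.

    The balanced trial count is the per-class minimum duration in 30-s epochs
    times the class count.
    """
    out = {}
    for name, minutes in (("four_state", CLASS_MINUTES_4), ("three_state", CLASS_MINUTES_3)):
        epochs_per_class = min(minutes) * 60 // 30
        n = epochs_per_class * len(minutes)
        cl = validation.chance_level(n, len(minutes), alpha)
        out[name] = {
            "n_trials": n,
            "n_classes": len(minutes),
            "level_pct": cl.level_pct,
            "level_pct_rounded": cl.level_pct_rounded,
        }
    return out


# --------------------------------------------------------------------------- #
# oracle equivalences
# --------------------------------------------------------------------------- #

def _explicit_blockdiag_logscore(model: classifiers.ConstrainedGaussianModel, traj: np.ndarray) -> np.ndarray:
    """(pT)-dimensional Gaussian log-density with tiled mean and block-diagonal
    covariance, built explicitly (the brute-force oracle)."""
    p, T = traj.shape
    scores = []
    for i in range(model.classes.size):
        mean_big = np.tile(model.means[i], T)
        cov_big = np.kron(np.eye(T), model.covs[i])
        scores.append(multivariate_normal.logpdf(traj.T.reshape(-1), mean_big, cov_big))
    return np.asarray(scores) - np.log(model.classes.size)


def _explicit_gpfa_posterior(params: gpfa.GPFAParams, Y: np.ndarray) -> np.ndarray:
    """Posterior mean by direct joint-Gaussian conditioning over [x; y]."""
    q, T = Y.shape
    p = params.n_factors
    Kbig = np.zeros((p * T, p * T))
    for i, tau in enumerate(params.taus_ms):
        Kbig[i * T : (i + 1) * T, i * T : (i + 1) * T] = synthetic.gp_kernel(
            tau, T, params.bin_ms, params.sigma_n_sq
        )
    Cbar = np.zeros((q * T, p * T))
    for t in range(T):
        for j in range(q):
            for i in range(p):
                Cbar[t * q + j, i * T + t] = params.C[j, i]
    Syy = Cbar @ Kbig @ Cbar.T + np.diag(np.tile(params.R, T))
    mu = Kbig @ Cbar.T @ np.linalg.solve(Syy, Y.T.reshape(-1) - np.tile(params.d, T))
    return mu.reshape(p, T)


def oracle_equivalences(seed: int = 0) -> dict:
    """Maximum deviation of the fast implementations from brute-force oracles.

    Checks the constrained Gaussian classifier against the explicit
    block-diagonal Gaussian and the structured GPFA posterior against direct
    joint-Gaussian conditioning, on random small instances with p*T <= 60.
    """
    rng = np.random.default_rng(seed)

    qda_err = 0.0
    for p, T in ((2, 3), (1, 1), (3, 10)):
        trajs = rng.standard_normal((8, p, T))
        labels = np.repeat(["a", "b"], 4)
        for shared in (False, True):
            model = classifiers.ConstrainedGaussianModel.fit(trajs, labels, shared)
            probe = rng.standard_normal((p, T))
            fast = model.log_scores(probe)
            slow = _explicit_blockdiag_logscore(model, probe)
            qda_err = max(qda_err, float(np.abs(fast - slow).max()))

    post_err = 0.0
    for q, p, T in ((2, 1, 3), (4, 2, 10), (5, 3, 20)):
        C = rng.standard_normal((q, p))
        d = rng.standard_normal(q)
        R = rng.uniform(0.1, 0.5, q)
        taus = rng.uniform(400, 5000, p)
        params = gpfa.GPFAParams(C, d, R, taus)
        Y = rng.standard_normal((q, T))
        fast = gpfa.gpfa_posterior(params, Y)
        slow = _explicit_gpfa_posterior(params, Y)
        post_err = max(post_err, float(np.abs(fast - slow).max()))

    return {"qda_blockdiag_max_abs_err": qda_err, "posterior_max_abs_err": post_err}


# --------------------------------------------------------------------------- #
# GPFA parameter recovery
# --------------------------------------------------------------------------- #

def tau_recovery(
    seed: int = 0,
    n_seeds: int = 3,
    n_epochs: int = 60,
    T: int = 120,
    max_iter: int = 200,
) -> dict:
    """Fit GPFA on data drawn from known parameters and measure recovery.

    Ground truth: q=12 channels, p=3 factors with timescales 300/1500/8000 ms.
    Reports the worst per-factor relative timescale error (taus compared after
    sorting) and the worst principal angle between fitted and true loading
    subspaces, across ``n_seeds`` independent datasets.
    """
    C, d, R, taus = synthetic.recovery_ground_truth()
    rel_errs, angles = [], []
    for i in range(n_seeds):
        Y, _ = synthetic.sample_gpfa_epochs(
            C, d, R, taus, n_epochs=n_epochs, T=T, seed=int(seed) * 1000 + i
        )
        fit = gpfa.gpfa_fit_em(Y, taus.size, max_iter=max_iter, tol=1e-6, seed=i)
        fit_taus = np.sort(fit.taus_ms)
        rel_errs.append(np.abs(fit_taus - np.sort(taus)) / np.sort(taus))
        angles.append(np.degrees(subspace_angles(fit.C, C)).max())
    return {
        "tau_max_rel_err": float(np.max(rel_errs)),
        "subspace_angle_max_deg": float(np.max(angles)),
        "n_seeds": n_seeds,
        "taus_true_ms": taus.tolist(),
    }


# --------------------------------------------------------------------------- #
# model comparison: FA vs GPFA vs reduced GPFA
# --------------------------------------------------------------------------- #

def rmse_comparison(
    seed: int = 0,
    n_repeats: int = 5,
    dims: tuple[int, ...] = (1, 2, 3),
    max_iter: int = 60,
) -> tuple[gpfa.RMSECurve, dict]:
    """Leave-one-channel-out RMSE of FA, GPFA, and reduced GPFA.

    Conditions: two states driven by genuinely smooth latents (timescales
    1-8 s), per-5-minute z-scored, 30-s epochs, 7-fold buffered CV with
    balanced training and full test folds.
    """
    specs = synthetic.smooth_latent_state_specs()
    sched = synthetic.Schedule.repeated([s.name for s in specs], n_repeats)
    env, blocks, _ = synthetic.generate_envelope_dataset(specs, sched, seed=seed)
    env_z = preprocess.zscore_segments(env)
    es = features.epoch(env_z, blocks)
    plan = validation.make_cv_plan(es.n_epochs, 7, 1)
    curve = gpfa.rmse_curve(
        es.epochs, es.labels, plan, dims=list(dims), seed=seed, max_iter=max_iter, tol=1e-5
    )
    summary = {
        "dims": curve.dimensions.tolist(),
        "rmse_fa": curve.rmse_fa.tolist(),
        "rmse_gpfa": curve.rmse_gpfa.tolist(),
        "rmse_reduced": curve.rmse_reduced.tolist(),
        "gpfa_below_fa_all_dims": bool(np.all(curve.rmse_gpfa < curve.rmse_fa)),
        "reduced_at_most_gpfa": bool(np.all(curve.rmse_reduced <= curve.rmse_gpfa * 1.02)),
    }
    return curve, summary


# --------------------------------------------------------------------------- #
# feature-family decoding
# --------------------------------------------------------------------------- #

def feature_family_decoding(seed: int = 0, n_repeats: int = 6, n_shuffles: int = 5) -> dict:
    """Decode four states from each of the five feature families.

    Conditions: all four planted differences (mean, variance, covariance,
    timescale).  Also runs a shuffled-label null: the per-family accuracy
    averaged over ``n_shuffles`` independent label permutations, which should
    sit at 1/n_classes, below the finite chance level.
    """
    env, blocks, _ = pipeline.synthesize_default_dataset(seed=seed, n_repeats=n_repeats)
    cfg = pipeline.ExperimentConfig(seed=seed)
    report = pipeline.run_experiment(env, blocks, cfg)

    es = features.epoch(env, blocks)
    env_z = preprocess.zscore_segments(env)
    es_z = features.epoch(env_z, blocks)
    plan = validation.make_cv_plan(es.n_epochs, cfg.n_folds, cfg.buffer_folds)
    mv = features.epoch_mean_var(es)
    q = es.n_channels
    cov = features.epoch_covariance(es_z)
    slow, fast = features.bandsplit_features(env_z, es_z)
    family_feats = {
        "mean": mv[:, :q],
        "variance": mv[:, q:],
        "covariance": cov.matrices,
        "slow": slow,
        "fast": fast,
    }

    rng = np.random.default_rng([seed, 0xD1CE])
    null_acc = {fam: [] for fam in family_feats}
    for _ in range(n_shuffles):
        labels_sh = rng.permutation(es.labels)
        for fam, feats in family_feats.items():
            if fam == "covariance":
                res = classifiers.train_eval_mdm(feats, labels_sh, plan, cfg.seed)
            else:
                res = classifiers.train_eval_svm(feats, labels_sh, plan, cfg.seed, cfg.svm_C)
            null_acc[fam].append(res.mean_pct)

    out = {
        "chance_level_pct": report["chance"]["level_pct"],
        "n_balanced": report["chance"]["n_trials"],
        "n_classes": report["chance"]["n_classes"],
        "families": {},
    }
    for fam in family_feats:
        out["families"][fam] = {
            "accuracy_pct": report["families"][fam]["mean_pct"],
            "se_pct": report["families"][fam]["se_pct"],
            "shuffled_mean_pct": float(np.mean(null_acc[fam])),
        }
    return out


# --------------------------------------------------------------------------- #
# latent-state decoding control (QDA vs LDA)
# --------------------------------------------------------------------------- #

def covariance_only_control(
    seed: int = 0, n_repeats: int = 6, p: int = 4, max_iter: int = 60
) -> dict:
    """GPFA decoding on states that differ only in covariance structure.

    The constrained QDA should decode above the finite chance level (class
    information lives in the latent factors' variance/covariance), while the
    LDA control (pooled covariance; only mean differences usable) should sit
    at chance.  Both incremental-order curves (slowest-first, fastest-first)
    coincide once all factors are included.
    """
    specs = synthetic.covariance_only_state_specs()
    sched = synthetic.Schedule.repeated([s.name for s in specs], n_repeats)
    env, blocks, _ = synthetic.generate_envelope_dataset(specs, sched, seed=seed)
    env_z = preprocess.zscore_segments(env)
    es = features.epoch(env_z, blocks)
    plan = validation.make_cv_plan(es.n_epochs, 7, 1)
    folds = gpfa.fit_fold_latents(
        es.epochs, es.labels, plan, p=p, seed=seed, max_iter=max_iter, tol=1e-5
    )
    qda_slow = gpfa.factor_decoding_curve(folds, es.labels, "slow_first")
    qda_fast = gpfa.factor_decoding_curve(folds, es.labels, "fast_first")
    lda = gpfa.factor_decoding_curve(folds, es.labels, "slow_first", shared_covariance=True)
    chance = validation.chance_level(qda_slow.n_balanced_total, np.unique(es.labels).size)
    return {
        "chance_level_pct": chance.level_pct,
        "n_balanced": int(qda_slow.n_balanced_total),
        "qda_slow_first_curve_pct": (100 * qda_slow.per_fold.mean(axis=0)).tolist(),
        "qda_fast_first_curve_pct": (100 * qda_fast.per_fold.mean(axis=0)).tolist(),
        "lda_curve_pct": (100 * lda.per_fold.mean(axis=0)).tolist(),
        "qda_all_factors_pct": 100 * float(qda_slow.per_fold[:, -1].mean()),
        "lda_all_factors_pct": 100 * float(lda.per_fold[:, -1].mean()),
        "orders_meet_at_full": bool(
            np.allclose(qda_slow.per_fold[:, -1], qda_fast.per_fold[:, -1])
        ),
    }


# --------------------------------------------------------------------------- #
# preprocessing round trip
# --------------------------------------------------------------------------- #

def preprocessing_roundtrip(seed: int = 0, fs_hz: float = 512.0, q: int = 10) -> dict:
    """Synthesize raw recordings, condition them, and measure recovery.

    Reports the minimum per-channel correlation between the planted and the
    recovered envelope under default noise, the steady-state 60 Hz notch
    attenuation, and whether despiking reproduces hand-computable toy cases.
    """
    specs = synthetic.roundtrip_state_specs(q)
    sched = synthetic.Schedule.repeated([s.name for s in specs], 2)
    env, blocks, _ = synthetic.generate_envelope_dataset(
        specs, sched, seed=seed, clip_at_zero=True,
        channel_ids=[f"G{i + 1}" for i in range(q)],
    )
    raw = synthetic.generate_raw_recording(env, fs_hz, seed=seed + 1)
    rec, mask = preprocess.condition_recording(raw, modality="ecog", reference="none")
    n = min(env.n_bins, rec.n_bins)
    kept = np.flatnonzero(mask.keep)
    corrs = [
        np.corrcoef(env.values[ch, :n], rec.values[i, :n])[0, 1]
        for i, ch in enumerate(kept)
    ]

    # steady-state 60 Hz attenuation of the notch chain (central window)
    t = np.arange(int(fs_hz) * 60) / fs_hz
    tone = preprocess.RawRecording(
        np.tile(np.sin(2 * np.pi * 60.0 * t), (3, 1)), fs_hz, ["a", "b", "c"]
    )
    out = preprocess.notch_filter(tone)
    sl = slice(int(fs_hz) * 5, int(fs_hz) * 55)
    atten_db = 20 * np.log10(
        np.std(out.samples[0][sl]) / np.std(tone.samples[0][sl])
    )

    toy = preprocess.EnvelopeSeries(np.array([[1.0, 1.0, 20.0, 1.0, 1.0]]))
    despiked_mid = preprocess.despike_envelope(toy).values[0]
    toy_edge = preprocess.EnvelopeSeries(np.array([[10.0, 1.0, 1.0, 1.0]]))
    despiked_edge = preprocess.despike_envelope(toy_edge).values[0]
    despike_exact = bool(
        np.array_equal(despiked_mid, np.ones(5)) and np.array_equal(despiked_edge, np.ones(4))
    )

    return {
        "roundtrip_min_channel_corr": float(np.min(corrs)),
        "roundtrip_median_channel_corr": float(np.median(corrs)),
        "notch_60hz_attenuation_db": float(-atten_db),
        "despike_toys_exact": despike_exact,
        "n_channels": int(kept.size),
        "n_bins_compared": int(n),
    }
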