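"""Sex assignment of cough and cough-epoch signals with Gaussian mixtures.

One diagonal-covariance Gaussian mixture (K = 30 components) is fitted per
sex on the pooled frames of the 41-row feature matrices (20 MFCC + 20
delta-MFCC + 1 delta-ZCR) of that sex's training signals.  EM runs from 3
k-means-seeded initialisations for up to 200 iterations; the best
log-likelihood fit is kept, with a variance floor on the diagonals.

A signal is classified by summing the per-frame log-likelihoods under each
class model and taking the larger total; priors are equal (the partitioned
data set is sex-balanced), so no prior term enters the comparison.  Ties
resolve to female and are flagged.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .audio_io import AudioSegment
from .features import SexFeatureMatrix, extract_sex_features

__all__ = [
    "GmmSexModel",
    "SexDecision",
    "fit_gmm",
    "fit_class_gmm",
    "classify_sex",
    "partition_sex_dataset",
    "em_loglik_trajectory",
]

VARIANCE_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class SexDecision:
    label: str                 # "female" | "male"
    log_likelihood_diff: float  # female total minus male total
    tie: bool = False


class GmmSexModel:
    """Per-sex diagonal-covariance Gaussian mixtures over 41-dim frames."""

    def __init__(self, female: GaussianMixture, male: GaussianMixture):
        for name, gmm in (("female", female), ("male", male)):
            if gmm.covariance_type != "diag":
                raise ValueError(f"{name} mixture must use diagonal covariance")
            w = gmm.weights_
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} mixture weights must be a distribution")
            if np.any(gmm.covariances_ <= 0):
                raise ValueError(f"{name} mixture has nonpositive variances")
        self.female = female
        self.male = male

    def log_likelihood(self, x: SexFeatureMatrix, label: str) -> float:
        """Total log-likelihood of a feature matrix (frames summed)."""
        gmm = self.female if label == "female" else self.male
        return float(np.sum(gmm.score_samples(x.values.T)))

    def save(self, path) -> None:
        arrays = {}
        for name, gmm in (("female", self.female), ("male", self.male)):
            arrays[f"{name}_weights"] = gmm.weights_
            arrays[f"{name}_means"] = gmm.means_
            arrays[f"{name}_covariances"] = gmm.covariances_
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GmmSexModel":
        with np.load(path) as data:
            gmms = {}
            for name in ("female", "male"):
                w = data[f"{name}_weights"]
                gmm = GaussianMixture(n_components=w.size, covariance_type="diag")
                gmm.weights_ = w
                gmm.means_ = data[f"{name}_means"]
                gmm.covariances_ = data[f"{name}_covariances"]
                gmm.precisions_cholesky_ = 1.0 / np.sqrt(gmm.covariances_)
                gmms[name] = gmm
        return cls(gmms["female"], gmms["male"])


def _pool_frames(features: Sequence[SexFeatureMatrix]) -> np.ndarray:
    if not features:
        raise ValueError("no feature matrices given")
    return np.concatenate([f.values.T for f in features], axis=0)


def fit_class_gmm(
    frames: np.ndarray,
    n_components: int = 30,
    n_init: int = 3,
    iterations: int = 200,
    seed: int = 0,
) -> GaussianMixture:
    """Fit one diagonal GMM on pooled (F, 41) frames via EM."""
    if frames.shape[0] < n_components:
        raise ValueError(
            f"{frames.shape[0]} frames cannot support {n_components} components"
        )
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        n_init=n_init,
        max_iter=iterations,
        reg_covar=VARIANCE_FLOOR,
        init_params="kmeans",
        random_state=seed,
    )
    gmm.fit(frames)
    return gmm


def fit_gmm(
    female_features: Sequence[SexFeatureMatrix],
    male_features: Sequence[SexFeatureMatrix],
    n_components: int = 30,
    n_init: int = 3,
    iterations: int = 200,
    seed: int = 0,
) -> GmmSexModel:
    """Fit the per-sex mixtures on training feature matrices."""
    female = fit_class_gmm(_pool_frames(female_features), n_components,
                           n_init, iterations, seed)
    male = fit_class_gmm(_pool_frames(male_features), n_components,
                         n_init, iterations, seed + 1)
    return GmmSexModel(female, male)


def em_loglik_trajectory(
    frames: np.ndarray,
    n_components: int,
    iterations: int,
    seed: int = 0,
) -> np.ndarray:
    """Mean log-likelihood after each EM iteration (single initialisation).

    Steps EM one iteration at a time (warm start) so the monotone ascent of
    the EM objective can be observed directly.
    """
    gmm = GaussianMixture(
        n_components=n_components, covariance_type="diag", n_init=1,
        max_iter=1, reg_covar=VARIANCE_FLOOR, init_params="kmeans",
        random_state=seed, warm_start=True, tol=0.0,
    )
    traj = []
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # single-iteration warm-start steps never "converge" by sklearn's
        # definition; that is the point of stepping manually
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(iterations):
            gmm.fit(frames)
            traj.append(float(gmm.score(frames)))
    return np.array(traj)


def classify_sex(x: SexFeatureMatrix, model: GmmSexModel) -> SexDecision:
    """Equal-prior maximum-likelihood sex decision for one feature matrix."""
    ll_f = model.log_likelihood(x, "female")
    ll_m = model.log_likelihood(x, "male")
    if not (np.isfinite(ll_f) and np.isfinite(ll_m)):
        raise FloatingPointError("non-finite log-likelihood")
    diff = ll_f - ll_m
    if diff == 0.0:
        return SexDecision("female", 0.0, tie=True)
    return SexDecision("female" if diff > 0 else "male", diff)


def classify_sex_signal(signal: AudioSegment, model: GmmSexModel,
                        source: str = "cough") -> SexDecision:
    return classify_sex(extract_sex_features(signal, source=source), model)


def epoch_signal(coughs: Sequence[AudioSegment]) -> AudioSegment:
    """Concatenate an epoch's constituent cough signals into one segment."""
    if not coughs:
        raise ValueError("epoch must contain at least one cough signal")
    sr = coughs[0].sample_rate
    if any(c.sample_rate != sr for c in coughs):
        raise ValueError("epoch members must share a sample rate")
    return AudioSegment(np.concatenate([c.samples for c in coughs]), sr,
                        coughs[0].start_time)


def partition_sex_dataset(
    participants: Sequence[tuple],
    seed: int = 0,
    train_counts: dict | None = None,
    test_counts: dict | None = None,
) -> tuple[list[str], list[str]]:
    """Participant-disjunct train/test split with fixed per-sex counts.

    ``participants`` holds (participant_id, sex, slept_alone) triples; only
    participants flagged as having slept alone are eligible.  Defaults
    mirror the balanced 19F/19M design: 10 female + 9 male for training,
    9 female + 10 male for testing.
    """
    train_counts = train_counts or {"female": 10, "male": 9}
    test_counts = test_counts or {"female": 9, "male": 10}
    rng = np.random.default_rng(seed)
    train, test = [], []
    for sex in ("female", "male"):
        pool = sorted(p for p, s, alone in participants if s == sex and alone)
        need = train_counts[sex] + test_counts[sex]
        if len(pool) < need:
            raise ValueError(
                f"need {need} eligible {sex} participants, got {len(pool)}"
            )
        rng.shuffle(pool)
        train.extend(pool[:train_counts[sex]])
        test.extend(pool[train_counts[sex]:need])
    return sorted(train), sorted(test)
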