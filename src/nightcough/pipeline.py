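"""End-to-end desk-scale experiments tying all stages together.

Each driver generates its synthetic inputs, runs the corresponding stage of
the pipeline, and returns plain dictionaries of computed quantities.  One
global seed fans out to per-stage seeds by fixed offsets so stages can be
re-run in isolation and still reproduce.

Default problem sizes are desk scale: 40 synthetic participants for window
recognition, 20 ten-minute nights for segmentation, and 38 sexed
participants for sex assignment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time

import numpy as np

from . import recognition, segmentation, sex_assignment
from .evaluation import (ConfusionCounts, NightCountRecord, bland_altman,
                         confusion_metrics, roc_pr_curves)
from .features import FeatureConfig, extract_sex_features
from .nn import ArchitectureSpec, desk_architecture
from .recognition import (EnsembleModel, TrainingConfig, partition_participants,
                          train_ensemble, tune_threshold, windows_from_corpus)
from .sex_assignment import epoch_signal
from .synthetic import (SyntheticNightConfig, sample_cough_spec,
                        synth_cough, synth_event_corpus, synth_night)

__all__ = [
    "RunConfig",
    "train_recognition_study",
    "run_segmentation_study",
    "run_sex_study",
    "run_end_to_end",
]

# fixed per-stage seed offsets fanned out from the global seed
_SEED_CORPUS = 11
_SEED_SPLIT = 23
_SEED_TRAIN = 37
_SEED_NIGHTS = 53
_SEED_SEX = 71


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    n_participants: int = 40
    coughs_per_participant: int = 5
    noncoughs_per_participant: int = 50
    iterations: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    n_nights: int = 20
    night_duration: float = 600.0
    sex_participants_per_class: int = 19
    sex_coughs_per_participant: int = 12
    run_segmentation: bool = True
    run_sex: bool = True
    desk_scale: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def manifest_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# recognition study

def train_recognition_study(
    seed: int = 0,
    n_participants: int = 40,
    coughs_per_participant: int = 5,
    noncoughs_per_participant: int = 50,
    iterations: int = 300,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
    arch: ArchitectureSpec | None = None,
    feature_config: FeatureConfig | None = None,
) -> dict:
    """Generate a desk-scale corpus, train the 5-member ensemble, tune the
    threshold on validation participants and evaluate on held-out test
    participants.

    Returns the trained :class:`EnsembleModel` plus window-level metrics.
    """
    arch = arch or desk_architecture()
    feature_config = feature_config or FeatureConfig()
    corpus = synth_event_corpus(
        n_participants=n_participants,
        coughs_per_participant=coughs_per_participant,
        noncoughs_per_participant=noncoughs_per_participant,
        sample_rate=feature_config.sample_rate,
        seed=seed + _SEED_CORPUS,
    )
    windows = windows_from_corpus(corpus, feature_config)
    train_ids, val_ids, test_ids = partition_participants(
        [w.participant_id for w in windows], seed=seed + _SEED_SPLIT
    )
    w_train = [w for w in windows if w.participant_id in set(train_ids)]
    w_val = [w for w in windows if w.participant_id in set(val_ids)]
    w_test = [w for w in windows if w.participant_id in set(test_ids)]

    cfg = TrainingConfig(learning_rate=learning_rate, batch_size=batch_size,
                         iterations=iterations, seed=seed + _SEED_TRAIN)
    members = train_ensemble(w_train, cfg, arch=arch, seed=seed + _SEED_TRAIN)
    threshold = tune_threshold(members, w_val)
    model = EnsembleModel(members, threshold, feature_config)

    y = np.array([w.label == "cough" for w in w_test])
    probs = recognition._mean_member_proba(members, w_test)
    pred = probs >= threshold
    counts = ConfusionCounts(
        tp=int(np.sum(pred & y)), fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)), tn=int(np.sum(~pred & ~y)),
    )
    return {
        "model": model,
        "threshold": threshold,
        "windows": {"train": w_train, "val": w_val, "test": w_test},
        "test_counts": counts,
        "test_metrics": confusion_metrics(counts),
        "test_curves": roc_pr_curves(probs, y),
        "n_windows": len(windows),
    }


# ---------------------------------------------------------------------------
# segmentation study

_SEED_VALNIGHTS = 104_729


def refine_segmentation_threshold(
    model: EnsembleModel,
    seed: int = 0,
    n_val_nights: int = 6,
    night_duration: float = 600.0,
    night_config: SyntheticNightConfig | None = None,
) -> EnsembleModel:
    """Calibrate the deployment threshold on synthetic validation nights.

    Scores ``n_val_nights`` validation nights (seeds disjoint from any test
    night) once, re-runs the threshold grid against their annotated cough
    counts, and returns a copy of the ensemble carrying the refined
    threshold.  See :func:`nightcough.segmentation.tune_segmentation_threshold`.
    """
    series_list, truths = [], []
    for k in range(n_val_nights):
        base = night_config or SyntheticNightConfig()
        cfg = dataclasses.replace(
            base, duration=night_duration,
            sex="female" if k % 2 == 0 else "male",
            seed=seed + _SEED_VALNIGHTS + k,
        )
        audio, labels = synth_night(cfg)
        series_list.append(segmentation.slide_and_score(audio, model))
        truths.append(len(labels.with_label("cough")))
    t = segmentation.tune_segmentation_threshold(series_list, truths)
    return EnsembleModel(model.members, t, model.feature_config)

def run_segmentation_study(
    model: EnsembleModel,
    seed: int = 0,
    n_nights: int = 20,
    night_duration: float = 600.0,
    night_config: SyntheticNightConfig | None = None,
) -> dict:
    """Segment synthetic nights and compare counts against ground truth."""
    cough_records, epoch_records, nights = [], [], []
    exact, epoch_exact_given_cough = 0, 0
    total_counts = ConfusionCounts()
    for k in range(n_nights):
        base = night_config or SyntheticNightConfig()
        cfg = dataclasses.replace(
            base, duration=night_duration,
            sex="female" if k % 2 == 0 else "male",
            seed=seed + _SEED_NIGHTS + k,
        )
        audio, labels = synth_night(cfg)
        result = segmentation.segment_recording(audio, model)
        truth = labels.with_label("cough")
        truth_times = sorted(e.start + (e.end - e.start) / 2 for e in truth)
        _, truth_epochs, _ = segmentation.derive_epochs(truth_times)
        match = segmentation.match_detections(result["detections"], labels)
        total_counts = total_counts + match["counts"]
        night_id = f"night{k:02d}"
        cough_records.append(NightCountRecord(
            night_id, result["cough_count"], len(truth)))
        epoch_records.append(NightCountRecord(
            night_id, result["epoch_count"], truth_epochs))
        if result["cough_count"] == len(truth):
            exact += 1
            if result["epoch_count"] == truth_epochs:
                epoch_exact_given_cough += 1
        nights.append({
            "night_id": night_id,
            "cough_count": result["cough_count"],
            "annotated_coughs": len(truth),
            "epoch_count": result["epoch_count"],
            "annotated_epochs": truth_epochs,
            "coughs_in_epochs": result["coughs_in_epochs"],
            "tp": match["counts"].tp, "fp": match["counts"].fp,
            "fn": match["counts"].fn,
        })
    out = {
        "nights": nights,
        "cough_records": cough_records,
        "epoch_records": epoch_records,
        "exact_count_rate": exact / n_nights,
        "epoch_agreement_given_cough": (
            epoch_exact_given_cough / exact if exact else None
        ),
        "totals": total_counts,
    }
    if len(cough_records) >= 2:
        out["bland_altman_coughs"] = bland_altman(cough_records)
        out["bland_altman_epochs"] = bland_altman(epoch_records)
    return out


# ---------------------------------------------------------------------------
# sex-assignment study

def run_sex_study(
    seed: int = 0,
    participants_per_class: int = 19,
    coughs_per_participant: int = 12,
    sample_rate: int = 22_050,
    n_components: int = 30,
    n_init: int = 3,
    iterations: int = 200,
) -> dict:
    """Train per-sex GMMs on synthetic sexed coughs and evaluate held-out
    cough-level and epoch-level accuracy.

    Participants are split with the balanced-design counts (10F/9M train,
    9F/10M test).  Epoch signals are concatenations of 2-4 of a
    participant's coughs.
    """
    rng = np.random.default_rng(seed + _SEED_SEX)
    coughs: dict[str, list] = {}
    participants = []
    for sex in ("female", "male"):
        for i in range(participants_per_class):
            pid = f"{sex[0].upper()}{i:02d}"
            participants.append((pid, sex, True))
            segs = []
            for _ in range(coughs_per_participant):
                spec = sample_cough_spec(sex, rng)
                segs.append(synth_cough(spec, sample_rate,
                                        int(rng.integers(2 ** 31))))
            coughs[pid] = segs
    train_ids, test_ids = sex_assignment.partition_sex_dataset(
        participants, seed=seed + _SEED_SEX)
    sex_of = {pid: sex for pid, sex, _ in participants}

    def features_of(ids, source):
        by_class = {"female": [], "male": []}
        items = []  # (true sex, SexFeatureMatrix)
        for pid in ids:
            segs = coughs[pid]
            if source == "cough":
                signals = segs
            else:
                signals, j = [], 0
                while j < len(segs):
                    k = int(rng.integers(2, 5))
                    group = segs[j:j + k]
                    j += k
                    if len(group) >= 2:
                        signals.append(epoch_signal(group))
            for s in signals:
                f = extract_sex_features(s, source=source)
                by_class[sex_of[pid]].append(f)
                items.append((sex_of[pid], f))
        return by_class, items

    train_c, _ = features_of(train_ids, "cough")
    model = sex_assignment.fit_gmm(
        train_c["female"], train_c["male"],
        n_components=n_components, n_init=n_init, iterations=iterations,
        seed=seed + _SEED_SEX,
    )

    def evaluate(items):
        counts = ConfusionCounts()
        for true_sex, f in items:
            decision = sex_assignment.classify_sex(f, model)
            pos, pred_pos = true_sex == "female", decision.label == "female"
            counts = counts + ConfusionCounts(
                tp=int(pos and pred_pos), fp=int(not pos and pred_pos),
                fn=int(pos and not pred_pos), tn=int(not pos and not pred_pos),
            )
        return counts

    _, test_cough_items = features_of(test_ids, "cough")
    _, test_epoch_items = features_of(test_ids, "epoch")
    cough_counts = evaluate(test_cough_items)
    epoch_counts = evaluate(test_epoch_items)
    return {
        "model": model,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "cough_counts": cough_counts,
        "epoch_counts": epoch_counts,
        "cough_metrics": confusion_metrics(cough_counts),
        "epoch_metrics": confusion_metrics(epoch_counts),
        "n_test_coughs": len(test_cough_items),
        "n_test_epochs": len(test_epoch_items),
    }


# ---------------------------------------------------------------------------
# end-to-end

def run_end_to_end(config: RunConfig, log=None) -> dict:
    """Execute simulate -> train -> tune -> segment -> sex-assign -> evaluate.

    Returns a report bundle with per-stage results and a manifest of all
    seeds and configuration; identical configs yield identical reports.
    """
    def stage(name):
        if log is not None:
            log(f"[{name}] t={time.perf_counter() - t0:.1f}s")

    t0 = time.perf_counter()
    report: dict = {"manifest": {
        "config": config.to_dict(),
        "config_hash": config.manifest_hash(),
        "stage_seeds": {
            "corpus": config.seed + _SEED_CORPUS,
            "split": config.seed + _SEED_SPLIT,
            "train": config.seed + _SEED_TRAIN,
            "nights": config.seed + _SEED_NIGHTS,
            "sex": config.seed + _SEED_SEX,
        },
    }}
    stage("train")
    rec = train_recognition_study(
        seed=config.seed,
        n_participants=config.n_participants,
        coughs_per_participant=config.coughs_per_participant,
        noncoughs_per_participant=config.noncoughs_per_participant,
        iterations=config.iterations,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
    )
    report["recognition"] = {
        "threshold": rec["threshold"],
        "test_metrics": rec["test_metrics"],
        "test_counts": dataclasses.asdict(rec["test_counts"]),
        "n_windows": rec["n_windows"],
    }
    model = rec["model"]
    if config.run_segmentation:
        stage("segment")
        seg_model = refine_segmentation_threshold(model, seed=config.seed)
        report["recognition"]["segmentation_threshold"] = seg_model.threshold
        seg = run_segmentation_study(
            seg_model, seed=config.seed,
            n_nights=config.n_nights, night_duration=config.night_duration,
        )
        report["segmentation"] = {
            "nights": seg["nights"],
            "exact_count_rate": seg["exact_count_rate"],
            "epoch_agreement_given_cough": seg["epoch_agreement_given_cough"],
            "bland_altman_coughs": seg.get("bland_altman_coughs"),
            "bland_altman_epochs": seg.get("bland_altman_epochs"),
        }
    if config.run_sex:
        stage("sex")
        sexr = run_sex_study(seed=config.seed,
                             participants_per_class=config.sex_participants_per_class,
                             coughs_per_participant=config.sex_coughs_per_participant)
        report["sex"] = {
            "cough_metrics": sexr["cough_metrics"],
            "epoch_metrics": sexr["epoch_metrics"],
            "n_test_coughs": sexr["n_test_coughs"],
            "n_test_epochs": sexr["n_test_epochs"],
        }
    stage("done")
    report["_model"] = model
    return report
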