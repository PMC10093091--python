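"""End-to-end orchestration of the synthetic demonstration pipeline.

``run_all`` executes: synthetic cohort + core rendering -> preprocessing
(segmentation, colour normalisation, patch extraction) -> adversarial
generator training -> encoder fine-tuning -> latent-space selection ->
classifier re-tuning (with and without augmentation) -> patient scoring and
threshold calibration -> Bayesian-network fusion with survival
stratification, and emits one JSON report with a section per stage.  All
stage seeds are a pure function of (global seed, stage name), so a config
and seed determine every number in the report.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayesnet, gan, preprocess, scoring, synthetic
from .types import Patch

__all__ = ["PipelineConfig", "stage_seed", "run_all", "run_ablation"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (kept below 2**31)."""
    return int((global_seed * 2_654_435_761 + zlib.crc32(stage.encode()))
               % (2 ** 31))


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Field defaults are desk-scale: small cores and networks so the full
    chain runs in minutes on one CPU.  The full-scale counterparts (7000px
    cores, 256px patches, 300,000 generated patches, large pretrained
    backbones) are reachable through the same fields.
    """

    # cohort sizes and the planted class imbalance of the benchmark
    n_train_patients: int = 40
    n_test_patients: int = 40
    train_bce_fraction: float = 0.1   # 1:9 imbalanced training benchmark
    test_bce_fraction: float = 0.5
    # imaging geometry
    core_size: int = 512
    n_ducts: int = 8
    patch_size: int = 64
    min_tissue: float = 0.5
    aggressive_fraction_high: float = 0.7
    aggressive_fraction_low: float = 0.1
    # generator / encoder / selection
    n_generate: int = 2000
    tau: float = 0.5
    k_neighbors: int = 5
    gan_epochs: int = 40
    encoder_epochs: int = 40
    # classifier / scoring
    classifier_epochs: int = 60
    k_retuned: int | None = None      # None: re-tune all layers
    decision_cutoff: float = 0.5
    calibration_fraction: float = 0.3  # training patients held out for
    #                                    ratio-threshold calibration
    # fusion
    bn_alpha: float = 1.0
    bn_restarts: int = 3
    fdr: float = 0.1
    km_horizon: float = 5.0
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None


def _make_patients(n: int, bce_fraction: float, prefix: str,
                   config: PipelineConfig, seed: int):
    """Patients with planted outcome labels and rendered cores."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(bce_fraction * n))
    statuses = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(statuses)
    base = synthetic.SyntheticCoreSpec(
        width=config.core_size, height=config.core_size,
        n_ducts=config.n_ducts, seed=seed)
    patients = []
    for i, status in enumerate(statuses):
        pid = f"{prefix}{i:04d}"
        n_cores = int(rng.integers(1, 4))
        samples = synthetic.generate_patient_images(
            pid, n_cores, int(status), base,
            high=config.aggressive_fraction_high,
            low=config.aggressive_fraction_low)
        patients.append({"patient_id": pid, "bce": int(status),
                         "samples": samples})
    return patients


def _preprocess_patients(patients, config: PipelineConfig, reference=None):
    """Segment, colour-normalise and attach masks; returns the reference."""
    if reference is None:
        reference = preprocess.build_reference(
            patients[0]["samples"][0].image)
    n_kept = 0
    for p in patients:
        cores, masks = [], []
        for sample in p["samples"]:
            mask = preprocess.segment_tissue(sample.image)
            core = preprocess.normalize_to_reference(sample.image, reference)
            cores.append(core)
            masks.append(mask)
        p["cores"], p["masks"] = cores, masks
        n_kept += len(cores)
    return reference, n_kept


def _training_patches(patients, config: PipelineConfig) -> list[Patch]:
    patches = []
    for p in patients:
        label = "aggressive" if p["bce"] else "non-aggressive"
        for core, mask in zip(p["cores"], p["masks"]):
            patches.extend(preprocess.extract_patches(
                core, mask, size=config.patch_size,
                stride=config.patch_size, min_tissue=config.min_tissue,
                weak_label=label))
    return patches


def _calibration_split(patients, fraction: float, seed: int):
    """Stratified patient-level split: (tuning set, calibration set).

    Calibration patients play the role of the training cohort's validation
    images — they never enter classifier re-tuning, so their scores are
    unbiased for picking the ratio threshold.  Each outcome class is split
    proportionally with at least one patient per side where possible.
    """
    rng = np.random.default_rng(seed)
    tune, cal = [], []
    for status in (0, 1):
        group = [p for p in patients if p["bce"] == status]
        if not group:
            continue
        order = rng.permutation(len(group))
        n_cal = int(round(fraction * len(group)))
        if len(group) >= 2:
            n_cal = min(max(n_cal, 1), len(group) - 1)
        else:
            n_cal = 0
        cal.extend(group[i] for i in order[:n_cal])
        tune.extend(group[i] for i in order[n_cal:])
    return tune, cal


def _score_cohort(clf, patients, config: PipelineConfig):
    scores = []
    for p in patients:
        scores.append(scoring.score_patient(
            clf, p["cores"], p["masks"], patch_size=config.patch_size,
            decision_cutoff=config.decision_cutoff,
            min_tissue=config.min_tissue))
    return scores


def _fusion_records(patients, scores, threshold, tils_model,
                    config: PipelineConfig, seed: int) -> pd.DataFrame:
    """Clinical table for the scored cohort: sampled clinicopathological
    covariates, imaging risk from the calibrated threshold, actual BCE."""
    spec = synthetic.CohortSpec(n_patients=len(patients), seed=seed)
    table = synthetic.generate_cohort(spec)
    table["patient_id"] = [p["patient_id"] for p in patients]
    table["bce"] = [p["bce"] for p in patients]
    table["gan_risk"] = ["high" if s.aggressive_fraction >= threshold
                         else "low" for s in scores]
    table["tils_risk"] = tils_model(table)
    return table


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and optionally writes) the report."""
    report = {"config": {k: v for k, v in asdict(config).items()},
              "seed": config.seed}

    # 1. synthetic data ------------------------------------------------------
    train = _make_patients(config.n_train_patients,
                           config.train_bce_fraction, "TR",
                           config, stage_seed(config.seed, "synth-train"))
    test = _make_patients(config.n_test_patients, config.test_bce_fraction,
                          "TE", config, stage_seed(config.seed, "synth-test"))
    report["synthetic_data"] = {
        "n_train_patients": len(train), "n_test_patients": len(test),
        "n_train_bce": int(sum(p["bce"] for p in train)),
        "n_test_bce": int(sum(p["bce"] for p in test)),
        "n_cores": int(sum(len(p["samples"]) for p in train + test)),
    }

    # 2. preprocess ----------------------------------------------------------
    reference, n_train_cores = _preprocess_patients(train, config)
    _, n_test_cores = _preprocess_patients(test, config,
                                           reference=reference)
    tune, calibration = _calibration_split(
        train, config.calibration_fraction,
        stage_seed(config.seed, "calibration-split"))
    patches = _training_patches(tune, config)
    n_aggressive = sum(p.weak_label == "aggressive" for p in patches)
    report["preprocess"] = {
        "reference_core": reference.core_id,
        "n_cores_normalized": n_train_cores + n_test_cores,
        "n_tuning_patients": len(tune),
        "n_calibration_patients": len(calibration),
        "n_patches_kept": len(patches),
        "n_patches_aggressive": int(n_aggressive),
        "n_patches_nonaggressive": int(len(patches) - n_aggressive),
    }

    # 3. generator -----------------------------------------------------------
    gan_cfg = gan.GANConfig(epochs=config.gan_epochs,
                            seed=stage_seed(config.seed, "gan"))
    generator = gan.train_generator(patches, gan_cfg)
    report["gan"] = {
        "n_training_patches": len(patches),
        "final_g_loss": generator.history["g_loss"][-1],
        "final_d_loss": generator.history["d_loss"][-1],
        "val_disc_accuracy": generator.history["val_disc_accuracy"],
    }

    # 4. encoder -------------------------------------------------------------
    enc_cfg = gan.EncoderConfig(epochs=config.encoder_epochs,
                                seed=stage_seed(config.seed, "encoder"))
    encoder = gan.finetune_encoder(patches, enc_cfg)
    report["encoder"] = {"embedding_dim": encoder.embedding_dim,
                         "final_loss": encoder.history["loss"][-1]}

    # 5. selection -----------------------------------------------------------
    generated = gan.sample_patches(generator, config.n_generate,
                                   seed=stage_seed(config.seed, "sample"))
    gen_emb = encoder.embed(generated)
    agg = [p for p in patches if p.weak_label == "aggressive"]
    non = [p for p in patches if p.weak_label == "non-aggressive"]
    selected_ix = gan.select_aggressive_generated(
        gen_emb, encoder.embed(agg), encoder.embed(non),
        tau=config.tau, k=config.k_neighbors)
    selected = [generated[i] for i in selected_ix]
    for p in selected:
        p.weak_label = "aggressive"
    report["selection"] = {"n_generated": len(generated),
                           "n_selected": len(selected),
                           "tau": config.tau, "k": config.k_neighbors}

    # 6. classifier (augmented + real-only ablation arm) ---------------------
    clf_cfg = scoring.ClassifierConfig(
        epochs=config.classifier_epochs,
        seed=stage_seed(config.seed, "classifier"))
    clf_aug = scoring.finetune_classifier(patches, selected,
                                          k=config.k_retuned, config=clf_cfg)
    clf_real = scoring.finetune_classifier(patches, [],
                                           k=config.k_retuned,
                                           config=clf_cfg)
    report["classifier"] = {
        "k_retuned": clf_aug.k_retuned,
        "n_pos_after_balance": clf_aug.history["n_pos"],
        "n_neg_after_balance": clf_aug.history["n_neg"],
        "n_generated_used": clf_aug.history["n_generated_used"],
        "held_out_patch_auc_augmented": clf_aug.history.get("test_auc"),
        "held_out_patch_auc_real_only": clf_real.history.get("test_auc"),
    }

    # 7. scoring -------------------------------------------------------------
    if len({p["bce"] for p in calibration}) < 2:
        # degenerate split (too few outcome-positive patients): fall back
        # to calibrating on the full training cohort
        calibration = train
    cal_scores = _score_cohort(clf_aug, calibration, config)
    threshold = scoring.calibrate_ratio_threshold(
        cal_scores, [p["bce"] for p in calibration])
    test_scores = _score_cohort(clf_aug, test, config)
    test_labels = [p["bce"] for p in test]
    metrics_aug = scoring.evaluate(test_scores, test_labels, threshold)

    real_scores = _score_cohort(clf_real, test, config)
    real_cal_scores = _score_cohort(clf_real, calibration, config)
    threshold_real = scoring.calibrate_ratio_threshold(
        real_cal_scores, [p["bce"] for p in calibration])
    metrics_real = scoring.evaluate(real_scores, test_labels,
                                    threshold_real)
    report["scoring"] = {
        "ratio_threshold": threshold,
        "augmented": metrics_aug.to_dict(),
        "real_only": metrics_real.to_dict(),
        "auc_difference": metrics_aug.auc - metrics_real.auc,
        "per_patient": [
            {"patient_id": s.patient_id, "n_aggressive": s.n_aggressive,
             "n_total": s.n_total,
             "fraction": s.aggressive_fraction, "bce": y}
            for s, y in zip(test_scores, test_labels)],
    }

    # 8. fusion --------------------------------------------------------------
    fusion_seed = stage_seed(config.seed, "fusion")
    train_table = synthetic.generate_cohort(synthetic.CohortSpec(
        n_patients=len(train), seed=stage_seed(config.seed, "fusion-train")))
    train_table["bce"] = [p["bce"] for p in train]
    tils_model = bayesnet.fit_tils_risk(train_table)
    records = _fusion_records(test, test_scores, threshold, tils_model,
                              config, fusion_seed)
    screen = bayesnet.screen_pairs(records, fdr=config.fdr)
    structure = bayesnet.learn_structure(
        records, restarts=config.bn_restarts,
        seed=stage_seed(config.seed, "bn"))
    bn = bayesnet.fit_cpts(records, structure.edges, alpha=config.bn_alpha)
    probs, loocv = bayesnet.loocv_auc(
        records, alpha=config.bn_alpha, restarts=1,
        seed=stage_seed(config.seed, "loocv"))
    cut = float(np.nanmedian(probs))
    try:
        _, km_p, km_stat = bayesnet.km_stratify(
            records, np.nan_to_num(probs, nan=cut), cut,
            horizon=config.km_horizon)
    except ValueError:
        km_p, km_stat = float("nan"), float("nan")
    report["fusion"] = {
        "n_pairs_screened": screen.n_pairs,
        "significant_pairs": [list(p) for p in screen.significant_pairs],
        "learned_edges": [list(e) for e in structure.edges],
        "loocv_auc": loocv,
        "km_logrank_p": km_p,
        "km_logrank_statistic": km_stat,
        "bn_alpha": config.bn_alpha,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        pd.DataFrame([{
            "patient_id": s.patient_id, "n_aggressive": s.n_aggressive,
            "n_total": s.n_total, "fraction": s.aggressive_fraction,
            "predicted_risk": int(s.aggressive_fraction >= threshold),
        } for s in test_scores]).to_csv(out / "scores.csv", index=False)
        (out / "network.json").write_text(bn.to_json())
    return report


def run_ablation(config: PipelineConfig, n_seeds: int = 5) -> dict:
    """Seed-paired augmentation-vs-real-only comparison.

    Both arms of every repetition share the same data, splits, generator,
    encoder and selection; only the classifier training set differs.
    Reports the two AUC series and their paired differences.
    """
    aug_aucs, real_aucs = [], []
    for i in range(n_seeds):
        cfg = PipelineConfig(**{**asdict(config),
                                "seed": stage_seed(config.seed,
                                                   f"ablation-{i}"),
                                "out_dir": None})
        report = run_all(cfg)
        aug_aucs.append(report["scoring"]["augmented"]["auc"])
        real_aucs.append(report["scoring"]["real_only"]["auc"])
    diffs = np.array(aug_aucs) - np.array(real_aucs)
    return {
        "n_seeds": n_seeds,
        "auc_augmented": aug_aucs,
        "auc_real_only": real_aucs,
        "mean_auc_augmented": float(np.mean(aug_aucs)),
        "mean_auc_real_only": float(np.mean(real_aucs)),
        "mean_difference": float(np.mean(diffs)),
        "sd_difference": float(np.std(diffs, ddof=1)) if n_seeds > 1
        else 0.0,
    }
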