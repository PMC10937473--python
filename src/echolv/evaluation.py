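"""End-to-end evaluation experiments on phantom cohorts.

These drive the two headline checks of the pipeline: parameter recovery
(train a small network on phantoms, measure keypoint and thickness errors on
a held-out cohort) and consensus-framework recovery (simulate a rater panel
with known noise and verify the dispersion statistics against the closed
form).  Both are deterministic per seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .annotation import Annotation, Dataset, KeypointName
from .measure import derive_measurements
from .model import KeypointModel, NetConfig, TrainConfig, predict_keypoints, train
from .phantom import (
    TINY_COHORT_RANGES,
    PhantomSpec,
    RaterModel,
    generate_cohort,
    simulate_raters,
)
from .validation import ValidationResult, build_summary, measurement_table
from .measure import measurement_rows

__all__ = ["RecoveryResult", "parameter_recovery", "consensus_recovery",
           "keypoint_errors", "TINY_BASE_SPEC"]

TINY_BASE_SPEC = PhantomSpec(size_px=128, spacing_cm_per_px=0.02)


def _relabel(dataset: Dataset, prefix: str) -> Dataset:
    frames = [dataclasses.replace(f, frame_id=prefix + f.frame_id,
                                  study_id=prefix + f.study_id)
              for f in dataset.frames]
    anns = [Annotation(frame_id=prefix + a.frame_id, rater_id=a.rater_id,
                       repeat_index=a.repeat_index, points=a.points)
            for a in dataset.annotations]
    return Dataset(frames=frames, annotations=anns)


def keypoint_errors(
    model: KeypointModel,
    dataset: Dataset,
    images: dict[str, np.ndarray],
    miss_penalty_px: float | None = None,
) -> tuple[list[float], list[float]]:
    """Per-point Euclidean errors (px) and per-site relative thickness errors.

    Truth is the dataset's ``TRUTH`` annotations.  A frame with any
    undetected point contributes ``miss_penalty_px`` (image size by default)
    to the keypoint errors and no thickness entries.
    """
    kp_errs: list[float] = []
    th_errs: list[float] = []
    for truth in dataset.annotations:
        if truth.rater_id != "TRUTH":
            continue
        frame = dataset.frame(truth.frame_id)
        penalty = miss_penalty_px if miss_penalty_px is not None else float(frame.width_px)
        preds = predict_keypoints(model, frame, images[frame.frame_id])
        pts = {k: (None if v is None else (v[0], v[1])) for k, v in preds.items()}
        if any(v is None for v in pts.values()):
            kp_errs.extend([penalty] * 4)
            continue
        for k in KeypointName:
            tx, ty = truth.points[k]
            kp_errs.append(float(np.hypot(pts[k][0] - tx, pts[k][1] - ty)))
        spacing = (frame.spacing_x_cm, frame.spacing_y_cm)
        got = derive_measurements(pts, spacing).cm_by_site()
        want = derive_measurements(truth.points, spacing).cm_by_site()
        th_errs.extend(abs(got[s] - want[s]) / want[s] for s in ("IVS", "LVD", "FW"))
    return kp_errs, th_errs


@dataclass
class RecoveryResult:
    model: KeypointModel
    mean_keypoint_error_px: float
    mean_thickness_error_frac: float
    n_eval_frames: int


def parameter_recovery(
    seed: int,
    n_train: int = 200,
    n_eval: int = 50,
    epochs: int = 10,
    net: NetConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> RecoveryResult:
    """Train a small network on a phantom cohort and score it on held-out phantoms.

    Defaults reproduce the package's standard small-scale experiment: depth-2
    base-8 U-Net at 128 px on 200 mildly speckled phantoms, evaluated on 50
    held-out frames.  A separate 20-frame cohort (distinct substream) monitors
    the held-out loss during training.
    """
    netc = net if net is not None else NetConfig(depth=2, base_channels=8,
                                                 working_size=(128, 128))
    cfg = train_cfg if train_cfg is not None else TrainConfig(
        epochs=epochs, batch_size=4, lr_init=0.003, seed=seed, sigma_px=6.0,
        augment=False, optimizer="ADAM")
    train_ds, images = generate_cohort(n_train, TINY_COHORT_RANGES,
                                       seed=seed, base_spec=TINY_BASE_SPEC)
    mon_ds, mon_imgs = generate_cohort(20, TINY_COHORT_RANGES,
                                       seed=seed + 1, base_spec=TINY_BASE_SPEC)
    mon_ds = _relabel(mon_ds, "M")
    images.update({"M" + k: v for k, v in mon_imgs.items()})
    model = train(train_ds, mon_ds, images, netc, cfg)

    eval_ds, eval_imgs = generate_cohort(n_eval, TINY_COHORT_RANGES,
                                         seed=seed + 2, base_spec=TINY_BASE_SPEC)
    kp, th = keypoint_errors(model, eval_ds, eval_imgs)
    return RecoveryResult(
        model=model,
        mean_keypoint_error_px=float(np.mean(kp)),
        mean_thickness_error_frac=float(np.mean(th)) if th else float("nan"),
        n_eval_frames=n_eval,
    )


def consensus_recovery(
    seed: int,
    n_frames: int = 50,
    sigma_transverse_px: float = 2.0,
    spacing_cm_per_px: float = 0.02,
) -> tuple[ValidationResult, float]:
    """Simulate a 13 x 2 panel with pure thickness noise and summarise it.

    With transverse-only noise of ``sigma_t`` px on each endpoint and an
    axis-aligned phantom, each thickness measurement deviates from truth by
    N(0, 2 sigma_t^2) px, so the expert dispersion (SD of deviations from the
    per-frame consensus) converges to sqrt(2) * sigma_t * spacing cm.
    Returns the validation summary (candidate = truth values, rater "AI") and
    that closed-form expectation.
    """
    model = RaterModel(sigma_transverse_px=sigma_transverse_px,
                       sigma_longitudinal_px=0.0,
                       rater_longitudinal_bias_sd_px=0.0)
    spec = PhantomSpec(size_px=320, axis_origin=(60.0, 160.0), axis_angle=0.0,
                       ivs_cm=0.5, lvd_cm=3.0, fw_cm=0.5,
                       spacing_cm_per_px=spacing_cm_per_px, speckle_strength=0.0)
    frames, annotations = [], []
    from .annotation import Phase
    from .phantom import generate_phantom
    for i in range(n_frames):
        frame, _, truth = generate_phantom(
            spec, seed=i, frame_id=f"F{i:03d}", study_id=f"S{i // 2:03d}",
            phase=Phase.ED if i % 2 == 0 else Phase.ES)
        frames.append(frame)
        annotations.extend(simulate_raters(truth, frame, model, seed=seed))
        annotations.append(Annotation(frame_id=frame.frame_id, rater_id="AI",
                                      repeat_index=1, points=truth.points))
    ds = Dataset(frames=frames, annotations=annotations)
    table = measurement_table(measurement_rows(ds))
    result = build_summary(table, candidate_id="AI")
    expected_sd = float(np.sqrt(2.0) * sigma_transverse_px * spacing_cm_per_px)
    return result, expected_sd
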