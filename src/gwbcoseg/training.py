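"""Training and refinement of the cascaded segmentation network.

The workflow mirrors how the method is meant to be used on real CT data:

1. per-image min–max normalization to [0,1];
2. an incremental split schedule (40% training, growing by 10% per step to
   80%, with nested training sets);
3. gradient pre-training of each stage with a composite pixelwise
   cross-entropy + soft-Dice loss (the Dice term counters the severe class
   imbalance of small organs) using adaptive-moment descent;
4. post-training GWBCO refinement of a layer subset: candidate weight
   vectors live in a box of half-width ``half_width`` around the pre-trained
   subset vector, the fitness is the mean validation Dice coefficient after
   injecting a candidate, and the population is seeded with the pre-trained
   vector itself — together with best-ever tracking this guarantees
   refinement never degrades validation DSC;
5. a four-arm ablation harness (base / GWO-only / BCO-only / full GWBCO)
   and the end-to-end two-stage pipeline.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .nn import bce_dice_loss, sigmoid
from .optimizer import OptimizerConfig, SearchSpace, gwbco_optimize
from .phantom import PhantomCase
from .unet import (FINAL_BLOCK_SUBSET, ParameterVector, StageNetwork,
                   StageNetworkConfig, build_stage_network,
                   extract_parameter_vector, fuse_predictions,
                   inject_parameter_vector, predict_mask, _resolve_subset)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing and splits
# ---------------------------------------------------------------------------

def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Scale one image to [0,1] by its own min/max; a constant image maps to
    all zeros rather than faulting on the zero range."""
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


@dataclass(frozen=True)
class SplitSchedule:
    """Nested incremental train/test splits over case indices."""

    train_fractions: tuple[float, ...]
    steps: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, test) per step

    def train_indices(self, step: int) -> tuple[int, ...]:
        return self.steps[step][0]

    def test_indices(self, step: int) -> tuple[int, ...]:
        return self.steps[step][1]


DEFAULT_FRACTIONS = (0.4, 0.5, 0.6, 0.7, 0.8)


def make_split_schedule(n_cases: int,
                        train_fractions: Sequence[float] = DEFAULT_FRACTIONS,
                        seed: int = 0) -> SplitSchedule:
    """Shuffle once, then grow the training set along the fraction ladder so
    each step's training cases are a superset of the previous step's."""
    if n_cases < 10:
        raise ValueError("need at least 10 cases to realize 10% steps")
    fracs = tuple(train_fractions)
    if any(f2 - f1 <= 0 for f1, f2 in zip(fracs, fracs[1:])):
        raise ValueError("train_fractions must be strictly increasing")
    if not 0 < fracs[0] and fracs[-1] < 1:
        raise ValueError("train_fractions must lie in (0, 1)")
    order = np.random.default_rng(seed).permutation(n_cases)
    steps = []
    for f in fracs:
        k = int(round(f * n_cases))
        if not 0 < k < n_cases:
            raise ValueError(f"fraction {f} leaves an empty train or test set")
        steps.append((tuple(int(i) for i in order[:k]),
                      tuple(int(i) for i in order[k:])))
    return SplitSchedule(train_fractions=fracs, steps=tuple(steps))


def stack_cases(cases: Sequence[PhantomCase], target: str = "pancreas",
                normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Collect (images, masks) arrays for one stage's truth.

    ``target`` is ``"pancreas"`` or ``"tumor"``.  A case whose target mask is
    missing (None) is skipped with a logged warning; an empty mask is a valid
    truth and is kept."""
    imgs, msks = [], []
    for case in cases:
        mask = case.pancreas_mask if target == "pancreas" else case.tumor_mask
        if mask is None:
            logger.warning("case %s has no %s mask; skipped", case.case_id, target)
            continue
        img = minmax_normalize(case.image) if normalize else np.asarray(case.image, float)
        imgs.append(img)
        msks.append(np.asarray(mask, float))
    if not imgs:
        raise ValueError(f"no cases with a {target} mask")
    return np.stack(imgs), np.stack(msks)


# ---------------------------------------------------------------------------
# gradient pre-training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50          # desk-scale default; 500 at full scale
    eval_every: int = 10      # 100 at full scale
    dice_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs and self.eval_every > self.epochs:
            raise ValueError("eval_every must not exceed epochs")


def pretrain_stage(net: StageNetwork, images: np.ndarray, masks: np.ndarray,
                   config: TrainConfig) -> dict:
    """Mini-batch gradient training of one stage; returns a history dict with
    per-epoch mean loss and periodic mean training DSC."""
    if len(images) == 0:
        raise ValueError("empty training set")
    x = images[:, None].astype(float)
    y = masks[:, None].astype(float)
    rng = np.random.default_rng(config.seed)
    opt = net.make_optimizer(config.learning_rate)
    history = {"epoch_loss": [], "eval_epochs": [], "eval_dsc": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for i0 in range(0, len(x), config.batch_size):
            idx = order[i0:i0 + config.batch_size]
            net.zero_grad()
            logits = net.forward(x[idx], train=True)
            loss, dlogits = bce_dice_loss(logits, y[idx], config.dice_weight)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training loss diverged (non-finite) at epoch {epoch}")
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["epoch_loss"].append(float(np.mean(losses)))
        if (epoch + 1) % config.eval_every == 0:
            history["eval_epochs"].append(epoch + 1)
            history["eval_dsc"].append(mean_dsc(net, images, masks))
    return history


def mean_dsc(net: StageNetwork, images: np.ndarray, masks: np.ndarray,
             threshold: float = 0.5) -> float:
    """Mean per-image Dice of thresholded predictions against truths."""
    logits = net.forward(images[:, None].astype(float))
    preds = sigmoid(logits[:, 0]) > threshold
    return float(np.mean([metrics.dsc(p, t) for p, t in
                          zip(preds.astype(np.uint8), masks.astype(np.uint8))]))


# ---------------------------------------------------------------------------
# GWBCO weight refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    net: StageNetwork
    initial_val_dsc: float
    final_val_dsc: float
    history: list[dict] = field(default_factory=list)
    best_vector: ParameterVector | None = None


def refine_with_gwbco(net: StageNetwork, val_images: np.ndarray,
                      val_masks: np.ndarray, opt_config: OptimizerConfig,
                      subset: Sequence[str] = FINAL_BLOCK_SUBSET,
                      half_width: float = 0.5,
                      dimension_cap: int = 4000,
                      threshold: float = 0.5) -> RefinementResult:
    """Swarm-refine a weight subset against mean validation DSC.

    The search box is centered on the pre-trained subset vector with
    componentwise half-width ``half_width``; the pre-trained vector seeds the
    population, so the returned network is never worse on the validation set
    than the input network."""
    if len(val_images) == 0:
        raise ValueError("empty validation set")
    vec0 = extract_parameter_vector(net, subset)
    if len(vec0) > dimension_cap:
        warnings.warn(
            f"refining {len(vec0)} parameters; search quality degrades in "
            f"high dimension (cap {dimension_cap})", stacklevel=2)
    layer_names = set(_resolve_subset(net, subset))
    start_stage = net.first_stage_of(layer_names)
    x = val_images[:, None].astype(float)
    y = val_masks.astype(np.uint8)
    # activations upstream of the refined layers never change: cache them once
    _, cache = net.forward_with_cache(x)

    layout = vec0.layout

    def fitness(position: np.ndarray) -> float:
        inject_parameter_vector(net, ParameterVector(position, layout))
        logits = net.forward_from(cache, start_stage)
        preds = (sigmoid(logits[:, 0]) > threshold).astype(np.uint8)
        return float(np.mean([metrics.dsc(p, t) for p, t in zip(preds, y)]))

    initial = fitness(vec0.values)
    if opt_config.max_iterations == 0:
        inject_parameter_vector(net, vec0)
        return RefinementResult(net=net, initial_val_dsc=initial,
                                final_val_dsc=initial, best_vector=vec0)
    space = SearchSpace(vec0.values - half_width, vec0.values + half_width)
    result = gwbco_optimize(fitness, space, opt_config,
                            initial_positions=[vec0.values])
    best = ParameterVector(result.best_position, layout)
    inject_parameter_vector(net, best)
    return RefinementResult(net=net, initial_val_dsc=initial,
                            final_val_dsc=float(result.best_fitness),
                            history=result.history, best_vector=best)


# ---------------------------------------------------------------------------
# end-to-end pipeline and ablation
# ---------------------------------------------------------------------------

ARM_CONFIGS = {
    "base": None,  # pre-training only
    "gwo": dict(eyeing=False, observation=False),
    "bco": dict(leader_mode="global_best", eyeing=True, observation=True),
    "gwbco": dict(),
}


def clone_network(net: StageNetwork) -> StageNetwork:
    fresh = StageNetwork(net.config, np.random.default_rng(0))
    for name, layer in net.layers.items():
        for pname, arr in layer.params().items():
            fresh.layers[name].params()[pname][...] = arr
    return fresh


@dataclass
class PipelineResult:
    predictions: list[tuple[str, object]]  # (case_id, CascadePrediction)
    pancreas_report: metrics.MetricReport
    tumor_report: metrics.MetricReport
    per_case: pd.DataFrame
    refinement: dict[str, RefinementResult] = field(default_factory=dict)


def _split_train_val(train_cases: list, val_fraction: float = 0.25
                     ) -> tuple[list, list]:
    n_val = max(1, int(round(val_fraction * len(train_cases))))
    return train_cases[:-n_val], train_cases[-n_val:]


def run_two_stage_pipeline(cases: Sequence[PhantomCase],
                           net_config: StageNetworkConfig | None = None,
                           train_config: TrainConfig | None = None,
                           opt_config: OptimizerConfig | None = None,
                           subset: Sequence[str] = FINAL_BLOCK_SUBSET,
                           seed: int = 0,
                           schedule_step: int = -1,
                           networks: tuple[StageNetwork, StageNetwork] | None = None,
                           ) -> PipelineResult:
    """Train (or reuse), optionally refine, and evaluate the full cascade.

    The split schedule's largest-train step is the reported model by
    default; refinement fitness is computed on a held-out quarter of the
    training cases.  ``opt_config=None`` skips refinement (the "base" arm);
    ``networks`` short-circuits pre-training with ready-made stage networks.
    """
    net_config = net_config or StageNetworkConfig()
    train_config = train_config or TrainConfig()
    schedule = make_split_schedule(len(cases), seed=seed)
    train_idx = schedule.train_indices(schedule_step)
    test_idx = schedule.test_indices(schedule_step)
    train_cases = [cases[i] for i in train_idx]
    test_cases = [cases[i] for i in test_idx]
    fit_cases, val_cases = _split_train_val(train_cases)

    refinement: dict[str, RefinementResult] = {}
    nets: dict[str, StageNetwork] = {}
    for stage_i, target in enumerate(("pancreas", "tumor")):
        if networks is not None:
            net = networks[stage_i]
        else:
            net = build_stage_network(net_config, seed + 1000 * (stage_i + 1))
            x, ymask = stack_cases(fit_cases, target)
            pretrain_stage(net, x, ymask, train_config)
        if opt_config is not None and networks is None:
            vx, vy = stack_cases(val_cases, target)
            refinement[target] = refine_with_gwbco(net, vx, vy, opt_config,
                                                   subset=subset)
        nets[target] = net

    rows, predictions = [], []
    pan_reports, tum_reports = [], []
    for case in test_cases:
        img = minmax_normalize(case.image)
        pan = predict_mask(nets["pancreas"], img)
        tum = predict_mask(nets["tumor"], img)
        fused = fuse_predictions(pan, tum)
        predictions.append((case.case_id, fused))
        pr = metrics.metric_report(pan, case.pancreas_mask)
        tr = metrics.metric_report(tum, case.tumor_mask)
        pan_reports.append(pr)
        tum_reports.append(tr)
        rows.append({"case_id": case.case_id, "target": "pancreas", **pr.as_dict()})
        rows.append({"case_id": case.case_id, "target": "tumor", **tr.as_dict()})

    return PipelineResult(
        predictions=predictions,
        pancreas_report=metrics.mean_report(pan_reports),
        tumor_report=metrics.mean_report(tum_reports),
        per_case=pd.DataFrame(rows),
        refinement=refinement,
    )


def run_ablation(cases: Sequence[PhantomCase],
                 net_config: StageNetworkConfig | None = None,
                 train_config: TrainConfig | None = None,
                 opt_config: OptimizerConfig | None = None,
                 subset: Sequence[str] = FINAL_BLOCK_SUBSET,
                 seed: int = 0,
                 arms: Sequence[str] = ("base", "gwo", "bco", "gwbco"),
                 ) -> pd.DataFrame:
    """Four-arm ablation: pre-train once per seed, then refine clones of the
    pre-trained stages under each arm's optimizer variant.

    Arms: ``base`` (no refinement), ``gwo`` (eyeing displacement forced to
    zero, observation phase disabled), ``bco`` (leader consensus replaced by
    a global-best-only update, eyeing and observation active), ``gwbco``
    (the full hybrid).  Returns a table of one row per arm × target."""
    net_config = net_config or StageNetworkConfig()
    train_config = train_config or TrainConfig()
    opt_config = opt_config or OptimizerConfig()
    schedule = make_split_schedule(len(cases), seed=seed)
    train_idx = schedule.train_indices(-1)
    test_idx = schedule.test_indices(-1)
    train_cases = [cases[i] for i in train_idx]
    test_cases = [cases[i] for i in test_idx]
    fit_cases, val_cases = _split_train_val(train_cases)

    pretrained: dict[str, StageNetwork] = {}
    for stage_i, target in enumerate(("pancreas", "tumor")):
        net = build_stage_network(net_config, seed + 1000 * (stage_i + 1))
        x, ymask = stack_cases(fit_cases, target)
        pretrain_stage(net, x, ymask, train_config)
        pretrained[target] = net

    rows = []
    for arm in arms:
        if arm not in ARM_CONFIGS:
            raise ValueError(f"unknown arm {arm!r}; choose from {list(ARM_CONFIGS)}")
        arm_nets = {}
        for target in ("pancreas", "tumor"):
            net = clone_network(pretrained[target])
            overrides = ARM_CONFIGS[arm]
            if overrides is not None:
                cfg_kwargs = {**opt_config.__dict__, **overrides}
                vx, vy = stack_cases(val_cases, target)
                refine_with_gwbco(net, vx, vy, OptimizerConfig(**cfg_kwargs),
                                  subset=subset)
            arm_nets[target] = net
        for target in ("pancreas", "tumor"):
            reports = []
            for case in test_cases:
                img = minmax_normalize(case.image)
                pred = predict_mask(arm_nets[target], img)
                truth = case.pancreas_mask if target == "pancreas" else case.tumor_mask
                reports.append(metrics.metric_report(pred, truth))
            agg = metrics.mean_report(reports)
            rows.append({"arm": arm, "target": target, **agg.as_dict()})
    return pd.DataFrame(rows)
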