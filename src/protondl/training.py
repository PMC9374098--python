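"""Model training, fine-tuning and dose conversion.

Training items are individual beams, each brought to the default field
orientation (gantry 270) and normalized before the network sees it; the model
therefore only ever learns one beam direction. Conversion offers two modes:

* ``per_beam`` (the recommended one): convert each beam separately in the
  default orientation, rotate the result back and sum.
* ``composite``: convert the summed plan dose in the native orientation in a
  single pass (no rotation), which is faster but mixes beam directions the
  model never saw in that arrangement.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np

from .dataset import SITES, CaseRecord
from .grid import ScalarVolume, VolumeKind
from .nn import Adam, HDUNet, ModelConfig, backward, constant, mse_loss, predict_volume
from .nn.model import DESK_SCALE_CONFIG, FULL_SCALE_CONFIG
from .preprocess import (
    NormalizationRecord,
    compose_beams,
    denormalize_dose,
    dose_bounding_box,
    normalize_ct,
    normalize_dose,
    patch_grid_corners,
    random_patch_corner,
    rotate_back,
    rotate_to_default,
    sample_patch,
)

__all__ = [
    "TrainConfig",
    "DESK_TRAIN_CONFIG",
    "FULL_SCALE_TRAIN_CONFIG",
    "TrainingHistory",
    "ExperimentSpec",
    "experiment",
    "train_model",
    "fine_tune",
    "convert_beam",
    "convert_case",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    The learning rate is reduced on a validation-loss plateau (halved after
    ``plateau_patience`` epochs without improvement, floored at ``min_lr``);
    the returned model carries the weights of the best validation epoch.
    """

    model: ModelConfig = FULL_SCALE_CONFIG
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 2
    patches_per_item: int = 2
    val_fraction: float = 0.2
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-5
    #: fraction of training patches centered on the PB-vs-reference
    #: discrepancy volume instead of the dose region. Off by default: uniform
    #: dose-region sampling trains at least as well in practice, but the knob
    #: is available for studies of interface-heavy anatomies.
    discrepancy_fraction: float = 0.0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.patches_per_item < 1:
            raise ValueError("invalid training configuration")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must be in [0, 1), got {self.val_fraction}")
        if not 0.0 <= self.discrepancy_fraction <= 1.0:
            raise ValueError(
                f"discrepancy_fraction must be in [0, 1], got {self.discrepancy_fraction}"
            )


#: full-size training configuration
FULL_SCALE_TRAIN_CONFIG = TrainConfig()

#: reduced configuration sized for quick desk runs on a single CPU
DESK_TRAIN_CONFIG = TrainConfig(
    model=DESK_SCALE_CONFIG, epochs=12, patches_per_item=1, plateau_patience=4
)

#: fine-tuning uses a fixed, lower learning rate for half the epochs
FINE_TUNE_LR = 1e-4


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def record(self, epoch: int, train_loss: float, val_loss: float, lr: float) -> None:
        self.epochs.append(
            {
                "epoch": epoch,
                "train_loss": float(train_loss),
                "val_loss": float(val_loss),
                "learning_rate": float(lr),
            }
        )
        if val_loss < self.best_val_loss:
            self.best_val_loss = float(val_loss)
            self.best_epoch = epoch


@dataclass(frozen=True)
class ExperimentSpec:
    """A training/evaluation protocol over the site families.

    The five standard protocols:

    1. ``single_site``   - train and evaluate on one site.
    2. ``cross_site``    - train on one site, evaluate on the others unseen.
    3. ``leave_one_out`` - train on all sites but one, evaluate the held-out one.
    4. ``joint``         - train and evaluate on all sites.
    5. ``fine_tune``     - leave-one-out model fine-tuned on the held-out site.
    """

    name: str
    train_sites: tuple[str, ...]
    eval_sites: tuple[str, ...]
    fine_tune_sites: tuple[str, ...] = ()

    def __post_init__(self):
        for s in self.train_sites + self.eval_sites + self.fine_tune_sites:
            if s not in SITES:
                raise ValueError(f"unknown site {s!r}")
        if not self.train_sites or not self.eval_sites:
            raise ValueError("experiment needs train and eval sites")


def experiment(protocol: str, site: str = "prostate_like") -> ExperimentSpec:
    """Build one of the five standard :class:`ExperimentSpec` protocols."""
    others = tuple(s for s in SITES if s != site)
    if protocol == "single_site":
        return ExperimentSpec("single_site", (site,), (site,))
    if protocol == "cross_site":
        return ExperimentSpec("cross_site", (site,), others)
    if protocol == "leave_one_out":
        return ExperimentSpec("leave_one_out", others, (site,))
    if protocol == "joint":
        return ExperimentSpec("joint", SITES, SITES)
    if protocol == "fine_tune":
        return ExperimentSpec("fine_tune", others, (site,), fine_tune_sites=(site,))
    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass
class _TrainItem:
    """One beam, rotated to the default orientation and normalized."""

    case_id: str
    ct_norm: ScalarVolume
    pb_norm: ScalarVolume
    mc_norm: ScalarVolume
    #: |reference - PB| in normalized units, for discrepancy-centered sampling
    diff: ScalarVolume


def _prepare_items(cases: list[CaseRecord]) -> list[_TrainItem]:
    items = []
    for case in cases:
        ct_n = normalize_ct(case.ct)
        for beam in case.beams:
            geo = beam.spec.geometry
            pb_r = rotate_to_default(beam.pb, geo)
            mc_r = rotate_to_default(beam.mc, geo)
            ct_r = rotate_to_default(ct_n, geo)
            pb_n, rec = normalize_dose(pb_r)
            mc_n, _ = normalize_dose(mc_r, rec)
            diff = ScalarVolume(
                pb_n.grid,
                np.abs(mc_n.values - pb_n.values),
                VolumeKind.NORMALIZED,
            )
            items.append(_TrainItem(case.case_id, ct_r, pb_n, mc_n, diff))
    return items


def _training_corner(
    rng: np.random.Generator, item: _TrainItem, patch_shape, discrepancy_fraction: float
):
    """Patch corner for one training draw: dose-centered or discrepancy-centered."""
    if rng.random() < discrepancy_fraction and item.diff.values.max() > 0:
        return random_patch_corner(rng, item.diff, patch_shape)
    return random_patch_corner(rng, item.pb_norm, patch_shape)


def _batch_tensors(items, corners, patch_shape):
    xs, ys = [], []
    for item, corner in zip(items, corners):
        pb_p, ct_p, mc_p = sample_patch(
            [item.pb_norm, item.ct_norm, item.mc_norm], corner, patch_shape
        )
        xs.append(np.stack([pb_p, ct_p], axis=-1))
        ys.append(mc_p[..., None])
    return constant(np.stack(xs)), constant(np.stack(ys))


def _validation_loss(model: HDUNet, items: list[_TrainItem], patch_shape) -> float:
    """Mean eval-mode patch loss over a fixed tiling of each item's treated region."""
    model.set_training(False)
    losses = []
    for item in items:
        lo, hi = dose_bounding_box(item.pb_norm)
        span = tuple(h - l + 1 for l, h in zip(lo, hi))
        corners = [
            tuple(c + l for c, l in zip(corner, lo))
            for corner in patch_grid_corners(span, patch_shape, 0.0)
        ]
        x, y = _batch_tensors([item] * len(corners), corners, patch_shape)
        losses.append(float(mse_loss(model(x), y).data))
    model.set_training(True)
    return float(np.mean(losses))


def _run_epochs(
    model: HDUNet,
    train_items: list[_TrainItem],
    val_items: list[_TrainItem],
    epochs: int,
    optimizer: Adam,
    config: TrainConfig,
    rng: np.random.Generator,
    history: TrainingHistory,
    adapt_lr: bool,
    log=None,
) -> dict[str, np.ndarray]:
    patch_shape = config.model.patch_shape
    best_state = {k: v.copy() for k, v in model.named_state().items()}
    if history.best_val_loss == float("inf") and val_items:
        history.best_val_loss = _validation_loss(model, val_items, patch_shape)
    epochs_since_best = 0
    start_epoch = len(history.epochs)
    for epoch in range(start_epoch, start_epoch + epochs):
        model.set_training(True)
        order = rng.permutation(len(train_items)).repeat(config.patches_per_item)
        rng.shuffle(order)
        train_losses = []
        for lo in range(0, len(order), config.batch_size):
            batch_idx = order[lo : lo + config.batch_size]
            items = [train_items[i] for i in batch_idx]
            corners = [
                _training_corner(rng, it, patch_shape, config.discrepancy_fraction)
                for it in items
            ]
            x, y = _batch_tensors(items, corners, patch_shape)
            loss = mse_loss(model(x), y)
            backward(loss)
            optimizer.step()
            optimizer.zero_grad()
            train_losses.append(float(loss.data))
        val_loss = (
            _validation_loss(model, val_items, patch_shape)
            if val_items
            else float(np.mean(train_losses))
        )
        improved = val_loss < history.best_val_loss
        history.record(epoch, float(np.mean(train_losses)), val_loss, optimizer.lr)
        if improved:
            best_state = {k: v.copy() for k, v in model.named_state().items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if adapt_lr and epochs_since_best >= config.plateau_patience:
                optimizer.lr = max(config.min_lr, optimizer.lr * config.plateau_factor)
                epochs_since_best = 0
        if log is not None:
            log(history.epochs[-1])
    return best_state


def train_model(
    cases: list[CaseRecord],
    config: TrainConfig = DESK_TRAIN_CONFIG,
    seed: int = 0,
    sites: tuple[str, ...] | None = None,
    log=None,
) -> tuple[HDUNet, TrainingHistory]:
    """Train an HD U-Net on the given cases (optionally filtered by site).

    The train/validation split is at case level so all beams of one case fall
    on the same side. Returns the model with the best-validation weights
    loaded, plus the per-epoch history. Everything is deterministic given the
    seed. ``log``, if given, is called with each epoch's record dict.
    """
    if sites is not None:
        cases = [c for c in cases if c.site in sites]
    if not cases:
        raise ValueError("no cases to train on")
    rng = np.random.default_rng(seed)
    model = HDUNet(config.model, rng)
    case_order = rng.permutation(len(cases))
    n_val = int(round(config.val_fraction * len(cases)))
    n_val = min(n_val, len(cases) - 1)
    val_cases = [cases[i] for i in case_order[:n_val]]
    train_cases = [cases[i] for i in case_order[n_val:]]
    train_items = _prepare_items(train_cases)
    val_items = _prepare_items(val_cases)
    history = TrainingHistory()
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    best_state = _run_epochs(
        model, train_items, val_items, config.epochs, optimizer, config, rng, history,
        adapt_lr=True, log=log,
    )
    model.load_state(best_state)
    model.set_training(False)
    return model, history


def fine_tune(
    model: HDUNet,
    cases: list[CaseRecord],
    epochs: int,
    seed: int = 0,
    learning_rate: float = FINE_TUNE_LR,
    config: TrainConfig | None = None,
    sites: tuple[str, ...] | None = None,
    log=None,
) -> tuple[HDUNet, TrainingHistory]:
    """Adapt a trained model to new cases at a fixed, lower learning rate.

    With ``epochs=0`` the model is returned unchanged. The base config (batch
    size etc.) defaults to the model's scale; the learning rate stays fixed
    (no plateau schedule) as befits a short adaptation run.
    """
    if sites is not None:
        cases = [c for c in cases if c.site in sites]
    if not cases:
        raise ValueError("no cases to fine-tune on")
    if config is None:
        config = TrainConfig(
            model=model.config, epochs=epochs, learning_rate=learning_rate
        )
    history = TrainingHistory()
    if epochs == 0:
        return model, history
    rng = np.random.default_rng(seed)
    case_order = rng.permutation(len(cases))
    n_val = min(int(round(config.val_fraction * len(cases))), len(cases) - 1)
    val_items = _prepare_items([cases[i] for i in case_order[:n_val]])
    train_items = _prepare_items([cases[i] for i in case_order[n_val:]])
    model.set_training(True)
    optimizer = Adam(model.parameters(), lr=learning_rate)
    best_state = _run_epochs(
        model, train_items, val_items, epochs, optimizer, config, rng, history,
        adapt_lr=False, log=log,
    )
    model.load_state(best_state)
    model.set_training(False)
    return model, history


def convert_beam(
    model: HDUNet,
    ct: ScalarVolume,
    pb: ScalarVolume,
    geometry,
) -> ScalarVolume:
    """Convert one beam's PB dose to MC-equivalent dose (Gy, native frame)."""
    ct_n = rotate_to_default(normalize_ct(ct), geometry)
    pb_r = rotate_to_default(pb, geometry)
    pb_n, rec = normalize_dose(pb_r)
    pred_n = predict_volume(model, pb_n, ct_n)
    pred = denormalize_dose(pred_n, rec)
    return rotate_back(pred, geometry, target_grid=pb.grid)


def convert_case(
    model: HDUNet, case: CaseRecord, method: str = "per_beam"
) -> ScalarVolume:
    """Convert a case's plan dose to MC-equivalent dose (Gy).

    ``per_beam`` converts each field in the default orientation and sums the
    rotated-back results; ``composite`` converts the summed dose in one pass.
    """
    if method == "per_beam":
        parts = [
            convert_beam(model, case.ct, b.pb, b.spec.geometry) for b in case.beams
        ]
        return compose_beams(parts)
    if method == "composite":
        ct_n = normalize_ct(case.ct)
        pb_n, rec = normalize_dose(case.pb_composite)
        pred_n = predict_volume(model, pb_n, ct_n)
        return denormalize_dose(pred_n, rec)
    raise ValueError(f"unknown conversion method {method!r}")
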