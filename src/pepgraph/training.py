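"""Multi-label training with FGM adversarial perturbations.

The loop minimizes mean binary cross-entropy over all peptide/label
entries.  With adversarial training enabled, each batch runs a clean
forward/backward pass, perturbs the designated embedding parameter by the
fast-gradient-method step r_adv = ε·∇L/‖∇L‖₂ (equivalently −ε·g/‖g‖₂ for
the score gradient g = ∇ log p), accumulates gradients from a second pass
at the perturbed point, restores the embedding, and takes one AdamW step
on the summed gradients.  Repeat-and-average ensembling mirrors the
standard practice of training several seeds and averaging predicted
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import AdamW, Tensor
from .graphnet import GraphNodeClassifier, PredictionResult
from .seqdata import PeptideDataset

_CLAMP = 1e-7


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (and its repeats)."""

    epochs: int = 100
    batch_size: int = 32
    encoder_lr: float = 5e-5
    gat_lr: float = 1e-3
    epsilon: float = 0.5
    adversarial: bool = True
    weight_decay: float = 0.01
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.encoder_lr <= 0 or self.gat_lr <= 0:
            raise TrainingError("learning rates must be positive")
        if self.epsilon < 0:
            raise TrainingError("epsilon must be >= 0")
        if self.n_repeats < 1:
            raise TrainingError("n_repeats must be >= 1")

    @property
    def seed_list(self) -> list[int]:
        return [self.seed + i for i in range(self.n_repeats)]


@dataclass(frozen=True)
class AdversarialPerturbation:
    """An FGM perturbation and the gradient it was derived from."""

    r_adv: np.ndarray
    g: np.ndarray
    epsilon: float


def multilabel_loss(probabilities, targets) -> Tensor:
    """Mean binary cross-entropy over all N x M entries.

    Probabilities are clamped to [1e-7, 1 - 1e-7] so the loss is always
    finite even at saturated predictions.
    """
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(probabilities)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape:
        raise TrainingError(f"shape mismatch: probs {p.shape} vs targets {y.shape}")
    p = p.clip(_CLAMP, 1.0 - _CLAMP)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def fgm_perturb(g: np.ndarray, epsilon: float) -> AdversarialPerturbation:
    """r_adv = −ε·g/‖g‖₂ over the whole gradient tensor; 0 when g = 0."""
    if epsilon < 0:
        raise TrainingError("epsilon must be >= 0")
    g = np.asarray(g, dtype=np.float64)
    norm = float(np.sqrt((g**2).sum()))
    if norm == 0.0 or epsilon == 0.0:
        r = np.zeros_like(g)
    else:
        r = -epsilon * g / norm
    return AdversarialPerturbation(r_adv=r, g=g, epsilon=float(epsilon))


def _model_inputs(dataset: PeptideDataset, model: GraphNodeClassifier) -> list[str]:
    # the pLM adapter is keyed by id; every other encoder consumes sequences
    if model.encoder.tag == "plm-adapter":
        return [p.id for p in dataset.peptides]
    return dataset.sequences


def adversarial_step(inputs, targets, model: GraphNodeClassifier,
                     optimizer: AdamW, config: TrainConfig,
                     batch_seed: int = 0) -> float:
    """One optimization step: clean pass, optional FGM pass, update.

    Both passes replay the same dropout noise (they differ only in the
    embedding perturbation), so ε = 0 reduces exactly to a clean step with
    doubled gradient accumulation.
    """
    optimizer.zero_grad()
    probs, _ = model.forward_batch(
        inputs, training=True, rng=np.random.default_rng(batch_seed)
    )
    loss = multilabel_loss(probs, targets)
    loss.backward()
    total = float(loss.data)
    if config.adversarial:
        site = model.perturbation_site()
        if site is None:
            raise TrainingError(
                "adversarial training needs an embedding/projection "
                "perturbation site, but the encoder exposes none"
            )
        # score gradient g = ∇ log p = −(loss gradient)
        pert = fgm_perturb(-site.grad, config.epsilon)
        backup = site.data.copy()
        site.data = site.data + pert.r_adv
        try:
            probs_adv, _ = model.forward_batch(
                inputs, training=True, rng=np.random.default_rng(batch_seed)
            )
            loss_adv = multilabel_loss(probs_adv, targets)
            loss_adv.backward()
            total += float(loss_adv.data)
        finally:
            site.data = backup
    if not np.isfinite(total):
        raise TrainingError(f"non-finite loss {total}")
    optimizer.step()
    return total


def make_optimizer(model: GraphNodeClassifier, config: TrainConfig) -> AdamW:
    groups = []
    enc = model.encoder_parameters()
    if enc:
        groups.append({"params": enc, "lr": config.encoder_lr})
    groups.append({"params": model.graph_parameters(), "lr": config.gat_lr})
    return AdamW(groups, weight_decay=config.weight_decay)


def train(model: GraphNodeClassifier, train_data: PeptideDataset,
          config: TrainConfig | None = None,
          seed: int | None = None) -> tuple[GraphNodeClassifier, list[dict]]:
    """Train in place for ``config.epochs`` epochs; returns (model, log).

    Deterministic given the seed: batch order, dropout noise and the FGM
    perturbations are all driven by it.
    """
    config = config or TrainConfig()
    seed = config.seed if seed is None else seed
    if len(train_data) == 0:
        raise TrainingError("empty training set")
    if train_data.label_space.names != model.label_space.names:
        raise TrainingError("label space of data and model differ")
    inputs = _model_inputs(train_data, model)
    if getattr(model.encoder, "needs_fit", False):
        model.encoder.fit_scaler(inputs)
    targets = train_data.label_matrix().astype(np.float64)
    n = len(inputs)
    optimizer = make_optimizer(model, config)
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_seed = int(rng.integers(0, 2**31 - 1))
            epoch_loss += adversarial_step(
                [inputs[i] for i in idx], targets[idx], model, optimizer,
                config, batch_seed=batch_seed,
            )
            n_batches += 1
        log.append({
            "epoch": epoch,
            "loss": epoch_loss / max(n_batches, 1),
            "encoder_lr": config.encoder_lr,
            "gat_lr": config.gat_lr,
        })
    return model, log


def train_ensemble(make_model, train_data: PeptideDataset,
                   config: TrainConfig | None = None) -> tuple[list[GraphNodeClassifier], list[list[dict]]]:
    """Train ``config.n_repeats`` models from different seeds.

    ``make_model(seed)`` must build a freshly initialized model.
    """
    config = config or TrainConfig()
    models, logs = [], []
    for s in config.seed_list:
        model = make_model(s)
        model, log = train(model, train_data, config, seed=s)
        models.append(model)
        logs.append(log)
    return models, logs


def ensemble_probabilities(models, inputs) -> np.ndarray:
    """Arithmetic mean of per-label probabilities across models."""
    if not models:
        raise TrainingError("empty model list")
    names = models[0].label_space.names
    for m in models[1:]:
        if m.label_space.names != names:
            raise TrainingError("models disagree on the label space")
    mats = []
    for m in models:
        probs, _ = m.forward_batch(inputs, training=False)
        mats.append(probs.data)
    return np.mean(mats, axis=0)


def ensemble_predict(models, inputs, threshold: float | None = None) -> list[PredictionResult]:
    """Average probabilities across models, then threshold."""
    mean = ensemble_probabilities(models, inputs)
    thr = models[0].config.threshold if threshold is None else threshold
    space = models[0].label_space
    return [PredictionResult.from_probabilities(row, space, thr) for row in mean]
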