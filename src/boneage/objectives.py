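"""Distribution-learning losses with temporal ensembling.

Each branch predicts a probability vector over the 240 monthly age bins and is
trained against the Gaussian-encoded report label ``Y`` with three terms:

* forward KL divergence ``(1/m) sum_i sum_c y_ic log(y_ic / yhat_ic)``;
* a bin-wise L1 distance ``(1/m) sum_i |y_i - yhat_i|_1``;
* a temporal-ensembling consistency term: the same KL kernel against the
  bias-corrected exponential moving average of the model's own per-sample
  predictions across epochs, weighted by a ramp ``T(t) = T_max exp(-5 (1-t)^2)``
  that grows from ~0.0067*T_max at the start of training to T_max.

The EMA targets are stored constants per epoch (no gradient flows into them):
early in training they carry little signal, hence the ramp; late in training
they act as a self-distilled, noise-averaged target.  The bone-part branch
omits the temporal term because individual part crops vary too much between
epochs for a per-sample EMA to be a stable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


def _as_batch(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.ndim != 2:
        raise ValueError(f"expected (m, C) or (C,) array, got shape {y.shape}")
    return y


def kl_loss(target: np.ndarray, predicted: np.ndarray) -> float:
    """Batch-mean forward KL divergence ``KL(target || predicted)``.

    Predictions are clipped below at 1e-12 before the log.  Non-negative by
    Gibbs' inequality; zero iff the distributions match.
    """
    y = _as_batch(target)
    yhat = _as_batch(predicted)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    yhat = np.clip(yhat, _EPS, None)
    ratio = np.where(y > 0, y / yhat, 1.0)
    return float(np.sum(y * np.log(ratio)) / y.shape[0])


def kl_grad(target: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`kl_loss` w.r.t. the predicted vector: -y/yhat/m."""
    y = _as_batch(target)
    yhat = np.clip(_as_batch(predicted), _EPS, None)
    return (-y / yhat / y.shape[0]).reshape(np.asarray(predicted).shape)


def mae_loss(target: np.ndarray, predicted: np.ndarray) -> float:
    """Batch mean of the bin-wise L1 distance between distribution vectors."""
    y = _as_batch(target)
    yhat = _as_batch(predicted)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return float(np.abs(y - yhat).sum(axis=1).mean())


def temporal_loss(assembled: np.ndarray, predicted: np.ndarray) -> tuple[float, int]:
    """KL of predictions against the assembled (EMA) targets.

    Samples whose assembled target is still the all-zero initialisation (no
    EMA update has happened yet) are excluded.  Returns ``(loss, n_skipped)``;
    the loss is 0.0 when every sample is excluded.
    """
    ybar = _as_batch(assembled)
    yhat = _as_batch(predicted)
    if ybar.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {ybar.shape} vs {yhat.shape}")
    live = ybar.sum(axis=1) > 0
    n_skipped = int((~live).sum())
    if not live.any():
        return 0.0, n_skipped
    return kl_loss(ybar[live], yhat[live]), n_skipped


@dataclass
class EnsembleState:
    """Per-sample EMA of predictions across epochs (temporal ensembling).

    ``assembled`` is the running sum ``S_t`` (zero-initialised before the
    first epoch); ``gamma`` the momentum; ``epoch`` the number of completed
    updates ``t``.  The bias-corrected training target is
    ``Ybar = S_t / (1 - gamma^t)``.
    """

    n_samples: int
    n_bins: int = 240
    gamma: float = 0.6
    epoch: int = 0
    assembled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not (0 < self.gamma < 1):
            raise ValueError(f"gamma must be in (0,1), got {self.gamma}")
        if self.assembled is None:
            self.assembled = np.zeros((self.n_samples, self.n_bins))

    def targets(self) -> np.ndarray:
        """Bias-corrected targets ``Ybar_{t+1} = S_t / (1 - gamma^t)``.

        All-zero rows (before the first update) are returned as zeros; the
        temporal loss skips them.
        """
        if self.epoch == 0:
            return np.zeros_like(self.assembled)
        return self.assembled / (1.0 - self.gamma ** self.epoch)

    def update(self, predictions: np.ndarray) -> np.ndarray:
        """Fold one epoch of predictions into the EMA; returns the new targets.

        ``S_t = gamma S_{t-1} + (1-gamma) Yhat_t`` with ``t`` incremented to
        at least 1, so the bias correction never divides by zero.
        """
        predictions = np.asarray(predictions, dtype=float)
        if predictions.shape != self.assembled.shape:
            raise ValueError(
                f"expected shape {self.assembled.shape}, got {predictions.shape}"
            )
        self.assembled = self.gamma * self.assembled + (1 - self.gamma) * predictions
        self.epoch += 1
        return self.targets()


def ema_update(state: EnsembleState, predictions: np.ndarray
               ) -> tuple[EnsembleState, np.ndarray]:
    """Functional wrapper over :meth:`EnsembleState.update`."""
    targets = state.update(predictions)
    return state, targets


@dataclass(frozen=True)
class RampSchedule:
    """Ramp for the temporal term: ``T(t) = T_max exp(-5 (1-t)^2)``.

    ``t`` is training progress, ``epoch / ramp_length`` capped at 1; the
    weight rises from ``T_max * e^-5`` at epoch 0 to ``T_max`` at the end of
    the ramp and stays there.
    """

    t_max: float = 1.0
    ramp_length: int = 80

    def __post_init__(self):
        if self.t_max <= 0 or self.ramp_length < 1:
            raise ValueError("t_max must be > 0 and ramp_length >= 1")


def ramp_weight(epoch: int, schedule: RampSchedule) -> float:
    """Evaluate the ramp at an epoch (monotone non-decreasing)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    t = min(epoch / schedule.ramp_length, 1.0)
    return schedule.t_max * float(np.exp(-5.0 * (1.0 - t) ** 2))


def branch_loss(
    target: np.ndarray,
    predicted: np.ndarray,
    assembled: np.ndarray | None = None,
    weight: float = 0.0,
    use_ensembling: bool = True,
) -> float:
    """One branch's loss: ``KL + L1 (+ weight * temporal)``.

    The raw- and hand-image branches use the temporal term
    (``use_ensembling=True``, ``weight`` from :func:`ramp_weight`); the
    bone-part branch does not.
    """
    loss = kl_loss(target, predicted) + mae_loss(target, predicted)
    if use_ensembling and weight != 0.0:
        if assembled is None:
            raise ValueError("use_ensembling requires assembled targets")
        t_loss, _ = temporal_loss(assembled, predicted)
        loss += weight * t_loss
    return loss


def total_loss(
    target: np.ndarray,
    raw: np.ndarray,
    hand: np.ndarray,
    parts: list[np.ndarray],
    raw_assembled: np.ndarray | None,
    hand_assembled: np.ndarray | None,
    weight: float,
) -> float:
    """Sum of the three branch losses; part losses are averaged over parts."""
    loss = branch_loss(target, raw, raw_assembled, weight, use_ensembling=True)
    loss += branch_loss(target, hand, hand_assembled, weight, use_ensembling=True)
    if parts:
        part_losses = [branch_loss(target, p, use_ensembling=False) for p in parts]
        loss += float(np.mean(part_losses))
    return loss
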