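"""Three-branch training and inference pipeline.

Branch 1 sees the whole (letterboxed) radiograph; its class-activation map
both predicts an age distribution and, thresholded, localises the hand.
Branch 2 sees the hand crop and is the branch read out at test time.  Branch 3
sees the top-N bone-part crops proposed from Branch 2's activation map.  All
branches share one backbone and one projection head by default (a config
switch gives each branch its own), and every branch is supervised with the
same image-level Gaussian label distribution — no box or part annotation is
used anywhere.

Training is minibatch momentum SGD on the composite loss (KL + L1 + ramped
temporal-ensembling consistency for branches 1 and 2; KL + L1 averaged over
parts for branch 3), with per-branch EMA prediction ensembles updated once
per epoch and model selection on validation MAE.
"""

from __future__ import annotations

import copy
import datetime
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import objectives
from .labels import (
    N_BINS,
    LabelParseError,
    decode_age,
    label_to_mu,
    make_distribution,
    parse_report_label,
)
from .localization import (
    RoIBox,
    activation_to_image_box,
    crop_and_resize,
    make_mask,
    mask_to_box,
    resize_bilinear,
)
from .nn import CAMModel, HeadOutputs, MomentumSGD
from .parts import AnchorConfig, ScoredRegion, propose_parts

_EPS = 1e-12


@dataclass
class TrainingConfig:
    """All knobs of the pipeline; defaults are the full-scale settings.

    ``input_size``/``part_size``/``proposal_frame`` shrink together for CPU-scale
    runs (see :func:`desk_config`); anchor scales and stride are always stated
    in the 576 canonical frame and rescale automatically.
    """

    sigma: float = 3.0          # label Gaussian width, months
    tau: float = 0.6            # hand-mask threshold on the normalised CAM
    eta: float = 4.0            # contrast stretch of the proposal map
    n_parts: int = 4            # bone-part crops per image
    gamma: float = 0.6          # temporal-ensembling momentum
    t_max: float = 1.0          # ceiling of the consistency ramp
    ramp_frac: float = 0.8      # fraction of epochs over which the ramp rises
    input_size: int = 576       # raw/hand branch input side, px
    part_size: int = 288        # part branch input side, px
    proposal_frame: int = 576       # frame the activation map is resized to for part proposal
    batch_size: int = 32
    epochs: int = 90
    learning_rate: float = 1e-3
    lr_decay_every: int = 30    # epochs between x lr_decay_factor steps
    lr_decay_factor: float = 0.1
    momentum: float = 0.9
    head_lr_mult: float = 1.0   # extra lr on the 1x1 projection head
    nms_iou: float = 0.25
    anchor_stride: int = 32     # in the 576 canonical frame
    cam: str = "argmax"         # masking channel: "argmax" or "soft" (p-weighted)
    readout: str = "expectation"  # distribution -> months: or "argmax"
    shared_backbone: bool = True
    seed: int = 0

    @property
    def ramp_length(self) -> int:
        return max(1, int(round(self.ramp_frac * self.epochs)))

    @property
    def anchor_config(self) -> AnchorConfig:
        return AnchorConfig(stride=self.anchor_stride)

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainingConfig":
        import yaml

        return cls(**(yaml.safe_load(text) or {}))


def desk_config(**overrides) -> TrainingConfig:
    """CPU-scale settings: 96 px inputs, 48 px parts, small batches.

    The optimisation constants differ from the full-scale defaults because
    the bundled backbone is a from-scratch 4-block net, not a pretrained
    ResNet: it needs a much larger step size, and the projection head an even
    larger one to sharpen its 240-bin outputs within a 30-epoch budget.
    """
    base = dict(input_size=96, part_size=48, proposal_frame=96,
                batch_size=8, epochs=30,
                learning_rate=0.3, head_lr_mult=10.0)
    base.update(overrides)
    return TrainingConfig(**base)


@dataclass
class Sample:
    """One training/evaluation item: an image plus its report label text."""

    image: np.ndarray
    label_text: str
    true_age_months: float | None = None
    key: int = 0  # stable per-sample identity for the EMA ensembles


def samples_from_phantoms(phantom_samples) -> list["Sample"]:
    """Adapt :mod:`boneage.phantoms` samples to pipeline samples."""
    return [
        Sample(image=s.image, label_text=s.report,
               true_age_months=s.truth.age_months, key=i)
        for i, s in enumerate(phantom_samples)
    ]


def load_manifest(manifest_path: str | Path) -> dict[str, list[Sample]]:
    """Read a manifest CSV into per-split sample lists.

    Columns: ``image_path, label_text, mu_months (optional), split``; image
    paths are resolved relative to the manifest.  Numeric ``mu_months``
    overrides ``label_text`` when the latter is empty.
    """
    from PIL import Image

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    out: dict[str, list[Sample]] = {}
    for i, row in df.iterrows():
        img = np.asarray(Image.open(root / row["image_path"]).convert("L"))
        text = str(row.get("label_text", "") or "")
        if not text.strip() and not pd.isna(row.get("mu_months")):
            text = f"{float(row['mu_months'])} months"
        split = str(row.get("split", "train") or "train")
        out.setdefault(split, []).append(
            Sample(image=img, label_text=text, key=int(i))
        )
    return out


class BranchModels:
    """The per-branch heads; one shared model by default."""

    def __init__(self, rng: np.random.Generator, shared: bool = True):
        self.shared = shared
        if shared:
            m = CAMModel(rng)
            self.raw = self.hand = self.part = m
        else:
            self.raw, self.hand, self.part = (CAMModel(rng) for _ in range(3))

    @property
    def unique(self) -> list[CAMModel]:
        return [self.raw] if self.shared else [self.raw, self.hand, self.part]

    @property
    def params(self):
        out = []
        for m in self.unique:
            out.extend(m.params)
        return out

    def zero_grad(self):
        for m in self.unique:
            m.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, m in zip(("raw", "hand", "part"), self.unique):
            for k, v in m.state_arrays().items():
                out[f"{prefix}.{k}"] = v
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for prefix, m in zip(("raw", "hand", "part"), self.unique):
            sub = {k.split(".", 1)[1]: v for k, v in arrays.items()
                   if k.startswith(prefix + ".")}
            m.load_state(sub)


def letterbox(image: np.ndarray, size: int) -> np.ndarray:
    """Resize preserving aspect ratio onto a centered zero-padded square."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    s = size / max(h, w)
    nh, nw = max(1, round(h * s)), max(1, round(w * s))
    resized = resize_bilinear(image, (nh, nw))
    canvas = np.zeros((size, size))
    oy, ox = (size - nh) // 2, (size - nw) // 2
    canvas[oy:oy + nh, ox:ox + nw] = resized
    return canvas


def _cam_channel(out: HeadOutputs, cam: str) -> np.ndarray:
    if cam == "argmax":
        return out.activation[:, :, int(np.argmax(out.probs))]
    if cam == "soft":
        return out.activation @ out.probs
    raise ValueError(f"unknown cam mode {cam!r}")


def _hand_box(raw_out: HeadOutputs, config: TrainingConfig
              ) -> tuple[RoIBox, bool]:
    """Hand localization: threshold the CAM, box the largest component, lift to image frame.

    Returns (box in the letterboxed-image frame, fallback flag); an empty or
    degenerate mask falls back to the full image.
    """
    channel = _cam_channel(raw_out, config.cam)
    full = RoIBox(0, 0, config.input_size, config.input_size,
                  frame="source-image")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = make_mask(channel, config.tau)
    box = mask_to_box(mask)
    if box is None:
        return full, True
    map_hw = channel.shape
    return activation_to_image_box(
        box, map_hw, (config.input_size, config.input_size)), False


def _part_regions(hand_out: HeadOutputs, config: TrainingConfig
                  ) -> list[ScoredRegion]:
    """Part proposal on the hand branch activation; boxes lifted to hand-image frame."""
    channel = _cam_channel(hand_out, config.cam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regions, _ = propose_parts(
            channel, eta=config.eta, n_parts=config.n_parts,
            iou_threshold=config.nms_iou, frame=config.proposal_frame,
            cfg=config.anchor_config,
        )
    s = config.input_size / config.proposal_frame
    lifted = []
    for r in regions:
        box = r.box.scaled(s, s, frame="source-image").clipped(
            config.input_size, config.input_size)
        lifted.append(ScoredRegion(box=box, score=r.score))
    return lifted


@dataclass
class ForwardResult:
    """Everything one multibranch pass produces."""

    raw: HeadOutputs
    hand: HeadOutputs
    parts: list[HeadOutputs]
    hand_box: RoIBox
    hand_fallback: bool
    part_regions: list[ScoredRegion]
    raw_image: np.ndarray
    hand_image: np.ndarray
    part_images: list[np.ndarray]


def forward_multibranch(image: np.ndarray, models: BranchModels,
                        config: TrainingConfig) -> ForwardResult:
    """Run all three branches on one image (inference path, no gradients)."""
    raw_img = letterbox(np.asarray(image, dtype=float) / 255.0,
                        config.input_size)
    raw_out = models.raw.forward(raw_img)
    box, fallback = _hand_box(raw_out, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hand_img = crop_and_resize(raw_img, box,
                                   (config.input_size, config.input_size))
    hand_out = models.hand.forward(hand_img)
    regions = _part_regions(hand_out, config)
    part_imgs = []
    part_outs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in regions:
            pimg = crop_and_resize(hand_img, r.box,
                                   (config.part_size, config.part_size))
            part_imgs.append(pimg)
            part_outs.append(models.part.forward(pimg))
    return ForwardResult(
        raw=raw_out, hand=hand_out, parts=part_outs,
        hand_box=box, hand_fallback=fallback, part_regions=regions,
        raw_image=raw_img, hand_image=hand_img, part_images=part_imgs,
    )


def predict(image: np.ndarray, models: BranchModels,
            config: TrainingConfig, full: bool = False):
    """Test-time prediction: the hand branch (Branch 2) is the output.

    The raw branch runs only to localise the hand; part proposals are not
    consulted.  Returns months, or ``(months, distribution, hand_box)`` when
    ``full=True``.
    """
    raw_img = letterbox(np.asarray(image, dtype=float) / 255.0,
                        config.input_size)
    raw_out = models.raw.forward(raw_img)
    box, _ = _hand_box(raw_out, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hand_img = crop_and_resize(raw_img, box,
                                   (config.input_size, config.input_size))
    hand_out = models.hand.forward(hand_img)
    months = decode_age(hand_out.probs, readout=config.readout)
    if full:
        return months, hand_out.probs, box
    return months


@dataclass
class EvalReport:
    """MAE in months plus accuracy within +/- k months thresholds."""

    mae_months: float
    accuracies: dict[int, float]  # threshold months -> percent
    n: int

    @property
    def acc6(self) -> float:
        return self.accuracies[6]

    @property
    def acc12(self) -> float:
        return self.accuracies[12]

    @property
    def acc24(self) -> float:
        return self.accuracies[24]


def evaluate(predictions, truths, thresholds=(6, 12, 24)) -> EvalReport:
    """MAE = mean |y - yhat|; acc_k = % of |error| <= k (boundary inclusive)."""
    preds = np.asarray(predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    if preds.shape != true.shape or preds.ndim != 1 or preds.size == 0:
        raise ValueError("predictions and truths must be equal-length 1-D, n >= 1")
    err = np.abs(preds - true)
    accs = {int(k): float(100.0 * np.mean(err <= k)) for k in thresholds}
    return EvalReport(mae_months=float(err.mean()), accuracies=accs,
                      n=int(preds.size))


def _encode_targets(samples: list[Sample], sigma: float
                    ) -> tuple[list[Sample], np.ndarray, int]:
    """Parse + encode labels; unparseable rows are dropped and counted."""
    kept, targets = [], []
    n_skipped = 0
    for s in samples:
        try:
            mu = label_to_mu(parse_report_label(s.label_text))
            targets.append(make_distribution(mu, sigma).probs)
            kept.append(s)
        except (LabelParseError, ValueError):
            n_skipped += 1
    if not kept:
        raise ValueError("no sample had a parseable label; aborting")
    return kept, np.array(targets), n_skipped


def _dprobs(y: np.ndarray, p: np.ndarray, ybar: np.ndarray | None,
            t_weight: float) -> np.ndarray:
    """d(KL + L1 + T * temporal)/d p for one sample."""
    pc = np.clip(p, _EPS, None)
    g = -y / pc + np.sign(p - y)
    if ybar is not None and t_weight > 0 and ybar.sum() > 0:
        g = g - t_weight * ybar / pc
    return g


@dataclass
class TrainResult:
    models: BranchModels
    config: TrainingConfig
    log: pd.DataFrame
    best_epoch: int
    best_val_mae: float | None
    n_label_skipped: int


def _run_epoch(models, optimizer, samples, targets, ybar_raw, ybar_hand,
               t_weight, config, epoch, order):
    """One training epoch; returns per-branch mean losses and epoch predictions."""
    n = len(samples)
    preds_raw = np.zeros((n, N_BINS))
    preds_hand = np.zeros((n, N_BINS))
    # "fit" tracks the KL + L1 part alone: the composite loss also carries the
    # ramped consistency weight, so only the fit term is comparable across epochs
    sums = {"raw": 0.0, "hand": 0.0, "parts": 0.0, "fit": 0.0}
    fallbacks = 0
    for start in range(0, n, config.batch_size):
        batch = order[start:start + config.batch_size]
        for idx in batch:
            s = samples[idx]
            y = targets[idx]
            raw_img = letterbox(np.asarray(s.image, dtype=float) / 255.0,
                                config.input_size)
            # Branch 1 — forward, loss, immediate backward (conv caches are
            # single-slot, so each branch backprops before the next forward)
            raw_out = models.raw.forward(raw_img)
            ybar_r = ybar_raw[idx]
            fit_r = objectives.branch_loss(y, raw_out.probs,
                                           use_ensembling=False)
            sums["raw"] += objectives.branch_loss(
                y, raw_out.probs, ybar_r, t_weight, use_ensembling=True)
            sums["fit"] += fit_r
            models.raw.backward(raw_out, _dprobs(y, raw_out.probs, ybar_r,
                                                 t_weight))
            preds_raw[idx] = raw_out.probs
            box, fb = _hand_box(raw_out, config)
            fallbacks += fb
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hand_img = crop_and_resize(
                    raw_img, box, (config.input_size, config.input_size))
            # Branch 2
            hand_out = models.hand.forward(hand_img)
            ybar_h = ybar_hand[idx]
            sums["hand"] += objectives.branch_loss(
                y, hand_out.probs, ybar_h, t_weight, use_ensembling=True)
            sums["fit"] += objectives.branch_loss(y, hand_out.probs,
                                                  use_ensembling=False)
            models.hand.backward(hand_out, _dprobs(y, hand_out.probs, ybar_h,
                                                   t_weight))
            preds_hand[idx] = hand_out.probs
            # Branch 3 — same image-level target on every part, loss averaged
            regions = _part_regions(hand_out, config)
            if regions:
                part_loss = 0.0
                for r in regions:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pimg = crop_and_resize(
                            hand_img, r.box,
                            (config.part_size, config.part_size))
                    part_out = models.part.forward(pimg)
                    part_loss += objectives.branch_loss(
                        y, part_out.probs, use_ensembling=False)
                    models.part.backward(
                        part_out,
                        _dprobs(y, part_out.probs, None, 0.0) / len(regions))
                sums["parts"] += part_loss / len(regions)
                sums["fit"] += part_loss / len(regions)
        optimizer.step(epoch=epoch, scale=1.0 / len(batch))
    means = {k: v / n for k, v in sums.items()}
    return means, preds_raw, preds_hand, fallbacks


def train(
    train_samples: list[Sample],
    config: TrainingConfig,
    val_samples: list[Sample] | None = None,
    out_dir: str | Path | None = None,
    resume_from: "Checkpoint | None" = None,
    stop_after: int | None = None,
) -> TrainResult:
    """Train the three-branch model with momentum SGD.

    Per epoch: encode labels at ``config.sigma``, run all branches per image
    with gradient accumulation over minibatches, update the per-branch EMA
    ensembles from this epoch's predictions, and evaluate validation MAE; the
    best-validation weights are restored at the end.  All randomness (weight
    init, batch order) derives from ``config.seed``; batch order depends only
    on (seed, epoch), so resuming from a checkpoint is bit-reproducible.
    """
    samples, targets, n_skipped = _encode_targets(train_samples, config.sigma)
    n = len(samples)
    schedule = objectives.RampSchedule(t_max=config.t_max,
                                       ramp_length=config.ramp_length)

    if resume_from is not None:
        models = BranchModels(np.random.default_rng(config.seed),
                              shared=config.shared_backbone)
        models.load_state(resume_from.model_arrays)
        optimizer = MomentumSGD(models, lr=config.learning_rate,
                                momentum=config.momentum,
                                decay_every=config.lr_decay_every,
                                decay_factor=config.lr_decay_factor,
                                head_lr_mult=config.head_lr_mult)
        optimizer.load_state(resume_from.optimizer_arrays)
        ens_raw = resume_from.ensemble_raw
        ens_hand = resume_from.ensemble_hand
        start_epoch = resume_from.epoch
    else:
        rng = np.random.default_rng(config.seed)
        models = BranchModels(rng, shared=config.shared_backbone)
        optimizer = MomentumSGD(models, lr=config.learning_rate,
                                momentum=config.momentum,
                                decay_every=config.lr_decay_every,
                                decay_factor=config.lr_decay_factor,
                                head_lr_mult=config.head_lr_mult)
        ens_raw = objectives.EnsembleState(n, gamma=config.gamma)
        ens_hand = objectives.EnsembleState(n, gamma=config.gamma)
        start_epoch = 0

    best_state = None
    best_val_mae = None
    best_epoch = 0
    rows = []
    # stop_after pauses a run mid-schedule (checkpointed) without altering the
    # schedule itself, so a resumed run is bit-identical to an uninterrupted one
    last_epoch = min(config.epochs, stop_after) if stop_after else config.epochs
    for epoch in range(start_epoch + 1, last_epoch + 1):
        order = np.random.default_rng([config.seed, epoch]).permutation(n)
        t_weight = objectives.ramp_weight(epoch - 1, schedule)
        ybar_raw = ens_raw.targets()
        ybar_hand = ens_hand.targets()
        means, preds_raw, preds_hand, fallbacks = _run_epoch(
            models, optimizer, samples, targets, ybar_raw, ybar_hand,
            t_weight, config, epoch, order)
        ens_raw.update(preds_raw)
        ens_hand.update(preds_hand)

        val_mae = np.nan
        if val_samples:
            preds = [predict(s.image, models, config) for s in val_samples]
            truths = [label_to_mu(parse_report_label(s.label_text))
                      if s.true_age_months is None else s.true_age_months
                      for s in val_samples]
            val_mae = evaluate(preds, truths).mae_months
            if best_val_mae is None or val_mae < best_val_mae:
                best_val_mae = val_mae
                best_epoch = epoch
                best_state = {k: v.copy()
                              for k, v in models.state_arrays().items()}
        total = means["raw"] + means["hand"] + means["parts"]
        rows.append({
            "epoch": epoch, "L_raw": means["raw"], "L_hand": means["hand"],
            "L_parts": means["parts"], "T_t": t_weight, "L_total": total,
            "L_fit": means["fit"],
            "val_mae": val_mae, "hand_fallbacks": fallbacks,
            "lr": optimizer.lr_at(epoch),
        })
        if out_dir is not None:
            ckpt = Checkpoint.capture(models, optimizer, ens_raw, ens_hand,
                                      config, epoch)
            ckpt.save(Path(out_dir) / "last.npz")
            stamp = datetime.datetime.now().isoformat(timespec="seconds")
            with open(Path(out_dir) / "train.log", "a") as f:
                f.write(f"{stamp} epoch {epoch} L_total={total:.6f} "
                        f"val_mae={val_mae:.4f} lr={optimizer.lr_at(epoch)}\n")

    if best_state is not None:
        models.load_state(best_state)
    else:
        best_epoch = config.epochs
    log = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log.to_csv(out_dir / "losses.csv", index=False)
        (out_dir / "config.yaml").write_text(config.to_yaml())
        Checkpoint.capture(models, optimizer, ens_raw, ens_hand, config,
                           config.epochs).save(out_dir / "best.npz")
    return TrainResult(models=models, config=config, log=log,
                       best_epoch=best_epoch, best_val_mae=best_val_mae,
                       n_label_skipped=n_skipped)


@dataclass
class Checkpoint:
    """Serializable training state: weights, optimizer, ensembles, config."""

    model_arrays: dict[str, np.ndarray]
    optimizer_arrays: dict[str, np.ndarray]
    ensemble_raw: objectives.EnsembleState
    ensemble_hand: objectives.EnsembleState
    config: TrainingConfig
    epoch: int

    @classmethod
    def capture(cls, models, optimizer, ens_raw, ens_hand, config, epoch):
        return cls(
            model_arrays={k: v.copy() for k, v in models.state_arrays().items()},
            optimizer_arrays={k: v.copy()
                              for k, v in optimizer.state_arrays().items()},
            ensemble_raw=copy.deepcopy(ens_raw),
            ensemble_hand=copy.deepcopy(ens_hand),
            config=config,
            epoch=epoch,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"model/{k}": v for k, v in self.model_arrays.items()}
        arrays |= {f"opt/{k}": v for k, v in self.optimizer_arrays.items()}
        arrays["ens_raw/assembled"] = self.ensemble_raw.assembled
        arrays["ens_hand/assembled"] = self.ensemble_hand.assembled
        meta = {
            "config": asdict(self.config),
            "epoch": self.epoch,
            "ens_raw": {"epoch": self.ensemble_raw.epoch,
                        "gamma": self.ensemble_raw.gamma},
            "ens_hand": {"epoch": self.ensemble_hand.epoch,
                         "gamma": self.ensemble_hand.gamma},
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            config = TrainingConfig(**meta["config"])
            model_arrays = {k[len("model/"):]: data[k] for k in data.files
                            if k.startswith("model/")}
            opt_arrays = {k[len("opt/"):]: data[k] for k in data.files
                          if k.startswith("opt/")}
            ens_raw = objectives.EnsembleState(
                n_samples=data["ens_raw/assembled"].shape[0],
                gamma=meta["ens_raw"]["gamma"],
                epoch=meta["ens_raw"]["epoch"],
                assembled=data["ens_raw/assembled"].copy(),
            )
            ens_hand = objectives.EnsembleState(
                n_samples=data["ens_hand/assembled"].shape[0],
                gamma=meta["ens_hand"]["gamma"],
                epoch=meta["ens_hand"]["epoch"],
                assembled=data["ens_hand/assembled"].copy(),
            )
        return cls(model_arrays=model_arrays, optimizer_arrays=opt_arrays,
                   ensemble_raw=ens_raw, ensemble_hand=ens_hand,
                   config=config, epoch=meta["epoch"])

    def restore_models(self) -> BranchModels:
        models = BranchModels(np.random.default_rng(self.config.seed),
                              shared=self.config.shared_backbone)
        models.load_state(self.model_arrays)
        return models


def evaluate_model(samples: list[Sample], models: BranchModels,
                   config: TrainingConfig) -> EvalReport:
    """Branch-2 predictions against true ages (or parsed label means)."""
    preds, truths = [], []
    for s in samples:
        preds.append(predict(s.image, models, config))
        if s.true_age_months is not None:
            truths.append(s.true_age_months)
        else:
            truths.append(label_to_mu(parse_report_label(s.label_text)))
    return evaluate(preds, truths)


def mean_baseline_report(train_truths, test_truths) -> EvalReport:
    """Reference: always predict the training-set mean age."""
    mean = float(np.mean(train_truths))
    preds = np.full(len(test_truths), mean)
    return evaluate(preds, test_truths)
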