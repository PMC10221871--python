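"""Deterministic phantom "radiographs" with a known bone age.

Each phantom is a bright hand rectangle on a dark noisy background.  Inside
it, two structures carry the age signal, mirroring where real skeletal
maturity is read: a "carpal" blob cluster whose blob count increases stepwise
(one blob per 24 months), and five "phalange" bars whose length grows
linearly with age.  The bar signal is fine-grained and the blob signal
coarse, so both regression and localization have something to find.  The
generator also emits ambiguous report strings of the two kinds seen in
radiology reports (a rounded point age or a one-year interval), paired with
ground-truth geometry for localization tests.

The phantoms are schematic by design — no X-ray physics, no anatomy — they
exist so that the whole pipeline is testable without any image download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .localization import RoIBox

MAX_AGE_MONTHS = 240.0
#: sampling range for generated datasets (growth signal saturates outside it)
AGE_RANGE = (24.0, 228.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines one phantom image."""

    age_months: float
    image_size: int = 128
    hand_offset: tuple[int, int] = (20, 16)  # (dx, dy) of hand top-left
    hand_frac: float = 0.62                  # hand side as fraction of image
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.age_months <= MAX_AGE_MONTHS):
            raise ValueError(f"age_months must be in (0, 240], got {self.age_months}")
        hand = int(self.image_size * self.hand_frac)
        dx, dy = self.hand_offset
        if dx < 0 or dy < 0 or dx + hand > self.image_size or dy + hand > self.image_size:
            raise ValueError("hand region must lie strictly inside the image")


@dataclass
class PhantomTruth:
    """Ground truth attached to a rendered phantom."""

    age_months: float
    hand_box: RoIBox                      # source-image frame
    part_centers: list[tuple[int, int]]   # (x, y), source-image frame
    bar_length_px: int                    # rendered phalange bar length
    carpal_blobs: int


def carpal_blob_count(age_months: float) -> int:
    """Stepwise coarse signal: one blob per started 24-month period (1..10)."""
    return int(min(10, 1 + age_months // 24))


def phalange_length_px(age_months: float, hand_px: int) -> int:
    """Linear fine signal: bar length grows from 15% to 65% of the hand height."""
    frac = 0.15 + 0.5 * age_months / MAX_AGE_MONTHS
    return max(2, int(round(frac * hand_px)))


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom; identical spec gives a bit-identical image.

    Returns an 8-bit grayscale image and the ground truth (hand box, part
    centers, rendered bar length).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = np.full((size, size), 0.08)
    img += rng.normal(0.0, 0.03, size=(size, size))  # background texture

    hand = int(size * spec.hand_frac)
    dx, dy = spec.hand_offset
    img[dy:dy + hand, dx:dx + hand] = 0.45
    hand_box = RoIBox(dx, dy, dx + hand, dy + hand, frame="source-image")

    centers: list[tuple[int, int]] = []

    # five phalange bars in the upper 2/3 of the hand
    bar_len = phalange_length_px(spec.age_months, hand)
    bar_w = max(2, hand // 16)
    gap = hand // 6
    top = dy + hand // 12
    for f in range(5):
        x0 = dx + gap // 2 + f * gap
        y1 = min(top + bar_len, dy + hand - 2)
        img[top:y1, x0:x0 + bar_w] = 0.95
        centers.append((x0 + bar_w // 2, (top + y1) // 2))

    # carpal blob cluster in the lower-left quadrant of the hand
    n_blobs = carpal_blob_count(spec.age_months)
    r = max(2, hand // 22)
    cy0 = dy + int(hand * 0.78)
    cx0 = dx + int(hand * 0.18)
    yy, xx = np.mgrid[0:size, 0:size]
    for b in range(n_blobs):
        bx = cx0 + (b % 5) * (3 * r)
        by = cy0 + (b // 5) * (3 * r)
        by = min(by, dy + hand - r - 1)
        bx = min(bx, dx + hand - r - 1)
        img[(yy - by) ** 2 + (xx - bx) ** 2 <= r * r] = 0.9
        centers.append((bx, by))

    img += rng.normal(0.0, spec.noise_sd, size=(size, size))
    img8 = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    truth = PhantomTruth(
        age_months=spec.age_months,
        hand_box=hand_box,
        part_centers=centers,
        bar_length_px=bar_len,
        carpal_blobs=n_blobs,
    )
    return img8, truth


_POINT_TEMPLATES = [
    "approximately {y} years old",
    "about {y} years old",
    "approximately {y} years",
]
_INTERVAL_TEMPLATES = [
    "{a}–{b} years old",
    "{a}-{b} years old",
    "aged between {a} and {b}",
]


def generate_report(age_months: float, style: str, seed: int = 0) -> str:
    """An ambiguous report string bracketing the age.

    ``style='point'`` rounds to whole years ("approximately 9 years old");
    ``style='interval'`` gives the enclosing one-year interval ("12-13 years
    old").  Ages under ~1.5 years fall back to month phrasing so the implied
    mean stays within 6 months of the true age.  The seed only picks among
    equivalent phrasings.
    """
    if not (0 < age_months <= MAX_AGE_MONTHS):
        raise ValueError(f"age_months must be in (0, 240], got {age_months}")
    rng = np.random.default_rng(seed)
    if style == "point":
        years = round(age_months / 12)
        if years < 1:
            return f"approximately {max(1, round(age_months))} months old"
        template = _POINT_TEMPLATES[rng.integers(len(_POINT_TEMPLATES))]
        return template.format(y=years)
    if style == "interval":
        lo = int(age_months // 12)
        if lo < 1:
            a = max(1, int(age_months) - 3)
            return f"between {a} and {a + 6} months"
        hi = min(lo + 1, 20)
        if hi == lo:
            lo -= 1
        template = _INTERVAL_TEMPLATES[rng.integers(len(_INTERVAL_TEMPLATES))]
        return template.format(a=lo, b=hi)
    raise ValueError(f"unknown report style {style!r}")


@dataclass
class PhantomSample:
    """One in-memory dataset row."""

    image: np.ndarray
    report: str
    truth: PhantomTruth
    split: str = "train"


def generate_samples(
    n: int,
    seed: int = 0,
    image_size: int = 128,
    noise_sd: float = 0.02,
) -> list[PhantomSample]:
    """Draw ``n`` phantoms with ages uniform on [24, 228] months.

    Report styles alternate point/interval; all randomness derives from
    ``seed``, so the same call returns identical samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        age = float(rng.uniform(*AGE_RANGE))
        style = "point" if i % 2 == 0 else "interval"
        sub = int(rng.integers(0, 2 ** 31 - 1))
        spec = PhantomSpec(age_months=age, image_size=image_size,
                           noise_sd=noise_sd, seed=sub)
        image, truth = generate_phantom(spec)
        report = generate_report(age, style, seed=sub)
        samples.append(PhantomSample(image=image, report=report, truth=truth))
    return samples


def assign_splits(samples: list[PhantomSample],
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> None:
    """Tag samples train/val/test in order, by cumulative fraction."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(samples)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    for i, s in enumerate(samples):
        s.split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")


def generate_dataset(
    n: int,
    seed: int,
    out_dir: str | Path,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    image_size: int = 128,
    noise_sd: float = 0.02,
) -> Path:
    """Write ``n`` phantom PNGs plus ``manifest.csv`` and ``truth.csv``.

    The manifest carries the ambiguous report string per image (columns
    ``image_path, label_text, mu_months, split``); ``truth.csv`` records the
    exact age and geometry for evaluation.  Returns the manifest path.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, seed, image_size=image_size, noise_sd=noise_sd)
    assign_splits(samples, split_fractions)

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as mf, \
            open(out_dir / "truth.csv", "w", newline="") as tf:
        mw = csv.writer(mf)
        tw = csv.writer(tf)
        mw.writerow(["image_path", "label_text", "mu_months", "split"])
        tw.writerow(["image_path", "age_months", "hand_x0", "hand_y0",
                     "hand_x1", "hand_y1", "part_centers"])
        for i, s in enumerate(samples):
            name = f"phantom_{i:04d}.png"
            Image.fromarray(s.image).save(out_dir / name)
            mw.writerow([name, s.report, "", s.split])
            b = s.truth.hand_box
            centers = ";".join(f"{x},{y}" for x, y in s.truth.part_centers)
            tw.writerow([name, f"{s.truth.age_months:.3f}",
                         b.x0, b.y0, b.x1, b.y1, centers])
    return manifest_path
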