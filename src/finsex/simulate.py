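"""Synthetic fish-image cohorts with the statistical structure of a
temperature-treatment dichromatism study.

Each synthetic fish is an ellipsoidal body plus a triangular caudal fin
rendered on a uniform light background.  Two sex cues are injected:

* **fin coloration** — the fin's Lab b* (blue–yellow) channel is drawn per
  individual around a sex-specific mean (males yellower than females),
  attenuated in temperature-treated males, and coupled to body weight in
  males only;
* **body shape** — females are rendered with a larger body-depth/length
  ratio (the "round shape" cue), giving a whole-body classifier a signal
  that survives color attenuation.

Composition happens in Lab space, so the generator's ground truth is in the
same units the color-feature extractor measures; images are stored as 8-bit
sRGB, which quantizes fin b* by a few tenths of a unit.

Default body weight and length cell means correspond to a real
treatment-by-sex design in adult zebrafish (grams and millimetres); all
defaults are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from finsex.imaging import GROUPS, SEXES, FishSample, lab_to_rgb_u8

Cell = tuple[str, str]  # (group, sex)

#: Default per-cell body-weight means in grams, (group, sex) keyed.
DEFAULT_WEIGHT_MEANS: dict[Cell, float] = {
    ("control", "M"): 0.3582,
    ("treatment", "M"): 0.3965,
    ("control", "F"): 0.4321,
    ("treatment", "F"): 0.4357,
}

#: Default per-cell total-length means in millimetres.
DEFAULT_LENGTH_MEANS: dict[Cell, float] = {
    ("control", "M"): 34.9648,
    ("treatment", "M"): 35.2450,
    ("control", "F"): 34.8316,
    ("treatment", "F"): 35.7502,
}

# Fixed rendering palette (Lab).  Only the fin b* channel varies by fish.
_BG_LAB = (88.0, 0.0, 4.0)
_BODY_LAB = (52.0, 6.0, 14.0)
_FIN_L, _FIN_A = 68.0, 4.0


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic treatment-by-sex cohort.

    Attributes
    ----------
    n_per_cell : int
        Fish per (group, sex) cell in ``balanced`` mode; in ``ratio`` mode
        each group has ``2 * n_per_cell`` fish with sex drawn per the
        configured male probabilities.
    image_size : (int, int)
        Image height and width in pixels (each >= 64).
    fin_fraction : float
        Caudal-fin length as a fraction of body length.
    yellow_mean_male, yellow_mean_female : float
        Mean fin b* yellowness per sex (Lab b* units).
    treatment_male_attenuation : float
        Subtractive b* shift applied to treated males' fin yellowness.
    size_color_slope_male : float
        Change in fin b* per gram of body weight, males only; applied to the
        within-cell weight deviation so cell mean yellowness stays at its
        configured value.
    color_sd : float
        Between-individual sd of fin yellowness (Lab b* units).
    noise_sd : float
        Per-pixel Gaussian noise sd added to every Lab channel.
    weight_means, length_means : mapping (group, sex) -> mean
        Cell means for body weight (g) and total length (mm).
    weight_sd, length_sd : float
        Between-individual sds of weight and length.
    male_prob_treated, male_prob_control : float
        Male probabilities used in ``ratio`` mode.
    mode : {"balanced", "ratio"}
        Fixed per-cell counts (default, reproducible contingency tables) or
        Bernoulli sex draws.
    seed : int
        Seed for all randomness; identical configs give identical cohorts.
    """

    n_per_cell: int = 50
    image_size: tuple[int, int] = (128, 192)
    fin_fraction: float = 0.25
    yellow_mean_male: float = 32.0
    yellow_mean_female: float = 17.0
    treatment_male_attenuation: float = 12.0
    size_color_slope_male: float = 30.0
    color_sd: float = 3.0
    noise_sd: float = 5.0
    weight_means: Mapping[Cell, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_MEANS)
    )
    length_means: Mapping[Cell, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MEANS)
    )
    weight_sd: float = 0.07
    length_sd: float = 1.9
    male_prob_treated: float = 0.798
    male_prob_control: float = 0.502
    mode: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell <= 0:
            raise SimConfigError("n_per_cell must be > 0")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise SimConfigError("image_size components must be >= 64")
        if not 0.05 <= self.fin_fraction <= 0.5:
            raise SimConfigError("fin_fraction must lie in [0.05, 0.5]")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be >= 0")
        if self.color_sd < 0:
            raise SimConfigError("color_sd must be >= 0")
        if self.weight_sd < 0 or self.length_sd < 0:
            raise SimConfigError("weight_sd and length_sd must be >= 0")
        for name, p in (
            ("male_prob_treated", self.male_prob_treated),
            ("male_prob_control", self.male_prob_control),
        ):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.mode not in ("balanced", "ratio"):
            raise SimConfigError("mode must be 'balanced' or 'ratio'")
        for cell in ((g, s) for g in GROUPS for s in SEXES):
            if cell not in self.weight_means:
                raise SimConfigError(f"weight_means missing cell {cell}")
            if cell not in self.length_means:
                raise SimConfigError(f"length_means missing cell {cell}")


@dataclass
class SyntheticCohort:
    """Generated samples plus the per-sample generating truth."""

    config: SimConfig
    samples: list[FishSample]
    truth: pd.DataFrame  # id, group, true_sex, yellowness, body_weight_g, total_length_mm


def _fin_geometry(config: SimConfig) -> dict[str, float]:
    h, w = config.image_size
    cy = h / 2.0
    a_len = 0.26 * w           # body semi-axis along the fish axis
    cx = 0.40 * w
    x0 = cx + a_len            # fin base = caudal end of the body
    fin_len = config.fin_fraction * 2.0 * a_len
    hfin = 0.14 * h            # fin half-height at the base
    return {"cy": cy, "cx": cx, "a_len": a_len, "x0": x0, "fin_len": fin_len, "hfin": hfin}


def fin_roi_for(config: SimConfig) -> tuple[int, int, int, int]:
    """Interior fin rectangle (x, y, w, h) guaranteed to contain fin pixels only.

    The ROI spans the first 40% of the fin's length and +/-45% of the base
    half-height, which sits strictly inside the triangle with a margin for
    pixel discretization.
    """
    g = _fin_geometry(config)
    x_lo = int(np.ceil(g["x0"])) + 1
    x_hi = int(np.floor(g["x0"] + 0.40 * g["fin_len"]))
    half = 0.45 * g["hfin"]
    y_lo = int(np.ceil(g["cy"] - half))
    y_hi = int(np.floor(g["cy"] + half))
    if x_hi <= x_lo or y_hi <= y_lo:
        raise SimConfigError("image_size/fin_fraction give a degenerate fin ROI")
    return (x_lo, y_lo, x_hi - x_lo, y_hi - y_lo + 1)


def render_fish(
    config: SimConfig, sex: str, yellowness: float, rng: np.random.Generator
) -> np.ndarray:
    """Render one fish as an 8-bit RGB image.

    Females get a deeper (rounder) body ellipse than males; the fin triangle
    carries the individual's b* yellowness.
    """
    h, w = config.image_size
    g = _fin_geometry(config)
    depth = (0.19 if sex == "F" else 0.13) * h
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    lab = np.empty((h, w, 3), dtype=float)
    lab[..., 0], lab[..., 1], lab[..., 2] = _BG_LAB

    body = ((xx - g["cx"]) / g["a_len"]) ** 2 + ((yy - g["cy"]) / depth) ** 2 <= 1.0
    frac = (xx - g["x0"]) / g["fin_len"]
    fin = (frac >= 0.0) & (frac < 1.0) & (np.abs(yy - g["cy"]) <= g["hfin"] * (1.0 - frac))
    fin &= ~body

    for c, v in enumerate(_BODY_LAB):
        lab[..., c][body] = v
    lab[..., 0][fin] = _FIN_L
    lab[..., 1][fin] = _FIN_A
    lab[..., 2][fin] = yellowness

    if config.noise_sd > 0:
        lab += rng.normal(0.0, config.noise_sd, size=lab.shape)
    return lab_to_rgb_u8(lab)


def _cell_sizes(config: SimConfig, rng: np.random.Generator) -> dict[Cell, int]:
    if config.mode == "balanced":
        return {(g, s): config.n_per_cell for g in GROUPS for s in SEXES}
    sizes: dict[Cell, int] = {}
    for group, p in (
        ("control", config.male_prob_control),
        ("treatment", config.male_prob_treated),
    ):
        n_group = 2 * config.n_per_cell
        n_male = int(rng.binomial(n_group, p))
        sizes[(group, "M")] = n_male
        sizes[(group, "F")] = n_group - n_male
    return sizes


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a synthetic cohort: rendered images plus generating truth.

    Deterministic given ``config.seed``.  Male fin yellowness tracks the
    within-cell body-weight deviation via ``size_color_slope_male``; female
    yellowness is independent of size.  Treated males are attenuated by
    ``treatment_male_attenuation`` b* units.
    """
    rng = np.random.default_rng(config.seed)
    roi = fin_roi_for(config)
    sizes = _cell_sizes(config, rng)

    samples: list[FishSample] = []
    rows: list[dict] = []
    for group in GROUPS:
        for sex in SEXES:
            n = sizes[(group, sex)]
            if n == 0:
                continue
            w_mean = config.weight_means[(group, sex)]
            l_mean = config.length_means[(group, sex)]
            weights = np.maximum(rng.normal(w_mean, config.weight_sd, size=n), 0.05)
            lengths = np.maximum(rng.normal(l_mean, config.length_sd, size=n), 5.0)
            if sex == "M":
                base = config.yellow_mean_male
                if group == "treatment":
                    base -= config.treatment_male_attenuation
                yellow = (
                    base
                    + config.size_color_slope_male * (weights - w_mean)
                    + rng.normal(0.0, config.color_sd, size=n)
                )
            else:
                yellow = config.yellow_mean_female + rng.normal(0.0, config.color_sd, size=n)
            for i in range(n):
                sid = f"{group[0].upper()}{sex}{i:04d}"
                img = render_fish(config, sex, float(yellow[i]), rng)
                samples.append(
                    FishSample(
                        id=sid,
                        image=img,
                        group=group,
                        true_sex=sex,
                        body_weight=float(weights[i]),
                        total_length=float(lengths[i]),
                        fin_roi=roi,
                    )
                )
                rows.append(
                    {
                        "id": sid,
                        "group": group,
                        "true_sex": sex,
                        "yellowness": float(yellow[i]),
                        "body_weight_g": float(weights[i]),
                        "total_length_mm": float(lengths[i]),
                    }
                )
    truth = pd.DataFrame(rows)
    return SyntheticCohort(config=config, samples=samples, truth=truth)


def truth_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-sample generating truth: the oracle for recovery tests."""
    return cohort.truth.copy()


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write images as PNG plus a metadata CSV; returns the metadata path."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.samples:
        rel = f"images/{s.id}.png"
        Image.fromarray(s.image).save(outdir / rel)
        x, y, w, h = s.fin_roi
        rows.append(
            {
                "id": s.id,
                "image_path": rel,
                "group": s.group,
                "true_sex": s.true_sex,
                "body_weight_g": s.body_weight,
                "total_length_mm": s.total_length,
                "roi_x": x,
                "roi_y": y,
                "roi_w": w,
                "roi_h": h,
            }
        )
    meta_path = outdir / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path


def attenuated(config: SimConfig, attenuation: float) -> SimConfig:
    """Copy of ``config`` with a different treated-male attenuation."""
    return replace(config, treatment_male_attenuation=attenuation)
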