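"""Synthetic consumer panels with planted valence/arousal structure.

The generator emulates the structure of a tasting study: each of
``n_subjects`` subjects rates every one of ``n_alternatives`` products on an
emotion battery (12 non-verbal or 39 verbal items, 0-4 scale) plus overall
liking (0-100 VAS), and one week later picks exactly one product.

Ground truth is a two-factor latent model.  Per subject x product trial the
latent valence and arousal are the product's mean level plus an independent
subject-specific deviation.  Emotion items load on the two factors through a
fixed loading pattern plus item noise and are discretized back to the 0-4
support; liking is affine in valence plus noise; the choice is drawn from a
conditional logit whose true utility combines standardized liking, valence and
arousal with known slopes and alternative-specific constants.  Every
quantity the analysis pipeline estimates therefore has a known target.

Default product means are calibrated so that two products dominate the
choices (roughly 40% and 30% shares), reproducing the strongly skewed
popularity pattern typical of real product sets and exercising the
alternative-specific constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import CHOSEN, LIKING, PRODUCT, SUBJECT, EmotionPanel

__all__ = ["SynthConfig", "GroundTruth", "generate_panel", "generate_paired_panels",
           "write_panel"]

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: per-product mean valence, calibrated for a ~40/30% two-leader choice pattern
_DEFAULT_VALENCE = (-0.2, -0.85, -0.95, -0.55, 0.2, 1.45, 1.1)
_DEFAULT_AROUSAL = (0.25, -0.3, 0.1, 0.45, -0.2, 0.05, -0.35)


@dataclass
class SynthConfig:
    """Study conditions for one generated panel.

    Defaults mirror the real design: 123 subjects x 7 products, a 12-item
    non-verbal instrument, ordinal 0-4 item scores, and a choice driven mainly
    by valence with a smaller independent liking contribution and no arousal
    effect at the group level.
    """

    n_subjects: int = 123
    n_alternatives: int = 7
    n_emotions: int = 12
    loadings: np.ndarray | None = None          # (n_emotions, 2), auto if None
    product_valence: tuple[float, ...] = _DEFAULT_VALENCE
    product_arousal: tuple[float, ...] = _DEFAULT_AROUSAL
    subject_sd: float = 1.0        # SD of per-trial latent deviations
    item_noise_sd: float = 0.5     # SD of per-item measurement noise
    liking_intercept: float = 50.0
    liking_slope: float = 15.0     # VAS mm per latent-valence unit
    liking_noise_sd: float = 10.0
    beta_liking: float = 0.6       # on liking standardized by liking_slope
    beta_valence: float = 1.0
    beta_arousal: float = 0.0
    asc: tuple[float, ...] | None = None        # defaults to zeros
    discretize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        J = self.n_alternatives
        if len(self.product_valence) != J or len(self.product_arousal) != J:
            raise ValueError("product mean vectors must match n_alternatives")
        if self.asc is not None and len(self.asc) != J:
            raise ValueError("asc must match n_alternatives")
        for name in ("subject_sd", "item_noise_sd", "liking_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_emotions < 2:
            raise ValueError("need at least 2 emotion items")

    @property
    def alternatives(self) -> list[str]:
        return list(_ALPHABET[:self.n_alternatives])


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyst must estimate."""

    valence: np.ndarray       # (n_subjects, J) latent valence per trial
    arousal: np.ndarray
    liking: np.ndarray
    utility: np.ndarray
    chosen: np.ndarray        # (n_subjects,) chosen alternative index
    loadings: np.ndarray      # (n_emotions, 2)
    config: SynthConfig = field(repr=False)


def default_loadings(n_emotions: int, rng: np.random.Generator) -> np.ndarray:
    """A dichotomous valence pattern plus alternating arousal loadings.

    Half the items load positively on valence and half negatively (the
    non-verbal instrument's balanced positive/negative emotion set); arousal
    loadings alternate sign at half the magnitude.  Small deterministic
    jitter breaks exact symmetry so no two items are identical.
    """
    signs_v = np.where(np.arange(n_emotions) < (n_emotions + 1) // 2, 1.0, -1.0)
    signs_a = np.where(np.arange(n_emotions) % 2 == 0, 1.0, -1.0)
    lv = signs_v * (0.55 + 0.15 * rng.random(n_emotions))
    la = signs_a * (0.25 + 0.15 * rng.random(n_emotions))
    return np.column_stack([lv, la])


def _emotion_names(n: int) -> list[str]:
    return [f"emotion_{k + 1:02d}" for k in range(n)]


def generate_panel(config: SynthConfig,
                   reuse: GroundTruth | None = None
                   ) -> tuple[EmotionPanel, GroundTruth]:
    """Draw one panel (and its ground truth) from the latent two-factor model.

    ``reuse`` re-renders a new emotion battery (e.g. the 39-item verbal
    instrument) on top of an existing ground truth so that both instruments
    share the same latents, liking scores and choices, exactly as when one
    subject pool completes two questionnaires in one session.
    """
    rng = np.random.default_rng([int(config.seed), int(config.n_emotions)])
    n, J = config.n_subjects, config.n_alternatives

    if reuse is None:
        mu_v = np.asarray(config.product_valence, dtype=float)
        mu_a = np.asarray(config.product_arousal, dtype=float)
        valence = mu_v[None, :] + rng.normal(0.0, config.subject_sd, (n, J))
        arousal = mu_a[None, :] + rng.normal(0.0, config.subject_sd, (n, J))
        liking = (config.liking_intercept + config.liking_slope * valence
                  + rng.normal(0.0, config.liking_noise_sd, (n, J)))
        liking = np.clip(np.round(liking, 1), 0.0, 100.0)
        asc = np.zeros(J) if config.asc is None else np.asarray(config.asc, dtype=float)
        utility = (asc[None, :]
                   + config.beta_liking * (liking - config.liking_intercept)
                   / config.liking_slope
                   + config.beta_valence * valence
                   + config.beta_arousal * arousal)
        centered = utility - utility.max(axis=1, keepdims=True)
        probs = np.exp(centered)
        probs /= probs.sum(axis=1, keepdims=True)
        chosen = np.array([rng.choice(J, p=probs[i]) for i in range(n)])
    else:
        valence, arousal = reuse.valence, reuse.arousal
        liking, chosen = reuse.liking, reuse.chosen
        utility = reuse.utility
        if (n, J) != valence.shape:
            raise ValueError("config dimensions do not match the reused ground truth")

    loadings = (np.asarray(config.loadings, dtype=float) if config.loadings is not None
                else default_loadings(config.n_emotions, rng))
    if loadings.shape != (config.n_emotions, 2):
        raise ValueError("loadings must be (n_emotions, 2)")
    latents = np.stack([valence, arousal], axis=2)          # (n, J, 2)
    emotions = 2.0 + latents @ loadings.T
    if config.item_noise_sd > 0:
        emotions = emotions + rng.normal(0.0, config.item_noise_sd, emotions.shape)
    emotions = np.clip(emotions, 0.0, 4.0)
    if config.discretize:
        emotions = np.round(emotions)

    names = _emotion_names(config.n_emotions)
    alts = config.alternatives
    rows = {
        SUBJECT: np.repeat([f"S{i + 1:03d}" for i in range(n)], J),
        PRODUCT: np.tile(alts, n),
        LIKING: liking.reshape(-1),
        CHOSEN: (np.tile(np.arange(J), n) ==
                 np.repeat(chosen, J)).astype(int),
    }
    df = pd.DataFrame(rows)
    emo = pd.DataFrame(emotions.reshape(n * J, config.n_emotions), columns=names)
    panel = EmotionPanel(pd.concat([df, emo], axis=1),
                         instrument=f"synthetic_{config.n_emotions}",
                         emotion_names=names, alternatives=alts)
    truth = GroundTruth(valence=valence, arousal=arousal, liking=liking,
                        utility=utility, chosen=chosen, loadings=loadings,
                        config=config)
    return panel, truth


def generate_paired_panels(config: SynthConfig, n_emotions_second: int = 39
                           ) -> tuple[EmotionPanel, EmotionPanel, GroundTruth]:
    """One subject pool measured with two instruments sharing latents/choices."""
    first, truth = generate_panel(config)
    second_cfg = replace(config, n_emotions=n_emotions_second, loadings=None)
    second, _ = generate_panel(second_cfg, reuse=truth)
    return first, second, truth


def write_panel(panel: EmotionPanel, path: str | Path, format: str = "s2") -> Path:
    """Write a panel as a tab-delimited study file.

    ``"s2"`` includes the delayed-choice column; ``"s3"`` omits it (the verbal
    instrument's file carries no choice column in the original layout).
    """
    if format not in ("s2", "s3"):
        raise ValueError("format must be 's2' or 's3'")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [SUBJECT, PRODUCT, LIKING]
    if format == "s2":
        if not panel.has_choice:
            raise ValueError("panel has no choice flags to write in s2 format")
        cols.append(CHOSEN)
    cols += panel.emotion_names
    panel.data[cols].to_csv(path, sep="\t", index=False, float_format="%.10g",
                            lineterminator="\n")
    return path
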