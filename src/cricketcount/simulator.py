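"""Synthetic detection-stream generator with ground truth.

Generates per-frame detection streams that exhibit every statistical
structure the counting pipeline corrects for — sparse passages through a
one-dimensional duct imaged at 5 fps, a right-skewed speed distribution,
occasional two-individual co-occupancy, backward travel and mid-duct
turnarounds, per-frame detection misses, unstable layer assignment
between frames, a systematic male misclassification in the entry frames
of every female (the ovipositor is not yet in view), and random
ovipositor-occlusion flips thereafter.

Each simulated crossing carries full ground truth (identity, sex,
direction, entry frame, per-frame positions, emitted-vs-missed flags),
so every pipeline stage can be tested against a known answer without any
recorded footage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import integrate, optimize, special, stats

from .stream_model import FEMALE, MALE, DetectionRecord, InfoMatrix

__all__ = [
    "SimConfig",
    "Crossing",
    "SimTruth",
    "simulate",
    "reference_regime_config",
]


@dataclass
class SimConfig:
    """Generator parameters.

    The defaults describe the reference farm-trial acquisition: a
    1920 x 1080 px camera at 5 fps over a transparent duct, crossing
    speeds averaging 50 px/frame with a 95th percentile near 120
    px/frame ("fairly Gaussian with a slight skew toward high speeds"),
    and a colony of 534 males and 747 females (female fraction
    747/1281).  Rates the reference study does not quantify (misses,
    layer shuffling, occlusion flips, reversals) default to values that
    keep the stream in the same sparse, low-co-occupancy regime.

    The speed law is what a per-frame speed histogram of the stream shows
    (every step of every passage pooled): a skew-normal with mean
    ``speed_mean`` and between-crossing spread ``speed_sd``, truncated
    below ``speed_floor_px_per_frame`` (slower than that is lingering,
    not a passage) and recentred so the realised step mean equals
    ``speed_mean``.  Because slow crossings contribute more frames, each
    crossing's base speed is drawn length-biased (weight proportional to
    speed) from that law; on top of the base speed every frame's advance
    fluctuates with ``speed_within_sd`` (crickets speed up and slow
    down), which widens the step histogram without shortening transits.
    """

    n_frames: int = 50_000
    fps: float = 5.0
    duct_length_px: float = 1920.0
    duct_height_px: float = 1080.0
    arrival_rate: float = 0.0028  # expected crossings per frame (Poisson)
    speed_mean_px_per_frame: float = 50.0
    speed_sd_px_per_frame: float = 25.0
    speed_skew: float = 2.0
    speed_within_sd_px_per_frame: float = 30.0
    backward_fraction: float = 0.0025
    reversal_prob: float = 0.005
    female_fraction: float = 747 / 1281
    entry_male_bias_frames: int = 3
    occlusion_flip_prob: float = 0.92
    spurious_female_prob: float = 0.0005
    miss_prob: float = 0.0005
    layer_shuffle_prob: float = 0.1
    speed_floor_px_per_frame: float = 8.0
    pos_jitter_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "backward_fraction",
            "reversal_prob",
            "female_fraction",
            "occlusion_flip_prob",
            "spurious_female_prob",
            "miss_prob",
            "layer_shuffle_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if self.speed_mean_px_per_frame <= 0 or self.speed_sd_px_per_frame <= 0:
            raise ValueError("speed mean and sd must be positive")
        if self.speed_skew < 0:
            raise ValueError("speed_skew must be >= 0")
        if self.entry_male_bias_frames < 0:
            raise ValueError("entry_male_bias_frames must be >= 0")
        if not 0.0 < self.speed_floor_px_per_frame < self.speed_mean_px_per_frame:
            raise ValueError(
                "speed_floor_px_per_frame must be positive and below the mean"
            )


def reference_regime_config(n_frames: int = 457_000, seed: int = 0) -> SimConfig:
    """Preset wired to the reference acquisition's printed constants.

    5 fps, 1920 px duct view, mean speed 50 px/frame, female fraction
    747/1281, and an arrival rate of 1281 crossings per 457,000 frames.
    At these rates the co-occupancy regime is sparse: second-layer
    passages are roughly an order of magnitude rarer than first-layer
    ones.
    """
    return SimConfig(
        n_frames=n_frames,
        arrival_rate=1281 / 457_000,
        seed=seed,
    )


@dataclass
class Crossing:
    """Ground truth for one simulated duct crossing."""

    id: int
    sex: str  # 'male' | 'female'
    entry_side: str  # 'left' (forward entrant) | 'right'
    reversed_midway: bool
    outcome: str  # 'to_box2' | 'to_box1' | 'censored'
    entry_frame: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    emitted: list[bool] = field(default_factory=list)
    layers: list[int | None] = field(default_factory=list)  # None = missed/beyond

    @property
    def exit_frame(self) -> int:
        return self.frames[-1] if self.frames else self.entry_frame

    @property
    def n_emitted(self) -> int:
        return int(sum(self.emitted))

    @property
    def speed_px_per_frame(self) -> float:
        if len(self.xs) < 2:
            return 0.0
        return float(
            np.mean(np.abs(np.diff(self.xs)) / np.diff(self.frames))
        )


@dataclass
class SimTruth:
    """Ground-truth record of a simulated stream."""

    n_frames: int
    crossings: list[Crossing] = field(default_factory=list)
    occupancy: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def n_to_box2(self) -> int:
        """Crossings that completed the forward passage (manual-count total)."""
        return sum(c.outcome == "to_box2" for c in self.crossings)

    def n_to_box1(self) -> int:
        return sum(c.outcome == "to_box1" for c in self.crossings)

    def sex_counts_to_box2(self) -> tuple[int, int]:
        """(females, males) among the completed forward passages."""
        fem = sum(
            c.outcome == "to_box2" and c.sex == "female" for c in self.crossings
        )
        male = sum(
            c.outcome == "to_box2" and c.sex == "male" for c in self.crossings
        )
        return fem, male

    def total_emitted(self) -> int:
        return sum(c.n_emitted for c in self.crossings)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "n_to_box2": self.n_to_box2(),
            "n_to_box1": self.n_to_box1(),
            "sex_counts_to_box2": self.sex_counts_to_box2(),
            "crossings": [asdict(c) for c in self.crossings],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        crossings = [Crossing(**c) for c in payload["crossings"]]
        truth = cls(n_frames=payload["n_frames"], crossings=crossings)
        occ = np.zeros(truth.n_frames, dtype=np.int64)
        for c in crossings:
            for f, emitted in zip(c.frames, c.emitted):
                if emitted:
                    occ[f] += 1
        truth.occupancy = occ
        return truth


# ---------------------------------------------------------------------------
# speed law


def _skewnorm_params(
    mean: float, sd: float, skew: float, lo: float = 1.0
) -> tuple[float, float]:
    """Location/scale of a skew-normal whose ``> lo`` truncation has the
    requested mean (spread is matched on the untruncated law)."""
    if skew == 0.0:
        delta = 0.0
    else:
        delta = skew / np.sqrt(1.0 + skew * skew)
    mean_std = delta * np.sqrt(2.0 / np.pi)
    sd_std = np.sqrt(1.0 - 2.0 * delta * delta / np.pi)
    omega = sd / sd_std
    xi0 = mean - omega * mean_std

    def truncated_mean(xi: float) -> float:
        sf = stats.skewnorm.sf(lo, skew, loc=xi, scale=omega)
        if sf <= 0:
            return np.inf
        val, _ = integrate.quad(
            lambda x: x * stats.skewnorm.pdf(x, skew, loc=xi, scale=omega),
            lo,
            xi + 12 * omega,
        )
        return val / sf

    try:
        shift = optimize.brentq(
            lambda s: truncated_mean(xi0 + s) - mean, -4 * sd, 2 * sd, xtol=1e-6
        )
    except ValueError:
        shift = 0.0  # truncation negligible; no recentering needed
    return xi0 + shift, omega


def _sample_speed(
    rng: np.random.Generator,
    xi: float,
    omega: float,
    skew: float,
    lo: float = 1.0,
    length_biased: bool = True,
) -> float:
    """Draw one crossing base speed from the (truncated) skew-normal.

    With ``length_biased`` the draw is weighted proportionally to the
    speed, so that per-frame pooling over whole crossings (slow animals
    occupy more frames) reproduces the unbiased law.
    """
    cap = xi + 6.0 * omega
    for _ in range(10_000):
        s = stats.skewnorm.rvs(skew, loc=xi, scale=omega, random_state=rng)
        if s <= lo:
            continue
        if not length_biased or rng.random() < min(1.0, s / cap):
            return float(s)
    raise RuntimeError("speed sampling failed: truncation region too small")


_STEP_FLOOR = 1.0  # px/frame: a passage never stalls completely


def _within_step_sampler(base_speed: float, sd: float):
    """Per-frame step law: normal around the crossing's base speed,
    truncated at the floor and recentred so its mean is exactly the base
    speed (otherwise slow crossings would be systematically shortened
    and the pooled per-frame speed histogram biased upward).

    Returns ``draw(u)`` mapping uniforms in [0, 1) to step lengths.
    """
    if sd <= 0:
        return lambda u: base_speed

    def trunc_mean(mu: float) -> float:
        alpha = (_STEP_FLOOR - mu) / sd
        lam = np.exp(
            stats.norm.logpdf(alpha) - stats.norm.logsf(alpha)
        )  # hazard of the standard normal
        return mu + sd * lam

    mu = optimize.brentq(
        lambda m: trunc_mean(m) - base_speed,
        base_speed - 40.0 * sd,
        base_speed + sd,
        xtol=1e-9,
    )
    p_lo = special.ndtr((_STEP_FLOOR - mu) / sd)

    def draw(u: float) -> float:
        return mu + sd * special.ndtri(p_lo + u * (1.0 - p_lo))

    return draw


# ---------------------------------------------------------------------------
# main generator


def simulate(config: SimConfig) -> tuple[InfoMatrix, SimTruth]:
    """Generate a detection stream and its ground truth.

    Reproducible bit-for-bit for a fixed ``config.seed``.  Entry frames
    are placed so every crossing completes inside the stream (the
    generator emits no passages censored by the end of the recording);
    a crossing that cannot fit is marked ``censored`` and truncated.
    """
    rng = np.random.default_rng(config.seed)
    lo = config.speed_floor_px_per_frame
    xi, omega = _skewnorm_params(
        config.speed_mean_px_per_frame,
        config.speed_sd_px_per_frame,
        config.speed_skew,
        lo=lo,
    )

    n_cross = int(rng.poisson(config.arrival_rate * config.n_frames))
    truth = SimTruth(n_frames=config.n_frames)
    L = config.duct_length_px
    H = config.duct_height_px

    for cid in range(n_cross):
        sex = "female" if rng.random() < config.female_fraction else "male"
        entry_side = "right" if rng.random() < config.backward_fraction else "left"
        speed = _sample_speed(rng, xi, omega, config.speed_skew, lo=lo)
        reverses = rng.random() < config.reversal_prob
        turn_at = rng.uniform(0.25, 0.75) * L if reverses else None

        step_draw = _within_step_sampler(
            speed, config.speed_within_sd_px_per_frame
        )
        sign = 1.0 if entry_side == "left" else -1.0
        x = rng.uniform(0.0, speed) if sign > 0 else L - rng.uniform(0.0, speed)
        y = rng.uniform(0.3, 0.7) * H
        xs: list[float] = []
        ys: list[float] = []
        turned = False
        while 0.0 <= x <= L:
            xs.append(x)
            ys.append(float(np.clip(y, 0.05 * H, 0.95 * H)))
            if turn_at is not None and not turned:
                passed = x >= turn_at if sign > 0 else x <= turn_at
                if passed:
                    sign = -sign
                    turned = True
            step = step_draw(rng.random())
            x += sign * step + rng.normal(0.0, config.pos_jitter_px)
            y += rng.normal(0.0, 1.0)

        if x > L:
            outcome = "to_box2"
        elif x < 0.0:
            outcome = "to_box1"
        else:  # pragma: no cover - loop only exits out of range
            outcome = "censored"

        duration = len(xs)
        latest_entry = config.n_frames - duration
        if latest_entry <= 0:
            entry = 0
            xs = xs[: config.n_frames]
            ys = ys[: config.n_frames]
            duration = len(xs)
            outcome = "censored"
        else:
            entry = int(rng.integers(0, latest_entry))

        truth.crossings.append(
            Crossing(
                id=cid,
                sex=sex,
                entry_side=entry_side,
                reversed_midway=turned,
                outcome=outcome,
                entry_frame=entry,
                frames=list(range(entry, entry + duration)),
                xs=xs,
                ys=ys,
                emitted=[False] * duration,
                layers=[None] * duration,
            )
        )

    # --- emission: misses, layer fill, shuffle, class votes ---------------
    truth.crossings.sort(key=lambda c: (c.entry_frame, c.id))
    active_by_frame: dict[int, list[int]] = {}
    for idx, c in enumerate(truth.crossings):
        for f in c.frames:
            active_by_frame.setdefault(f, []).append(idx)

    records: dict[tuple[int, int], DetectionRecord] = {}
    occupancy = np.zeros(config.n_frames, dtype=np.int64)
    emitted_counts = [0] * len(truth.crossings)

    for f in sorted(active_by_frame):
        present = active_by_frame[f]  # already in arrival order
        emitted_idx = [
            i for i in present if rng.random() >= config.miss_prob
        ]
        if len(emitted_idx) >= 2 and rng.random() < config.layer_shuffle_prob:
            emitted_idx[0], emitted_idx[1] = emitted_idx[1], emitted_idx[0]
        occupancy[f] = len(emitted_idx)
        for layer, i in enumerate(emitted_idx, start=1):
            c = truth.crossings[i]
            j = f - c.entry_frame
            c.emitted[j] = True
            c.layers[j] = layer
            if c.sex == "female":
                if emitted_counts[i] < config.entry_male_bias_frames:
                    vote = MALE  # rear not yet in view: systematic male vote
                elif rng.random() < config.occlusion_flip_prob:
                    vote = MALE
                else:
                    vote = FEMALE
            else:
                vote = FEMALE if rng.random() < config.spurious_female_prob else MALE
            emitted_counts[i] += 1
            prob = float(rng.beta(20.0, 2.0))
            records[(f, layer)] = DetectionRecord(
                frame=f,
                layer=layer,
                sex_class=vote,
                prob=prob,
                cx=float(c.xs[j]),
                cy=float(c.ys[j]),
            )

    truth.occupancy = occupancy
    if config.n_frames and (occupancy > 4).sum() > 0.001 * config.n_frames:
        warnings.warn(
            "arrival rate yields occupancy above 4 in more than 0.1% of "
            "frames; the duct regime is meant to be sparse",
            stacklevel=2,
        )

    matrix = InfoMatrix(
        n_frames=config.n_frames,
        fps=config.fps,
        frame_width=config.duct_length_px,
        frame_height=config.duct_height_px,
        records=records,
    )
    return matrix, truth
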