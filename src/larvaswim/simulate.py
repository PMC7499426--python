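"""Synthetic larval-zebrafish locomotion generator.

Simulates cohorts of 5-dpf larvae with clutch structure and genotype
effects, and produces per-frame tail-angle/head-position traces for two
assays:

* **slow-swim sessions** — 5 min at 100 Hz of spontaneous beat-and-glide
  locomotion: a renewal train of discrete bouts, each either a forward
  swim (max |bend| < 25 deg) or a routine turn (max |bend| > 25 deg);
* **escape trials** — 1 s at 650 Hz with an acousto-vestibular stimulus
  at 200 ms, answered (with some probability) by a short-latency C-start:
  a large first bend, an opposite counter bend, then a decaying tail-beat
  train.

Every injected event is recorded in a ground-truth table so downstream
detection, classification and aggregation can be validated bout by bout.

Calibration
-----------
The default parameter sets (:data:`SLOW_DEFAULTS`, :data:`ESCAPE_DEFAULTS`)
reproduce published group means for wild-type and somatostatin-knockout
5-dpf larvae (bout rate ~0.9-0.95 Hz, forward-swim distance 0.48-0.56 mm,
escape C-bend ~100 deg, escape latency ~5.4 ms, ...).  Between-fish
coefficients of variation are calibrated from the published SEMs
(SD = SEM * sqrt(n)).  Two deliberate choices keep the cohort-level
expectation pinned at the configured group mean:

* fish- and clutch-level offsets are *normal* (clipped at a small positive
  floor), not log-normal, so that E[latent] equals the group mean exactly;
* clutch offsets are shared by the two genotypes of a clutch (each clutch
  is one incross, so mutant and wild-type siblings share the clutch
  environment) and centred to zero mean across clutches, so the finite
  number of clutches does not shift the cohort mean while the
  clutch-correlated structure needed by the mixed model is preserved.

Within a fish, per-bout draws are log-normal anchored on the *median*
(slow swim, where fish are summarised by medians) or on the *mean*
(escape trials, where fish are summarised by means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ConfigError, GenerationError

__all__ = [
    "SlowSwimParams",
    "EscapeParams",
    "CohortConfig",
    "SLOW_DEFAULTS",
    "ESCAPE_DEFAULTS",
    "FISH_CV",
    "generate_cohort",
    "simulate_slow_session",
    "simulate_escape_trial",
    "iter_slow_sessions",
    "iter_escape_trials",
    "latents_to_summaries",
    "LATENT_TO_SUMMARY",
]

# classifier cutoff the generator keeps a margin around (degrees)
FORWARD_TURN_CUTOFF = 25.0
#: forward-swim max-bend range and turn first-bend range (degrees); the
#: gap [22, 28] keeps the 25-degree classifier unambiguous on ground truth
FORWARD_MAX_BEND_RANGE = (5.0, 22.0)
TURN_FIRST_BEND_RANGE = (28.0, 90.0)
#: smallest injected bend (degrees)
MIN_BEND = 1.6
#: refractory glide between bouts (s); real beat-and-glide glides are longer
MIN_GAP_S = 0.15
#: slow-regime bouts travel at most a couple of mm (also keeps the fish
#: head renderable inside the 15-mm well together with the wall steering)
MAX_SLOW_DISTANCE_MM = 2.0

TAIL_NOISE_SD_DEG = 0.5
POSITION_NOISE_SD_MM = 0.01

WELL_DIAMETER_MM = 15.0
#: steer back toward the centre when the head gets this close to the wall:
#: body length (3.2 mm) + max slow-bout travel (2 mm) + slack, so the whole
#: silhouette stays renderable inside the well (wall thigmotaxis is not
#: modelled)
HEAD_STEER_MARGIN_MM = 5.5


@dataclass(frozen=True)
class SlowSwimParams:
    """Group-level slow-swim kinematics (one instance per genotype).

    Per-bout distance is not drawn directly: the generator draws bout
    duration and speed and takes distance = duration * speed, which keeps
    the three published means mutually consistent at the cohort level.
    """

    bout_rate: float = 0.95           # bouts/s over the session
    p_forward: float = 0.75           # probability a bout is a forward swim
    forward_duration_mean: float = 0.27   # s
    forward_speed_mean: float = 1.78      # mm/s
    forward_median_bend_mean: float = 2.57  # deg, per-bout median |bend|
    forward_max_bend_mean: float = 10.0     # deg, first (largest) bend scale
    turn_duration_mean: float = 0.386
    turn_speed_mean: float = 3.86
    turn_median_bend_mean: float = 4.60
    turn_first_bend_mean: float = 40.0
    tbf_mean: float = 11.75           # Hz, tail-beat frequency
    forward_n_osc_mean: float = 3.38  # oscillations, fish-level latent
    turn_n_osc_mean: float = 5.12

    def validate(self) -> None:
        if self.bout_rate <= 0:
            raise ConfigError("bout_rate must be > 0")
        if not 0.0 <= self.p_forward <= 1.0:
            raise ConfigError("p_forward must be in [0, 1]")
        if not self.turn_first_bend_mean > FORWARD_TURN_CUTOFF:
            raise ConfigError("turn_first_bend_mean must exceed 25 degrees")
        if not self.forward_max_bend_mean < FORWARD_TURN_CUTOFF:
            raise ConfigError("forward_max_bend_mean must stay below 25 degrees")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "p_forward" and v <= 0:
                raise ConfigError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class EscapeParams:
    """Group-level escape (C-start) kinematics.

    Escape bout duration is derived as n_osc / TBF and speed as
    distance / duration; the published per-fish means of duration and
    speed are not independent anchors (means of ratios do not multiply).
    """

    latency_mean: float = 5.34        # ms after the stimulus
    cbend_mean: float = 100.2         # deg, first (largest) bend
    counterbend_mean: float = 45.15   # deg, second bend, opposite sign
    tbf_mean: float = 37.45           # Hz
    distance_mean: float = 8.73       # mm path length
    n_osc_mean: float = 8.22          # oscillations
    response_prob: float = 0.9        # probability a trial shows an escape

    def validate(self) -> None:
        if not self.latency_mean < 30.0:
            raise ConfigError("latency_mean must be below the 30 ms selection rule")
        if not self.cbend_mean > 60.0:
            raise ConfigError("cbend_mean must exceed the 60-degree selection rule")
        if not 0.0 < self.counterbend_mean < self.cbend_mean:
            raise ConfigError("counterbend_mean must be positive and below cbend_mean")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ConfigError("response_prob must be in [0, 1]")
        for name in ("tbf_mean", "distance_mean", "n_osc_mean", "latency_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


#: defaults per genotype, calibrated to published group means
SLOW_DEFAULTS: dict[str, SlowSwimParams] = {
    "wt": SlowSwimParams(),
    "mut": SlowSwimParams(
        bout_rate=0.91,
        p_forward=0.7534,
        forward_duration_mean=0.2857,
        forward_speed_mean=1.96,
        forward_median_bend_mean=2.88,
        turn_duration_mean=0.4067,
        turn_speed_mean=3.86,
        turn_median_bend_mean=4.87,
        turn_n_osc_mean=5.42,
    ),
}

ESCAPE_DEFAULTS: dict[str, EscapeParams] = {
    "wt": EscapeParams(),
    "mut": EscapeParams(
        latency_mean=5.45,
        cbend_mean=100.6,
        counterbend_mean=46.51,
        tbf_mean=37.56,
        distance_mean=9.12,
        n_osc_mean=8.27,
    ),
}

#: between-fish coefficient of variation per latent parameter,
#: calibrated from published SEMs (SD = SEM * sqrt(n))
FISH_CV: dict[str, float] = {
    "bout_rate": 0.335,
    "fwd_duration": 0.113,
    "fwd_speed": 0.233,
    "fwd_median_bend": 0.265,
    "fwd_max_bend": 0.20,
    "fwd_nosc": 0.154,
    "fwd_tbf": 0.059,
    "turn_duration": 0.20,
    "turn_speed": 0.099,
    "turn_median_bend": 0.219,
    "turn_first_bend": 0.12,
    "turn_nosc": 0.225,
    "turn_tbf": 0.052,
    "esc_latency": 0.269,
    "esc_cbend": 0.069,
    "esc_counterbend": 0.187,
    "esc_tbf": 0.151,
    "esc_distance": 0.161,
    "esc_nosc": 0.189,
}

# mapping latent column -> (params attribute, which param set)
_SLOW_LATENTS = {
    "bout_rate": "bout_rate",
    "fwd_duration": "forward_duration_mean",
    "fwd_speed": "forward_speed_mean",
    "fwd_median_bend": "forward_median_bend_mean",
    "fwd_max_bend": "forward_max_bend_mean",
    "fwd_nosc": "forward_n_osc_mean",
    "fwd_tbf": "tbf_mean",
    "turn_duration": "turn_duration_mean",
    "turn_speed": "turn_speed_mean",
    "turn_median_bend": "turn_median_bend_mean",
    "turn_first_bend": "turn_first_bend_mean",
    "turn_nosc": "turn_n_osc_mean",
    "turn_tbf": "tbf_mean",
}
_ESCAPE_LATENTS = {
    "esc_latency": "latency_mean",
    "esc_cbend": "cbend_mean",
    "esc_counterbend": "counterbend_mean",
    "esc_tbf": "tbf_mean",
    "esc_distance": "distance_mean",
    "esc_nosc": "n_osc_mean",
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout and hierarchical dispersion.

    ``clutch_sd_scale`` / ``fish_sd_scale`` multiply the calibrated
    per-parameter standard deviations (clutch SD = 0.3 * total between-fish
    SD by default, fish SD the complementary share); setting both to zero
    gives every fish of a genotype identical latent parameters.
    """

    n_clutches: int = 4
    fish_per_clutch_per_genotype: int = 15
    genotype_labels: tuple[str, str] = ("wt", "mut")
    clutch_sd_scale: float = 1.0
    fish_sd_scale: float = 1.0
    #: "clutch" centres the clutch offsets within each genotype (default),
    #: "full" additionally centres the fish offsets so the realised cohort
    #: mean equals the configured group mean exactly (calibration runs),
    #: "none" draws everything i.i.d. (inference simulations, e.g. type-I
    #: error, where honest sampling noise between groups is required)
    centering: str = "clutch"
    seed: int = 0
    slow: dict[str, SlowSwimParams] = field(default_factory=lambda: dict(SLOW_DEFAULTS))
    escape: dict[str, EscapeParams] = field(default_factory=lambda: dict(ESCAPE_DEFAULTS))

    #: share of the between-fish SD attributed to the clutch level
    CLUTCH_SHARE = 0.3

    def validate(self) -> None:
        if self.n_clutches < 1 or self.fish_per_clutch_per_genotype < 1:
            raise ConfigError("counts must be >= 1")
        if self.clutch_sd_scale < 0 or self.fish_sd_scale < 0:
            raise ConfigError("dispersion scales must be >= 0")
        if len(self.genotype_labels) != 2:
            raise ConfigError("exactly two genotype labels are required")
        if self.centering not in ("none", "clutch", "full"):
            raise ConfigError("centering must be 'none', 'clutch' or 'full'")
        for g in self.genotype_labels:
            if g not in self.slow or g not in self.escape:
                raise ConfigError(f"no parameter set for genotype {g!r}")
            self.slow[g].validate()
            self.escape[g].validate()


def _latent_means(slow: SlowSwimParams, escape: EscapeParams) -> dict[str, float]:
    means = {col: getattr(slow, attr) for col, attr in _SLOW_LATENTS.items()}
    means.update({col: getattr(escape, attr) for col, attr in _ESCAPE_LATENTS.items()})
    return means


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort of fish with per-fish latent kinematic parameters.

    Returns one row per fish: ``fish_id``, ``clutch``, ``genotype``, the
    latent columns of :data:`FISH_CV` plus the derived ``fwd_distance``,
    ``turn_distance``, ``esc_duration``, ``esc_speed`` and ``p_forward``.
    Latent = genotype mean + centred clutch offset + fish offset,
    reproducible from ``config.seed`` alone.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2001]))
    rows = []
    n_c, n_f = config.n_clutches, config.fish_per_clutch_per_genotype
    fish_share = math.sqrt(1.0 - config.CLUTCH_SHARE**2)
    # clutch offsets are shared by both genotypes of a clutch: a clutch is
    # one incross, so its wild-type and mutant siblings share the
    # clutch-level environment
    pooled = {
        col: 0.5 * (getattr(config.slow[config.genotype_labels[0]], attr)
                    + getattr(config.slow[config.genotype_labels[1]], attr))
        for col, attr in _SLOW_LATENTS.items()
    }
    pooled.update({
        col: 0.5 * (getattr(config.escape[config.genotype_labels[0]], attr)
                    + getattr(config.escape[config.genotype_labels[1]], attr))
        for col, attr in _ESCAPE_LATENTS.items()
    })
    clutch_off = {}
    for col, cv in FISH_CV.items():
        sd_c = config.CLUTCH_SHARE * cv * pooled[col] * config.clutch_sd_scale
        off = rng.normal(0.0, sd_c, size=n_c) if sd_c > 0 else np.zeros(n_c)
        if config.centering in ("clutch", "full") and n_c > 1:
            off = off - off.mean()
        clutch_off[col] = off
    for genotype in config.genotype_labels:
        means = _latent_means(config.slow[genotype], config.escape[genotype])
        fish_off = {}
        for col, cv in FISH_CV.items():
            sd_f = fish_share * cv * means[col] * config.fish_sd_scale
            f_off = (rng.normal(0.0, sd_f, size=n_c * n_f) if sd_f > 0
                     else np.zeros(n_c * n_f))
            if config.centering == "full" and n_c * n_f > 1:
                f_off = f_off - f_off.mean()
            fish_off[col] = f_off
        for c in range(n_c):
            for k in range(n_f):
                row = {
                    "fish_id": f"{genotype}_c{c}_f{k}",
                    "clutch": f"clutch{c}",
                    "genotype": genotype,
                }
                for col in FISH_CV:
                    val = (means[col] + clutch_off[col][c]
                           + fish_off[col][c * n_f + k])
                    row[col] = max(val, 0.05 * means[col])
                # spontaneous slow-swim rates above ~1.5 Hz would leave no
                # room for glides between bouts
                row["bout_rate"] = float(np.clip(row["bout_rate"], 0.12, 1.5))
                # p_forward: mild fish-level jitter around the group value
                p = config.slow[genotype].p_forward
                jitter = rng.normal(0.0, 0.05 * config.fish_sd_scale)
                row["p_forward"] = float(np.clip(p + jitter, 0.05, 0.98))
                rows.append(row)
    cohort = pd.DataFrame(rows)
    cohort["fwd_distance"] = cohort["fwd_duration"] * cohort["fwd_speed"]
    cohort["turn_distance"] = cohort["turn_duration"] * cohort["turn_speed"]
    cohort["esc_duration"] = cohort["esc_nosc"] / cohort["esc_tbf"]
    cohort["esc_speed"] = cohort["esc_distance"] / cohort["esc_duration"]
    return cohort


# ---------------------------------------------------------------------------
# waveform construction


#: |bend| spacing (degrees) around the median bend; comparable to the
#: sensor-noise scale so the *noisy* sample median stays centred on the
#: injected median (tightly clustered magnitudes would bias the sample
#: median toward the top of the cluster)
_BEND_STEP = 0.6


def _bend_magnitudes(n_bends: int, max_bend: float, median_bend: float) -> np.ndarray:
    """Decreasing |bend| sequence whose sample median equals
    ``median_bend``.

    The first bend is the largest (``max_bend``).  For an even count the
    two middle elements sit symmetrically at median +-
    :data:`_BEND_STEP`/2, so their average — the sample median — equals
    the target exactly and stays centred under additive sensor noise (a
    one-sided cluster of magnitudes would bias the *measured* median
    upward).  For an odd count the middle element is the target itself.
    Magnitudes are floored at :data:`MIN_BEND`; the upper part decays
    geometrically from the max, the lower part in :data:`_BEND_STEP`
    decrements.
    """
    if n_bends == 1:
        return np.array([max_bend])
    m = max(min(median_bend, 0.9 * max_bend), MIN_BEND + 0.1)
    if n_bends == 2:
        return np.array([max_bend, m])
    even = n_bends % 2 == 0
    mid = n_bends // 2 - 1 if even else (n_bends - 1) // 2
    mags = np.empty(n_bends)
    if even:
        delta = _BEND_STEP / 2.0
        mags[mid] = m + delta
        mags[mid + 1] = max(MIN_BEND, m - delta)
        # keep the pair average on target even when the floor binds
        mags[mid] = 2 * m - mags[mid + 1]
        first_low = mid + 2
    else:
        mags[mid] = m
        first_low = mid + 1
    for i in range(first_low, n_bends):
        mags[i] = max(MIN_BEND, mags[first_low - 1] - _BEND_STEP * (i - first_low + 1))
    hi = min(mags[mid] + _BEND_STEP, 0.95 * max_bend)
    for j in range(mid):
        mags[j] = max_bend * (hi / max_bend) ** (j / mid) if mid > 1 else max_bend
    # keep the sequence decreasing down to the middle
    for j in range(mid, 0, -1):
        if mags[j - 1] <= mags[j]:
            mags[j - 1] = mags[j] + 0.15
    return mags


def _bout_waveform(n_frames: int, bends: np.ndarray) -> np.ndarray:
    """Tail-angle samples of one bout over ``n_frames + 1`` frames.

    Alternating-sign lobes: zero at the lobe boundaries, the signed peak
    at the lobe centre, PCHIP-interpolated so peaks fall exactly on frame
    samples and are never overshot.
    """
    n_bends = len(bends)
    edges = np.round(np.linspace(0, n_frames, n_bends + 1)).astype(int)
    knots_t, knots_v = [], []
    for j in range(n_bends):
        peak = (edges[j] + edges[j + 1]) // 2
        if peak <= edges[j]:
            peak = edges[j] + 1
        knots_t += [edges[j], peak]
        knots_v += [0.0, bends[j]]
    knots_t.append(n_frames)
    knots_v.append(0.0)
    knots_t = np.array(knots_t, dtype=float)
    knots_v = np.array(knots_v, dtype=float)
    keep = np.concatenate([[True], np.diff(knots_t) > 0])
    interp = PchipInterpolator(knots_t[keep], knots_v[keep])
    return interp(np.arange(n_frames + 1, dtype=float))


def _lognormal_median(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float) -> float:
    return float(mean * np.exp(rng.normal(-0.5 * sigma**2, sigma)))


# ---------------------------------------------------------------------------
# slow-swim sessions

_GT_COLUMNS = [
    "bout_index", "category", "onset_frame", "offset_frame", "onset_s",
    "duration_s", "distance_mm", "speed_mm_s", "n_osc", "tbf_hz",
    "max_bend_deg", "median_bend_deg", "first_bend_deg", "heading_delta_deg",
]

# per-bout (within-fish) log-normal sigmas
_BOUT_SIGMA = {"duration": 0.35, "speed": 0.30, "median_bend": 0.35,
               "max_bend": 0.30, "tbf": 0.10}
_TURN_GAIN = 0.6  # deg heading change per deg of first bend


def _draw_bout(fish, rng, category: str, rate: float):
    """Draw one slow-swim bout's true parameters for a fish."""
    pre = "fwd" if category == "forward" else "turn"
    dur = _lognormal_median(rng, fish[f"{pre}_duration"], _BOUT_SIGMA["duration"])
    dur = float(np.clip(dur, 0.08, 1.5))
    speed = _lognormal_median(rng, fish[f"{pre}_speed"], _BOUT_SIGMA["speed"])
    n_frames = max(6, int(round(dur * rate)))
    dur = n_frames / rate
    m = _lognormal_median(rng, fish[f"{pre}_median_bend"], _BOUT_SIGMA["median_bend"])
    if category == "forward":
        m = float(np.clip(m, MIN_BEND + 0.1, 20.0))
        a = _lognormal_median(rng, fish["fwd_max_bend"], _BOUT_SIGMA["max_bend"])
        lo = max(FORWARD_MAX_BEND_RANGE[0], 1.25 * m + 0.5)
        a = float(np.clip(a, lo, FORWARD_MAX_BEND_RANGE[1]))
        m = min(m, 0.9 * a)
    else:
        m = float(np.clip(m, MIN_BEND + 0.1, 15.0))
        a = float(np.clip(rng.normal(fish["turn_first_bend"], 6.0),
                          *TURN_FIRST_BEND_RANGE))
    tbf = _lognormal_median(rng, fish["fwd_tbf"], _BOUT_SIGMA["tbf"])
    n_osc = int(np.clip(round(tbf * dur), 1, max(1, n_frames // 6)))
    n_bends = 2 * n_osc
    mags = _bend_magnitudes(n_bends, a, m)
    distance = min(speed * dur, MAX_SLOW_DISTANCE_MM)
    signs = rng.choice([-1.0, 1.0]) * (-1.0) ** np.arange(n_bends)
    return dur, n_frames, distance, mags * signs, n_osc


def simulate_slow_session(
    fish,
    duration_s: float = 300.0,
    rate: float = 100.0,
    rng: np.random.Generator | int | None = None,
    tail_noise_sd: float = TAIL_NOISE_SD_DEG,
    position_noise_sd: float = POSITION_NOISE_SD_MM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one spontaneous slow-swim session for one fish.

    Parameters
    ----------
    fish
        A cohort row (mapping) with the latent columns of
        :func:`generate_cohort`.
    duration_s, rate
        Recording length (default 5 min) and sampling rate (default 100 Hz).
    rng
        :class:`numpy.random.Generator`, seed, or None.

    Returns
    -------
    (trace, ground_truth)
        ``trace`` has the standard per-frame columns; ``ground_truth`` one
        row per injected bout with its true kinematics.
    """
    if duration_s <= 0 or rate <= 0:
        raise GenerationError("duration_s and rate must be > 0")
    rng = np.random.default_rng(rng)
    n_frames = int(round(duration_s * rate))
    tail = np.zeros(n_frames)
    x = np.zeros(n_frames)
    y = np.zeros(n_frames)
    heading = np.zeros(n_frames)

    p_fwd = float(fish["p_forward"])
    # per-bout durations are log-normal anchored on the median, so the
    # mean bout length carries an exp(sigma^2/2) factor
    mean_bout = (p_fwd * fish["fwd_duration"]
                 + (1 - p_fwd) * fish["turn_duration"])
    mean_bout *= math.exp(0.5 * _BOUT_SIGMA["duration"] ** 2)
    gap_mean = 1.0 / fish["bout_rate"] - mean_bout
    if gap_mean <= MIN_GAP_S + 0.05:
        raise GenerationError(
            f"bout rate {fish['bout_rate']:.2f} Hz leaves no room for glides "
            f"between bouts of mean duration {mean_bout:.2f} s"
        )

    pos = np.zeros(2)
    head = rng.uniform(0.0, 360.0)
    frame = 0
    gt_rows = []
    well_r = WELL_DIAMETER_MM / 2.0
    while True:
        gap = MIN_GAP_S + rng.gamma(2.0, (gap_mean - MIN_GAP_S) / 2.0)
        onset = frame + max(3, int(round(gap * rate)))
        category = "forward" if rng.random() < p_fwd else "turn"
        dur, nf, distance, bends, n_osc = _draw_bout(fish, rng, category, rate)
        if onset + nf >= n_frames:
            break
        # steer back toward the well centre when close to the wall
        if np.hypot(*pos) > well_r - HEAD_STEER_MARGIN_MM:
            head = math.degrees(math.atan2(-pos[1], -pos[0])) + rng.uniform(-30, 30)
        tail[onset:onset + nf + 1] = _bout_waveform(nf, bends)
        x[frame:onset + 1] = pos[0]
        y[frame:onset + 1] = pos[1]
        direction = np.array([math.cos(math.radians(head)),
                              math.sin(math.radians(head))])
        steps = pos + np.outer(np.arange(1, nf + 1) * (distance / nf), direction)
        x[onset + 1:onset + nf + 1] = steps[:, 0]
        y[onset + 1:onset + nf + 1] = steps[:, 1]
        heading[frame:onset + nf] = head
        pos = steps[-1]
        delta = 0.0
        if category == "turn":
            delta = _TURN_GAIN * bends[0]
            head = (head + delta) % 360.0
        gt_rows.append({
            "bout_index": len(gt_rows), "category": category,
            "onset_frame": onset, "offset_frame": onset + nf,
            "onset_s": onset / rate, "duration_s": nf / rate,
            "distance_mm": distance, "speed_mm_s": distance / (nf / rate),
            "n_osc": n_osc, "tbf_hz": n_osc / (nf / rate),
            "max_bend_deg": float(np.abs(bends).max()),
            "median_bend_deg": float(np.median(np.abs(bends))),
            "first_bend_deg": float(bends[0]), "heading_delta_deg": delta,
        })
        frame = onset + nf
    x[frame:] = pos[0]
    y[frame:] = pos[1]
    heading[frame:] = head

    if tail_noise_sd > 0:
        tail += rng.normal(0.0, tail_noise_sd, n_frames)
    if position_noise_sd > 0:
        x += rng.normal(0.0, position_noise_sd, n_frames)
        y += rng.normal(0.0, position_noise_sd, n_frames)
    trace = pd.DataFrame({
        "frame_index": np.arange(n_frames),
        "time_s": np.arange(n_frames) / rate,
        "x_mm": x, "y_mm": y,
        "heading_deg": heading % 360.0,
        "tail_angle_deg": tail,
    })
    gt = pd.DataFrame(gt_rows, columns=_GT_COLUMNS)
    return trace, gt


# ---------------------------------------------------------------------------
# escape trials

_ESC_GT_COLUMNS = _GT_COLUMNS + ["responded", "latency_ms",
                                 "cbend_deg", "counterbend_deg"]
_ESC_SIGMA = {"latency": 0.25, "tbf": 0.08, "distance": 0.10}


def simulate_escape_trial(
    fish,
    trial_len: float = 1.0,
    stim_time: float = 0.2,
    rate: float = 650.0,
    rng: np.random.Generator | int | None = None,
    tail_noise_sd: float = TAIL_NOISE_SD_DEG,
    position_noise_sd: float = POSITION_NOISE_SD_MM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one acousto-vestibular escape trial.

    The trace is quiescent until ``stim_time`` plus the drawn latency,
    then shows a C-start: largest first bend, opposite-sign counter bend,
    and a geometrically decaying tail-beat train at the escape TBF.  The
    ground-truth table has exactly one row (``responded`` False for the
    trials without an escape, drawn with probability
    ``1 - response_prob``).
    """
    rng = np.random.default_rng(rng)
    n_frames = int(round(trial_len * rate))
    stim_frame = int(round(stim_time * rate))
    tail = np.zeros(n_frames)
    x = np.zeros(n_frames)
    y = np.zeros(n_frames)
    head = rng.uniform(0.0, 360.0)

    responded = rng.random() < float(fish.get("esc_response_prob", 0.9))
    gt = {c: np.nan for c in _ESC_GT_COLUMNS}
    gt.update({"bout_index": 0, "responded": responded, "category": "escape",
               "heading_delta_deg": 0.0})
    if responded:
        latency = _lognormal_mean(rng, fish["esc_latency"], _ESC_SIGMA["latency"])
        latency = float(np.clip(latency, 1.0, 29.0))
        tbf = _lognormal_mean(rng, fish["esc_tbf"], _ESC_SIGMA["tbf"])
        n_osc = int(np.clip(round(rng.normal(fish["esc_nosc"], 0.8)), 2, 20))
        dur = n_osc / tbf
        nf = int(round(dur * rate))
        distance = _lognormal_mean(rng, fish["esc_distance"], _ESC_SIGMA["distance"])
        cbend = float(np.clip(rng.normal(fish["esc_cbend"], 4.0), 61.0, 179.0))
        counter = float(np.clip(rng.normal(fish["esc_counterbend"], 5.0),
                                10.0, 0.95 * cbend))
        onset = stim_frame + max(1, int(round(latency * rate / 1000.0)))
        if onset + nf >= n_frames:
            raise GenerationError("escape bout does not fit in the trial window")
        n_bends = 2 * n_osc
        mags = np.empty(n_bends)
        mags[0], mags[1] = cbend, counter
        lo = max(5.0, 0.1 * counter)
        for j in range(2, n_bends):
            mags[j] = counter * (lo / counter) ** ((j - 1) / (n_bends - 2))
        sign = rng.choice([-1.0, 1.0])
        bends = mags * sign * (-1.0) ** np.arange(n_bends)
        tail[onset:onset + nf + 1] = _bout_waveform(nf, bends)
        direction = np.array([math.cos(math.radians(head)),
                              math.sin(math.radians(head))])
        steps = np.outer(np.arange(1, nf + 1) * (distance / nf), direction)
        x[onset + 1:onset + nf + 1] = steps[:, 0]
        y[onset + 1:onset + nf + 1] = steps[:, 1]
        x[onset + nf + 1:] = steps[-1, 0]
        y[onset + nf + 1:] = steps[-1, 1]
        gt.update({
            "onset_frame": onset, "offset_frame": onset + nf,
            "onset_s": onset / rate, "duration_s": nf / rate,
            "distance_mm": distance, "speed_mm_s": distance / (nf / rate),
            "n_osc": n_osc, "tbf_hz": n_osc / (nf / rate),
            "max_bend_deg": cbend, "median_bend_deg": float(np.median(mags)),
            "first_bend_deg": float(bends[0]),
            "latency_ms": (onset - stim_frame) / rate * 1000.0,
            "cbend_deg": cbend, "counterbend_deg": counter,
        })

    if tail_noise_sd > 0:
        tail += rng.normal(0.0, tail_noise_sd, n_frames)
    if position_noise_sd > 0:
        x += rng.normal(0.0, position_noise_sd, n_frames)
        y += rng.normal(0.0, position_noise_sd, n_frames)
    trace = pd.DataFrame({
        "frame_index": np.arange(n_frames),
        "time_s": np.arange(n_frames) / rate,
        "x_mm": x, "y_mm": y,
        "heading_deg": np.full(n_frames, head % 360.0),
        "tail_angle_deg": tail,
    })
    return trace, pd.DataFrame([gt], columns=_ESC_GT_COLUMNS)


# ---------------------------------------------------------------------------
# cohort-level convenience iterators


def iter_slow_sessions(cohort: pd.DataFrame, duration_s: float = 300.0,
                       rate: float = 100.0, seed: int = 0, **noise):
    """Yield ``(fish_row, trace, ground_truth)`` per fish, one independent
    child RNG stream each (reproducible from ``seed``)."""
    ss = np.random.SeedSequence([seed, 3001]).spawn(len(cohort))
    for child, (_, fish) in zip(ss, cohort.iterrows()):
        trace, gt = simulate_slow_session(fish, duration_s, rate,
                                          np.random.default_rng(child), **noise)
        yield fish, trace, gt


#: latent column -> fish-summary column produced by the full pipeline
LATENT_TO_SUMMARY = {
    "bout_rate": "bout_rate_hz",
    "fwd_distance": "fwd_distance_mm", "fwd_duration": "fwd_duration_s",
    "fwd_speed": "fwd_speed_mm_s", "fwd_median_bend": "fwd_median_bend_deg",
    "fwd_nosc": "fwd_n_osc", "fwd_tbf": "fwd_tbf_hz",
    "turn_distance": "turn_distance_mm", "turn_duration": "turn_duration_s",
    "turn_speed": "turn_speed_mm_s", "turn_median_bend": "turn_median_bend_deg",
    "turn_nosc": "turn_n_osc", "turn_tbf": "turn_tbf_hz",
    "esc_distance": "esc_distance_mm", "esc_duration": "esc_duration_s",
    "esc_speed": "esc_speed_mm_s", "esc_nosc": "esc_n_osc",
    "esc_tbf": "esc_tbf_hz", "esc_latency": "esc_latency_ms",
    "esc_cbend": "esc_cbend_deg", "esc_counterbend": "esc_counterbend_deg",
}


def latents_to_summaries(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-fish summary table built directly from the cohort latents.

    With hundreds of bouts per fish the pipeline's per-fish medians (and
    escape means) concentrate on the latent values, so inference-level
    simulations (type-I error, power) can skip trace synthesis and work
    on the latents directly.
    """
    out = cohort[["fish_id", "clutch", "genotype"]].copy()
    for latent, summary in LATENT_TO_SUMMARY.items():
        out[summary] = cohort[latent].to_numpy()
    out["qc_pass"] = True
    return out


def iter_escape_trials(cohort: pd.DataFrame, n_trials: int = 10,
                       trial_len: float = 1.0, stim_time: float = 0.2,
                       rate: float = 650.0, seed: int = 0):
    """Yield ``(fish_row, trial_index, trace, ground_truth)`` per trial."""
    ss = np.random.SeedSequence([seed, 4001]).spawn(len(cohort))
    for child, (_, fish) in zip(ss, cohort.iterrows()):
        rng = np.random.default_rng(child)
        for t in range(n_trials):
            trace, gt = simulate_escape_trial(fish, trial_len, stim_time, rate, rng)
            yield fish, t, trace, gt
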