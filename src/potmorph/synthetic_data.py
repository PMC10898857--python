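"""Seeded synthetic morphogenesis datasets.

The generator emulates the structure of the cross-cultural wheel-throwing
study: 3 communities of practice (PR, MK, FR) with 9/6/6 potters, 5 trials
per potter per vessel type, 8 vessel types (cylinder / bowl / sphere / vase
at 0.75 and 2.25 kg of clay), each trial an ordered sequence of half-profile
outlines from preform to final form.

Shapes live in a 4-D latent space (log aspect ratio, linear taper, mid-height
belly, rim flare) mapped to a 6-control-point radius-vs-height profile.  A
trial's morphogenetic path interpolates from a community-specific preform
template to the vessel-type final template along a potter-specific monotone
schedule, with a mid-path waypoint perturbation encoding the community's
style of change (e.g. the tall-barrel overshoot vs the flat-disk start).
Hierarchical Gaussian effects act on the latent coordinates: community-level
offsets on the final shape, potter-level offsets constant across trials,
trial-level noise, plus independent measurement noise on the rendered
profile x-coordinates.  A stage schedule scales potter/trial variability
from the preform (wider) to the final form (narrower), reproducing the
narrowing range of variation along morphogenesis.

All randomness flows from one seed through per-potter / per-trial
``numpy.random.SeedSequence`` substreams, so any subset is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConfigError
from .profile_io import (CalibratedProfile, Outline, TrialRecord,
                         close_outline, smooth_profile)

__all__ = ["GeneratorConfig", "ShapeTemplate", "generate_study",
           "generate_null", "ground_truth"]

LATENT_NAMES = ("log_aspect", "taper", "belly", "flare")
COMMUNITY_NAMES = ("PR", "MK", "FR")

# final-shape latent templates per vessel form (aspect ratios follow the
# study's descriptive means; taper/belly/flare sketch the silhouettes)
FINAL_LATENTS = {
    "cylinder": np.array([np.log(1.90), 0.00, 0.00, 0.00]),
    "bowl":     np.array([np.log(0.37), 1.00, 0.00, 0.20]),
    "sphere":   np.array([np.log(0.80), 0.00, 0.55, -0.10]),
    "vase":     np.array([np.log(0.65), -0.15, 0.70, 0.25]),
}

# community preform templates: PR tall barrel, FR flat disk, MK intermediate
PREFORM_LATENTS = {
    "PR": np.array([np.log(1.50), -0.10, 0.15, 0.00]),
    "MK": np.array([np.log(0.85), 0.00, 0.30, 0.10]),
    "FR": np.array([np.log(0.28), 0.15, 0.00, 0.00]),
}

# community mid-path waypoints (style of change): PR overshoots in height
# before shortening; FR passes through a wide-bottomed phase; MK is gradual
COMMUNITY_WAYPOINTS = {
    "PR": np.array([0.22, 0.00, -0.05, 0.00]),
    "MK": np.array([0.00, 0.00, 0.00, 0.00]),
    "FR": np.array([-0.08, -0.15, 0.00, 0.00]),
}

SIZE_BY_MASS = {0.75: 14.0, 2.25: 20.0}          # cm size scale per clay mass
DURATION_BY_MASS = {0.75: 100.0, 2.25: 160.0}    # s, community-modulated
DURATION_FACTOR = {"PR": 1.2, "MK": 0.65, "FR": 1.0}

DEFAULT_VESSEL_TYPES = tuple(
    (shape, mass) for shape in ("cylinder", "bowl", "sphere", "vase")
    for mass in (0.75, 2.25)
)


@dataclass
class GeneratorConfig:
    """Study-design and effect-scale parameters of the generator.

    Effect scales are in latent shape units (the latent coordinates are
    O(0.3-1.7)); measurement noise is in cm on profile x-coordinates.  The
    stage schedule (preform multiplier, final multiplier) scales potter- and
    trial-level variability along the path, decreasing by default.
    """

    n_communities: int = 3
    potters_per_community: tuple = (9, 6, 6)
    trials_per_potter: int = 5
    gestures_range: tuple = (6, 14)
    vessel_types: tuple = DEFAULT_VESSEL_TYPES
    sigma_community: float = 0.10
    sigma_potter: float = 0.05
    sigma_trial: float = 0.02
    sigma_measurement: float = 0.02
    stage_schedule: tuple = (1.6, 0.6)
    n_profile_points: int = 256
    smooth_cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 1 or self.n_communities > len(COMMUNITY_NAMES):
            raise ConfigError("n_communities must be between 1 and 3")
        if len(self.potters_per_community) != self.n_communities:
            raise ConfigError("potters_per_community length must equal n_communities")
        if min(self.potters_per_community) < 1 or self.trials_per_potter < 1:
            raise ConfigError("counts must be >= 1")
        if self.gestures_range[0] < 2 or self.gestures_range[1] < self.gestures_range[0]:
            raise ConfigError("gestures_range must be (lo >= 2, hi >= lo)")
        for s in (self.sigma_community, self.sigma_potter, self.sigma_trial,
                  self.sigma_measurement):
            if s < 0:
                raise ConfigError("effect scales must be >= 0")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")

    @property
    def communities(self) -> tuple:
        return COMMUNITY_NAMES[: self.n_communities]


@dataclass
class ShapeTemplate:
    """Radius-vs-height profile: 6 control points at strictly increasing
    height fractions, relative radii, and absolute height / diameter scales."""

    heights: np.ndarray
    radii: np.ndarray
    height_scale: float
    diameter_scale: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, float)
        self.radii = np.asarray(self.radii, float)
        if len(self.heights) != 6 or len(self.radii) != 6:
            raise ConfigError("a shape template has exactly 6 control points")
        if np.any(np.diff(self.heights) <= 0):
            raise ConfigError("control heights must be strictly increasing")
        if np.any(self.radii <= 0):
            raise ConfigError("control radii must be positive")

    def radius_at(self, h: np.ndarray) -> np.ndarray:
        """Radius (cm) at height fraction h, including the on-axis pinch at
        both ends that closes the silhouette."""
        r = PchipInterpolator(self.heights, self.radii)(h)
        pinch = (1.0 - np.exp(-h / 0.035)) * (1.0 - np.exp(-(1.0 - h) / 0.035))
        return (self.diameter_scale / 2.0) * r * pinch

    def nominal_dimensions(self, n: int = 2048) -> tuple[float, float]:
        """(height, max diameter) of the ideal (noise-free) silhouette."""
        h = np.linspace(0.0, 1.0, n)
        return self.height_scale, float(2.0 * self.radius_at(h).max())


_BUMP_CENTER, _BUMP_WIDTH = 0.45, 0.28


def template_from_latent(theta: np.ndarray, size: float) -> ShapeTemplate:
    """Map a latent shape vector to a control-point template.

    aspect = exp(log_aspect) = height / diameter; the size scale fixes
    absolute dimensions (height = size * aspect^(2/3),
    diameter = size * aspect^(-1/3))."""
    la, taper, belly, flare = np.asarray(theta, float)
    a = np.exp(la)
    h = np.linspace(0.0, 1.0, 6)
    f = (1.0
         + taper * (h - 0.5)
         + belly * np.exp(-(((h - _BUMP_CENTER) / _BUMP_WIDTH) ** 2))
         + flare * np.maximum(0.0, (h - 0.7) / 0.3))
    f = np.maximum(f, 0.15)
    return ShapeTemplate(heights=h, radii=f,
                         height_scale=size * a ** (2.0 / 3.0),
                         diameter_scale=size * a ** (-1.0 / 3.0))


def _render_outline(theta, size, cfg: GeneratorConfig, rng,
                    gesture_index: int, elapsed_time: float) -> Outline:
    tmpl = template_from_latent(theta, size)
    n = cfg.n_profile_points
    h = np.linspace(0.0, 1.0, n)
    x = tmpl.radius_at(h)
    if cfg.sigma_measurement > 0:
        x = x + rng.normal(0.0, cfg.sigma_measurement, size=n)
    x = np.maximum(x, 0.0)
    x[0] = x[-1] = 0.0
    y = h * tmpl.height_scale
    prof = CalibratedProfile(points=np.column_stack([x, y]))
    if cfg.smooth_cutoff is not None:
        prof = smooth_profile(prof, cfg.smooth_cutoff)
        pts = prof.points.copy()
        pts[0, 0] = pts[-1, 0] = 0.0
        pts[:, 0] = np.maximum(pts[:, 0], 0.0)
        prof = CalibratedProfile(points=pts)
    return close_outline(prof, gesture_index=gesture_index,
                         elapsed_time=elapsed_time)


def _draw_effects(cfg: GeneratorConfig) -> dict:
    """All community- and potter-level random effects, drawn deterministically
    from the config seed.  Trial-level noise comes from per-trial substreams
    derived from the same root (see :func:`generate_study`)."""
    root = np.random.SeedSequence(cfg.seed)
    eff_seq, _ = root.spawn(2)
    rng = np.random.default_rng(eff_seq)
    ledger: dict = {"seed": cfg.seed, "community_final_offsets": {},
                    "potters": {}}
    shapes = sorted({shape for shape, _ in cfg.vessel_types})
    for c in cfg.communities:
        for shape in shapes:
            ledger["community_final_offsets"][(c, shape)] = rng.normal(
                0.0, cfg.sigma_community, size=4)
    for ci, c in enumerate(cfg.communities):
        for pi in range(cfg.potters_per_community[ci]):
            pid = f"{c}{pi + 1}"
            ledger["potters"][pid] = {
                "community": c,
                "preform_offset": rng.normal(0.0, cfg.sigma_potter, size=4),
                "final_offset": rng.normal(0.0, cfg.sigma_potter, size=4),
                "waypoint": rng.normal(0.0, cfg.sigma_potter, size=4),
                "schedule_gamma": float(np.exp(rng.normal(0.0, 0.2))),
                "duration_factor": float(np.exp(rng.normal(0.0, 0.15))),
            }
    return ledger


def _null_mask(ledger: dict, cfg: GeneratorConfig, null: str | None) -> dict:
    """Apply a null hypothesis to a drawn-effects ledger.

    ``"community"`` removes every community-level difference (offsets zeroed,
    shared mean preform template and waypoint), making potters exchangeable
    across communities; ``"potter"`` removes potter-level effects;
    ``"both"`` removes both."""
    if null is None:
        return ledger
    if null not in ("community", "potter", "both"):
        raise ConfigError(f"unknown null mode {null!r}")
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in ledger.items()}
    out["null"] = null
    if null in ("community", "both"):
        out["community_final_offsets"] = {
            k: np.zeros(4) for k in ledger["community_final_offsets"]}
        mean_pre = np.mean([PREFORM_LATENTS[c] for c in cfg.communities], axis=0)
        mean_way = np.mean([COMMUNITY_WAYPOINTS[c] for c in cfg.communities], axis=0)
        out["shared_preform"] = mean_pre
        out["shared_waypoint"] = mean_way
        out["shared_duration_factor"] = float(
            np.mean([DURATION_FACTOR[c] for c in cfg.communities]))
    if null in ("potter", "both"):
        out["potters"] = {
            pid: {**eff, "preform_offset": np.zeros(4),
                  "final_offset": np.zeros(4), "waypoint": np.zeros(4),
                  "schedule_gamma": 1.0, "duration_factor": 1.0}
            for pid, eff in ledger["potters"].items()}
    return out


def _generate(cfg: GeneratorConfig, ledger: dict) -> list[TrialRecord]:
    root = np.random.SeedSequence(cfg.seed)
    _, trial_seq = root.spawn(2)
    s0, s1 = cfg.stage_schedule
    trials: list[TrialRecord] = []
    potter_ids = sorted(ledger["potters"], key=lambda p: (
        ledger["potters"][p]["community"], p))
    n_types = len(cfg.vessel_types)
    streams = iter(trial_seq.spawn(len(potter_ids) * n_types * cfg.trials_per_potter))

    for pid in potter_ids:
        eff = ledger["potters"][pid]
        c = eff["community"]
        theta_pre_base = ledger.get("shared_preform", PREFORM_LATENTS[c])
        way_comm = ledger.get("shared_waypoint", COMMUNITY_WAYPOINTS[c])
        dur_comm = ledger.get("shared_duration_factor", DURATION_FACTOR[c])
        for shape, mass in cfg.vessel_types:
            theta_fin_base = (FINAL_LATENTS[shape]
                              + ledger["community_final_offsets"][(c, shape)])
            size = SIZE_BY_MASS.get(mass, 14.0 + 2.7 * mass)
            for trial_no in range(1, cfg.trials_per_potter + 1):
                rng = np.random.default_rng(next(streams))
                m = int(rng.integers(cfg.gestures_range[0],
                                     cfg.gestures_range[1] + 1))
                d_pre_t = rng.normal(0.0, cfg.sigma_trial, size=4)
                d_fin_t = rng.normal(0.0, cfg.sigma_trial, size=4)
                way_t = rng.normal(0.0, cfg.sigma_trial, size=4)
                duration = (DURATION_BY_MASS.get(mass, 120.0) * dur_comm
                            * eff["duration_factor"]
                            * float(np.exp(rng.normal(0.0, 0.1))))
                inc = rng.gamma(2.0, 1.0, size=m - 1)
                times = np.concatenate([[0.0], np.cumsum(inc)])
                times = times / times[-1] * duration
                s_path = (np.arange(m) / (m - 1)) ** eff["schedule_gamma"]

                theta_pre = (theta_pre_base
                             + s0 * (eff["preform_offset"] + d_pre_t))
                theta_fin = (theta_fin_base
                             + s1 * (eff["final_offset"] + d_fin_t))
                waypoint = way_comm + eff["waypoint"] + way_t

                outlines = []
                for k, s in enumerate(s_path):
                    theta = ((1.0 - s) * theta_pre + s * theta_fin
                             + np.sin(np.pi * s) * waypoint)
                    outlines.append(_render_outline(
                        theta, size, cfg, rng, gesture_index=k,
                        elapsed_time=float(times[k])))
                trials.append(TrialRecord(
                    potter_id=pid, community=c, vessel_type=shape,
                    clay_mass_kg=float(mass), trial_number=trial_no,
                    outlines=outlines))
    return trials


def generate_study(config: GeneratorConfig) -> list[TrialRecord]:
    """The full hierarchical synthetic study, reproducible from the seed."""
    return _generate(config, _draw_effects(config))


def generate_null(config: GeneratorConfig, mode: str = "community") -> list[TrialRecord]:
    """A null-hypothesis dataset: ``mode="community"`` removes all
    community-level structure (for community-test calibration),
    ``"potter"`` removes potter-level structure, ``"both"`` removes both."""
    return _generate(config, _null_mask(_draw_effects(config), config, mode))


def ground_truth(config: GeneratorConfig, mode: str | None = None) -> dict:
    """The exact community/potter effects and schedules behind a dataset."""
    return _null_mask(_draw_effects(config), config, mode)
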