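import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from potmorph.efa import coefficient_vector
from potmorph.profile_io import CalibratedProfile, Outline, close_outline
from potmorph.synthetic_data import (GeneratorConfig, generate_study,
                                     template_from_latent)


def circle_outline(r: float = 2.0, cy: float = 5.0, n: int = 4096) -> Outline:
    """Circle centered on the symmetry axis, traversed clockwise from the
    on-axis top point."""
    th = np.linspace(0.0, 2.0 * np.pi, n + 1)
    x = r * np.sin(th)
    y = cy + r * np.cos(th)
    x[-1], y[-1] = x[0], y[0]
    return Outline(points=np.column_stack([x, y]))


def ellipse_outline(a: float, b: float, cy: float = 5.0, n: int = 4096) -> Outline:
    """Axis-aligned ellipse (horizontal semi-axis a, vertical b) sampled at
    equal trigonometric parameter steps."""
    th = np.linspace(0.0, 2.0 * np.pi, n + 1)
    x = a * np.sin(th)
    y = cy + b * np.cos(th)
    x[-1], y[-1] = x[0], y[0]
    return Outline(points=np.column_stack([x, y]))


def random_vessel_outline(rng: np.random.Generator, n: int = 256) -> Outline:
    """A noise-free vessel outline with random latent shape parameters drawn
    from the generator's plausible range."""
    theta = np.array([
        rng.uniform(np.log(0.3), np.log(1.9)),   # log aspect
        rng.uniform(-0.3, 0.8),                  # taper
        rng.uniform(-0.2, 0.7),                  # belly
        rng.uniform(-0.2, 0.3),                  # flare
    ])
    tmpl = template_from_latent(theta, size=rng.uniform(12.0, 22.0))
    h = np.linspace(0.0, 1.0, n)
    x = tmpl.radius_at(h)
    x[0] = x[-1] = 0.0
    prof = CalibratedProfile(points=np.column_stack([x, h * tmpl.height_scale]))
    return close_outline(prof)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240227)


@pytest.fixture(scope="session")
def small_study():
    """A reduced hierarchical study reused across test modules: 3 communities
    x (3, 2, 2) potters x 3 trials of one vessel type."""
    cfg = GeneratorConfig(potters_per_community=(3, 2, 2), trials_per_potter=3,
                          gestures_range=(5, 8), vessel_types=(("vase", 2.25),),
                          seed=42)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_study_coeffs(small_study):
    """Per-trial (n_outlines x 60) coefficient matrices for the small study."""
    return {t.key: np.vstack([coefficient_vector(o).values for o in t.outlines])
            for t in small_study}
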