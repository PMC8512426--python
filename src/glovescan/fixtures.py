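"""Standard synthetic study fixtures.

These fix the simulated scanning conditions used throughout the test
suite and the reproduction script, so every quality number the package
reports refers to a well-defined scene:

* **sphere fixture** — R = 100 mm sphere, 20 000 samples, 50% transit
  lifted 10-100 mm, noise-free, one central reference, 5 deg selection
  grid.  The exactness benchmark: noise-free filtering must recover the
  surface to numerical precision.
* **cylinder fixture** — R = 35 mm, h = 200 mm capped cylinder (the
  7 cm x 20 cm test object), 10 000 samples, 50% transit, noise-free,
  axial references.  Used for the selectivity ladder and the
  multi-reference comparison.
* **noisy-foot fixture** — composite foot-like shape, 30 000 samples,
  50% transit, per-axis noise reproducing the tracker's 1.4 mm RMS,
  1% gross outliers at 200 mm, references near the bridge of the foot
  and the ankle, 4 deg selection grid.  The realism benchmark.
"""

from __future__ import annotations

from .filtering import FilterConfig
from .simulator import (
    SENSOR_SIGMA_PER_AXIS_MM,
    RigidMotion,
    SurfaceModel,
    TraceConfig,
    plant_reference_points,
)

#: Angular-size ladder used for selectivity curves (degrees).
SELECTIVITY_LADDER = (0.25, 1.0, 3.0, 5.0, 8.0)


def sphere_fixture(seed: int = 0, n_samples: int = 20_000):
    model = SurfaceModel("sphere", {"radius": 100.0})
    cfg = TraceConfig(
        n_samples=n_samples,
        fraction_transit=0.5,
        lift_range=(10.0, 100.0),
        noise_sigma=0.0,
        seed=seed,
    )
    refs = plant_reference_points(model, 1)
    return model, cfg, refs, FilterConfig(fine_angular_size=5.0)


def cylinder_fixture(seed: int = 0, n_samples: int = 10_000, noise_sigma: float = 0.0):
    model = SurfaceModel("capped_cylinder", {"radius": 35.0, "height": 200.0})
    cfg = TraceConfig(
        n_samples=n_samples,
        fraction_transit=0.5,
        lift_range=(10.0, 100.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    refs = plant_reference_points(model, 2)
    return model, cfg, refs, FilterConfig(fine_angular_size=5.0)


def foot_fixture(seed: int = 0, n_samples: int = 30_000):
    model = SurfaceModel("foot_like")
    cfg = TraceConfig(
        n_samples=n_samples,
        fraction_transit=0.5,
        lift_range=(10.0, 100.0),
        noise_sigma=SENSOR_SIGMA_PER_AXIS_MM,
        gross_outlier_rate=0.01,
        gross_outlier_magnitude=200.0,
        seed=seed,
    )
    refs = plant_reference_points(model, 2)  # bridge of the foot + ankle
    return model, cfg, refs, FilterConfig(fine_angular_size=4.0)


def standard_motion() -> RigidMotion:
    """Object motion used in motion-compensation checks: 30 deg/s about +z
    plus 20 mm/s translation."""
    return RigidMotion(
        axis=(0.0, 0.0, 1.0), angular_rate_deg_s=30.0, velocity_mm_s=(20.0, 0.0, 0.0)
    )
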