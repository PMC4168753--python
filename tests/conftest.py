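import numpy as np
import pytest

from mechanoca import (
    ForceCurve,
    GeneratorConfig,
    ProbeMeta,
)

SEED = 20140711


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def config():
    return GeneratorConfig()


def triangle_curve(
    contact_z=2.0,
    z_max=3.0,
    slope_nn_per_um=100.0,
    k=39.0,
    speed=2.0,
    dwell=0.0,
    dz=0.01,
    z_start=1.0,
    retract_scale=1.0,
    noise_sd_nn=0.0,
    rng=None,
):
    """Noiseless (or noisy) piecewise-linear indentation cycle.

    Force is 0 until ``contact_z``, then rises linearly; the retract
    force is the approach force times ``retract_scale``.  The grid
    includes ``contact_z`` exactly when (contact_z - z_start)/dz is an
    integer.
    """
    n = int(round((z_max - z_start) / dz))
    z_app = z_start + dz * np.arange(n + 1)
    dt = dz / speed
    t_app = dt * np.arange(n + 1)
    f_app = np.clip(slope_nn_per_um * (z_app - contact_z), 0.0, None)
    n_dwell = int(round(dwell / dt))
    if n_dwell:
        t_dw = t_app[-1] + dt * np.arange(1, n_dwell + 1)
        z_dw = np.full(n_dwell, z_max)
        f_dw = np.full(n_dwell, f_app[-1])
    else:
        t_dw = z_dw = f_dw = np.empty(0)
    t0 = t_dw[-1] if n_dwell else t_app[-1]
    # the retract path carries its own apex sample so its force there is
    # the retract (scaled) value, not the approach one
    t_ret = t0 + dt * np.arange(1, n + 2)
    z_ret = z_max - dz * np.arange(0, n + 1)
    f_ret = retract_scale * np.clip(slope_nn_per_um * (z_ret - contact_z), 0.0, None)
    time = np.concatenate([t_app, t_dw, t_ret])
    z = np.concatenate([z_app, z_dw, z_ret])
    force = np.concatenate([f_app, f_dw, f_ret])
    deflection = force / k
    if noise_sd_nn > 0:
        deflection = deflection + (rng or np.random.default_rng(0)).normal(
            0, noise_sd_nn / k, deflection.size
        )
    meta = ProbeMeta(spring_constant=k, indentation_speed=speed, dwell_time=dwell)
    return ForceCurve(time=time, z=z, deflection=deflection, meta=meta)
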