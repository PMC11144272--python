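import numpy as np
import pytest

from emrestore import diffusion


@pytest.fixture(scope="session")
def toy_schedule():
    """Short cosine schedule used throughout the learning tests: with only
    50 steps a linear 1e-4..0.02 ramp would leave most of the signal intact
    at t = T, so the cosine ramp is used to drive alpha_bar below 1e-2."""
    return diffusion.build_schedule(T=50, beta_min=1e-4, beta_max=0.999,
                                    kind="cosine")


class LinearBlendNet:
    """Oracle for volume interpolation: eps consistent with x0 equal to the
    linear blend ((R+1-j) c_u + j c_l) / (R+1) of the conditioning slices."""

    def __init__(self, R, schedule):
        self.R = R
        self.schedule = schedule

    def __call__(self, x_t, cond, t, j=None):
        from emrestore.nn import Tensor

        x_t = np.asarray(getattr(x_t, "data", x_t))
        cond = np.asarray(getattr(cond, "data", cond))
        t = int(np.atleast_1d(t)[0])
        jv = int(np.atleast_1d(j)[0]) if j is not None else 1
        upper, lower = cond[:, 0], cond[:, 1]
        x0 = ((self.R + 1 - jv) * upper + jv * lower) / (self.R + 1)
        ab = self.schedule.alpha_bar[t]
        eps = (x_t[:, 0] - np.sqrt(ab) * x0) / np.sqrt(1.0 - ab)
        return (Tensor(eps[:, None]),
                Tensor(np.ones_like(eps[:, None])))


@pytest.fixture
def linear_blend_net(toy_schedule):
    def make(R):
        return LinearBlendNet(R, toy_schedule)

    return make
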