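"""Fossil-calibration node-age priors: offset lognormal and offset
exponential.

A fossil gives a hard minimum age (the offset); the distribution above
the offset expresses how much older the node is believed to be. The
lognormal is parameterised by the real-space mean and standard
deviation of the non-offset part, the exponential by its mean. All ages
in Ma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CalibrationPrior", "offset_lognormal", "offset_exponential"]

KINDS = ("offset_lognormal", "offset_exponential")


@dataclass(frozen=True)
class CalibrationPrior:
    """An offset age prior for a calibrated node."""

    kind: str
    offset: float  # Ma, the fossil minimum age
    mean: float  # real-space mean of the part above the offset
    sd: float | None = None  # real-space sd (lognormal only)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if self.kind == "offset_lognormal":
            if self.sd is None or self.sd <= 0:
                raise ValueError("lognormal prior needs sd > 0")

    @property
    def _dist(self):
        if self.kind == "offset_exponential":
            return stats.expon(loc=self.offset, scale=self.mean)
        # moment-match: sigma^2 = ln(1 + sd^2/mean^2), mu = ln mean - sigma^2/2
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        sigma = np.sqrt(sigma2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return stats.lognorm(s=sigma, loc=self.offset, scale=np.exp(mu))

    def quantile(self, q: float) -> float:
        """Age (Ma) below which a fraction q of the prior mass lies."""
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("q must be strictly inside (0, 1)")
        out = self._dist.ppf(q)
        return float(out) if out.shape == () else out

    def cdf(self, x) -> float:
        out = self._dist.cdf(x)
        return float(out) if np.ndim(out) == 0 else out

    def pdf(self, x):
        return self._dist.pdf(x)

    def sample(self, n: int, rng) -> np.ndarray:
        """n Monte-Carlo draws using a numpy Generator."""
        return self._dist.rvs(size=n, random_state=rng)

    def summary(self):
        """(median, (lower 2.5%, upper 97.5%)) in Ma."""
        return self.quantile(0.5), (self.quantile(0.025), self.quantile(0.975))

    def summary_frame(self):
        import pandas as pd

        qs = [0.025, 0.05, 0.5, 0.95, 0.975]
        return pd.DataFrame(
            {"quantile": qs, "age_ma": [self.quantile(q) for q in qs]}
        )


def offset_lognormal(offset: float, mean: float, sd: float) -> CalibrationPrior:
    return CalibrationPrior("offset_lognormal", offset, mean, sd)


def offset_exponential(offset: float, mean: float) -> CalibrationPrior:
    return CalibrationPrior("offset_exponential", offset, mean)
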