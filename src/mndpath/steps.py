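"""Anchored gamma duration distributions for pathway stages.

Every stage of the diagnostic pathway is modelled as a fixed minimum
feasible time plus a gamma-distributed excess.  The gamma part is
parameterised by its mean and standard deviation in days; shape and
scale follow by moment matching::

    shape = (mean / sd)**2        scale = sd**2 / mean

A standard deviation of zero is admitted as an explicit point mass at
``minimum + mean``, which makes exact closed-form tests possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ParameterError", "StepSpec", "gamma_params_from_moments", "sample_step"]


class ParameterError(ValueError):
    """A duration parameter is outside its valid domain."""


def gamma_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a gamma distribution to a mean and standard deviation.

    Parameters
    ----------
    mean : float
        Target mean in days; must be strictly positive.
    sd : float
        Target standard deviation in days; must be strictly positive.

    Returns
    -------
    (shape, scale) : tuple of float
        ``shape = (mean/sd)**2`` (dimensionless) and ``scale = sd**2/mean``
        (days), so that ``shape * scale == mean`` and
        ``shape * scale**2 == sd**2``.
    """
    if not mean > 0:
        raise ParameterError(f"mean must be > 0, got mean={mean!r}")
    if not sd > 0:
        raise ParameterError(f"sd must be > 0, got sd={sd!r}")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


@dataclass(frozen=True)
class StepSpec:
    """One pathway stage's duration distribution.

    The stage duration is ``minimum + Gamma(shape, scale)`` where the
    gamma moments are ``mean`` and ``sd`` (the minimum offset is *not*
    included in ``mean``).  ``sd == 0`` denotes a point mass at
    ``minimum + mean``.

    Attributes
    ----------
    name : str
        Short label, e.g. ``"s2gp"``.
    mean, sd, minimum : float
        Days.  ``mean > 0``, ``sd >= 0``, ``minimum >= 0``.
    """

    name: str
    mean: float
    sd: float
    minimum: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ParameterError(f"{self.name}.mean must be > 0, got {self.mean!r}")
        if not self.sd >= 0:
            raise ParameterError(f"{self.name}.sd must be >= 0, got {self.sd!r}")
        if not self.minimum >= 0:
            raise ParameterError(
                f"{self.name}.minimum must be >= 0, got {self.minimum!r}"
            )

    @property
    def is_degenerate(self) -> bool:
        """True when the stage is a point mass (``sd == 0``)."""
        return self.sd == 0

    @property
    def shape(self) -> float:
        """Moment-matched gamma shape; undefined for a point mass."""
        return gamma_params_from_moments(self.mean, self.sd)[0]

    @property
    def scale(self) -> float:
        """Moment-matched gamma scale in days; undefined for a point mass."""
        return gamma_params_from_moments(self.mean, self.sd)[1]

    def scaled(self, factor: float) -> "StepSpec":
        """Dilate the whole distribution by ``factor``.

        Multiplies mean, sd and minimum alike, which is equivalent to
        multiplying every sampled duration by ``factor``; the gamma
        shape is unchanged and the scale is multiplied by ``factor``.
        """
        if not factor > 0:
            raise ParameterError(f"scaling factor must be > 0, got {factor!r}")
        return dataclasses.replace(
            self,
            mean=self.mean * factor,
            sd=self.sd * factor,
            minimum=self.minimum * factor,
        )


def quantile(spec: StepSpec, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF transform of uniforms ``u`` under ``spec``.

    Sampling through the quantile function keeps a fixed stream of
    uniforms reusable across parameter values (common random numbers),
    which the scenario comparisons and calibration rely on.
    """
    u = np.asarray(u, dtype=float)
    if spec.is_degenerate:
        return np.full(u.shape, spec.minimum + spec.mean)
    shape, scale = gamma_params_from_moments(spec.mean, spec.sd)
    return spec.minimum + stats.gamma.ppf(u, shape, scale=scale)


def sample_step(
    spec: StepSpec, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` durations (days) for one stage.

    Parameters
    ----------
    spec : StepSpec
    n : int
        Number of draws; must be >= 1.
    rng : numpy Generator or int seed

    Returns
    -------
    ndarray of shape (n,), every value >= ``spec.minimum``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return quantile(spec, rng.random(int(n)))
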