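"""Network density and outlier screening.

Density of a temporal network is the mean of the absolute values of all
auto- and cross-lagged coefficients: the sum of |Phi| entries over a divisor.
For a p-node network the natural divisor is p^2 (16 effects for four
emotions); the original analysis of this protocol divided by 20, so an
explicit divisor is supported as a compatibility mode and both the sum and
the divisor are always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from emonet.mlvar import PersonNetwork


@dataclass
class DensityResult:
    subject_id: object
    density: float
    abs_sum: float
    n_effects_summed: int
    divisor: int


@dataclass
class OutlierScreen:
    """Single-pass screen: values diverging more than k sample SDs from the
    sample mean are flagged.  Strict inequality: a value exactly at
    mean +/- k*SD is retained.  Mean and SD come from the full vector; the
    screen is not iterated."""

    values: np.ndarray
    mean: float
    sd: float
    k: float
    retained: np.ndarray  # boolean mask

    @property
    def n_removed(self) -> int:
        return int((~self.retained).sum())


def density(network: PersonNetwork | np.ndarray, divisor: int | str = "auto") -> DensityResult:
    """Mean absolute temporal effect of a person-specific network.

    ``divisor="auto"`` uses p^2, the number of auto- plus cross-lagged
    effects, making density the arithmetic mean of |Phi| entries.  An
    explicit integer divisor (e.g. 20) reproduces the published convention
    for this protocol.
    """
    if isinstance(network, PersonNetwork):
        Phi = network.Phi
        sid = network.subject_id
    else:
        Phi = np.asarray(network, dtype=float)
        sid = None
    if Phi.ndim != 2 or Phi.shape[0] != Phi.shape[1]:
        raise ValueError("network matrix must be square")
    if not np.all(np.isfinite(Phi)):
        raise ValueError("network matrix contains non-finite entries")
    p = Phi.shape[0]
    if divisor == "auto":
        div = p * p
    else:
        div = int(divisor)
        if div <= 0:
            raise ValueError("divisor must be positive")
    abs_sum = float(np.abs(Phi).sum())
    return DensityResult(
        subject_id=sid,
        density=abs_sum / div,
        abs_sum=abs_sum,
        n_effects_summed=p * p,
        divisor=div,
    )


def screen_outliers(values, k: float = 3.0) -> OutlierScreen:
    """Flag values diverging more than ``k`` sample SDs from the mean.

    The mean and the (n-1)-denominator SD are computed once on the full
    vector; flagged values are those with |v - mean| strictly greater than
    k * SD.  With fewer than 3 values or zero SD everything is retained.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mean = float(v.mean()) if v.size else float("nan")
    sd = float(v.std(ddof=1)) if v.size >= 2 else 0.0
    if v.size < 3 or sd == 0.0:
        retained = np.ones(v.size, dtype=bool)
    else:
        retained = np.abs(v - mean) <= k * sd
    return OutlierScreen(values=v, mean=mean, sd=sd, k=float(k), retained=retained)
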