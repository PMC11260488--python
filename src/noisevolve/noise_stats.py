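"""Expression-noise statistics: Fano factor, CV², and the dual-reporter
intrinsic/extrinsic decomposition.

The Fano factor (variance over mean, σ²/μ) of log-transformed
fluorescence is the per-sample noise metric; it is less sensitive to
shifts in mean abundance than the raw variance and more sensitive than
CV² to variance-driven noise changes.

The dual-reporter decomposition partitions total noise between two
identical reporters ``c`` and ``y`` measured in the same cells:

    η_int² = ⟨(c−y)²⟩ / (2⟨c⟩⟨y⟩)
    η_ext² = (⟨cy⟩ − ⟨c⟩⟨y⟩) / (⟨c⟩⟨y⟩)
    η_tot² = (⟨c²⟩ + ⟨y²⟩ − 2⟨c⟩⟨y⟩) / (2⟨c⟩⟨y⟩)

with plain averages over cells, so that η_tot² = η_int² + η_ext² holds
as an algebraic identity. Intrinsic noise is the uncorrelated part
(stochastic expression of each gene copy); extrinsic noise is the
correlated part (cell-global fluctuations). A negative η_ext² sample
estimate is possible and is reported as-is — clipping would break the
additivity identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cytometry import EmptyPopulationError, EventTable


@dataclass(frozen=True)
class NoiseSummary:
    """Per-sample noise statistics for one channel."""

    n: int
    mean: float
    variance: float
    fano: float
    cv2: float
    channel: str = ""
    scale: str = "linear"  # "linear" or "log<base>"

    def to_dict(self) -> dict:
        return {
            "channel": self.channel, "n": self.n, "mean": self.mean,
            "variance": self.variance, "fano": self.fano, "cv2": self.cv2,
            "scale": self.scale,
        }


@dataclass(frozen=True)
class NoiseDecomposition:
    """Squared intrinsic, extrinsic, and total noise of a dual-reporter pair."""

    eta_int2: float
    eta_ext2: float
    eta_tot2: float
    n: int

    def to_dict(self) -> dict:
        return {"n": self.n, "eta_int2": self.eta_int2,
                "eta_ext2": self.eta_ext2, "eta_tot2": self.eta_tot2}


def fano(values, channel: str = "", scale: str = "linear") -> NoiseSummary:
    """Fano factor (σ²/μ, sample variance with ddof=1) of an intensity vector.

    Raises if the mean is non-positive: a negative mean usually means a
    log-transform was applied to sub-unity intensities, where σ²/μ is
    meaningless.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if len(v) < 2:
        raise EmptyPopulationError("need at least 2 events for a variance")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError(
            "mean is non-positive; Fano factor undefined — check the "
            "log-transform domain (intensities must exceed 1 on the linear scale)"
        )
    var = float(v.var(ddof=1))
    return NoiseSummary(
        n=len(v), mean=mean, variance=var,
        fano=var / mean, cv2=var / mean**2,
        channel=channel, scale=scale,
    )


def decompose(c, y) -> NoiseDecomposition:
    """Dual-reporter intrinsic/extrinsic/total noise decomposition.

    Both channels are first rescaled to unit mean, making the result
    invariant to separate rescaling of either channel (different
    fluorophore brightness or detector gain). Inputs are linear-scale
    paired intensities of the two reporters over the same cells.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("c and y must be paired 1-D vectors of equal length")
    n = len(c)
    if n < 2:
        raise EmptyPopulationError("need at least 2 cells")
    if c.mean() <= 0 or y.mean() <= 0:
        raise ValueError("channel means must be positive (linear-scale intensities)")
    c = c / c.mean()
    y = y / y.mean()
    mc, my = c.mean(), y.mean()  # both 1 after normalization
    denom = mc * my
    eta_int2 = float(np.mean((c - y) ** 2) / (2 * denom))
    eta_ext2 = float((np.mean(c * y) - denom) / denom)
    eta_tot2 = float((np.mean(c**2) + np.mean(y**2) - 2 * denom) / (2 * denom))
    return NoiseDecomposition(eta_int2, eta_ext2, eta_tot2, n)


def sample_noise(events: EventTable, channel: str, force: bool = False) -> NoiseSummary:
    """Fano factor of one fluorescence channel of a gated, logged population.

    Refuses ungated or un-log-transformed tables unless ``force`` is set,
    because the noise metric is defined on the gated, log-scale
    population only.
    """
    if events.n == 0:
        raise EmptyPopulationError("empty population")
    if not force:
        if not events.is_gated():
            raise ValueError("events are ungated; gate first or pass force=True")
        if channel not in events.log_channels:
            raise ValueError(
                f"channel {channel!r} is not log-transformed; "
                "apply log_transform first or pass force=True"
            )
    scale = "log" if channel in events.log_channels else "linear"
    return fano(events.channel(channel), channel=channel, scale=scale)


def lognormal_eta2(sigma_ext: float, sigma_int: float) -> tuple[float, float]:
    """Analytic (η_int², η_ext²) of the multiplicative lognormal model.

    For intensities mu·E·I with log-scale SDs (sigma_ext, sigma_int):
    η_ext² = e^{σ_ext²} − 1 and η_int² = e^{σ_ext²}(e^{σ_int²} − 1),
    which reduce to σ² to first order for small σ.
    """
    eta_ext2 = np.expm1(sigma_ext**2)
    eta_int2 = np.exp(sigma_ext**2) * np.expm1(sigma_int**2)
    return float(eta_int2), float(eta_ext2)
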