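"""Small self-contained assay computations.

Four quantitative readouts that accompany the noise phenotyping:
relative transcript abundance by qPCR (2^-ΔΔCt), maximal growth rate
from a plate-reader OD curve, polysome-to-monosome ratio from an A254
sucrose-gradient trace, and marker-controlled competition fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def ddct_fold_change(
    ct_target_test: float,
    ct_control_gene_test: float,
    ct_target_ref: float,
    ct_control_gene_ref: float,
) -> float:
    """Relative expression fold change by the 2^-ΔΔCt method.

    ΔCt normalizes the target gene to an endogenous control within each
    sample; ΔΔCt compares the test sample with the reference sample. One
    PCR cycle corresponds to a factor of two in template abundance.
    """
    cts = [ct_target_test, ct_control_gene_test, ct_target_ref, ct_control_gene_ref]
    if not np.all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_control_gene_test) - (ct_target_ref - ct_control_gene_ref)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class GrowthRateResult:
    rate: float           # OD/min, max OLS slope
    window_start: int     # index of the first point of the winning window
    window_time: float    # time (min) of that point


def max_growth_rate(time, od, window: int = 20) -> GrowthRateResult:
    """Maximal growth rate as the steepest OLS slope over a sliding window.

    Every contiguous window of ``window`` points is fit by ordinary
    least squares; the maximum slope and the window where it occurs are
    returned (ties go to the earliest window). Adding a constant to all
    OD readings does not change the result.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and od must be matched 1-D vectors")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    n = len(t)
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < window:
        raise ValueError(f"need at least {window} points, got {n}")
    slopes = np.empty(n - window + 1)
    for i in range(n - window + 1):
        tw = t[i:i + window]
        yw = y[i:i + window]
        tc = tw - tw.mean()
        slopes[i] = float(tc @ (yw - yw.mean()) / (tc @ tc))
    best = int(np.argmax(slopes))  # first max on ties
    return GrowthRateResult(float(slopes[best]), best, float(t[best]))


@dataclass(frozen=True)
class PMRatioResult:
    ratio: float
    polysome_area: float
    monosome_area: float
    baseline: float


def pm_ratio(position, absorbance, boundaries) -> PMRatioResult:
    """Polysome-to-monosome ratio from an A254 gradient trace.

    ``boundaries`` is a list of (label, start, end) segments; at least
    one ``polysome`` segment and one ``80S`` segment are required. The
    baseline is the minimum absorbance over the full span covered by
    the boundaries, subtracted before trapezoidal integration; only the
    80S peak enters the monosome denominator (the 40S/60S subunit peaks
    do not).
    """
    x = np.asarray(position, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("position and absorbance must be matched 1-D vectors")
    segs = [(str(lab), float(a), float(b)) for lab, a, b in boundaries]
    labels = {lab for lab, _, _ in segs}
    if "polysome" not in labels:
        raise ValueError("no polysome segment in boundaries")
    if "80S" not in labels:
        raise ValueError("no 80S segment in boundaries")
    for lab, a, b in segs:
        if not (x.min() <= a < b <= x.max()):
            raise ValueError(f"segment {lab} [{a}, {b}] outside trace span")

    span_lo = min(a for _, a, _ in segs)
    span_hi = max(b for _, _, b in segs)
    span_mask = (x >= span_lo) & (x <= span_hi)
    baseline = float(y[span_mask].min())

    def area(a: float, b: float) -> float:
        m = (x >= a) & (x <= b)
        return float(np.trapezoid(y[m] - baseline, x[m]))

    poly = sum(area(a, b) for lab, a, b in segs if lab == "polysome")
    mono = sum(area(a, b) for lab, a, b in segs if lab == "80S")
    if mono <= 0:
        raise ValueError("80S area is non-positive after baseline subtraction")
    return PMRatioResult(poly / mono, poly, mono, baseline)


def competition_fitness(experimental_ratios, control_ratios) -> pd.Series:
    """Marker-controlled competition fitness series.

    The mutant-to-reference ratio at each time point is divided by the
    matched control ratio (an otherwise isogenic marker-carrying strain
    against the same reference), cancelling the fitness cost of the
    marker itself. Missing control points propagate as missing output.
    """
    exp = pd.Series(np.asarray(experimental_ratios, dtype=float))
    ctl = pd.Series(np.asarray(control_ratios, dtype=float))
    if len(exp) != len(ctl):
        raise ValueError("experimental and control series must be matched")
    if np.any(ctl.to_numpy() == 0):
        raise ValueError("control ratio is zero; normalization undefined")
    return exp / ctl
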