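"""Seeded synthetic-data generators for every input the pipeline consumes.

All wet-lab inputs of the analysis chain are emulated here with the
statistical structure the downstream methods assume:

* dual-reporter cytometry events — bivariate lognormal fluorescence with
  a shared (extrinsic) and two per-channel (intrinsic) multiplicative
  factors, plus debris and doublet contamination;
* F1 haploid crosses — one causal locus among neutral markers, Haldane
  recombination within chromosomes, replicated noise phenotypes;
* pooled sequencing — binomial read sampling of the pool allele
  frequency with a symmetric base-error rate;
* logistic growth curves and Gaussian-peak absorbance traces for the
  small assay computations.

Every generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytometry import DEFAULT_TRIGGER, EventTable


# ---------------------------------------------------------------------------
# dual-reporter cytometry events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterModel:
    """Generative model of a dual-reporter strain on the cytometer.

    Fluorescence of a singlet cell is ``mu_ch * E * I_ch`` where ``E`` is
    a lognormal extrinsic factor shared by both channels within a cell
    (cell size, cycle stage, expression machinery) and ``I_ch`` are
    independent lognormal intrinsic factors (stochastic expression of
    each reporter). Scatter channels are correlated lognormals; debris
    sits below the forward-scatter trigger threshold and doublets are
    sums of two singlets with inflated FSC-W.

    Parameters
    ----------
    mu_gfp, mu_mcherry
        Linear-scale mean intensities (a.u.).
    sigma_ext
        Log-scale SD of the shared extrinsic factor.
    sigma_int_gfp, sigma_int_mcherry
        Log-scale SDs of the per-channel intrinsic factors.
    scatter_mu, scatter_sigma
        Lognormal parameters of FSC-A; SSC-A is generated with log-scale
        correlation ``rho_scatter``.
    f_debris, f_doublet
        Contamination fractions in [0, 1) with ``f_debris + f_doublet < 1``.
    """

    mu_gfp: float = 1200.0
    mu_mcherry: float = 900.0
    sigma_ext: float = 0.25
    sigma_int_gfp: float = 0.15
    sigma_int_mcherry: float = 0.15
    scatter_mu: float = float(np.log(6.0e4))
    scatter_sigma: float = 0.22
    rho_scatter: float = 0.65
    width_mu: float = float(np.log(100.0))
    width_sigma: float = 0.05
    f_debris: float = 0.0
    f_doublet: float = 0.0

    def __post_init__(self) -> None:
        params = [
            self.mu_gfp, self.mu_mcherry, self.sigma_ext, self.sigma_int_gfp,
            self.sigma_int_mcherry, self.scatter_mu, self.scatter_sigma,
            self.rho_scatter, self.width_mu, self.width_sigma,
            self.f_debris, self.f_doublet,
        ]
        if not np.all(np.isfinite(params)):
            raise ValueError("reporter model parameters must be finite")
        if self.mu_gfp <= 0 or self.mu_mcherry <= 0:
            raise ValueError("mean intensities must be positive")
        if min(self.sigma_ext, self.sigma_int_gfp, self.sigma_int_mcherry,
               self.scatter_sigma, self.width_sigma) < 0:
            raise ValueError("sigmas must be non-negative")
        if not (0 <= self.f_debris < 1 and 0 <= self.f_doublet < 1
                and self.f_debris + self.f_doublet < 1):
            raise ValueError("contamination fractions must satisfy f_debris + f_doublet < 1")
        if not -1.0 < self.rho_scatter < 1.0:
            raise ValueError("rho_scatter must lie in (-1, 1)")


#: uniform FSC-W inflation range for doublets relative to a singlet draw
DOUBLET_WIDTH_RANGE = (1.6, 2.2)


def _singlet_draws(model: ReporterModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    ext = rng.normal(0.0, model.sigma_ext, n) if model.sigma_ext > 0 else np.zeros(n)
    ig = rng.normal(0.0, model.sigma_int_gfp, n) if model.sigma_int_gfp > 0 else np.zeros(n)
    im = (rng.normal(0.0, model.sigma_int_mcherry, n)
          if model.sigma_int_mcherry > 0 else np.zeros(n))
    gfp = model.mu_gfp * np.exp(ext + ig)
    mch = model.mu_mcherry * np.exp(ext + im)

    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    log_fsc = model.scatter_mu + model.scatter_sigma * z1
    log_ssc = (model.scatter_mu - np.log(3.0)) + model.scatter_sigma * (
        model.rho_scatter * z1 + np.sqrt(1 - model.rho_scatter**2) * z2
    )
    width = np.exp(model.width_mu + model.width_sigma * rng.normal(size=n))
    return pd.DataFrame({
        "FSC_A": np.exp(log_fsc),
        "FSC_W": width,
        "SSC_A": np.exp(log_ssc),
        "GFP": gfp,
        "mCherry": mch,
    })


def gen_events(model: ReporterModel, n_cells: int, seed: int) -> EventTable:
    """Generate an ungated event table of ``n_cells`` events.

    Each event is independently a singlet, debris particle, or doublet
    with probabilities ``1 - f_debris - f_doublet``, ``f_debris``,
    ``f_doublet``; the ``provenance`` column records which. Debris has
    FSC-A below the trigger threshold and near-zero fluorescence;
    doublets are sums of two singlet draws with FSC-W inflated by a
    uniform factor in ``DOUBLET_WIDTH_RANGE``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    kind = rng.choice(
        3, size=n_cells,
        p=[1.0 - model.f_debris - model.f_doublet, model.f_debris, model.f_doublet],
    )
    n_singlet = int((kind == 0).sum())
    n_debris = int((kind == 1).sum())
    n_doublet = int((kind == 2).sum())

    parts = np.empty(n_cells, dtype=object)
    frames: dict[int, pd.DataFrame] = {}
    frames[0] = _singlet_draws(model, max(n_singlet, 1), rng).iloc[:n_singlet]

    if n_debris:
        frames[1] = pd.DataFrame({
            "FSC_A": rng.uniform(0.02 * DEFAULT_TRIGGER, 0.97 * DEFAULT_TRIGGER, n_debris),
            "FSC_W": np.exp(model.width_mu + model.width_sigma * rng.normal(size=n_debris)),
            "SSC_A": rng.uniform(1.0, 50.0, n_debris),
            "GFP": rng.uniform(0.0, 5.0, n_debris),
            "mCherry": rng.uniform(0.0, 5.0, n_debris),
        })
    if n_doublet:
        a = _singlet_draws(model, n_doublet, rng)
        b = _singlet_draws(model, n_doublet, rng)
        frames[2] = pd.DataFrame({
            "FSC_A": a["FSC_A"].to_numpy() + b["FSC_A"].to_numpy(),
            "FSC_W": a["FSC_W"].to_numpy() * rng.uniform(*DOUBLET_WIDTH_RANGE, n_doublet),
            "SSC_A": a["SSC_A"].to_numpy() + b["SSC_A"].to_numpy(),
            "GFP": a["GFP"].to_numpy() + b["GFP"].to_numpy(),
            "mCherry": a["mCherry"].to_numpy() + b["mCherry"].to_numpy(),
        })

    label = {0: "singlet", 1: "debris", 2: "doublet"}
    data = pd.DataFrame(index=range(n_cells),
                        columns=[*frames[0].columns], dtype=float)
    for k, frame in frames.items():
        idx = np.flatnonzero(kind == k)
        data.iloc[idx] = frame.to_numpy()
        parts[idx] = label[k]
    data["provenance"] = parts
    return EventTable(data)


# ---------------------------------------------------------------------------
# F1 cross: segregant genotypes and replicated noise phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossDesign:
    """Design of an evolved x ancestral F1 haploid cross.

    ``map_positions`` gives each locus a (chromosome, centimorgan)
    position; loci default to one locus per chromosome (all unlinked).
    Exactly one locus (``causal_index``) carries the evolved allele that
    shifts the noise phenotype by ``phenotype_effect`` Fano units; every
    segregant is phenotyped ``n_replicates`` times with Gaussian
    measurement noise of SD ``phenotype_noise_sd``.
    """

    n_loci: int = 50
    causal_index: int = 0
    n_segregants: int = 100
    phenotype_effect: float = 0.5
    phenotype_noise_sd: float = 0.05
    n_replicates: int = 3
    base_fano: float = 0.5
    map_positions: tuple[tuple[int, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.causal_index < self.n_loci:
            raise ValueError("causal_index out of range")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_segregants < 1:
            raise ValueError("n_segregants must be >= 1")
        if self.phenotype_noise_sd < 0:
            raise ValueError("phenotype_noise_sd must be >= 0")
        if self.map_positions is not None and len(self.map_positions) != self.n_loci:
            raise ValueError("map_positions must have one entry per locus")

    def positions(self) -> list[tuple[int, float]]:
        if self.map_positions is not None:
            return list(self.map_positions)
        return [(i, 0.0) for i in range(self.n_loci)]  # one locus per chromosome

    @property
    def ancestral_fano(self) -> float:
        return self.base_fano

    @property
    def evolved_fano(self) -> float:
        return self.base_fano + self.phenotype_effect


def haldane_recomb_prob(d_cm: float) -> float:
    """Haldane map function: recombination probability for d centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


@dataclass(frozen=True)
class SegregantSet:
    """Genotypes (1 = evolved allele) and replicate phenotypes of a cross."""

    design: CrossDesign
    genotypes: np.ndarray  # (n_segregants, n_loci) int8
    phenotypes: np.ndarray  # (n_segregants, n_replicates) Fano values


def gen_segregants(design: CrossDesign, seed: int) -> SegregantSet:
    """Simulate F1 haploid segregants of an evolved x ancestral cross.

    The leftmost locus of each chromosome segregates 1:1; adjacent loci
    on a chromosome recombine with Haldane probability for their map
    distance; loci on different chromosomes assort independently.
    """
    rng = np.random.default_rng(seed)
    pos = design.positions()
    n, m = design.n_segregants, design.n_loci
    geno = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        if j == 0 or pos[j][0] != pos[j - 1][0]:
            geno[:, j] = rng.random(n) < 0.5
        else:
            d = abs(pos[j][1] - pos[j - 1][1])
            recomb = rng.random(n) < haldane_recomb_prob(d)
            geno[:, j] = np.where(recomb, 1 - geno[:, j - 1], geno[:, j - 1])

    base = design.base_fano + design.phenotype_effect * geno[:, design.causal_index]
    noise = (rng.normal(0.0, design.phenotype_noise_sd, (n, design.n_replicates))
             if design.phenotype_noise_sd > 0 else np.zeros((n, design.n_replicates)))
    return SegregantSet(design, geno, base[:, None] + noise)


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------

def gen_pool_reads(
    pool_genotypes: np.ndarray,
    depth: int,
    error_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Binomial read counts per site for a pool of segregant genotypes.

    The observed alternate-allele probability at a site with true pool
    frequency ``p`` is ``p(1-e) + (1-p)e`` for a symmetric base-error
    rate ``e``; counts are Binomial(depth, .). Returns a frame with
    ``ref_count``/``alt_count`` per site.
    """
    pool = np.asarray(pool_genotypes)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise ValueError("pool_genotypes must be a non-empty (n_pool, n_loci) array")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    p = pool.mean(axis=0)
    p_obs = p * (1.0 - error_rate) + (1.0 - p) * error_rate
    alt = rng.binomial(depth, p_obs)
    return pd.DataFrame({
        "site": np.arange(pool.shape[1]),
        "ref_count": depth - alt,
        "alt_count": alt,
    })


# ---------------------------------------------------------------------------
# assay fixtures: growth curves and A254 traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCurveTruth:
    """Logistic growth curve with known parameters (OD units, minutes)."""

    time: np.ndarray
    od: np.ndarray
    rate: float
    capacity: float
    od0: float

    @property
    def max_slope(self) -> float:
        """Analytic maximal slope of the noiseless logistic: r*K/4."""
        return self.rate * self.capacity / 4.0


def gen_growth_curve(
    rate: float,
    lag: float,
    capacity: float,
    dt: float = 12.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 120,
    od0: float = 0.02,
) -> GrowthCurveTruth:
    """Logistic OD curve sampled every ``dt`` minutes with additive noise.

    ``lag`` shifts the logistic midpoint in minutes; the inflection (and
    the maximal slope ``rate*capacity/4``) occurs at half-capacity.
    """
    if rate <= 0 or capacity <= 0 or dt <= 0 or od0 <= 0 or od0 >= capacity:
        raise ValueError("need rate, capacity, dt > 0 and 0 < od0 < capacity")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(n_points) * dt
    t_mid = lag + np.log(capacity / od0 - 1.0) / rate
    od = capacity / (1.0 + np.exp(-rate * (t - t_mid)))
    if noise_sd > 0:
        od = od + np.random.default_rng(seed).normal(0.0, noise_sd, n_points)
    return GrowthCurveTruth(t, od, rate, capacity, od0)


@dataclass(frozen=True)
class TraceTruth:
    """A254 absorbance trace built from Gaussian peaks over a baseline."""

    position: np.ndarray
    absorbance: np.ndarray
    peak_centers: tuple[float, ...]
    peak_areas: tuple[float, ...]
    peak_widths: tuple[float, ...]
    baseline: float


def gen_polysome_trace(
    peak_centers,
    peak_areas,
    widths,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 2000,
    span: tuple[float, float] | None = None,
) -> TraceTruth:
    """Sum-of-Gaussians absorbance trace with known per-peak areas.

    Each peak contributes total area ``peak_areas[i]`` (Gaussian mass),
    so trapezoidal integration over +/-4 widths recovers it to <0.1%.
    """
    centers = np.asarray(peak_centers, dtype=float)
    areas = np.asarray(peak_areas, dtype=float)
    w = np.asarray(widths, dtype=float)
    if not (len(centers) == len(areas) == len(w)):
        raise ValueError("peak_centers, peak_areas, widths must have equal length")
    if np.any(areas <= 0) or np.any(w <= 0):
        raise ValueError("peak areas and widths must be positive")
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if span is None:
        span = (float(centers.min() - 6 * w.max()), float(centers.max() + 6 * w.max()))
    x = np.linspace(span[0], span[1], n_points)
    y = np.full(n_points, float(baseline))
    for c, a, s in zip(centers, areas, w):
        y += a / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / s) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n_points)
    return TraceTruth(x, y, tuple(centers), tuple(areas), tuple(w), baseline)


# ---------------------------------------------------------------------------
# writers (spec'd text interchange formats)
# ---------------------------------------------------------------------------

def write_pool_counts_tsv(evolved: pd.DataFrame, ancestral: pd.DataFrame, path,
                          chrom: str = "chrI", positions=None) -> None:
    """Write per-site pooled counts for two bulks as TSV."""
    if positions is None:
        positions = (evolved["site"].to_numpy() + 1) * 1000
    out = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "ref": "A",
        "alt": "T",
        "ref_count_evolved": evolved["ref_count"],
        "alt_count_evolved": evolved["alt_count"],
        "ref_count_ancestral": ancestral["ref_count"],
        "alt_count_ancestral": ancestral["alt_count"],
    })
    out.to_csv(path, sep="\t", index=False)


def write_series_csv(x: np.ndarray, y: np.ndarray, path, names=("x", "y")) -> None:
    pd.DataFrame({names[0]: x, names[1]: y}).to_csv(path, index=False)
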