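"""Stochastic simulator of the FACS noise-enrichment evolution protocol.

One round of EMS mutagenesis seeds genetic diversity in a founding
wild-type population; the population then cycles through alternating
cell sorts and recovery growth:

1. sort the 10% outermost cells of the log-GFP/log-mCherry plane that
   fall in the anti-correlated quadrants (QII: high mCherry/low GFP,
   QIV: high GFP/low mCherry) — this disfavors mutations in general
   activators/repressors, which move both reporters together;
2. recover in non-fermentable (glycerol) medium — this depletes
   lineages with mitochondrial defects, which barely grow;
3. sort the outermost cells of QI (high in both reporters) — this
   counter-selects lineages whose reporter genes are broken;
4. recover again.

Lineages are parameter vectors (reporter model + relative growth rate +
defect flags) with integer abundances; sorting draws a cytometry sample
from the lineage mixture, applies the standard gating chain, and keeps
the masked cells. Recovery is deterministic exponential growth followed
by multinomial resampling to the target population size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cytometry, synthio
from .cytometry import EventTable
from .noise_stats import fano

LINEAGE_CLASSES = (
    "wild-type", "noise-up", "general-up", "general-down",
    "gfp-defect", "mcherry-defect", "mito-defect", "neutral",
)

#: relative glycerol growth rate of mitochondrially defective lineages
MITO_GROWTH = 0.05


@dataclass(frozen=True)
class Lineage:
    """One genotype: reporter model, relative glycerol growth, abundance."""

    id: int
    klass: str
    model: synthio.ReporterModel
    growth_rate: float = 1.0  # relative to wild-type
    abundance: int = 0

    def __post_init__(self) -> None:
        if self.klass not in LINEAGE_CLASSES:
            raise ValueError(f"unknown lineage class {self.klass!r}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if self.klass == "mito-defect" and self.growth_rate > 0.1:
            raise ValueError("mito-defect lineages must grow at <= 0.1x wild-type")


@dataclass
class Population:
    lineages: list[Lineage]

    @property
    def size(self) -> int:
        return sum(l.abundance for l in self.lineages)

    def class_frequencies(self) -> dict[str, float]:
        total = self.size
        freqs = {k: 0.0 for k in LINEAGE_CLASSES}
        if total == 0:
            return freqs
        for lin in self.lineages:
            freqs[lin.klass] += lin.abundance / total
        return freqs


@dataclass(frozen=True)
class MutationEffects:
    """Per-class probabilities and effect-size ranges for EMS mutants.

    Probabilities apply to mutagenized cells; any probability mass not
    assigned to a class is treated as phenotypically neutral. Effect
    magnitudes are drawn uniformly from the stated ranges per founder
    lineage.
    """

    class_probs: dict = field(default_factory=lambda: {
        "noise-up": 0.002,
        "general-up": 0.002,
        "general-down": 0.002,
        "gfp-defect": 0.002,
        "mcherry-defect": 0.002,
        "mito-defect": 0.01,
        "neutral": 0.98,
    })
    noise_up_range: tuple[float, float] = (1.8, 2.5)
    mean_up_range: tuple[float, float] = (2.0, 4.0)
    mean_down_range: tuple[float, float] = (0.25, 0.5)
    defect_residual: float = 0.01  # broken reporter retains 1% of its mean

    def __post_init__(self) -> None:
        bad = set(self.class_probs) - set(LINEAGE_CLASSES)
        if bad:
            raise ValueError(f"unknown mutant classes {sorted(bad)}")
        total = sum(self.class_probs.values())
        if total > 1.0 + 1e-12:
            raise ValueError(f"class probabilities sum to {total} > 1")


def _apply_effect(klass: str, base: synthio.ReporterModel,
                  eff: MutationEffects, rng: np.random.Generator
                  ) -> tuple[synthio.ReporterModel, float]:
    """Return (mutant reporter model, relative growth rate) for a class."""
    growth = 1.0
    model = base
    if klass == "noise-up":
        m = rng.uniform(*eff.noise_up_range)
        model = replace(base,
                        sigma_int_gfp=base.sigma_int_gfp * m,
                        sigma_int_mcherry=base.sigma_int_mcherry * m,
                        sigma_ext=base.sigma_ext * m)
    elif klass == "general-up":
        m = rng.uniform(*eff.mean_up_range)
        model = replace(base, mu_gfp=base.mu_gfp * m, mu_mcherry=base.mu_mcherry * m)
    elif klass == "general-down":
        m = rng.uniform(*eff.mean_down_range)
        model = replace(base, mu_gfp=base.mu_gfp * m, mu_mcherry=base.mu_mcherry * m)
    elif klass == "gfp-defect":
        model = replace(base, mu_gfp=base.mu_gfp * eff.defect_residual)
    elif klass == "mcherry-defect":
        model = replace(base, mu_mcherry=base.mu_mcherry * eff.defect_residual)
    elif klass == "mito-defect":
        growth = MITO_GROWTH
    return model, growth


def ems_mutagenize(
    population: Population,
    mutant_fraction: float,
    effects: MutationEffects,
    seed: int,
    max_founders_per_class: int = 10,
) -> Population:
    """One round of chemical mutagenesis before any sorting.

    A Binomial(N, mutant_fraction) number of cells acquire mutations and
    are assigned to effect classes multinomially. Cells of one class are
    grouped into at most ``max_founders_per_class`` founder lineages
    (each with its own sampled effect magnitude); total abundance is
    conserved exactly.
    """
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must lie in [0, 1]")
    if len(population.lineages) != 1 or population.lineages[0].klass != "wild-type":
        raise ValueError("mutagenesis expects a single founding wild-type lineage")
    wt = population.lineages[0]
    rng = np.random.default_rng(seed)
    n_mut = int(rng.binomial(wt.abundance, mutant_fraction))
    if n_mut == 0:
        return Population([wt])

    classes = [k for k in LINEAGE_CLASSES if k != "wild-type"]
    probs = np.array([effects.class_probs.get(k, 0.0) for k in classes], dtype=float)
    probs[classes.index("neutral")] += max(0.0, 1.0 - probs.sum())
    counts = rng.multinomial(n_mut, probs / probs.sum())

    lineages = [replace(wt, abundance=wt.abundance - n_mut)]
    next_id = wt.id + 1
    for klass, count in zip(classes, counts):
        if count == 0:
            continue
        k = min(count, max_founders_per_class)
        share = np.full(k, count // k, dtype=int)
        share[: count % k] += 1
        for ab in share:
            model, growth = _apply_effect(klass, wt.model, effects, rng)
            lineages.append(Lineage(next_id, klass, model, growth, int(ab)))
            next_id += 1
    return Population(lineages)


def outermost_selection(events: EventTable, fraction: float = 0.10) -> np.ndarray:
    """Mask of the exact floor(fraction*n) outermost cells.

    Events are ranked by Mahalanobis distance from the population
    centroid in the (log GFP, log mCherry) plane using the sample
    covariance, which respects the elliptical shape of lognormal clouds.
    Ties are broken by event index (stable sort), so the selection is
    deterministic. A singular covariance (constant channel) falls back
    to Euclidean distance with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if events.n < 10:
        raise ValueError("need at least 10 events to rank outermost cells")
    for ch in ("GFP", "mCherry"):
        if ch not in events.log_channels:
            raise ValueError("outermost selection requires log-transformed GFP/mCherry")
    xy = np.column_stack([events.channel("GFP"), events.channel("mCherry")])
    centered = xy - xy.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.cond(cov) > 1e12:
        warnings.warn("singular covariance; falling back to Euclidean distance",
                      stacklevel=2)
        d2 = (centered**2).sum(axis=1)
    else:
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    n_keep = int(np.floor(fraction * events.n))
    order = np.argsort(-d2, kind="stable")
    mask = np.zeros(events.n, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


def quadrant_mask(events: EventTable, which: str) -> np.ndarray:
    """Quadrant membership with boundaries at the per-channel medians.

    QI: both channels above their median; QII: mCherry above, GFP
    at/below; QIV: GFP above, mCherry at/below. Events exactly at a
    median go to the "at/below" side. ``which`` may union quadrants,
    e.g. ``"QII+QIV"``.
    """
    gfp = events.channel("GFP")
    mch = events.channel("mCherry")
    mg, mm = np.median(gfp), np.median(mch)
    quads = {
        "QI": (gfp > mg) & (mch > mm),
        "QII": (gfp <= mg) & (mch > mm),
        "QIV": (gfp > mg) & (mch <= mm),
    }
    mask = np.zeros(events.n, dtype=bool)
    for name in which.replace("∪", "+").split("+"):
        name = name.strip()
        if name not in quads:
            raise ValueError(f"unknown quadrant {name!r}; use QI, QII, QIV or unions")
        mask |= quads[name]
    return mask


class SelectionExtinguishedError(RuntimeError):
    """No cells passed the sort mask."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the simulated selection protocol (desk-scale defaults).

    The bench protocol sorts 1e5 cells per event from a much larger
    population; the simulator default acquires 2e4 events and keeps up
    to 1e4 sorted cells, recovering to 1e5 — a 10x scale-down that
    preserves the frequency dynamics.
    """

    wt_model: synthio.ReporterModel = synthio.ReporterModel()
    founding_size: int = 100_000
    mutant_fraction: float = 0.5
    effects: MutationEffects = field(default_factory=MutationEffects)
    events_per_sort: int = 20_000
    n_sorted: int = 10_000
    outer_fraction: float = 0.10
    recovery_size: int = 100_000
    recovery_generations: float = 10.0
    n_rounds: int = 2
    trigger: float = cytometry.DEFAULT_TRIGGER
    width_quantile: float = 0.90
    contour_fraction: float = 0.80
    apply_doublet_gate: bool = True


def sample_events(population: Population, n_events: int, seed: int) -> EventTable:
    """Draw a cytometry acquisition from the lineage mixture.

    Cells are allocated to lineages multinomially by abundance; each
    lineage's events come from its own reporter model. The
    ``provenance`` column carries the lineage id so sorted cells can be
    attributed.
    """
    if population.size == 0:
        raise SelectionExtinguishedError("population is empty")
    rng = np.random.default_rng(seed)
    weights = np.array([l.abundance for l in population.lineages], dtype=float)
    counts = rng.multinomial(n_events, weights / weights.sum())
    frames = []
    for lin, cnt in zip(population.lineages, counts):
        if cnt == 0:
            continue
        sub = synthio.gen_events(lin.model, int(cnt),
                                 seed=int(rng.integers(2**31)))
        df = sub.data.copy()
        df["provenance"] = lin.id
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    # deterministic shuffle so lineage blocks do not bias index tie-breaks
    data = data.iloc[rng.permutation(len(data))].reset_index(drop=True)
    return EventTable(data)


def sort_step(
    population: Population,
    gate: str,
    config: ProtocolConfig,
    seed: int,
) -> Population:
    """One FACS sort: acquire, gate, mask outermost ∩ quadrant, collect.

    The new population's per-lineage abundances are the selected cell
    counts (capped at ``config.n_sorted`` by seeded subsampling).
    """
    rng = np.random.default_rng(seed)
    events = sample_events(population, config.events_per_sort,
                           seed=int(rng.integers(2**31)))
    gated = cytometry.gate_pipeline(
        events, min_fsc=config.trigger, width_quantile=config.width_quantile,
        contour_fraction=config.contour_fraction,
        apply_doublet_gate=config.apply_doublet_gate,
    )
    mask = outermost_selection(gated, config.outer_fraction) & quadrant_mask(gated, gate)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionExtinguishedError(
            f"selection extinguished population at gate {gate}"
        )
    if idx.size > config.n_sorted:
        idx = rng.choice(idx, size=config.n_sorted, replace=False)
    selected_ids = gated.data.loc[idx, "provenance"].to_numpy()
    counts = pd.Series(selected_ids).value_counts()
    lineages = [
        replace(l, abundance=int(counts.get(l.id, 0)))
        for l in population.lineages
        if counts.get(l.id, 0) > 0
    ]
    return Population(lineages)


def recover(population: Population, target_size: int, generations: float,
            seed: int) -> Population:
    """Regrow to ``target_size`` cells by growth-weighted resampling.

    Lineage weights are abundance x 2^(relative_growth x generations);
    the multinomial draw makes the post-recovery total exactly
    ``target_size``. In glycerol, mito-defective lineages (growth
    <= 0.1x) are strongly depleted.
    """
    if population.size == 0:
        raise SelectionExtinguishedError("population is empty")
    rng = np.random.default_rng(seed)
    weights = np.array(
        [l.abundance * 2.0 ** (l.growth_rate * generations) for l in population.lineages]
    )
    counts = rng.multinomial(target_size, weights / weights.sum())
    lineages = [replace(l, abundance=int(c))
                for l, c in zip(population.lineages, counts) if c > 0]
    return Population(lineages)


def _record(rows: list, step: str, population: Population,
            config: ProtocolConfig, seed: int) -> None:
    events = sample_events(population, min(population.size, 5000), seed)
    gated = cytometry.gate_pipeline(
        events, min_fsc=config.trigger, width_quantile=config.width_quantile,
        contour_fraction=config.contour_fraction,
        apply_doublet_gate=config.apply_doublet_gate,
    )
    fano_g = fano(gated.channel("GFP")).fano
    fano_m = fano(gated.channel("mCherry")).fano
    for klass, freq in population.class_frequencies().items():
        rows.append({
            "step": step, "lineage_class": klass, "frequency": freq,
            "fano_gfp": fano_g, "fano_mcherry": fano_m,
        })


def run_protocol(config: ProtocolConfig, seed: int) -> pd.DataFrame:
    """Run mutagenesis then ``n_rounds`` of the alternating sort schedule.

    Schedule per round: sort QII+QIV -> recover -> sort QI -> recover.
    Returns a tidy trajectory table (step, lineage_class, frequency,
    fano_gfp, fano_mcherry).
    """
    rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(rng.integers(2**31))

    wt = Lineage(0, "wild-type", config.wt_model, 1.0, config.founding_size)
    pop = Population([wt])
    rows: list[dict] = []
    _record(rows, "founding", pop, config, next_seed())

    pop = ems_mutagenize(pop, config.mutant_fraction, config.effects, next_seed())
    _record(rows, "post-EMS", pop, config, next_seed())

    for rnd in range(1, config.n_rounds + 1):
        for gate, tag in (("QII+QIV", "sortA"), ("QI", "sortB")):
            pop = sort_step(pop, gate, config, next_seed())
            _record(rows, f"round{rnd}-{tag}", pop, config, next_seed())
            pop = recover(pop, config.recovery_size,
                          config.recovery_generations, next_seed())
            _record(rows, f"round{rnd}-{tag}-recovered", pop, config, next_seed())
    return pd.DataFrame(rows)
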