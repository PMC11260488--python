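"""Flow-cytometry event tables and the three-stage gating scheme.

The analysis chain for dual-reporter noise measurements is a fixed
gate order: a forward-scatter trigger threshold that removes debris
and fluidic noise, an FSC-W doublet gate, a highest-density contour
gate on the FSC-A/SSC-A plane that keeps the physiologically uniform
core of the population, and finally a log-transform of the
fluorescence channels. Gates subset events but never reorder them, so
provenance labels attached by the synthetic generators stay aligned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: channels every event table must carry, in canonical column order
CHANNELS = ("FSC_A", "FSC_W", "SSC_A", "GFP", "mCherry")

#: forward-scatter trigger threshold (a.u.) used on the sorter
DEFAULT_TRIGGER = 2570.0


class EmptyPopulationError(ValueError):
    """Raised when a gate or statistic is asked to act on zero events."""


@dataclass(frozen=True)
class GateReport:
    """Record of one gating stage: counts in/out and the parameters used."""

    stage: str
    n_input: int
    n_output: int
    params: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_output > self.n_input:
            raise ValueError("gate cannot create events")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_output": self.n_output,
            "params": dict(self.params),
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class EventTable:
    """Rectangular per-event channel intensities plus gating provenance.

    ``data`` holds one row per event with the columns in :data:`CHANNELS`
    and optionally ``provenance`` (singlet/debris/doublet or a lineage
    label). ``log_channels`` flags which fluorescence channels have been
    log-transformed; ``history`` accumulates one :class:`GateReport` per
    applied stage.
    """

    data: pd.DataFrame
    log_channels: frozenset = frozenset()
    history: tuple[GateReport, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(
                f"event table missing channels {missing}; expected columns "
                f"{list(CHANNELS)} (+ optional 'provenance')"
            )
        for ch in self.log_channels:
            vals = self.data[ch].to_numpy()
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"log-transformed channel {ch} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"channel {name!r} not present; have {list(self.data.columns)}")
        return self.data[name].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray, report: GateReport) -> "EventTable":
        """Keep masked events (order preserved) and append the gate report."""
        return replace(
            self,
            data=self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            history=self.history + (report,),
        )

    def is_gated(self) -> bool:
        return len(self.history) > 0

    def history_json(self) -> str:
        return json.dumps([r.to_dict() for r in self.history], indent=2)


def trigger_threshold(
    events: EventTable, min_fsc: float = DEFAULT_TRIGGER
) -> tuple[EventTable, GateReport]:
    """Drop events with FSC-A strictly below the trigger threshold.

    Events exactly at the threshold are retained (only ``< min_fsc`` is
    excluded).
    """
    fsc = events.channel("FSC_A")
    mask = fsc >= min_fsc
    report = GateReport("trigger", events.n, int(mask.sum()), {"min_fsc": min_fsc})
    return events.subset(mask, report), report


def doublet_gate(
    events: EventTable, width_quantile: float = 0.90
) -> tuple[EventTable, GateReport]:
    """Remove events whose FSC-W exceeds the within-sample width quantile.

    Doublets and aggregates carry an inflated pulse width; the boundary is
    data-driven because no absolute width cutoff generalizes across
    instruments. With fewer than 10 events the quantile is unreliable and
    the gate is skipped with a warning.
    """
    if not 0.0 < width_quantile < 1.0:
        raise ValueError("width_quantile must lie in (0, 1)")
    params = {"width_quantile": width_quantile}
    if events.n < 10:
        msg = f"doublet gate skipped: only {events.n} events (<10), quantile unreliable"
        warnings.warn(msg, stacklevel=2)
        report = GateReport("doublet", events.n, events.n, params, (msg,))
        return events.subset(np.ones(events.n, dtype=bool), report), report
    width = events.channel("FSC_W")
    cutoff = float(np.quantile(width, width_quantile))
    mask = width <= cutoff
    report = GateReport(
        "doublet", events.n, int(mask.sum()), {**params, "cutoff": cutoff}
    )
    return events.subset(mask, report), report


def density_contour_gate(
    events: EventTable,
    channels: tuple[str, str] = ("FSC_A", "SSC_A"),
    fraction: float = 0.80,
    bins: int = 64,
) -> tuple[EventTable, GateReport]:
    """Retain the highest-density region holding ``fraction`` of events.

    A 2-D histogram is built on the two scatter channels; bins are
    admitted in order of decreasing occupancy (ties broken by (row,
    column) index, deterministically) until the admitted bins first hold
    at least ``fraction`` of the events. The retained fraction therefore
    overshoots by at most the mass of the last admitted bin.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if events.n < 100:
        raise EmptyPopulationError(
            f"contour gate needs >=100 events, got {events.n}"
        )
    warns: list[str] = []
    if events.n < bins:
        coarse = max(2, int(np.sqrt(events.n)))
        warns.append(f"grid coarsened from {bins} to {coarse} bins/axis for {events.n} events")
        warnings.warn(warns[-1], stacklevel=2)
        bins = coarse

    x = events.channel(channels[0])
    y = events.channel(channels[1])
    x_edges = np.linspace(x.min(), x.max(), bins + 1)
    y_edges = np.linspace(y.min(), y.max(), bins + 1)
    # events on the top edge belong to the last bin
    ix = np.clip(np.searchsorted(x_edges, x, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(y_edges, y, side="right") - 1, 0, bins - 1)
    flat = ix * bins + iy
    counts = np.bincount(flat, minlength=bins * bins)

    rows, cols = np.divmod(np.arange(bins * bins), bins)
    order = np.lexsort((cols, rows, -counts))
    cum = np.cumsum(counts[order])
    n_needed = fraction * events.n
    n_admit = int(np.searchsorted(cum, n_needed, side="left") + 1)
    admitted = np.zeros(bins * bins, dtype=bool)
    admitted[order[:n_admit]] = True

    mask = admitted[flat]
    report = GateReport(
        "contour",
        events.n,
        int(mask.sum()),
        {"channels": list(channels), "fraction": fraction, "bins": bins},
        tuple(warns),
    )
    return events.subset(mask, report), report


def log_transform(
    events: EventTable,
    channels: tuple[str, ...] = ("GFP", "mCherry"),
    base: float = 10.0,
) -> tuple[EventTable, GateReport]:
    """Log-transform fluorescence channels, dropping non-positive events.

    Events with a non-positive intensity in any requested channel cannot
    be transformed and are removed; their count is reported, with a
    warning if they exceed 5% of the input. Noise statistics downstream
    read the resulting scale flag, because the Fano factor is not
    invariant to the choice of log base.
    """
    if base <= 0 or base == 1.0:
        raise ValueError("log base must be positive and != 1")
    keep = np.ones(events.n, dtype=bool)
    for ch in channels:
        keep &= events.channel(ch) > 0
    n_dropped = int(events.n - keep.sum())
    warns: list[str] = []
    if events.n and n_dropped / events.n > 0.05:
        warns.append(
            f"{n_dropped}/{events.n} events non-positive in {channels}; "
            "check upstream gating"
        )
        warnings.warn(warns[-1], stacklevel=2)
    report = GateReport(
        "log_transform",
        events.n,
        int(keep.sum()),
        {"channels": list(channels), "base": base, "n_dropped_nonpositive": n_dropped},
        tuple(warns),
    )
    out = events.subset(keep, report)
    data = out.data.copy()
    for ch in channels:
        data[ch] = np.log(data[ch].to_numpy(dtype=float)) / np.log(base)
    return (
        replace(out, data=data, log_channels=out.log_channels | frozenset(channels)),
        report,
    )


def gate_pipeline(
    events: EventTable,
    min_fsc: float = DEFAULT_TRIGGER,
    width_quantile: float = 0.90,
    contour_fraction: float = 0.80,
    bins: int = 64,
    log_base: float = 10.0,
    apply_doublet_gate: bool = True,
) -> EventTable:
    """Apply the fixed pipeline: trigger -> doublet -> contour -> log."""
    out, _ = trigger_threshold(events, min_fsc)
    if out.n == 0:
        raise EmptyPopulationError("no events above trigger threshold")
    if apply_doublet_gate:
        out, _ = doublet_gate(out, width_quantile)
    out, _ = density_contour_gate(out, fraction=contour_fraction, bins=bins)
    out, _ = log_transform(out, base=log_base)
    if out.n == 0:
        raise EmptyPopulationError("empty population after gating")
    return out


def write_events(events: EventTable, path, header_comment: str | None = None) -> None:
    """Write an event table as CSV (event_id, channels, provenance)."""
    df = events.data.copy()
    df.insert(0, "event_id", np.arange(len(df)))
    if "provenance" not in df.columns:
        df["provenance"] = "unknown"
    df = df[["event_id", *CHANNELS, "provenance"]]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_events(path) -> EventTable:
    """Read a CSV event table written by :func:`write_events`."""
    df = pd.read_csv(path, comment="#")
    expected = {"event_id", *CHANNELS}
    unknown = set(df.columns) - expected - {"provenance"}
    missing = expected - set(df.columns)
    if unknown or missing:
        raise ValueError(
            f"unexpected event-table header: unknown={sorted(unknown)} "
            f"missing={sorted(missing)}; expected "
            f"event_id,{','.join(CHANNELS)}[,provenance]"
        )
    cols = [*CHANNELS] + (["provenance"] if "provenance" in df.columns else [])
    return EventTable(df[cols].reset_index(drop=True))
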