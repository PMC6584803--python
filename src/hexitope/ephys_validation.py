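"""Residual conductance from patch-clamp recordings and prediction concordance.

Membrane conductance is computed Ohmically on a constant voltage-command
window (the +40 mV depolarizing step): mean current over the window divided
by the command voltage, with pA / mV = nS.  Residual conductance is the
post-antibody conductance as a percentage of the pre-antibody (control)
conductance from the same protocol.  A blocked-condition recording (channels
blocked with divalent cations) can supply leak subtraction.

Concordance joins motif-based selectivity predictions with measured residual
conductances: an isoform counts as measured-inhibited when its residual is
below a cutoff (50% by default — the measured values split bimodally at
16-25% versus 73-98%, so any cutoff between the modes gives the same
classification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hexitope.errors import HexitopeError
from hexitope.motif_scan import SelectivityCall


@dataclass
class CurrentRecording:
    """One whole-cell recording: time (s), command voltage (mV), current (pA)."""

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (len(self.time) == len(self.voltage) == len(self.current)):
            raise HexitopeError("time, voltage and current series must have equal length")

    @classmethod
    def from_delimited(cls, path: str, condition: str = "control",
                       sep: str = "\t") -> "CurrentRecording":
        df = pd.read_csv(path, sep=sep, comment="#")
        cols = {c.lower(): c for c in df.columns}
        try:
            return cls(
                time=df[cols["time_s"]].to_numpy(),
                voltage=df[cols["voltage_mv"]].to_numpy(),
                current=df[cols["current_pa"]].to_numpy(),
                condition=condition,
            )
        except KeyError as exc:
            raise HexitopeError(
                f"{path}: expected columns time_s, voltage_mV, current_pA"
            ) from exc


def _window_mask(rec: CurrentRecording, step_window: tuple[float, float]) -> np.ndarray:
    t0, t1 = step_window
    mask = (rec.time >= t0) & (rec.time <= t1)
    if not mask.any():
        raise HexitopeError(f"window [{t0}, {t1}] s outside recording")
    return mask


def membrane_conductance(
    rec: CurrentRecording,
    step_window: tuple[float, float],
    leak: CurrentRecording | None = None,
    reversal_mv: float = 0.0,
) -> float:
    """Ohmic conductance (nS) on a constant-voltage window.

    ``leak``, when given, is a recording with the channels blocked under the
    same protocol; its conductance over the same window is subtracted.
    """
    mask = _window_mask(rec, step_window)
    v = rec.voltage[mask]
    if np.ptp(v) > 1e-6:
        raise HexitopeError("command voltage is not constant over the step window")
    v_cmd = float(v[0]) - reversal_mv
    if abs(v_cmd) < 1e-12:
        raise HexitopeError("zero driving voltage over the step window")
    g = float(rec.current[mask].mean()) / v_cmd  # pA / mV = nS
    if leak is not None:
        g -= membrane_conductance(leak, step_window, reversal_mv=reversal_mv)
    return g


def residual_conductance(
    pre: CurrentRecording,
    post: CurrentRecording,
    step_window: tuple[float, float],
    leak: CurrentRecording | None = None,
) -> float:
    """Post-antibody conductance as % of the pre-antibody conductance."""
    mask_pre = _window_mask(pre, step_window)
    mask_post = _window_mask(post, step_window)
    if not np.allclose(pre.voltage[mask_pre], post.voltage[mask_post]):
        raise HexitopeError("pre/post voltage protocols differ over the window")
    g_pre = membrane_conductance(pre, step_window, leak=leak)
    g_post = membrane_conductance(post, step_window, leak=leak)
    if g_pre <= 0:
        raise HexitopeError(f"non-positive control conductance ({g_pre:.3g} nS)")
    return 100.0 * g_post / g_pre


@dataclass
class ConductanceRecord:
    """Residual conductance (% of control) for one isoform."""

    isoform: str
    residual_pct: float
    source: str = "computed"  # "computed" | "bundled_reference_table"

    def __post_init__(self) -> None:
        if self.residual_pct < 0:
            raise HexitopeError("residual conductance cannot be negative")


def concordance_report(
    calls: list[SelectivityCall],
    records: list[ConductanceRecord],
    inhibition_cutoff: float = 50.0,
    aliases: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, float | None, dict[str, list[str]]]:
    """Join predictions with measurements and score agreement.

    ``aliases`` maps measurement isoform names onto prediction names (e.g.
    the composite name ``hCx30.2/31.3`` onto the motif table's ``hCx30.2``).
    Returns (per-isoform table, concordant fraction, unjoined names by
    side).  The fraction is ``None`` when the join is empty — never silently
    0 or 1.
    """
    aliases = aliases or {}
    by_isoform = {c.isoform: c for c in calls}
    rows = []
    unjoined_measured: list[str] = []
    joined_pred: set[str] = set()
    for rec in records:
        name = aliases.get(rec.isoform, rec.isoform)
        call = by_isoform.get(name)
        if call is None:
            unjoined_measured.append(rec.isoform)
            continue
        joined_pred.add(name)
        measured_inhibited = rec.residual_pct < inhibition_cutoff
        predicted_inhibited = call.predicted_class == "inhibited"
        rows.append(
            {
                "isoform": rec.isoform,
                "residual_pct": rec.residual_pct,
                "measured_inhibited": measured_inhibited,
                "predicted_class": call.predicted_class,
                "concordant": measured_inhibited == predicted_inhibited,
            }
        )
    unjoined_predicted = sorted(set(by_isoform) - joined_pred)
    table = pd.DataFrame(rows)
    fraction = float(table["concordant"].mean()) if len(table) else None
    unjoined = {"measured": unjoined_measured, "predicted": unjoined_predicted}
    return table, fraction, unjoined
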