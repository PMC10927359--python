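"""Impedance (cell-index) kinetics: plate I/O, baseline normalization,
sliding-window AUC and the 0/100 control-anchored AUC scale.

The readout is the "cell index" of an xCELLigence-style real-time cell
analyzer: an impedance-derived measure of monolayer integrity that drops
acutely on barrier disruption (e.g. thrombin) and recovers over hours.
Screens treat wells with kinase inhibitors shortly after thrombin; the
vehicle (DMSO) well anchors the normalized scale at 100.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("treking.kinetics")

CONTROL_ID = "DMSO"

PLATE_COLUMNS = ["time_min", "well", "inhibitor", "condition", "replicate", "cell_index"]


class PlateFormatError(ValueError):
    """Raised when a plate CSV violates the declared dialect."""


class PlateValidationError(ValueError):
    """Raised when plate contents violate a TimeSeriesPlate invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesPlate:
    """Annotated cell-index kinetics for one plate.

    times are minutes relative to inhibitor addition (t=0); negative times
    are pre-treatment samples. ``values`` is a (well, time) DataFrame whose
    index is well_id and whose columns are the times. ``wells`` maps
    well_id -> (inhibitor, condition, replicate).
    """

    times: np.ndarray
    wells: pd.DataFrame            # index well_id; columns inhibitor, condition, replicate
    values: pd.DataFrame           # index well_id; columns times
    thrombin_time_min: float = 0.0
    inhibitor_time_min: float = 0.0
    tnf_preconditioned: bool = False
    control_id: str = CONTROL_ID

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise PlateValidationError("times must be strictly increasing")
        if self.values.isna().any().any():
            raise PlateValidationError("every well must have a value at every time")
        if list(self.values.columns) != list(self.times):
            raise PlateValidationError("value columns must equal the time vector")
        if not self.values.index.equals(self.wells.index):
            raise PlateValidationError("values and wells must cover the same wells")
        if (self.wells["replicate"] < 1).any():
            raise PlateValidationError("replicate indices must be >= 1")
        inhibs = set(self.wells["inhibitor"])
        if self.control_id not in inhibs:
            raise PlateValidationError(
                f"control inhibitor {self.control_id!r} absent from plate"
            )

    @property
    def inhibitors(self) -> list[str]:
        seen: dict[str, None] = {}
        for x in self.wells["inhibitor"]:
            seen.setdefault(x, None)
        return list(seen)

    def mean_by_inhibitor(self) -> pd.DataFrame:
        """Average cell index across replicate wells per inhibitor."""
        return self.values.groupby(self.wells["inhibitor"]).mean()

    def well_series(self, well_id: str) -> tuple[np.ndarray, np.ndarray]:
        return self.times, self.values.loc[well_id].to_numpy(dtype=float)


@dataclass
class WindowGrid:
    """Ordered sliding windows (start, end, midpoint) of fixed width.

    First-phase starts advance by ``fine_step`` up to ``fine_span``; later
    starts advance by ``coarse_step`` — the acquisition cadence of a 2 h
    per-minute / 4 h per-5-minute impedance time course.
    """

    windows: list[tuple[float, float, float]]
    width_min: float = 5.0

    def __post_init__(self) -> None:
        mids = [w[2] for w in self.windows]
        if len(set(mids)) != len(mids) or any(
            b <= a for a, b in zip(mids, mids[1:])
        ):
            raise ValueError("window midpoints must be strictly increasing and unique")
        for s, e, m in self.windows:
            if abs((e - s) - self.width_min) > 1e-9:
                raise ValueError("every window must have the declared width")
            if abs(m - (s + self.width_min / 2)) > 1e-9:
                raise ValueError("midpoint must be start + width/2")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows])

    def index_range_for_minutes(self, t0: float, t1: float) -> tuple[int, int]:
        """Inclusive window-index range whose midpoints fall in [t0, t1]."""
        mids = self.midpoints
        idx = np.nonzero((mids >= t0) & (mids <= t1))[0]
        if idx.size == 0:
            raise ValueError(f"no window midpoint in [{t0}, {t1}]")
        return int(idx[0]), int(idx[-1])


@dataclass
class AUCMatrix:
    """Per-window AUC per inhibitor, raw and on the 0/100 anchored scale.

    In each window column of ``normalized`` the control row is 100 and,
    whenever the most negative control-subtracted AUC (min_delta) is < 0,
    the minimum over inhibitors is 0.
    """

    raw: pd.DataFrame              # index inhibitor, columns window midpoints
    normalized: pd.DataFrame
    control_id: str
    min_delta: pd.Series = field(default=None)  # per-window m = min(delta)
    grid: WindowGrid | None = None

    def __post_init__(self) -> None:
        if self.raw.shape != self.normalized.shape:
            raise ValueError("raw and normalized must share shape")
        if not (self.raw.index.equals(self.normalized.index)
                and self.raw.columns.equals(self.normalized.columns)):
            raise ValueError("raw and normalized must share index labels")


# ---------------------------------------------------------------------------
# Plate I/O (long-format CSV with a commented metadata header)
# ---------------------------------------------------------------------------

def write_plate(plate: TimeSeriesPlate, path) -> None:
    """Write a plate as long-format CSV with a commented metadata block."""
    with open(path, "w") as fh:
        fh.write(f"# thrombin_time_min={plate.thrombin_time_min}\n")
        fh.write(f"# inhibitor_time_min={plate.inhibitor_time_min}\n")
        fh.write(f"# tnf_preconditioned={plate.tnf_preconditioned}\n")
        fh.write(f"# control_id={plate.control_id}\n")
        long = (
            plate.values.reset_index(names="well")
            .melt(id_vars="well", var_name="time_min", value_name="cell_index")
            .merge(plate.wells.reset_index(names="well"), on="well")
        )
        long = long[PLATE_COLUMNS].sort_values(["well", "time_min"])
        long.to_csv(fh, index=False)


def read_plate(path) -> TimeSeriesPlate:
    """Read a long-format plate CSV (see :func:`write_plate`) and validate it."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").rstrip("\n").partition("=")
                meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plate CSV missing column(s): {', '.join(missing)}")
    if df[PLATE_COLUMNS].isna().any().any():
        raise PlateFormatError("plate CSV contains missing cells")
    dup = df.duplicated(subset=["well", "time_min"])
    if dup.any():
        raise PlateValidationError("duplicated (well, time) rows in plate CSV")

    values = df.pivot(index="well", columns="time_min", values="cell_index")
    if values.isna().any().any():
        raise PlateValidationError("every well must have a value at every time")
    wells = (
        df[["well", "inhibitor", "condition", "replicate"]]
        .drop_duplicates()
        .set_index("well")
        .loc[values.index]
    )
    wells["replicate"] = wells["replicate"].astype(int)
    return TimeSeriesPlate(
        times=values.columns.to_numpy(dtype=float),
        wells=wells,
        values=values,
        thrombin_time_min=float(meta.get("thrombin_time_min", 0.0)),
        inhibitor_time_min=float(meta.get("inhibitor_time_min", 0.0)),
        tnf_preconditioned=meta.get("tnf_preconditioned", "False") == "True",
        control_id=meta.get("control_id", CONTROL_ID),
    )


# ---------------------------------------------------------------------------
# Normalization and windowing
# ---------------------------------------------------------------------------

def normalize_baseline(plate: TimeSeriesPlate, mode: str = "delta") -> TimeSeriesPlate:
    """Zero each well at the last sample strictly before thrombin addition.

    mode="delta" subtracts the reference value (scale-preserving);
    mode="ratio_minus_one" divides by it and subtracts 1 (the instrument
    convention). Both leave the reference time at exactly 0.
    """
    pre = np.nonzero(plate.times < plate.thrombin_time_min)[0]
    if pre.size == 0:
        raise PlateValidationError("no sample strictly before thrombin addition")
    ref_col = plate.values.columns[pre[-1]]
    ref = plate.values[ref_col]
    if mode == "delta":
        values = plate.values.sub(ref, axis=0)
    elif mode == "ratio_minus_one":
        if (ref == 0).any():
            raise PlateValidationError("zero reference cell index; cannot take ratio")
        values = plate.values.div(ref, axis=0) - 1.0
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return TimeSeriesPlate(
        times=plate.times,
        wells=plate.wells.copy(),
        values=values,
        thrombin_time_min=plate.thrombin_time_min,
        inhibitor_time_min=plate.inhibitor_time_min,
        tnf_preconditioned=plate.tnf_preconditioned,
        control_id=plate.control_id,
    )


def enumerate_windows(
    total_min: float,
    width: float = 5.0,
    fine_step: float = 1.0,
    fine_span: float = 120.0,
    coarse_step: float = 5.0,
) -> WindowGrid:
    """Sliding windows over [0, total_min]: fine steps first, coarse after.

    Starts are 0..(fine_span-width) by fine_step, then fine_span..
    (total_min-width) by coarse_step; spans not divisible by the step
    truncate the last start downward.
    """
    if width > total_min:
        raise ValueError("window width exceeds the total span")
    if fine_span > total_min:
        raise ValueError("fine_span exceeds the total span")
    starts: list[float] = []
    s = 0.0
    while s <= fine_span - width + 1e-9:
        starts.append(s)
        s += fine_step
    s = fine_span
    while s <= total_min - width + 1e-9:
        starts.append(s)
        s += coarse_step
    windows = [(s, s + width, s + width / 2) for s in starts]
    return WindowGrid(windows=windows, width_min=width)


def window_auc(times: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> float:
    """Trapezoidal AUC of one well's trace over [start, end].

    Boundary values not on the sample grid are linearly interpolated, so the
    result is exact for piecewise-linear signals and additive over adjacent
    windows.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 samples")
    start, end = window
    if start < times[0] - 1e-9 or end > times[-1] + 1e-9:
        raise ValueError(f"window {window} outside sampled range "
                         f"[{times[0]}, {times[-1]}]")
    inside = (times > start) & (times < end)
    t = np.concatenate(([start], times[inside], [end]))
    v = np.interp(t, times, values)
    return float(np.trapezoid(v, t))


def normalize_auc(
    raw_column: pd.Series, control_id: str = CONTROL_ID
) -> tuple[pd.Series, float]:
    """Anchor one window's AUC column: control -> 100, most negative
    control-subtracted AUC -> 0.

    delta_i = AUC_i − AUC_control; with m = min(delta) < 0 the affine map
    100·(delta−m)/(−m) fixes the two anchors. If m >= 0 (no inhibitor below
    control) the unscaled fallback 100 + delta keeps the control anchor.
    """
    if control_id not in raw_column.index:
        raise KeyError(f"control {control_id!r} missing from AUC column")
    delta = raw_column - raw_column[control_id]
    m = float(delta.min())
    if m < 0:
        # divide first: (delta-m)/(-m) is exactly 1 at the control and
        # exactly 0 at the minimum, so the anchors hold bit-exactly
        normalized = 100.0 * ((delta - m) / (-m))
    else:
        logger.warning(
            "no AUC below control in this window (min_delta=%g); "
            "using unscaled fallback 100 + delta", m)
        warnings.warn("min_delta >= 0: unscaled AUC normalization fallback",
                      stacklevel=2)
        normalized = 100.0 + delta
    return normalized, m


def compute_auc_matrix(
    plate: TimeSeriesPlate,
    grid: WindowGrid,
    per_replicate: bool = False,
) -> AUCMatrix:
    """Windowed, normalized AUC matrix for a baseline-normalized plate.

    Cell index is averaged across replicates per inhibitor before AUC unless
    ``per_replicate``; each window column is then anchored by
    :func:`normalize_auc`.
    """
    traces = plate.values if per_replicate else plate.mean_by_inhibitor()
    times = plate.times
    raw = pd.DataFrame(
        {
            mid: [window_auc(times, traces.loc[r].to_numpy(), (s, e))
                  for r in traces.index]
            for s, e, mid in grid.windows
        },
        index=traces.index,
    )
    norm_cols: dict[float, pd.Series] = {}
    min_deltas: dict[float, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mid in raw.columns:
            norm_cols[mid], min_deltas[mid] = normalize_auc(raw[mid], plate.control_id)
    normalized = pd.DataFrame(norm_cols, index=raw.index)
    return AUCMatrix(
        raw=raw,
        normalized=normalized,
        control_id=plate.control_id,
        min_delta=pd.Series(min_deltas),
        grid=grid,
    )


def write_auc_matrix(auc: AUCMatrix, path) -> None:
    """Write the normalized AUC matrix with window midpoints as headers."""
    auc.normalized.to_csv(path, index_label="inhibitor")


def read_auc_matrix(path, control_id: str = CONTROL_ID) -> AUCMatrix:
    df = pd.read_csv(path, index_col="inhibitor")
    df.columns = df.columns.astype(float)
    return AUCMatrix(raw=df.copy(), normalized=df, control_id=control_id)
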