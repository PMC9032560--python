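"""Volumetric capnogram construction and feature extraction.

A single-breath recording pairs an expired CO2 partial-pressure series
(mmHg) with an expiratory flow series (L/s), both sampled at ``fs`` Hz.
Integrating flow over time places CO2 on an expired-volume axis; the
resulting CO2-vs-volume curve (the volumetric capnogram) divides into
three phases:

* phase I   -- airway dead-space gas, CO2 near a low baseline;
* phase II  -- the steep transitional rise (slope S2);
* phase III -- the alveolar plateau (slope S3).

Ten summary features are computed from two fitted phase lines: the
phase I/II boundary (C12, V12), the phase II/III boundary (C23, V23),
the phase volumes (V2, V3), the slopes (S2, S3, S3/S2) and the interior
angle between the two lines (Angle23).

The segmentation windows are not uniquely standardized; the defaults
here follow common capnovolumetric practice and are configurable
through :class:`ExtractionConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ExtractionError, SchemaError

__all__ = [
    "CapnogramTrace",
    "CapnoFeatures",
    "PhaseLines",
    "ExtractionConfig",
    "integrate_volume",
    "fit_phase_lines",
    "compute_features",
    "read_breath_csv",
    "write_breath_csv",
    "features_to_frame",
]

#: Column order used for feature CSV output (Table-style names).
FEATURE_COLUMNS = (
    "C12", "C23", "V12", "V23", "V2", "V3", "S2", "S3", "S3_over_S2", "Angle23",
)

BREATH_CSV_COLUMNS = ("time_s", "co2_mmHg", "flow_lps")


def integrate_volume(flow: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative expired volume (mL) from an expiratory flow series (L/s).

    Trapezoidal integration over time; negative flow excursions (sensor
    noise around zero) are clipped so the volume axis is non-decreasing.

    Parameters
    ----------
    flow : array-like of float
        Expiratory flow in L/s.
    fs : float
        Sampling frequency in Hz, must be positive.

    Returns
    -------
    numpy.ndarray
        Volume in mL, same length as ``flow``, first element 0.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.size == 0:
        raise ValueError("flow series is empty")
    if not np.isfinite(fs) or fs <= 0:
        raise ValueError(f"sampling frequency must be positive, got {fs}")
    clipped = np.maximum(flow, 0.0)
    vol_l = cumulative_trapezoid(clipped, dx=1.0 / fs, initial=0.0)
    return vol_l * 1000.0


@dataclass
class CapnogramTrace:
    """One expiration: CO2 (mmHg) and expiratory flow (L/s) at ``fs`` Hz.

    ``volume`` (mL, cumulative, non-decreasing) is derived from ``flow``
    on construction unless supplied explicitly.
    """

    co2: np.ndarray
    flow: np.ndarray
    fs: float = 200.0
    volume: np.ndarray | None = None

    def __post_init__(self):
        self.co2 = np.asarray(self.co2, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.co2.ndim != 1 or self.flow.ndim != 1:
            raise ValueError("co2 and flow must be 1-D")
        if self.co2.size != self.flow.size:
            raise ValueError(
                f"co2 ({self.co2.size}) and flow ({self.flow.size}) lengths differ"
            )
        if self.co2.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(self.co2 < 0):
            raise ValueError("CO2 partial pressure cannot be negative")
        if self.volume is None:
            self.volume = integrate_volume(self.flow, self.fs)
        else:
            self.volume = np.asarray(self.volume, dtype=float)
            if self.volume.size != self.co2.size:
                raise ValueError("volume length mismatch")
            if np.any(np.diff(self.volume) < -1e-9):
                raise ValueError("volume must be non-decreasing")

    def __len__(self) -> int:
        return self.co2.size

    @property
    def end_expired_volume(self) -> float:
        """Total expired volume in mL."""
        return float(self.volume[-1])


@dataclass(frozen=True)
class CapnoFeatures:
    """The ten volumetric-capnography summary features.

    Units: C12/C23 in mmHg, V12/V23/V2/V3 in mL, S2/S3 in mmHg/L,
    S3_over_S2 dimensionless, Angle23 in degrees.
    """

    C12: float
    C23: float
    V12: float
    V23: float
    V2: float
    V3: float
    S2: float
    S3: float
    S3_over_S2: float
    Angle23: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)


@dataclass(frozen=True)
class PhaseLines:
    """Least-squares phase II/III lines in (volume L, CO2 mmHg) space."""

    slope2: float       # mmHg/L
    intercept2: float   # mmHg
    slope3: float       # mmHg/L
    intercept3: float   # mmHg
    end_volume: float   # mL
    end_tidal: float    # mmHg


@dataclass(frozen=True)
class ExtractionConfig:
    """Segmentation windows for phase-line fitting.

    ``phase3_window``: fraction of total expired volume over which the
    alveolar plateau is fitted.  ``phase2_band``: CO2 band, as fractions
    of the end-tidal value, through which the transitional rise is
    fitted.  ``baseline_fraction``: leading volume fraction averaged to
    define the phase I baseline.  ``knee_margin``: CO2 clearance (mmHg)
    below the extrapolated phase III line required for a sample to count
    as phase II (keeps plateau samples out of the rise fit when the CO2
    band overlaps the plateau).
    """

    phase3_window: tuple[float, float] = (0.60, 0.95)
    phase2_band: tuple[float, float] = (0.25, 0.75)
    baseline_fraction: float = 0.05
    end_tidal_fraction: float = 0.05
    knee_margin: float = 1.0


def _fit_line(volume_l: np.ndarray, co2: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(volume_l, co2, 1)
    return float(slope), float(intercept)


def fit_phase_lines(
    trace: CapnogramTrace, config: ExtractionConfig = ExtractionConfig()
) -> PhaseLines:
    """Fit the phase II and phase III lines of a volumetric capnogram.

    Phase III is fitted over the configured expired-volume window
    (default 60-95 %).  Phase II is fitted over the contiguous run of
    samples whose CO2 lies between the configured fractions of the
    end-tidal value (default 25-75 %) and which sit clearly below the
    extrapolated phase III line; the run starts at the first upward
    crossing of the lower band edge and stops as soon as either
    condition fails, so alveolar-plateau samples cannot leak into the
    rise fit.

    Raises
    ------
    ExtractionError
        If either fitting window holds fewer than 3 samples, or the
        fitted phase II slope is not positive.
    """
    vol = trace.volume
    co2 = trace.co2
    ve = trace.end_expired_volume
    if ve <= 0:
        raise ExtractionError("no expired volume", window="volume axis")

    # End-tidal CO2: mean over the trailing volume fraction.
    et_mask = vol >= (1.0 - config.end_tidal_fraction) * ve
    end_tidal = float(np.mean(co2[et_mask]))
    if end_tidal <= 1.0:
        raise ExtractionError(
            f"end-tidal CO2 {end_tidal:.2f} mmHg too low for segmentation",
            window="end-tidal",
        )

    # Phase III: plateau over the volume window.
    lo3, hi3 = config.phase3_window
    mask3 = (vol >= lo3 * ve) & (vol <= hi3 * ve)
    if int(mask3.sum()) < 3:
        raise ExtractionError(
            "fewer than 3 samples in the phase III volume window "
            f"[{lo3:.0%}, {hi3:.0%}] of expired volume",
            window="phase III",
        )
    s3, b3 = _fit_line(vol[mask3] / 1000.0, co2[mask3])

    # Phase II: contiguous rise through the CO2 band, below the
    # extrapolated plateau line.
    lo2, hi2 = config.phase2_band
    lo_thr = lo2 * end_tidal
    hi_thr = hi2 * end_tidal
    above = np.flatnonzero(co2 >= lo_thr)
    if above.size == 0:
        raise ExtractionError(
            "CO2 never reaches the lower phase II band edge", window="phase II"
        )
    start = int(above[0])
    idx = []
    for i in range(start, len(co2)):
        line_val = s3 * vol[i] / 1000.0 + b3
        if co2[i] > hi_thr or co2[i] > line_val - config.knee_margin:
            break
        idx.append(i)
    if len(idx) < 3:
        raise ExtractionError(
            "fewer than 3 samples in the phase II CO2 band "
            f"[{lo2:.0%}, {hi2:.0%}] of end-tidal",
            window="phase II",
        )
    idx = np.asarray(idx)
    s2, b2 = _fit_line(vol[idx] / 1000.0, co2[idx])
    if s2 <= 0:
        raise ExtractionError(
            f"non-positive phase II slope ({s2:.3f} mmHg/L)", window="phase II"
        )
    return PhaseLines(s2, b2, s3, b3, ve, end_tidal)


def compute_features(
    trace: CapnogramTrace, config: ExtractionConfig = ExtractionConfig()
) -> CapnoFeatures:
    """Extract the ten capnogram features from a single-breath trace.

    The phase I baseline is the mean CO2 over the leading volume
    fraction (default 5 %).  The phase I/II boundary is the intersection
    of the phase II line with that baseline; the phase II/III boundary
    is the intersection of the two fitted lines.  Angle23 is the
    interior angle at the knee, ``180 - atan(S2) + atan(S3)`` with
    slopes taken in mmHg/L (no axis renormalization).
    """
    if np.any(np.diff(trace.volume) < -1e-9):
        raise ValueError("volume must be non-decreasing")
    lines = fit_phase_lines(trace, config)
    ve = lines.end_volume

    base_mask = trace.volume <= config.baseline_fraction * ve
    if not np.any(base_mask):
        base_mask = np.zeros(len(trace), dtype=bool)
        base_mask[0] = True
    baseline = float(np.mean(trace.co2[base_mask]))

    c12 = baseline
    v12 = (baseline - lines.intercept2) / lines.slope2 * 1000.0  # mL

    denom = lines.slope2 - lines.slope3
    if abs(denom) < 1e-12:
        raise ExtractionError("phase II and III lines are parallel", window="knee")
    v23 = (lines.intercept3 - lines.intercept2) / denom * 1000.0  # mL
    c23 = lines.slope2 * v23 / 1000.0 + lines.intercept2
    if v23 < v12:
        raise ExtractionError(
            f"phase boundaries out of order (V12={v12:.0f} mL > V23={v23:.0f} mL)",
            window="knee",
        )
    v2 = v23 - v12
    v3 = max(ve - v23, 0.0)
    s2, s3 = lines.slope2, lines.slope3
    angle = 180.0 - np.degrees(np.arctan(s2)) + np.degrees(np.arctan(s3))
    return CapnoFeatures(
        C12=c12, C23=c23, V12=v12, V23=v23, V2=v2, V3=v3,
        S2=s2, S3=s3, S3_over_S2=s3 / s2, Angle23=float(angle),
    )


def read_breath_csv(path: str | Path, fs: float = 200.0) -> CapnogramTrace:
    """Read a per-breath device export (columns time_s, co2_mmHg, flow_lps)."""
    df = pd.read_csv(path)
    missing = [c for c in BREATH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"breath CSV {path} is missing columns: {missing}")
    if len(df) >= 2:
        dt = np.diff(df["time_s"].to_numpy())
        if np.all(dt > 0):
            fs = float(1.0 / np.median(dt))
    return CapnogramTrace(
        co2=df["co2_mmHg"].to_numpy(), flow=df["flow_lps"].to_numpy(), fs=fs
    )


def write_breath_csv(path: str | Path, trace: CapnogramTrace) -> None:
    t = np.arange(len(trace)) / trace.fs
    pd.DataFrame(
        {"time_s": t, "co2_mmHg": trace.co2, "flow_lps": trace.flow}
    ).to_csv(path, index=False, float_format="%.5f")


def features_to_frame(features: list[CapnoFeatures]) -> pd.DataFrame:
    """Stack feature records into a DataFrame with Table-style column names."""
    return pd.DataFrame(
        [f.as_array() for f in features], columns=list(FEATURE_COLUMNS)
    )
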