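"""Counts-to-quantity conversion and measurement characterisation.

OD is decadic absorbance relative to a per-experiment blank,
``OD = -log10(counts / blank_counts)``.  Because the instrument's short
vertical light path reads roughly half the OD of a cuvette-geometry
reference instrument, a per-well log-linear transform
``ln(od_instrument + 1) = m * od_reference + b`` is fitted once on a bead
dilution series and inverted in later experiments,
``adjusted = (ln(r + 1) - b) / m``, to put readings on the reference scale.
The natural log is used throughout the transform.

The dilution-series characterisation reports, per well: sensitivity (slope
of counts vs concentration over the linear range), the 3-sigma-blank limit
of detection, the upper end of the linear range, fit R^2, and dynamic range
(linear_upper / LOD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wells import N_WELLS, WELLS


def compute_od(counts, blank_counts):
    """Decadic absorbance -log10(counts / blank); 0 at the blank itself.

    Strictly decreasing in counts.  Nonpositive counts indicate a saturated
    or dark well and are rejected.
    """
    c = np.asarray(counts, dtype=float)
    b = np.asarray(blank_counts, dtype=float)
    if np.any(c <= 0) or np.any(b <= 0):
        raise ValueError("counts and blank_counts must be > 0 "
                         "(saturated or dark well?)")
    od = -np.log10(c / b)
    return float(od) if od.ndim == 0 else od


@dataclass
class ODTransform:
    """Per-well log-linear map from instrument OD to reference OD."""

    slope: np.ndarray      # m, one per well
    intercept: np.ndarray  # b
    r2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("slope", "intercept", "r2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_WELLS,):
                raise ValueError(f"{name}: expected {N_WELLS} values")
            setattr(self, name, arr)
        if np.any(self.slope == 0):
            raise ValueError("slopes must be nonzero")

    def to_csv(self, path) -> None:
        pd.DataFrame({"well": WELLS, "m": self.slope, "b": self.intercept,
                      "r2": self.r2}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ODTransform":
        df = pd.read_csv(path)
        if list(df["well"]) != list(WELLS):
            raise ValueError(f"{path}: wells must be A1..H12 row-major")
        return cls(df["m"].to_numpy(float), df["b"].to_numpy(float),
                   df["r2"].to_numpy(float))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS y ~ x returning (slope, intercept, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate fit: all x values equal")
    sxy = np.sum((x - xm) * (y - ym))
    m = sxy / sxx
    b = ym - m * xm
    syy = np.sum((y - ym) ** 2)
    r2 = 1.0 if syy == 0 else float(1.0 - np.sum((y - (m * x + b)) ** 2) / syy)
    return float(m), float(b), r2


def fit_od_transform(od_instrument: np.ndarray,
                     od_reference: np.ndarray) -> ODTransform:
    """Fit ln(od_instrument + 1) ~ od_reference per well by OLS.

    od_instrument is (k, 96): k dilutions for each of 96 wells.
    od_reference is (k,) shared reference values or (k, 96) per-well.
    Needs at least 3 paired points per well and reference values spanning
    more than one dilution step.
    """
    y = np.log1p(np.asarray(od_instrument, dtype=float))
    if y.ndim != 2 or y.shape[1] != N_WELLS:
        raise ValueError("od_instrument must be (k, 96)")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 paired points per well")
    x = np.asarray(od_reference, dtype=float)
    if x.ndim == 1:
        x = np.broadcast_to(x[:, None], y.shape)
    if x.shape != y.shape:
        raise ValueError("od_reference shape mismatch")
    slopes = np.empty(N_WELLS)
    intercepts = np.empty(N_WELLS)
    r2 = np.empty(N_WELLS)
    for i in range(N_WELLS):
        slopes[i], intercepts[i], r2[i] = _ols(x[:, i], y[:, i])
    return ODTransform(slopes, intercepts, r2)


def adjust_od(r, m, b):
    """Invert the log-linear transform: adjusted = (ln(r + 1) - b) / m."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= -1):
        raise ValueError("instrument OD must be > -1")
    if np.any(np.asarray(m, dtype=float) == 0):
        raise ValueError("slope m must be nonzero")
    out = (np.log1p(r) - b) / m
    return float(out) if out.ndim == 0 else out


@dataclass
class DilutionSeriesResult:
    """Per-well fluorescence characterisation statistics."""

    sensitivity: np.ndarray   # counts per µg/mL
    lod: np.ndarray           # µg/mL
    linear_upper: np.ndarray  # µg/mL
    r2: np.ndarray
    dynamic_range: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sensitivity", "lod", "linear_upper", "r2",
                     "dynamic_range"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        if np.any(self.sensitivity <= 0) or np.any(self.lod <= 0):
            raise ValueError("sensitivity and lod must be > 0")
        if np.any(self.linear_upper < self.lod):
            raise ValueError("linear_upper must be >= lod")

    def summary(self) -> dict[str, float]:
        """Mean +/- SD style aggregation across the 96 wells."""
        out = {}
        for name in ("sensitivity", "lod", "linear_upper", "r2",
                     "dynamic_range"):
            arr = getattr(self, name)
            out[f"{name}_mean"] = float(arr.mean())
            out[f"{name}_sd"] = float(arr.std(ddof=1))
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame({"well": WELLS, "sensitivity": self.sensitivity,
                      "lod": self.lod, "linear_upper": self.linear_upper,
                      "r2": self.r2,
                      "dynamic_range": self.dynamic_range}).to_csv(
                          path, index=False)


#: Minimum R^2 for a fit to count as linear when growing the linear range.
LINEAR_R2_MIN = 0.99


def characterize_dilution_series(concs, counts_per_well,
                                 blank_counts,
                                 r2_min: float = LINEAR_R2_MIN
                                 ) -> DilutionSeriesResult:
    """Fluorescence characterisation from a dye dilution series.

    Parameters
    ----------
    concs : (k,) strictly increasing concentrations (µg/mL), k >= 4.
    counts_per_well : (k, 96) averaged counts at each concentration.
    blank_counts : (n_blank, 96) replicated blank readings; their SD sets
        the detection limit, LOD = 3 x SD(blank) / sensitivity.

    The linear range is grown from the low-concentration end: starting from
    the three lowest points, higher concentrations are appended while the
    per-well linear fit keeps R^2 >= ``r2_min``; ``linear_upper`` is the
    largest concentration retained.  Sensitivity and R^2 come from the fit
    over that range, and dynamic_range = linear_upper / LOD.
    """
    concs = np.asarray(concs, dtype=float)
    counts = np.asarray(counts_per_well, dtype=float)
    blanks = np.atleast_2d(np.asarray(blank_counts, dtype=float))
    if concs.ndim != 1 or concs.size < 4:
        raise ValueError("need at least 4 concentrations")
    if np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if counts.shape != (concs.size, N_WELLS):
        raise ValueError("counts_per_well must be (k, 96)")
    if blanks.shape[0] < 2 or blanks.shape[1] != N_WELLS:
        raise ValueError("need >= 2 replicated blank readings per well")

    k = concs.size
    sens = np.empty(N_WELLS)
    r2s = np.empty(N_WELLS)
    upper = np.empty(N_WELLS)
    for i in range(N_WELLS):
        best = None
        for stop in range(3, k + 1):
            m, b, r2 = _ols(concs[:stop], counts[:stop, i])
            if r2 < r2_min:
                break
            best = (m, r2, concs[stop - 1])
        if best is None or best[0] <= 0:
            raise ValueError(
                f"no linear region found for well {WELLS[i]} "
                f"(first-3-point R^2 below {r2_min} or nonpositive slope)")
        sens[i], r2s[i], upper[i] = best
    blank_sd = blanks.std(axis=0, ddof=1)
    # a perfectly noise-free blank has no defined detection limit
    lod = np.where(blank_sd > 0, 3.0 * blank_sd / sens, np.nan)
    return DilutionSeriesResult(sensitivity=sens, lod=lod, linear_upper=upper,
                                r2=r2s, dynamic_range=upper / lod)
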