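"""Multi-echo relaxometry: voxelwise mono-exponential R2/R2* estimation,
ROI summaries and linear iron calibration.

The signal model is S(TE) = S0 * exp(-R * TE) with TE in milliseconds at the
interface and seconds internally, so rates come out in s^-1. The default
estimator log-linearizes (OLS of ln S on TE) after discarding echoes at or
below the noise floor; a nonlinear least-squares refinement from the
log-linear start is available for noisy data. Negative fitted rates are
clamped to zero and flagged rather than dropped, so maps stay complete.

Iron conversion is a user-supplied affine calibration (rate in s^-1 to a
concentration); no default coefficients ship because the published
conversion is a calculator, not a pair of numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EchoSeries",
    "RelaxMap",
    "ROIMask",
    "CalibrationLine",
    "VoxelFit",
    "fit_monoexponential",
    "map_relaxation",
    "roi_summary",
    "multi_roi_representative",
    "apply_iron_calibration",
    "save_volume",
    "load_volume",
]

MS_PER_S = 1000.0

REASON_OK = ""
REASON_TOO_FEW = "insufficient echoes"
REASON_CLAMPED = "negative rate clamped to 0"


@dataclass
class EchoSeries:
    """Signal volumes across echoes: ``signal`` has shape (n_echoes, *grid)."""

    te_ms: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.te_ms = np.asarray(self.te_ms, float)
        self.signal = np.asarray(self.signal, float)
        if self.te_ms.ndim != 1 or len(self.te_ms) < 3:
            raise ValueError("need at least 3 echo times")
        if np.any(self.te_ms <= 0) or np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.signal.shape[0] != len(self.te_ms):
            raise ValueError("signal leading dimension must match echo count")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.signal.shape[1:]


@dataclass
class RelaxMap:
    """Voxelwise fit results on the acquisition grid."""

    rate: np.ndarray  # s^-1
    s0: np.ndarray
    r_squared: np.ndarray
    n_echoes_used: np.ndarray
    valid: np.ndarray
    reason: np.ndarray  # string codes, "" where clean

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.rate.shape


@dataclass
class ROIMask:
    labels: np.ndarray  # integer label per voxel
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        unknown = set(np.unique(self.labels)) - set(self.label_names) - {0}
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from the dictionary")


@dataclass
class CalibrationLine:
    slope: float
    intercept: float
    input_unit: str = "s^-1"
    output_unit: str = "a.u."

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("calibration coefficients must be finite")


@dataclass
class VoxelFit:
    s0: float
    rate: float  # s^-1
    r_squared: float
    n_used: int
    valid: bool
    reason: str


def _r_squared(signal: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((signal - pred) ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_monoexponential(
    te_ms: np.ndarray,
    signal: np.ndarray,
    method: str = "loglinear",
    noise_floor: float = 0.0,
) -> VoxelFit:
    """Fit S(TE) = S0 exp(-R TE) for one voxel.

    Echoes with signal <= ``noise_floor`` (or <= 0) are excluded; fewer than
    3 usable echoes yields an invalid result with reason "insufficient
    echoes". ``method='nonlinear'`` refines the log-linear start by
    least squares on the signal scale.
    """
    te_s = np.asarray(te_ms, float) / MS_PER_S
    signal = np.asarray(signal, float)
    usable = signal > max(noise_floor, 0.0)
    n_used = int(usable.sum())
    if n_used < 3:
        return VoxelFit(np.nan, np.nan, np.nan, n_used, False, REASON_TOO_FEW)
    t = te_s[usable]
    s = signal[usable]
    # OLS of ln S on TE
    slope, intercept = np.polyfit(t, np.log(s), 1)
    rate = -float(slope)
    s0 = float(np.exp(intercept))
    if method == "nonlinear":
        def resid(p):
            return p[0] * np.exp(-p[1] * t) - s
        sol = optimize.least_squares(resid, x0=[s0, rate], method="lm")
        s0, rate = float(sol.x[0]), float(sol.x[1])
    elif method != "loglinear":
        raise ValueError("method must be 'loglinear' or 'nonlinear'")
    reason = REASON_OK
    if rate < 0:
        rate = 0.0
        reason = REASON_CLAMPED
    pred = s0 * np.exp(-rate * t)
    return VoxelFit(s0, rate, _r_squared(s, pred), n_used, True, reason)


def _vectorized_loglinear(
    te_s: np.ndarray, flat: np.ndarray, noise_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Masked per-voxel OLS of ln S on TE over all voxels at once.

    ``flat`` is (n_echoes, n_voxels). Returns (s0, rate, r2, n_used).
    """
    usable = flat > max(noise_floor, 0.0)
    n_used = usable.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, flat, 1.0)), 0.0)
    t = te_s[:, None] * usable
    sw = n_used.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_t = t.sum(axis=0) / sw
        mean_y = logs.sum(axis=0) / sw
        cov_ty = ((t - mean_t) * usable * (logs - mean_y)).sum(axis=0)
        var_t = (((te_s[:, None] - mean_t) * usable) ** 2).sum(axis=0)
        slope = cov_ty / var_t
        intercept = mean_y - slope * mean_t
    rate = -slope
    s0 = np.exp(intercept)
    # goodness of fit on the signal scale over usable echoes
    pred = s0[None, :] * np.exp(-rate[None, :] * te_s[:, None])
    resid = np.where(usable, flat - pred, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_s = np.where(n_used > 0, flat.sum(axis=0, where=usable) / sw, 0.0)
        ss_tot = (((flat - mean_s) * usable) ** 2).sum(axis=0)
        ss_res = (resid**2).sum(axis=0)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.where(ss_res == 0, 1.0, 0.0))
    return s0, rate, r2, n_used


def map_relaxation(
    series: EchoSeries, method: str = "loglinear", noise_floor: float = 0.0
) -> RelaxMap:
    """Voxelwise mono-exponential fit over the whole volume.

    Per-voxel failures become validity flags; the volume never aborts.
    """
    n_echo = series.signal.shape[0]
    flat = series.signal.reshape(n_echo, -1)
    te_s = series.te_ms / MS_PER_S
    s0, rate, r2, n_used = _vectorized_loglinear(te_s, flat, noise_floor)
    valid = n_used >= 3
    reason = np.where(valid, REASON_OK, REASON_TOO_FEW).astype(object)
    clamped = valid & (rate < 0)
    rate = np.where(clamped, 0.0, rate)
    reason[clamped] = REASON_CLAMPED
    if clamped.any():
        pred = s0[None, :] * np.exp(0.0 * te_s[:, None])
        # recompute fit quality for clamped voxels against the flat model
        for v in np.flatnonzero(clamped):
            usable = flat[:, v] > max(noise_floor, 0.0)
            r2[v] = _r_squared(flat[usable, v], s0[v] * np.ones(usable.sum()))
    if method == "nonlinear":
        for v in np.flatnonzero(valid):
            fit = fit_monoexponential(series.te_ms, flat[:, v], "nonlinear", noise_floor)
            s0[v], rate[v], r2[v] = fit.s0, fit.rate, fit.r_squared
            reason[v] = fit.reason
    elif method != "loglinear":
        raise ValueError("method must be 'loglinear' or 'nonlinear'")
    rate = np.where(valid, rate, np.nan)
    s0 = np.where(valid, s0, np.nan)
    r2 = np.where(valid, r2, np.nan)
    shape = series.grid_shape
    return RelaxMap(
        rate.reshape(shape),
        s0.reshape(shape),
        r2.reshape(shape),
        n_used.reshape(shape),
        valid.reshape(shape),
        reason.reshape(shape),
    )


def roi_summary(relax_map: RelaxMap, mask: ROIMask) -> pd.DataFrame:
    """Mean rate, sd and voxel count per ROI label, over valid voxels only.

    Labels with zero valid voxels appear with ``n_voxels = 0`` and NaN
    statistics. Geometry mismatch raises ``ValueError``.
    """
    if mask.labels.shape != relax_map.grid_shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} != map shape {relax_map.grid_shape}"
        )
    rows = []
    for label, name in sorted(mask.label_names.items()):
        sel = (mask.labels == label) & relax_map.valid
        vals = relax_map.rate[sel]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "label": label,
                "name": name,
                "mean_rate": float(vals.mean()) if vals.size else np.nan,
                "sd_rate": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def multi_roi_representative(roi_means: np.ndarray) -> float:
    """Unweighted mean of several ROI means (the multi-ROI averaging scheme)."""
    roi_means = np.asarray(roi_means, float)
    if roi_means.size == 0 or not np.all(np.isfinite(roi_means)):
        raise ValueError("ROI means must be finite and non-empty")
    return float(roi_means.mean())


def apply_iron_calibration(rate, line: CalibrationLine | None):
    """Affine conversion of a relaxation rate (s^-1) to an iron estimate."""
    if line is None:
        raise ValueError(
            "no calibration line configured; supply slope/intercept explicitly"
        )
    return line.slope * np.asarray(rate, float) + line.intercept


# ---------------------------------------------------------------------------
# Volume I/O: NIfTI when available, NPZ fallback


def save_volume(path: str | Path, series: EchoSeries | None = None,
                mask: ROIMask | None = None) -> None:
    path = str(path)
    if path.endswith(".npz"):
        payload = {}
        if series is not None:
            payload["te_ms"] = series.te_ms
            payload["signal"] = series.signal
        if mask is not None:
            payload["labels"] = mask.labels
            payload["label_keys"] = np.array(list(mask.label_names.keys()))
            payload["label_vals"] = np.array(list(mask.label_names.values()))
        np.savez(path, **payload)
        return
    import nibabel as nib

    if series is not None:
        # echoes stored on the last axis of a 4D NIfTI
        img = nib.Nifti1Image(np.moveaxis(series.signal, 0, -1), np.eye(4))
        img.header["pixdim"][4] = 1.0
        nib.save(img, path)
    if mask is not None:
        nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), np.eye(4)), path)


def load_volume(path: str | Path, te_ms: np.ndarray | None = None) -> EchoSeries:
    path = str(path)
    if path.endswith(".npz"):
        data = np.load(path)
        return EchoSeries(te_ms=data["te_ms"], signal=data["signal"])
    import nibabel as nib

    if te_ms is None:
        raise ValueError("echo times must be supplied when loading NIfTI volumes")
    arr = np.asarray(nib.load(path).get_fdata())
    return EchoSeries(te_ms=te_ms, signal=np.moveaxis(arr, -1, 0))
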