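"""Temporal cleaning of masked BOLD series.

Pipeline order is fixed: discard initial volumes -> motion screening ->
nuisance regression (Friston-24 motion expansion + WM/CSF means, intercept
always included) -> linear detrend -> band-pass filter.  Spatial steps
(slice timing, realignment, normalization) are assumed done upstream; this
module consumes already-aligned volumes and, for motion, the realignment
parameter table.

All matrix operations act on a (time, voxels) array as produced by
:meth:`fcdens.volumes.GrayMatterMask.extract`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .volumes import BoldSeries

__all__ = [
    "PreprocParams",
    "DesignError",
    "discard_initial",
    "motion_screen",
    "friston24",
    "nuisance_regress",
    "detrend_linear",
    "bandpass",
    "run_preprocess",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


class DesignError(ValueError):
    """Nuisance design matrix is rank deficient."""


@dataclass
class PreprocParams:
    """Temporal-cleaning parameters.

    band_high_hz defaults to 0.1 Hz; at TR = 3 s the Nyquist frequency is
    1/6 Hz so the standard 0.01-0.1 Hz resting-state band is representable.
    Motion limits are strict inequalities: a subject is excluded only when
    the maximum absolute translation exceeds ``max_translation_mm`` or any
    rotation exceeds ``max_rotation_deg``.
    """

    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    max_translation_mm: float = 1.5
    max_rotation_deg: float = 1.5
    use_friston24: bool = True
    use_wm: bool = True
    use_csf: bool = True
    filter_method: str = "dft"  # "dft" (zero-phase frequency bins) | "butter"

    def validate(self, tr_s: float) -> None:
        nyq = 1.0 / (2.0 * tr_s)
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= nyq:
            raise ValueError(
                f"band_high_hz {self.band_high_hz} >= Nyquist {nyq:.4f} at TR={tr_s}"
            )
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")


def discard_initial(bold: BoldSeries, n_discard: int = 10) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard >= bold.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes"
        )
    if n_discard == 0:
        return bold
    return BoldSeries(
        grid=bold.grid,
        data=bold.data[..., n_discard:],
        tr_s=bold.tr_s,
        subject_id=bold.subject_id,
    )


def motion_screen(
    confounds: pd.DataFrame,
    max_translation_mm: float = 1.5,
    max_rotation_deg: float = 1.5,
) -> bool:
    """True if the subject passes the head-motion screen.

    Excludes when any translation axis exceeds ``max_translation_mm`` or any
    rotation axis exceeds ``max_rotation_deg`` (max absolute value over
    volumes, relative to the reference volume; strict ``>``).
    """
    missing = [c for c in MOTION_COLUMNS if c not in confounds.columns]
    if missing:
        raise KeyError(f"confound table missing motion columns: {missing}")
    trans = confounds[MOTION_COLUMNS[:3]].abs().to_numpy().max()
    rot = confounds[MOTION_COLUMNS[3:]].abs().to_numpy().max()
    return not (trans > max_translation_mm or rot > max_rotation_deg)


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 expansion of 6 realignment parameters.

    Columns: the 6 parameters, their one-volume-lagged versions (first row
    zero), and the squares of both.  Input shape (time, 6) -> (time, 24).
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"expected (time, 6) motion array, got {m.shape}")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.hstack([m, lag, m**2, lag**2])


def nuisance_regress(series: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """Residualize (time, voxels) series against confounds + intercept.

    Residuals are orthogonal to every regressor.  Raises
    :class:`DesignError` naming the offending columns when the design
    (including intercept) is rank deficient.
    """
    y = np.asarray(series, dtype=float)
    n_t = y.shape[0]
    parts = [np.ones((n_t, 1))]
    if confounds is not None and np.size(confounds):
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n_t:
            raise ValueError(
                f"confound rows {c.shape[0]} != time points {n_t}"
            )
        parts.append(c)
    x = np.hstack(parts)
    # rank check via QR: near-zero diagonal entries of R mark dependent columns
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.where(diag <= tol)[0]
    if bad.size:
        raise DesignError(
            f"nuisance design is rank deficient; dependent columns (0=intercept): "
            f"{bad.tolist()}"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove per-voxel least-squares line (mean and slope)."""
    y = np.asarray(series, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need >= 3 time points to detrend")
    return sp_signal.detrend(y, axis=0, type="linear")


def bandpass(
    series: np.ndarray,
    tr_s: float,
    band_low_hz: float = 0.01,
    band_high_hz: float = 0.1,
    method: str = "dft",
) -> np.ndarray:
    """Zero-phase band-pass along the time axis.

    ``method="dft"`` zeroes DFT bins outside [low, high] (exact, zero phase;
    the default).  ``method="butter"`` applies a 4th-order Butterworth with
    forward-backward filtering.
    """
    y = np.asarray(series, dtype=float)
    n_t = y.shape[0]
    if n_t < 3:
        raise ValueError("need >= 3 time points to filter")
    nyq = 1.0 / (2.0 * tr_s)
    if not 0 < band_low_hz < band_high_hz:
        raise ValueError("need 0 < band_low_hz < band_high_hz")
    if band_high_hz >= nyq:
        raise ValueError(f"band_high_hz {band_high_hz} >= Nyquist {nyq:.4f}")
    if method == "dft":
        freqs = np.fft.rfftfreq(n_t, d=tr_s)
        spec = np.fft.rfft(y, axis=0)
        keep = (freqs >= band_low_hz) & (freqs <= band_high_hz)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=n_t, axis=0)
    if method == "butter":
        sos = sp_signal.butter(
            4, [band_low_hz / nyq, band_high_hz / nyq], btype="band", output="sos"
        )
        return sp_signal.sosfiltfilt(sos, y, axis=0)
    raise ValueError(f"unknown filter method {method!r}")


def run_preprocess(
    bold: BoldSeries,
    mask,
    params: PreprocParams | None = None,
    confounds: pd.DataFrame | None = None,
) -> np.ndarray:
    """Full temporal pipeline on one subject; returns (time, voxels) matrix.

    ``confounds`` may carry motion columns (Friston-24 expanded here) and
    ``wm`` / ``csf`` mean-signal columns; when absent (synthetic data) only
    the intercept is regressed, making nuisance regression a demeaning step.
    Raises ``RuntimeError`` if the subject fails the motion screen.
    """
    params = params or PreprocParams()
    params.validate(bold.tr_s)
    bold = discard_initial(bold, params.n_discard)
    cols = []
    if confounds is not None:
        confounds = confounds.iloc[-bold.n_volumes:].reset_index(drop=True)
        has_motion = all(c in confounds.columns for c in MOTION_COLUMNS)
        if has_motion:
            if not motion_screen(
                confounds, params.max_translation_mm, params.max_rotation_deg
            ):
                raise RuntimeError(
                    f"subject {bold.subject_id or '?'} fails motion screen"
                )
            if params.use_friston24:
                cols.append(friston24(confounds[MOTION_COLUMNS].to_numpy()))
            else:
                cols.append(confounds[MOTION_COLUMNS].to_numpy())
        if params.use_wm and "wm" in confounds.columns:
            cols.append(confounds[["wm"]].to_numpy())
        if params.use_csf and "csf" in confounds.columns:
            cols.append(confounds[["csf"]].to_numpy())
    x = np.hstack(cols) if cols else None
    mat = mask.extract(bold)
    mat = nuisance_regress(mat, x)
    mat = detrend_linear(mat)
    mat = bandpass(
        mat, bold.tr_s, params.band_low_hz, params.band_high_hz, params.filter_method
    )
    return mat
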