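"""LUT inversion, synthetic PPG generation and evaluation metrics.

The forward simulation maps (HbA1c, SpO2) to a ratio pair (R1, R2); the
:class:`RatioInverter` estimator inverts that map by inverse-distance-
weighted averaging of the k nearest LUT nodes in standardized ratio space
(exact at LUT nodes).  It follows the scikit-learn estimator protocol so it
can be dropped into pipelines and model selection, and it exposes a slot for
a custom regression adapter so a feature-based calibrator can replace the
IDW rule.

Synthetic PPG stands in for device recordings: a raised-cosine pulse train
per channel whose baseline and amplitude encode the LUT row's DC and AC,
plus optional white noise.  Ratio extraction then measures per-beat
peak-to-trough amplitudes (AC) and diastolic baselines (DC), matching the
convention the LUT is built with, so the noiseless round trip
generate -> extract -> invert is exact at grid nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin

from .experiments import RatioLUT, compute_ratios


class ExtrapolationWarning(UserWarning):
    """A ratio query fell well outside the LUT's covered region."""


class RatioInverter(BaseEstimator, RegressorMixin):
    """Invert (R1, R2) to (%HbA1c, %SpO2) by k-NN inverse-distance weighting.

    Parameters
    ----------
    k : int
        Number of nearest LUT nodes averaged (default 4).
    standardize : bool
        Standardize the ratio space before distance computation.
    extrapolation_tol : float
        Warn when a query's nearest-node distance exceeds this many times the
        LUT's median nearest-neighbor spacing.

    After ``fit``: ``X_`` (n, 2) ratio nodes, ``y_`` (n, 2) targets in
    percent, ``scale_`` the standardization scales.
    """

    def __init__(self, k: int = 4, standardize: bool = True, extrapolation_tol: float = 3.0):
        self.k = k
        self.standardize = standardize
        self.extrapolation_tol = extrapolation_tol

    def fit(self, X, y=None):
        """Fit from a RatioLUT, a ratios DataFrame, or (X=(n,2) ratios, y=(n,2) %)."""
        if isinstance(X, RatioLUT):
            df = X.ratios
            X_arr = df[["r1", "r2"]].to_numpy(float)
            y_arr = df[["hba1c", "spo2"]].to_numpy(float) * 100.0
        elif isinstance(X, pd.DataFrame):
            X_arr = X[["r1", "r2"]].to_numpy(float)
            y_arr = X[["hba1c", "spo2"]].to_numpy(float) * 100.0
        else:
            X_arr = np.asarray(X, float)
            y_arr = np.asarray(y, float)
        if X_arr.ndim != 2 or X_arr.shape[1] != 2:
            raise ValueError("expected (n, 2) ratio array")
        if len(X_arr) < self.k:
            raise ValueError(f"LUT has {len(X_arr)} nodes, fewer than k={self.k}")
        self.X_ = X_arr
        self.y_ = y_arr
        self.scale_ = X_arr.std(axis=0) if self.standardize else np.ones(2)
        self.scale_ = np.where(self.scale_ > 0, self.scale_, 1.0)
        self._tree = cKDTree(X_arr / self.scale_)
        d, _ = self._tree.query(X_arr / self.scale_, k=2)
        self.node_spacing_ = float(np.median(d[:, 1])) if len(X_arr) > 1 else 1.0
        return self

    def predict(self, X) -> np.ndarray:
        """(n, 2) array of (%HbA1c, %SpO2) estimates."""
        if not hasattr(self, "X_"):
            raise AttributeError("RatioInverter is not fitted")
        Q = np.atleast_2d(np.asarray(X, float)) / self.scale_
        d, idx = self._tree.query(Q, k=min(self.k, len(self.X_)))
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        out = np.empty((len(Q), 2))
        far = d[:, 0] > self.extrapolation_tol * self.node_spacing_
        if far.any():
            warnings.warn(
                f"{int(far.sum())} ratio queries lie outside the LUT coverage",
                ExtrapolationWarning,
                stacklevel=2,
            )
        for i in range(len(Q)):
            if d[i, 0] < 1e-12:  # exact node short-circuit
                out[i] = self.y_[idx[i, 0]]
            else:
                w = 1.0 / d[i]
                out[i] = (w[:, None] * self.y_[idx[i]]).sum(axis=0) / w.sum()
        return out


def invert(r1: float, r2: float, lut: RatioLUT, k: int = 4) -> tuple[float, float]:
    """Single-query inversion: (%HbA1c, %SpO2) from one ratio pair."""
    est = RatioInverter(k=k).fit(lut)
    h, s = est.predict([[r1, r2]])[0]
    return float(h), float(s)


@dataclass
class SyntheticPPG:
    """Synthetic multi-channel PPG with known ground truth."""

    signals: dict  # channel -> np.ndarray
    sampling_rate_hz: float
    pulse_rate_hz: float
    hba1c: float  # fraction
    spo2: float  # fraction
    noise_sigma: float
    seed: int
    kind: str = "fingertip_reflection"
    truth_acdc: dict = field(default_factory=dict)  # channel -> (ac, dc)


def generate_ppg(
    lut_row: pd.DataFrame,
    pulse_rate_hz: float = 1.25,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sampling_rate_hz: float = 100.0,
    duration_s: float = 10.0,
    kind: str = "fingertip_reflection",
) -> SyntheticPPG:
    """Raised-cosine pulse train per channel from one LUT row.

    The signal is ``DC - AC * (1 - cos(2 pi f t)) / 2``: baseline (diastolic)
    level DC, dipping by the pulsatile amplitude AC at each systolic trough,
    plus white noise scaled by ``noise_sigma`` (absolute intensity units).
    Doubling the pulse rate changes only the timing, never AC or DC.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * pulse_rate_hz * t))
    signals = {}
    truth = {}
    for row in lut_row.itertuples():
        base = row.dc - row.ac * pulse
        noise = rng.normal(0.0, noise_sigma, size=n) if noise_sigma > 0 else 0.0
        signals[row.channel] = base + noise
        truth[row.channel] = (row.ac, row.dc)
    return SyntheticPPG(
        signals=signals,
        sampling_rate_hz=sampling_rate_hz,
        pulse_rate_hz=pulse_rate_hz,
        hba1c=float(lut_row.hba1c.iloc[0]),
        spo2=float(lut_row.spo2.iloc[0]),
        noise_sigma=noise_sigma,
        seed=seed,
        kind=kind,
        truth_acdc=truth,
    )


def _beat_acdc(signal: np.ndarray, fs: float, pulse_rate_hz: float) -> tuple[float, float]:
    """Per-beat AC (mean peak-to-trough) and DC (mean diastolic peak)."""
    beat = max(2, int(round(fs / pulse_rate_hz)))
    n_beats = len(signal) // beat
    if n_beats == 0:
        seg = signal[None, :]
    else:
        seg = signal[: n_beats * beat].reshape(n_beats, beat)
    peaks = seg.max(axis=1)
    troughs = seg.min(axis=1)
    return float(np.mean(peaks - troughs)), float(np.mean(peaks))


def extract_ratios(ppg: SyntheticPPG) -> tuple[float, float]:
    """(R1, R2) from the PPG channels via per-beat AC/DC extraction.

    A flat (non-pulsatile) channel yields AC = 0; the fingertip/wrist
    wavelength equations then return zero ratios with a warning.
    """
    acdc = {}
    flat = []
    for ch, sig in ppg.signals.items():
        ac, dc = _beat_acdc(np.asarray(sig, float), ppg.sampling_rate_hz, ppg.pulse_rate_hz)
        if dc == 0:
            raise ValueError(f"channel {ch!r} has zero DC level")
        if ac == 0:
            flat.append(ch)
        acdc[ch] = ac / dc
    if flat:
        warnings.warn(f"non-pulsatile channels {flat}: AC = 0", stacklevel=2)
        ref = "sensor3" if ppg.kind == "wrist_multi_pd" else 615.0
        if ref in flat:
            return 0.0, 0.0
    return compute_ratios(acdc, ppg.kind)


@dataclass
class EstimateReport:
    """Aggregate agreement metrics between estimates and references (percent scale)."""

    estimates: np.ndarray
    references: np.ndarray
    mse: float
    me: float
    mad: float
    rmse: float
    pearson_r: float
    rcf: float
    bias: float
    sd: float
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    zone_counts: dict  # EGA zones A/B/C

    def to_frame(self) -> pd.DataFrame:
        resid = self.estimates - self.references
        return pd.DataFrame(
            {"reference": self.references, "estimate": self.estimates, "residual": resid}
        )


def metrics(estimates, references) -> EstimateReport:
    """Evaluation metrics on percent-scale values.

    MSE/ME/MAD/RMSE/Pearson r; the reference closeness factor
    ``RCF = mean(1 - |ref - est| / 100)``; Bland-Altman bias with 1.96-SD
    limits of agreement; and error-grid zones (A within 20 % of the
    reference, B within 40 %, C beyond).  SD-based quantities are NaN for a
    single record.
    """
    est = np.asarray(estimates, float)
    ref = np.asarray(references, float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length 1-D arrays")
    if len(est) == 0:
        raise ValueError("need at least 1 record")
    resid = est - ref
    abs_resid = np.abs(resid)
    zone_a = abs_resid <= 0.2 * ref
    zone_b = ~zone_a & (abs_resid <= 0.4 * ref)
    zone_c = ~zone_a & ~zone_b
    if len(est) < 2 or np.std(est) == 0 or np.std(ref) == 0:
        r = np.nan  # Pearson undefined for constant or single-record series
    else:
        r = float(stats.pearsonr(est, ref).statistic)
    # SD-based quantities are NaN for a single record
    sd = float(np.std(resid, ddof=1)) if len(est) >= 2 else np.nan
    bias = float(np.mean(resid))
    mse = float(np.mean(resid**2))
    return EstimateReport(
        estimates=est,
        references=ref,
        mse=mse,
        me=bias,
        mad=float(np.mean(abs_resid)),
        rmse=float(np.sqrt(mse)),
        pearson_r=r,
        rcf=float(np.mean(1.0 - abs_resid / 100.0)),
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        zone_counts={"A": int(zone_a.sum()), "B": int(zone_b.sum()), "C": int(zone_c.sum())},
    )
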