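"""Surfactant-displacement kinetics and affinity labeling.

Adding sodium cholate (SC) to an ssDNA-wrapped nanotube displaces the DNA;
the nanotube's fluorescence peak blue-shifts with first-order kinetics whose
time constant tau measures how strongly the sequence binds (longer = more
stable wrapping).  Traces with no measurable shift within the observation
window are censored (INF): very strong binders.

Also here: the 90-s high/low affinity labeling rule, the nuclease cut
ratio CR = I_c/(I_a + I_c), and the per-base dissociation-enthalpy sum
estimator with its Pearson correlation against measured time constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sequences import SequenceError
from .synthetic import KineticTrace

AFFINITY_THRESHOLD_S = 90.0
SHIFT_MIN_NM = 1.0


class FitError(RuntimeError):
    pass


@dataclass
class TimeConstantResult:
    """Fitted displacement time constant, or a censored (INF) flag."""

    tau_s: float | None
    lambda0_nm: float
    lambdaInf_nm: float
    rmse_nm: float
    n_points: int
    censored: bool

    def __post_init__(self) -> None:
        if self.censored:
            self.tau_s = None
        elif self.tau_s is None or not self.tau_s > 0:
            raise ValueError("uncensored result requires tau_s > 0")


@dataclass(frozen=True)
class AffinityLabel:
    label: str  # "high" | "low"
    threshold_s: float = AFFINITY_THRESHOLD_S

    @property
    def is_high(self) -> bool:
        return self.label == "high"


def extract_peak_wavelength(
    wavelengths_nm: np.ndarray,
    intensities: np.ndarray,
    window: tuple[float, float],
) -> float:
    """Peak wavelength within *window*, refined by 3-point parabolic
    interpolation around the discrete maximum."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    mask = (wl >= window[0]) & (wl <= window[1])
    if mask.sum() < 3:
        raise ValueError("need at least 3 spectral points inside the window")
    wl, inten = wl[mask], inten[mask]
    order = np.argsort(wl)
    wl, inten = wl[order], inten[order]
    i = int(np.argmax(inten))
    if i == 0 or i == len(wl) - 1:
        return float(wl[i])
    y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:  # flat top: keep the grid point
        return float(wl[i])
    # assumes a locally uniform grid around the maximum
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    return float(wl[i] + delta * step)


def _exp_model(t, lam_inf, shift, tau):
    return lam_inf + shift * np.exp(-t / tau)


def fit_time_constant(
    trace: KineticTrace, shift_min_nm: float = SHIFT_MIN_NM
) -> TimeConstantResult:
    """Least-squares single-exponential fit of the post-addition trace.

    lambda(t) = lambdaInf + (lambda0 - lambdaInf) exp(-(t - t_add)/tau) on
    t >= t_add with all three parameters free.  Initialization: lambda0 from
    the pre-addition mean, lambdaInf from the tail, tau from a log-linear
    slope.  A trace is reported censored (no measurable displacement = very
    strong binding) unless both the fitted shift |lambda0 - lambdaInf| and
    the model-free shift (pre-addition mean minus tail mean) reach
    *shift_min_nm*: requiring the model-free amplitude too keeps a
    three-parameter fit from manufacturing a "shift" out of noise on a
    flat trace.
    """
    t = np.asarray(trace.times, dtype=float)
    lam = np.asarray(trace.wavelengths, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    after = t >= trace.t_add
    n_after = int(after.sum())
    if n_after < 5:
        raise ValueError("need at least 5 points at or after t_add")
    ta = t[after] - trace.t_add
    ya = lam[after]
    pre = lam[~after]
    lam0_init = float(pre.mean()) if len(pre) else float(ya[0])
    lam_inf_init = float(ya[-min(3, n_after) :].mean())
    shift_init = lam0_init - lam_inf_init

    raw_shift = abs(shift_init)
    # tau init from log-linearizing |lambda - lambdaInf| where it is positive
    resid = (ya - lam_inf_init) * np.sign(shift_init if shift_init != 0 else 1.0)
    pos = resid > max(1e-3, 0.05 * raw_shift)
    if pos.sum() >= 2:
        slope = np.polyfit(ta[pos], np.log(resid[pos]), 1)[0]
        tau_init = -1.0 / slope if slope < 0 else ta[-1] / 2
    else:
        tau_init = ta[-1] / 2
    tau_init = float(np.clip(tau_init, 1e-3, 100 * ta[-1]))

    try:
        popt, _ = optimize.curve_fit(
            _exp_model,
            ta,
            ya,
            p0=(lam_inf_init, shift_init, tau_init),
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6 * max(ta[-1], 1.0)]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        if raw_shift < shift_min_nm:
            return TimeConstantResult(
                tau_s=None,
                lambda0_nm=lam0_init,
                lambdaInf_nm=lam_inf_init,
                rmse_nm=float(np.std(ya)),
                n_points=n_after,
                censored=True,
            )
        raise FitError(
            f"exponential fit failed to converge (raw shift {raw_shift:.2f} nm, "
            f"tau init {tau_init:.1f} s): {exc}"
        ) from exc
    lam_inf, shift, tau = popt
    rmse = float(np.sqrt(np.mean((_exp_model(ta, *popt) - ya) ** 2)))
    if min(abs(shift), raw_shift) < shift_min_nm:
        return TimeConstantResult(
            tau_s=None,
            lambda0_nm=lam_inf + shift,
            lambdaInf_nm=lam_inf,
            rmse_nm=rmse,
            n_points=n_after,
            censored=True,
        )
    return TimeConstantResult(
        tau_s=float(tau),
        lambda0_nm=float(lam_inf + shift),
        lambdaInf_nm=float(lam_inf),
        rmse_nm=rmse,
        n_points=n_after,
        censored=False,
    )


def label_affinity(
    result: TimeConstantResult, threshold_s: float = AFFINITY_THRESHOLD_S
) -> AffinityLabel:
    """High affinity iff censored (INF) or tau >= threshold (default 90 s)."""
    high = result.censored or (result.tau_s is not None and result.tau_s >= threshold_s)
    return AffinityLabel(label="high" if high else "low", threshold_s=threshold_s)


def label_affinity_table(
    table: pd.DataFrame, threshold_s: float = AFFINITY_THRESHOLD_S
) -> pd.DataFrame:
    """Vectorized labeling of a (sequence, tau_s, censored) table."""
    out = table.copy()
    labels = []
    for tau, cens in zip(out["tau_s"], out["censored"]):
        res = TimeConstantResult(
            tau_s=None if cens or pd.isna(tau) else float(tau),
            lambda0_nm=np.nan,
            lambdaInf_nm=np.nan,
            rmse_nm=np.nan,
            n_points=0,
            censored=bool(cens or pd.isna(tau)),
        )
        labels.append(label_affinity(res, threshold_s).label)
    out["label"] = labels
    return out


def cut_ratio(I_a: float, I_c: float) -> float:
    """Nuclease cut ratio CR = I_c / (I_a + I_c) from gel band intensities."""
    if I_a < 0 or I_c < 0:
        raise ValueError("band intensities must be non-negative")
    total = I_a + I_c
    if total == 0:
        raise ValueError("cut ratio undefined: both band intensities are zero")
    return I_c / total


def enthalpy_sum(seq: str, table: dict) -> float:
    """Estimated dissociation enthalpy: sum of per-base enthalpies.

    The per-base values are a required user input (literature-derived);
    units are whatever the supplied table uses.
    """
    missing = set(seq) - set(table)
    if missing:
        raise SequenceError(f"enthalpy table missing entries for {sorted(missing)}")
    return float(sum(table[b] for b in seq))


def correlate_tau_enthalpy(
    taus: Sequence[float], enthalpies: Sequence[float]
) -> float:
    """Pearson correlation between time constants and enthalpy estimates.

    Censored taus must be excluded upstream; the correlation is computed on
    the linear tau scale.
    """
    x = np.asarray(taus, dtype=float)
    y = np.asarray(enthalpies, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite (exclude censored values)")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def fit_manifest(
    manifest: pd.DataFrame,
    threshold_s: float = AFFINITY_THRESHOLD_S,
    shift_min_nm: float = SHIFT_MIN_NM,
) -> pd.DataFrame:
    """Batch fit: manifest columns (sequence_id, trace_path) -> result table."""
    rows = []
    for _, row in manifest.iterrows():
        trace = KineticTrace.from_tsv(Path(row["trace_path"]))
        res = fit_time_constant(trace, shift_min_nm=shift_min_nm)
        rows.append(
            {
                "sequence_id": row["sequence_id"],
                "tau_s": res.tau_s,
                "censored": res.censored,
                "lambda0": res.lambda0_nm,
                "lambdaInf": res.lambdaInf_nm,
                "rmse": res.rmse_nm,
                "label": label_affinity(res, threshold_s).label,
            }
        )
    return pd.DataFrame(rows)
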