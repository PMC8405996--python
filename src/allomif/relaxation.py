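"""NMR spin-relaxation and chemical-shift-perturbation analysis.

The pipeline starts at peak heights and peak positions (no spectral
processing). Longitudinal (R1) and transverse (R2) rates come from
nonlinear least-squares fits of per-residue peak heights to a single
exponential decay I(t) = I0·exp(-R·t); rate uncertainties propagate the
intensity noise estimated from duplicate relaxation delays through the fit
covariance. The heteronuclear NOE is the ratio of saturated to reference
peak heights. The R1·R2 product suppresses the anisotropic-tumbling
contribution and highlights chemical-exchange effects.

Combined ¹H/¹⁵N chemical-shift perturbations use
Δδ = sqrt(ΔδH² + (w·ΔδN)²) with the community-standard nitrogen scaling
w = 0.14. Per-residue profiles (CSP bars, wt-vs-variant relaxation
deviations) are flagged against the 10%-trimmed mean ± 1.5σ rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ParameterError

#: longitudinal (T1) relaxation-delay schedule, seconds
T1_DELAYS_S = np.array([0, 20, 60, 100, 200, 600, 800, 1200, 1500, 2000, 2500]) / 1e3
#: duplicate T1 delays used for uncertainty estimation, seconds
T1_REPLICATE_DELAYS_S = np.array([20, 60, 600]) / 1e3
#: total transverse (T2/CPMG) relaxation delays, seconds
T2_DELAYS_S = np.array([0, 16.9, 33.9, 67.8, 136, 169, 203]) / 1e3
#: duplicate T2 delays, seconds
T2_REPLICATE_DELAYS_S = np.array([16.9, 33.9, 136, 203]) / 1e3

#: default ¹⁵N scaling weight in the combined CSP
CSP_NITROGEN_WEIGHT = 0.14


@dataclass
class RateFit:
    """Single-exponential fit result for one residue."""

    residue: int | str
    rate: float          # s⁻¹
    rate_err: float      # s⁻¹, 1σ from the weighted fit covariance
    amplitude: float
    amplitude_err: float
    negative_rate: bool = False  # flagged, never silently clamped


def replicate_noise_sd(table: pd.DataFrame) -> float:
    """Pooled intensity noise σ_I from duplicate-delay measurements.

    For every (residue, delay) measured more than once, the difference of a
    replicate pair has variance 2σ_I²; σ_I is the RMS of the differences
    divided by √2, pooled across residues and delays.
    """
    diffs = []
    for (_, _), grp in table.groupby(["residue", "delay_s"]):
        vals = grp["intensity"].to_numpy(float)
        if len(vals) >= 2:
            for i in range(1, len(vals)):
                diffs.append(vals[i] - vals[0])
    if not diffs:
        raise ParameterError("no duplicate delays found; cannot estimate noise")
    d = np.asarray(diffs, float)
    return float(np.sqrt(np.mean(d**2) / 2.0))


def fit_exponential_decay(
    delays: np.ndarray,
    intensities: np.ndarray,
    sigma: float | np.ndarray | None = None,
    residue: int | str = "",
) -> RateFit:
    """Least-squares fit of I(t) = I0·exp(-R·t) over (I0, R).

    ``sigma`` (scalar or per-point) weights the fit and makes the returned
    uncertainties absolute; with no sigma the covariance is scaled by the
    residual variance. A negative fitted rate is returned flagged.
    """
    t = np.asarray(delays, float)
    y = np.asarray(intensities, float)
    if t.size != y.size:
        raise ParameterError("delays and intensities differ in length")
    if np.unique(t).size < 3:
        raise ParameterError("need >= 3 distinct delays")
    if np.any(t < 0):
        raise ParameterError("delays must be non-negative")
    if np.allclose(y, 0):
        raise ParameterError("intensities are all zero")
    # start values from a log-linear fit on the positive points
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(np.max(np.abs(y))), 1.0)
    if np.ptp(y) == 0:  # constant intensities: R = 0 exactly
        return RateFit(residue, 0.0, 0.0, float(y[0]), 0.0)

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    sig = None
    absolute = False
    if sigma is not None:
        sig = np.broadcast_to(np.asarray(sigma, float), y.shape)
        absolute = True
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, sigma=sig, absolute_sigma=absolute, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit failed for residue {residue!r}: {exc}") from exc
    i0, r = popt
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    return RateFit(
        residue,
        float(r),
        float(perr[1]),
        float(i0),
        float(perr[0]),
        negative_rate=bool(r < 0),
    )


def fit_rates(table: pd.DataFrame, sigma: float | None = None) -> pd.DataFrame:
    """Fit every residue of a (residue, delay_s, intensity, replicate_id) table.

    When ``sigma`` is None it is estimated from the table's duplicate delays
    (falling back to unweighted fits if there are none). Returns a DataFrame
    with columns residue, rate, rate_err, amplitude, negative_rate.
    """
    required = {"residue", "delay_s", "intensity"}
    if not required <= set(table.columns):
        raise ParameterError(f"table needs columns {sorted(required)}")
    if sigma is None:
        try:
            sigma = replicate_noise_sd(table)
        except ParameterError:
            sigma = None
    rows = []
    for residue, grp in table.groupby("residue", sort=True):
        fit = fit_exponential_decay(
            grp["delay_s"].to_numpy(float),
            grp["intensity"].to_numpy(float),
            sigma=sigma,
            residue=residue,
        )
        rows.append(
            {
                "residue": residue,
                "rate": fit.rate,
                "rate_err": fit.rate_err,
                "amplitude": fit.amplitude,
                "negative_rate": fit.negative_rate,
            }
        )
    return pd.DataFrame(rows)


def compute_noe(saturated: float, reference: float, residue: int | str = "") -> float:
    """Heteronuclear NOE: saturated / reference peak-height ratio."""
    if reference == 0:
        raise ParameterError(f"zero reference intensity for residue {residue!r}")
    return saturated / reference


def r1r2_product(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-residue R1·R2 (s⁻²) with first-order error propagation.

    ``rates`` needs columns residue, R1, R2 (and optionally R1_err, R2_err).
    Residues missing either rate are dropped and listed in the
    ``skipped`` attribute of the returned frame.
    """
    df = rates.copy()
    ok = df["R1"].notna() & df["R2"].notna()
    skipped = df.loc[~ok, "residue"].tolist()
    df = df[ok].copy()
    df["R1R2"] = df["R1"] * df["R2"]
    e1 = df.get("R1_err", pd.Series(0.0, index=df.index)).fillna(0.0)
    e2 = df.get("R2_err", pd.Series(0.0, index=df.index)).fillna(0.0)
    df["R1R2_err"] = np.sqrt((e1 * df["R2"]) ** 2 + (df["R1"] * e2) ** 2)
    df.attrs["skipped"] = skipped
    return df


def combined_csp(
    wt_peak: tuple[float, float],
    variant_peak: tuple[float, float],
    nitrogen_weight: float = CSP_NITROGEN_WEIGHT,
) -> float:
    """Combined ¹H/¹⁵N shift perturbation Δδ = sqrt(ΔδH² + (w·ΔδN)²), ppm."""
    dh = variant_peak[0] - wt_peak[0]
    dn = variant_peak[1] - wt_peak[1]
    return float(np.sqrt(dh**2 + (nitrogen_weight * dn) ** 2))


def csp_table(
    wt_peaks: pd.DataFrame,
    variant_peaks: pd.DataFrame,
    nitrogen_weight: float = CSP_NITROGEN_WEIGHT,
) -> pd.DataFrame:
    """Per-residue combined CSP from two (residue, dH_ppm, dN_ppm) tables.

    Residues present in the wild-type list but missing from the variant are
    flagged ``broadened`` (peak vanished — an input annotation, not an
    inference from intensities) and carry NaN CSP.
    """
    wt = wt_peaks.set_index("residue")
    var = variant_peaks.set_index("residue")
    rows = []
    for residue in wt.index:
        if residue in var.index:
            val = combined_csp(
                (wt.loc[residue, "dH_ppm"], wt.loc[residue, "dN_ppm"]),
                (var.loc[residue, "dH_ppm"], var.loc[residue, "dN_ppm"]),
                nitrogen_weight,
            )
            rows.append({"residue": residue, "csp_ppm": val, "broadened": False})
        else:
            rows.append({"residue": residue, "csp_ppm": np.nan, "broadened": True})
    return pd.DataFrame(rows)


@dataclass
class ThresholdResult:
    trimmed_mean: float
    sigma: float
    threshold: float
    significant: np.ndarray  # indices into the input profile


def threshold_profile(
    values: np.ndarray,
    trim_fraction: float = 0.10,
    n_sigma: float = 1.5,
    sigma_on_trimmed: bool = False,
) -> ThresholdResult:
    """Flag profile values above the 10%-trimmed mean + 1.5σ.

    The trimmed mean removes ``trim_fraction/2`` of the values from each
    tail (10% trimmed = lowest 5% and highest 5%); σ is by default the
    standard deviation of the full, untrimmed profile. NaNs (e.g. broadened
    residues) are excluded from the statistics and never flagged.
    """
    v = np.asarray(values, float)
    finite = np.isfinite(v)
    vv = v[finite]
    if vv.size < 10:
        raise ParameterError(f"need >= 10 values, got {vv.size}")
    tm = float(stats.trim_mean(vv, trim_fraction / 2.0))
    if sigma_on_trimmed:
        lo, hi = np.quantile(vv, [trim_fraction / 2.0, 1 - trim_fraction / 2.0])
        sig = float(np.std(vv[(vv >= lo) & (vv <= hi)], ddof=1))
    else:
        sig = float(np.std(vv, ddof=1))
    cut = tm + n_sigma * sig
    significant = np.flatnonzero(finite & (v > cut))
    return ThresholdResult(tm, sig, cut, significant)


@dataclass
class OutlierReport:
    """Residues deviating from the x = y line of a wt-vs-variant diagram."""

    residues: list
    deviations: np.ndarray       # variant − reference (perpendicular/√2)
    trimmed_mean: float
    sigma: float
    flagged: list                # residues with |dev − trimmed mean| > n_sigma·σ
    rho: float                   # Spearman correlation over all paired residues
    rho_pvalue: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "residues": list(self.residues),
            "deviations": self.deviations.tolist(),
            "trimmed_mean": self.trimmed_mean,
            "sigma": self.sigma,
            "flagged": list(self.flagged),
            "spearman_rho": self.rho,
            "spearman_p": self.rho_pvalue,
            **self.metadata,
        }


def correlation_outliers(
    reference: pd.Series | dict,
    variant: pd.Series | dict,
    trim_fraction: float = 0.10,
    n_sigma: float = 1.5,
    perpendicular: bool = False,
) -> OutlierReport:
    """Two-sided trimmed-mean outlier calls on a wt-vs-variant correlation.

    The deviation axis is the simple difference variant − reference (the
    reference line is x = y); ``perpendicular=True`` divides by √2 to
    report the perpendicular offset from that line instead. Flags follow
    |deviation − trimmed mean| > n_sigma·σ with σ over the untrimmed
    deviations. Spearman's rho is computed over all paired residues.
    """
    ref = pd.Series(reference, dtype=float)
    var = pd.Series(variant, dtype=float)
    common = ref.index.intersection(var.index)
    ref, var = ref.loc[common], var.loc[common]
    mask = ref.notna() & var.notna()
    ref, var = ref[mask], var[mask]
    if len(ref) < 10:
        raise ParameterError(f"only {len(ref)} common residues; need >= 10")
    dev = (var - ref).to_numpy(float)
    scale = np.sqrt(2.0) if perpendicular else 1.0
    dev = dev / scale
    tm = float(stats.trim_mean(dev, trim_fraction / 2.0))
    sig = float(np.std(dev, ddof=1))
    if sig == 0.0:
        flag_mask = np.zeros(len(dev), bool)
    else:
        flag_mask = np.abs(dev - tm) > n_sigma * sig
    rho, p = stats.spearmanr(ref.to_numpy(), var.to_numpy())
    return OutlierReport(
        residues=list(ref.index),
        deviations=dev,
        trimmed_mean=tm,
        sigma=sig,
        flagged=[r for r, f in zip(ref.index, flag_mask) if f],
        rho=float(rho),
        rho_pvalue=float(p),
        metadata={
            "deviation_axis": "perpendicular" if perpendicular else "difference",
            "trim_fraction": trim_fraction,
            "n_sigma": n_sigma,
        },
    )
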