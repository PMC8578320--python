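"""Sigmoidal precipitation-curve fitting and PEG₁/₂ inference.

The precipitation curve is modelled by the four-parameter logistic

    y(x) = (a − b) / (1 + exp(s·(x − PEG₁/₂))) + b

with upper plateau *a* (fully soluble), lower plateau *b*, slope *s* > 0
(the curve decreases with PEG under this sign convention) and inflection
point PEG₁/₂, the PEG % w/v at which half the protein remains soluble —
the relative-solubility readout of the assay.

Workflow: an initial four-parameter fit estimates the plateaus, the data
are normalised to [0, 1] using them, the normalised curve is refit with the
plateaus fixed, and 95 % confidence intervals on PEG₁/₂ and the slope come
from a 500-cycle bootstrap.  Two derived quantities are available: the
precipitation onset (tangent-at-inflection construction, onset =
PEG₁/₂ − 2/s) and the apparent absolute solubility (log-linear
extrapolation of the transition region to 0 % PEG — informative but
extremely sensitive to noise; treat as qualitative).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm as _norm_dist, t as _t_dist

from .quantification import SolubilityCurve

__all__ = [
    "FitResult",
    "DerivedSolubility",
    "NoTransitionError",
    "sigmoid",
    "fit_sigmoid",
    "normalize_curve",
    "bootstrap_ci",
    "estimate_onset",
    "extrapolate_apparent_solubility",
    "plot_fit",
]

_MAX_NFEV = 2000
_TOL = 1e-10


class NoTransitionError(ValueError):
    """The data show no detectable precipitation transition."""


def sigmoid(x, a, b, s, peg_half):
    """Four-parameter logistic, decreasing in x for s > 0."""
    z = np.clip(s * (np.asarray(x, dtype=float) - peg_half), -500.0, 500.0)
    return (a - b) / (1.0 + np.exp(z)) + b


def _logistic(x, s, peg_half):
    z = np.clip(s * (x - peg_half), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class FitResult:
    """Sigmoid parameters with optional bootstrap confidence intervals."""

    a: float
    b: float
    s: float
    peg_half: float
    rss: float
    converged: bool
    ci95_peg_half: tuple[float, float] | None = None
    ci95_s: tuple[float, float] | None = None
    n_boot: int = 0

    def predict(self, x):
        return sigmoid(x, self.a, self.b, self.s, self.peg_half)

    def to_json_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "s": self.s,
            "peg_half": self.peg_half,
            "ci95_peg_half": list(self.ci95_peg_half) if self.ci95_peg_half else None,
            "ci95_s": list(self.ci95_s) if self.ci95_s else None,
            "rss": self.rss,
            "n_boot": self.n_boot,
            "converged": self.converged,
        }


@dataclass
class DerivedSolubility:
    """Onset and log-extrapolated apparent absolute solubility."""

    onset_peg: float  # % w/v
    apparent_solubility: float  # mg/mL at 0% PEG; apparent, noise-sensitive
    extrapolation_points: int

    def to_json_dict(self) -> dict:
        return {
            "onset_peg": self.onset_peg,
            "apparent_solubility": self.apparent_solubility,
            "extrapolation_points": self.extrapolation_points,
        }


def _as_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, SolubilityCurve):
        return curve.peg_pct, curve.mean
    x, y = curve
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    a0, b0 = float(y.max()), float(y.min())
    mid = 0.5 * (a0 + b0)
    x0 = float(x[np.argmin(np.abs(y - mid))])
    # slope from the x-range spanning 10-90% of the drop
    hi, lo = b0 + 0.9 * (a0 - b0), b0 + 0.1 * (a0 - b0)
    inside = x[(y < hi) & (y > lo)]
    width = float(np.ptp(inside)) if inside.size >= 2 else 0.0
    if width <= 0:
        width = max(float(np.ptp(x)) / 4.0, 1e-6)
    return a0, b0, 4.0 / width, x0


def fit_sigmoid(
    curve: SolubilityCurve | tuple[Sequence[float], Sequence[float]],
    noise_floor: float = 0.0,
) -> FitResult:
    """Nonlinear least-squares fit of the four-parameter logistic.

    The slope is bound-constrained positive (decreasing curve).  Data whose
    total drop does not exceed *noise_floor* raise :class:`NoTransitionError`.
    Non-convergence returns best-effort parameters with ``converged=False``.
    """
    x, y = _as_xy(curve)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit the sigmoid")
    if np.ptp(x) == 0:
        raise ValueError("all PEG concentrations equal; cannot fit")
    if np.ptp(y) <= noise_floor:
        raise NoTransitionError("no transition detected (flat data)")

    a0, b0, s0, x00 = _initial_guess(x, y)
    span = float(np.ptp(x))

    def residuals(p):
        a, b, s, xh = p
        return sigmoid(x, a, b, s, xh) - y

    def jac(p):
        a, b, s, xh = p
        sig = _logistic(x, s, xh)
        d = sig * (1.0 - sig)
        return np.column_stack(
            [sig, 1.0 - sig, -(a - b) * d * (x - xh), (a - b) * d * s]
        )

    res = least_squares(
        residuals,
        x0=[a0, b0, s0, x00],
        jac=jac,
        bounds=([-np.inf, -np.inf, 1e-8, x.min() - 2 * span],
                [np.inf, np.inf, np.inf, x.max() + 2 * span]),
        method="trf",
        xtol=_TOL,
        ftol=_TOL,
        gtol=_TOL,
        max_nfev=_MAX_NFEV,
    )
    a, b, s, xh = (float(v) for v in res.x)
    return FitResult(
        a=a, b=b, s=s, peg_half=xh, rss=float(2 * res.cost),
        converged=bool(res.success and np.all(np.isfinite(res.x))),
    )


def _fit_normalized(
    x: np.ndarray, y: np.ndarray, s0: float, x00: float
) -> tuple[float, float, float, bool]:
    """Two-parameter refit with plateaus fixed at a=1, b=0."""

    def residuals(p):
        return _logistic(x, p[0], p[1]) - y

    def jac(p):
        sig = _logistic(x, p[0], p[1])
        d = sig * (1.0 - sig)
        return np.column_stack([-d * (x - p[1]), d * p[0]])

    span = float(np.ptp(x))
    res = least_squares(
        residuals,
        x0=[max(s0, 1e-6), x00],
        jac=jac,
        bounds=([1e-8, x.min() - 2 * span], [np.inf, x.max() + 2 * span]),
        method="trf",
        xtol=_TOL,
        ftol=_TOL,
        gtol=_TOL,
        max_nfev=_MAX_NFEV,
    )
    return (
        float(res.x[0]),
        float(res.x[1]),
        float(2 * res.cost),
        bool(res.success and np.all(np.isfinite(res.x))),
    )


def normalize_curve(
    curve: SolubilityCurve, fit: FitResult
) -> tuple[SolubilityCurve, FitResult]:
    """Normalise by the fitted plateaus and refit with them fixed.

    y' = (y − b)/(a − b); spreads and replicate values scale by 1/(a − b).
    Returns the normalised curve and the two-parameter refit (a=1, b=0).
    """
    if not fit.converged:
        raise ValueError("cannot normalise by a non-converged fit")
    scale = fit.a - fit.b
    if scale == 0:
        raise ValueError("degenerate fit: a == b")
    norm = SolubilityCurve(
        peg_pct=curve.peg_pct.copy(),
        mean=(curve.mean - fit.b) / scale,
        sd=curve.sd / abs(scale),
        n_wells=curve.n_wells.copy(),
        n_excluded=curve.n_excluded.copy(),
        replicate_values=(
            [(v - fit.b) / scale for v in curve.replicate_values]
            if curve.replicate_values is not None
            else None
        ),
        blank_values=(
            [v / scale for v in curve.blank_values]
            if curve.blank_values is not None
            else None
        ),
        protein_id=curve.protein_id,
        readout="normalized",
    )
    s, xh, rss, ok = _fit_normalized(norm.peg_pct, norm.mean, fit.s, fit.peg_half)
    return norm, FitResult(a=1.0, b=0.0, s=s, peg_half=xh, rss=rss, converged=ok)


def bootstrap_ci(
    curve: SolubilityCurve,
    fit: FitResult,
    n_cycles: int = 500,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> FitResult:
    """Percentile bootstrap confidence intervals on PEG₁/₂ and the slope.

    Uses case resampling of the technical-replicate wells within each
    concentration when replicate values are available (≥2 wells everywhere);
    otherwise falls back to resampling fit residuals.  Blank wells are
    resampled as cases too when the curve carries them: the blank-mean
    subtracted from every sample well at a concentration is itself an
    estimate, and its error is common to the whole point, invisible to
    sample-well resampling alone.  Resampled means carry the standard
    finite-sample scale correction √(n/(n−1)), without which the bootstrap
    SE of a mean of n resampled cases is biased low by √((n−1)/n) — material
    at the 2-4 technical replicates typical here.  Each cycle refits the
    normalised two-parameter sigmoid.  Intervals are widened, if needed, to
    contain the point estimate.  Fully deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y = curve.peg_pct, curve.mean
    reps = curve.replicate_values
    case = reps is not None and all(len(v) >= 2 for v in reps)
    if case:
        centers = np.array([v.mean() for v in reps])
        inflate = np.array([np.sqrt(len(v) / (len(v) - 1.0)) for v in reps])
        blanks = curve.blank_values
        use_blanks = blanks is not None and all(len(v) >= 2 for v in blanks)
        if use_blanks:
            b_centers = np.array([v.mean() for v in blanks])
            b_inflate = np.array([np.sqrt(len(v) / (len(v) - 1.0)) for v in blanks])
    model = fit.predict(x)
    resid = y - model
    s_star, x_star = [], []
    failures = 0
    for _ in range(n_cycles):
        if case:
            means = np.array([rng.choice(v, size=len(v)).mean() for v in reps])
            y_b = centers + inflate * (means - centers)
            if use_blanks:
                b_means = np.array([rng.choice(v, size=len(v)).mean() for v in blanks])
                y_b = y_b - b_inflate * (b_means - b_centers)
        else:
            y_b = model + rng.choice(resid, size=resid.size, replace=True)
        s, xh, _, ok = _fit_normalized(x, y_b, fit.s, fit.peg_half)
        if ok:
            s_star.append(s)
            x_star.append(xh)
        else:
            failures += 1
    if failures > 0.2 * n_cycles:
        warnings.warn(
            f"{failures}/{n_cycles} bootstrap refits failed to converge; "
            "intervals may be unreliable"
        )
    if not s_star:
        raise RuntimeError("every bootstrap refit failed")
    alpha = 100 * (1 - level) / 2
    lo_x, hi_x = np.percentile(x_star, [alpha, 100 - alpha])
    lo_s, hi_s = np.percentile(s_star, [alpha, 100 - alpha])
    # Small-sample correction: with few replicate wells per point the
    # bootstrap variance is itself estimated on few degrees of freedom, so
    # the percentile interval behaves like a z-interval where a t-interval
    # is required.  Scale deviations from the point estimate by t/z at the
    # Welch-Satterthwaite effective dof of the replicate design.
    if case:
        f_s, f_x = _t_over_z_factors(curve, fit, level, use_blanks)
    else:
        nu = max(x.size - 2, 1)
        f_s = f_x = _t_dist.ppf(1 - (1 - level) / 2, nu) / _norm_dist.ppf(
            1 - (1 - level) / 2
        )
    lo_x = fit.peg_half + f_x * (float(lo_x) - fit.peg_half)
    hi_x = fit.peg_half + f_x * (float(hi_x) - fit.peg_half)
    lo_s = fit.s + f_s * (float(lo_s) - fit.s)
    hi_s = fit.s + f_s * (float(hi_s) - fit.s)
    return replace(
        fit,
        ci95_peg_half=(min(lo_x, fit.peg_half), max(hi_x, fit.peg_half)),
        ci95_s=(min(lo_s, fit.s), max(hi_s, fit.s)),
        n_boot=len(s_star),
    )


def _t_over_z_factors(
    curve: SolubilityCurve, fit: FitResult, level: float, use_blanks: bool
) -> tuple[float, float]:
    """t/z interval-scaling factors for (s, peg_half).

    Linearizing the two-parameter fit, each estimate is a weighted sum of
    the per-point means, whose variances are estimated from n_i replicate
    wells (and m_i blank wells) on n_i−1 (m_i−1) dof each; the effective dof
    of the combination follow Welch-Satterthwaite.
    """
    x = curve.peg_pct
    sig = _logistic(x, fit.s, fit.peg_half)
    d = sig * (1.0 - sig)
    jac = np.column_stack([-d * (x - fit.peg_half), d * fit.s])
    h = np.linalg.pinv(jac)  # 2 × n: rows map point errors to (s, x0) errors
    comps: list[list[tuple[float, float]]] = [[], []]  # per param: (c_k, dof_k)
    for i, v in enumerate(curve.replicate_values):
        parts = [(float(np.var(v, ddof=1)) / len(v), len(v) - 1)]
        if use_blanks:
            b = curve.blank_values[i]
            parts.append((float(np.var(b, ddof=1)) / len(b), len(b) - 1))
        for p in range(2):
            w = h[p, i] ** 2
            comps[p].extend((w * var, dof) for var, dof in parts)
    q = 1 - (1 - level) / 2
    z = _norm_dist.ppf(q)
    factors = []
    for parts in comps:
        total = sum(c for c, _ in parts)
        if total <= 0:
            factors.append(1.0)
            continue
        denom = sum(c * c / dof for c, dof in parts if dof > 0)
        nu = total * total / denom if denom > 0 else np.inf
        factors.append(float(_t_dist.ppf(q, max(nu, 1.0)) / z))
    return factors[0], factors[1]


def estimate_onset(fit: FitResult) -> float:
    """Precipitation onset: tangent at the inflection extended to the upper
    plateau.

    The tangent at PEG₁/₂ has slope −s(a−b)/4 and passes through (a+b)/2, so
    it meets y = a at PEG₁/₂ − 2/s, independent of the plateau values.
    """
    if not fit.converged:
        raise ValueError("onset requires a converged fit")
    if fit.s <= 0:
        raise ValueError("onset requires a positive slope")
    return fit.peg_half - 2.0 / fit.s


def extrapolate_apparent_solubility(
    curve: SolubilityCurve,
    fit: FitResult,
    window: tuple[float, float] = (0.2, 0.8),
) -> DerivedSolubility:
    """Log-linear extrapolation of the transition region to 0 % PEG.

    Points whose fitted value lies between 20 % and 80 % of the drop (and
    whose measured value is strictly positive) enter a linear fit of
    ln(concentration) vs PEG %; the intercept exponentiated is the apparent
    absolute solubility.  The estimate is extremely sensitive to small
    errors in the transition points and is reported as apparent only.
    """
    x, y = curve.peg_pct, curve.mean
    frac = (fit.predict(x) - fit.b) / (fit.a - fit.b)
    lo, hi = window
    mask = (frac >= lo) & (frac <= hi) & (y > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} usable transition points (< 3); "
            "cannot extrapolate apparent solubility"
        )
    slope, intercept = np.polyfit(x[mask], np.log(y[mask]), 1)
    return DerivedSolubility(
        onset_peg=estimate_onset(fit),
        apparent_solubility=float(np.exp(intercept)),
        extrapolation_points=int(mask.sum()),
    )


def plot_fit(
    curve: SolubilityCurve,
    fit: FitResult,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Plot the curve, the fitted sigmoid and the PEG₁/₂ CI band to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(
        curve.peg_pct, curve.mean, yerr=curve.sd, fmt="o", ms=4, capsize=2,
        label="data",
    )
    xs = np.linspace(curve.peg_pct.min(), curve.peg_pct.max(), 300)
    ax.plot(xs, fit.predict(xs), "-", label="fit")
    ax.axvline(fit.peg_half, color="k", lw=0.8, label=f"PEG$_{{1/2}}$ = {fit.peg_half:.2f}%")
    if fit.ci95_peg_half:
        ax.axvspan(*fit.ci95_peg_half, color="k", alpha=0.12, label="95% CI")
    ax.set_xlabel("PEG (% w/v)")
    ax.set_ylabel(
        "soluble concentration (mg/mL)"
        if curve.readout == "concentration"
        else ("soluble fraction" if curve.readout == "normalized" else "turbidity (AU)")
    )
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
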