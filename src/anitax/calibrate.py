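"""Calibration of genome-wide ANI against multilocus sequence similarity.

When a taxon cannot be genome-sequenced (an obligate endosymbiont, say)
its ANI against sequenced relatives can still be predicted from the
similarity of a concatenated housekeeping-locus panel. The calibration
fits the three-parameter logarithmic curve

    ANI = a + b * ln(sim - c)

to (similarity %, ANI %) pairs from genome-sequenced taxa, then maps new
similarities through the fitted curve with residual-based t prediction
intervals. The curve is only defined for sim > c; the offset c sits below
the smallest observed similarity and produces the saturating shape the
empirical relationship shows.

Fitting profiles the nonlinear parameter: for fixed c the model is linear
in (a, b), so a grid over c (with closed-form a, b at each node) locates
the global basin cheaply, a bounded 1-D refinement polishes c, and a final
full 3-parameter Levenberg–Marquardt pass tightens everything. This
sidesteps the flat likelihood ridge that appears when c approaches
min(sim).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .seqio import SymMatrix

__all__ = [
    "CalibrationModel",
    "AniPrediction",
    "CalibrationError",
    "fit_calibration",
    "predict_ani",
    "bootstrap_intervals",
    "correlation_report",
]

SPECIES_ANI_THRESHOLD = 95.0


class CalibrationError(RuntimeError):
    """Raised when the calibration fit cannot be completed."""


@dataclass
class CalibrationModel:
    """Fitted map from multilocus similarity (%) to ANI (%)."""

    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    residuals: np.ndarray
    fit_converged: bool
    sim_range: tuple[float, float]

    @property
    def residual_sd(self) -> float:
        dof = self.n_points - 3
        if dof <= 0:
            return float("nan")
        return float(np.sqrt(np.sum(self.residuals**2) / dof))

    def predict(self, sim_pct: float | np.ndarray) -> float | np.ndarray:
        sim = np.asarray(sim_pct, dtype=float)
        if np.any(sim <= self.c):
            raise ValueError(
                f"similarity {sim_pct} outside model support (requires sim > c = {self.c:.3f})"
            )
        out = self.a + self.b * np.log(sim - self.c)
        return float(out) if np.isscalar(sim_pct) else out

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "r_squared": self.r_squared, "n_points": self.n_points,
            "residual_sd": self.residual_sd, "fit_converged": self.fit_converged,
            "sim_range": list(self.sim_range),
        }


@dataclass(frozen=True)
class AniPrediction:
    """Predicted ANI for one taxon pair, with a t prediction interval."""

    taxon_pair: tuple[str, str]
    sim_pct: float
    predicted_ani: float
    lower: float
    upper: float

    @property
    def below_species_threshold(self) -> bool:
        """True when even the interval's upper bound sits below 95 % ANI."""
        return self.upper < SPECIES_ANI_THRESHOLD


def _profile_ab(sims: np.ndarray, anis: np.ndarray, c: float) -> tuple[float, float, float]:
    """Closed-form (a, b) and SSR for fixed c (model linear in a, b)."""
    x = np.log(sims - c)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, anis, rcond=None)
    resid = anis - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    c_grid_size: int = 20,
    polish: bool = True,
) -> CalibrationModel:
    """Least-squares fit of ANI = a + b·ln(sim − c).

    ``points`` are (similarity %, ANI %) pairs; at least 4 are required and
    the similarities must not all coincide. Deterministic: the c grid spans
    [min(sim) − 40, min(sim) − 0.5], the best node is refined by bounded
    1-D minimization, and (optionally) a full 3-parameter least-squares
    polish runs from that start.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (sim_pct, ani_pct) pairs")
    if pts.shape[0] < 4:
        raise ValueError(f"need at least 4 points to fit 3 parameters, got {pts.shape[0]}")
    sims, anis = pts[:, 0], pts[:, 1]
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite calibration points")
    if np.ptp(sims) == 0:
        raise ValueError("degenerate input: all similarities equal")

    smin = float(sims.min())
    lo, hi = smin - 40.0, smin - 0.5
    grid = np.linspace(lo, hi, c_grid_size)
    ssr_grid = [_profile_ab(sims, anis, c)[2] for c in grid]
    c0 = float(grid[int(np.argmin(ssr_grid))])

    res = optimize.minimize_scalar(
        lambda c: _profile_ab(sims, anis, c)[2],
        bounds=(lo, smin - 1e-9),
        method="bounded",
        options={"xatol": 1e-12},
    )
    c_best = float(res.x) if res.fun <= min(ssr_grid) else c0
    a_best, b_best, ssr_best = _profile_ab(sims, anis, c_best)

    if polish:
        def residual_fn(theta):
            a, b, c = theta
            return a + b * np.log(np.maximum(sims - c, 1e-12)) - anis

        # c stays inside the documented search window: letting it run to -inf
        # rides the flat likelihood ridge where the curve degenerates to a line
        ls = optimize.least_squares(
            residual_fn,
            x0=[a_best, b_best, c_best],
            bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, smin - 1e-9]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        ssr_ls = float(2 * ls.cost)
        if np.isfinite(ssr_ls) and ssr_ls <= ssr_best + 1e-12:
            a_best, b_best, c_best = map(float, ls.x)
            ssr_best = ssr_ls
    converged = bool(np.isfinite(ssr_best) and np.isfinite([a_best, b_best, c_best]).all())

    resid = anis - (a_best + b_best * np.log(sims - c_best))
    ss_tot = float(np.sum((anis - anis.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    model = CalibrationModel(
        a=a_best, b=b_best, c=c_best,
        r_squared=r2, n_points=int(pts.shape[0]),
        residuals=resid, fit_converged=converged,
        sim_range=(smin, float(sims.max())),
    )
    if not converged:
        raise CalibrationError(
            f"calibration fit did not converge; best SSR {ssr_best:.4g} with "
            f"(a, b, c) = ({a_best:.4g}, {b_best:.4g}, {c_best:.4g})"
        )
    return model


def predict_ani(
    model: CalibrationModel,
    sim_pct: float,
    taxon_pair: tuple[str, str] = ("query", "reference"),
    alpha: float = 0.05,
) -> AniPrediction:
    """Predict ANI for one similarity with a residual-based t interval.

    The interval is prediction ± t(1−α/2, n−3) · residual SD. Similarities
    at or below the model offset c are outside the curve's domain and
    raise.
    """
    if sim_pct <= model.c:
        raise ValueError(
            f"similarity {sim_pct} is at or below the model offset c = {model.c:.3f}; "
            "prediction undefined"
        )
    pred = model.predict(sim_pct)
    dof = model.n_points - 3
    half = stats.t.ppf(1 - alpha / 2, dof) * model.residual_sd if dof > 0 else float("inf")
    return AniPrediction(
        taxon_pair=tuple(taxon_pair),
        sim_pct=float(sim_pct),
        predicted_ani=float(pred),
        lower=float(pred - half),
        upper=float(pred + half),
    )


def bootstrap_intervals(
    points: Sequence[tuple[float, float]],
    n_boot: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap confidence intervals for (a, b, c).

    Cases (points) are resampled with replacement; degenerate resamples
    (all similarities equal) are redrawn. The quick profile fit (no
    polish) is used per replicate for speed.
    """
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    n = pts.shape[0]
    samples = {"a": [], "b": [], "c": []}
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(pts[idx, 0]) > 0:
                break
        try:
            m = fit_calibration(pts[idx], polish=False)
        except (ValueError, CalibrationError):
            continue
        samples["a"].append(m.a)
        samples["b"].append(m.b)
        samples["c"].append(m.c)
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    return {
        k: tuple(np.percentile(v, qs)) for k, v in samples.items() if v
    }


def correlation_report(
    sim: SymMatrix,
    ani: SymMatrix,
    plot_path: str | None = None,
) -> dict:
    """Pair up shared taxa of a similarity and an ANI matrix and fit the curve.

    Returns the paired points, the fitted model, and an F-test p-value of
    the fitted curve against an intercept-only model. Optionally writes a
    scatter-plus-curve plot.
    """
    shared = [l for l in sim.labels if l in ani.labels]
    if len(shared) < 3:
        raise ValueError(f"matrices share only {len(shared)} taxa; need at least 3")
    points, pairs = [], []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            s = sim.value(shared[i], shared[j])
            v = ani.value(shared[i], shared[j])
            if np.isfinite(s) and np.isfinite(v):
                points.append((s, v))
                pairs.append((shared[i], shared[j]))
    if len(points) < 4:
        raise ValueError(f"only {len(points)} shared pairs with values; need at least 4")
    model = fit_calibration(points)

    anis = np.array([p[1] for p in points])
    n = len(points)
    ss_tot = float(np.sum((anis - anis.mean()) ** 2))
    ss_res = float(np.sum(model.residuals**2))
    df_model, df_resid = 2, n - 3  # two slope-like params beyond the intercept
    if df_resid > 0 and ss_res > 0:
        f_stat = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
        p_value = float(stats.f.sf(f_stat, df_model, df_resid))
    else:
        f_stat, p_value = float("inf"), 0.0

    if plot_path is not None:
        _plot_calibration(points, model, plot_path)

    return {
        "pairs": pairs,
        "points": points,
        "model": model,
        "r_squared": model.r_squared,
        "f_statistic": f_stat,
        "p_value": p_value,
    }


def _plot_calibration(points, model: CalibrationModel, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sims = np.array([p[0] for p in points])
    anis = np.array([p[1] for p in points])
    grid = np.linspace(sims.min(), sims.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(sims, anis, s=25, color="k", zorder=3)
    ax.plot(grid, model.predict(grid), color="tab:red",
            label=f"ANI = {model.a:.1f} + {model.b:.1f}·ln(sim − {model.c:.1f})")
    ax.set_xlabel("multilocus sequence similarity (%)")
    ax.set_ylabel("ANI (%)")
    ax.legend(fontsize=8)
    ax.set_title(f"R² = {model.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
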