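"""Initial-rate and dose-response model fitting with AICc model selection.

Models
------
Michaelis–Menten (MM)        v = Vmax * S / (Km + S)
Substrate inhibition (SI)    v = Vmax * S / (Km + S + S^2 / Ki)
Four-parameter logistic (4PL) y = bottom + (top - bottom) / (1 + (x / IC50)^hill)

The SI form is the canonical uncompetitive-substrate-inhibition rate law; its
curve rises, peaks at S = sqrt(Km * Ki), and falls — the signature of a
substrate that binds a second, inhibitory site at high concentration.  As
Ki → ∞ it reduces to MM.  Rates stay in assay signal units (e.g. cpm/min);
no molar calibration is attempted.

Model choice between MM and SI uses small-sample-corrected Akaike
information criterion (AICc); |ΔAICc| < 2 is flagged ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError


@dataclass
class RateSeries:
    """Initial-rate measurements for one substrate.

    ``points`` are (concentration, rate, replicate) triples; concentration in
    μM, rate in signal units per unit time.
    """

    substrate_id: str
    points: list[tuple[float, float, int]]
    enzyme_concentration: float | None = None

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, substrate_id: str | None = None
                   ) -> "RateSeries":
        if substrate_id is not None:
            df = df[df["substrate_id"] == substrate_id]
        elif "substrate_id" in df.columns:
            substrate_id = str(df["substrate_id"].iloc[0])
        reps = df["replicate"] if "replicate" in df.columns else [1] * len(df)
        pts = [(float(c), float(r), int(k)) for c, r, k in
               zip(df["concentration_uM"], df["rate"], reps)]
        return cls(substrate_id=substrate_id or "", points=pts)


@dataclass
class KineticFit:
    model: str  # "MM", "SI" or "4PL"
    parameters: dict[str, float]
    standard_errors: dict[str, float]
    aicc: float
    converged: bool
    rss: float = np.nan
    n_points: int = 0
    diagnostics: str = ""
    ambiguous: bool = field(default=False)

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        p = self.parameters
        if self.model == "MM":
            return mm_rate(s, p["Vmax"], p["Km"])
        if self.model == "SI":
            return si_rate(s, p["Vmax"], p["Km"], p["Ki"])
        if self.model == "4PL":
            return logistic4(s, p["top"], p["bottom"], p["IC50"], p["hill"])
        raise ValueError(f"unknown model {self.model!r}")


def mm_rate(s, vmax, km):
    return vmax * s / (km + s)


def si_rate(s, vmax, km, ki):
    return vmax * s / (km + s + s * s / ki)


def logistic4(x, top, bottom, ic50, hill):
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, bottom, dtype=float)
    pos = x > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (x[pos] / ic50) ** hill)
    out[~pos] = top  # zero inhibitor: full activity
    return out


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC for a Gaussian least-squares fit."""
    rss = max(float(rss), np.finfo(float).tiny)
    base = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        base += 2 * k * (k + 1) / (n - k - 1)
    return float(base)


def _half_max_concentration(s: np.ndarray, v: np.ndarray) -> float:
    """Interpolated concentration where the rate first crosses half max."""
    order = np.argsort(s)
    s, v = s[order], v[order]
    half = v.max() / 2.0
    above = np.nonzero(v >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return float(s[s > 0].min()) if np.any(s > 0) else 1.0
    i = above[0]
    s0, s1, v0, v1 = s[i - 1], s[i], v[i - 1], v[i]
    if v1 == v0:
        return float(s1)
    return float(s0 + (half - v0) * (s1 - s0) / (v1 - v0))


def _require_distinct(series: RateSeries, n: int) -> None:
    if len(set(series.concentrations.tolist())) < n:
        raise ValueError(f"need >= {n} distinct concentrations for this fit")


def _ls_fit(model, fn, series: RateSeries, p0, names, bounds) -> KineticFit:
    s, v = series.concentrations, series.rates
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(fn, s, v, p0=p0, bounds=bounds, maxfev=20_000)
        resid = v - fn(s, *popt)
        rss = float(resid @ resid)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        return KineticFit(
            model=model,
            parameters=dict(zip(names, map(float, popt))),
            standard_errors=dict(zip(names, map(float, se))),
            aicc=aicc(rss, len(s), len(names) + 1),  # +1 for sigma
            converged=True,
            rss=rss,
            n_points=len(s),
        )
    except (RuntimeError, ValueError) as exc:
        return KineticFit(
            model=model,
            parameters=dict.fromkeys(names, np.nan),
            standard_errors=dict.fromkeys(names, np.nan),
            aicc=np.inf,
            converged=False,
            n_points=len(s),
            diagnostics=str(exc),
        )


def fit_mm(series: RateSeries) -> KineticFit:
    """Least-squares Michaelis–Menten fit."""
    _require_distinct(series, 4)
    s, v = series.concentrations, series.rates
    p0 = [max(v.max(), 1e-9), max(_half_max_concentration(s, v), 1e-9)]
    return _ls_fit("MM", mm_rate, series, p0, ["Vmax", "Km"],
                   ([0, 0], [np.inf, np.inf]))


def fit_si(series: RateSeries) -> KineticFit:
    """Least-squares substrate-inhibition fit; curve peaks at sqrt(Km*Ki)."""
    _require_distinct(series, 4)
    s, v = series.concentrations, series.rates
    p0 = [max(v.max(), 1e-9), max(_half_max_concentration(s, v), 1e-9),
          max(s.max(), 1e-9)]
    return _ls_fit("SI", si_rate, series, p0, ["Vmax", "Km", "Ki"],
                   ([0, 0, 0], [np.inf, np.inf, np.inf]))


def select_model(series: RateSeries, ambiguity_band: float = 2.0
                 ) -> tuple[KineticFit, dict[str, KineticFit]]:
    """Fit MM and SI, pick the lower-AICc model; |ΔAICc| < band ⇒ ambiguous."""
    fits = {"MM": fit_mm(series), "SI": fit_si(series)}
    if not any(f.converged for f in fits.values()):
        raise FitError(f"neither MM nor SI converged for {series.substrate_id!r}")
    winner = min(fits.values(), key=lambda f: f.aicc)
    delta = abs(fits["MM"].aicc - fits["SI"].aicc)
    if np.isfinite(delta) and delta < ambiguity_band:
        winner.ambiguous = True
    winner.diagnostics = (winner.diagnostics +
                          f" dAICc={delta:.3f}").strip()
    return winner, fits


def fit_ic50(dose_response) -> KineticFit:
    """Four-parameter logistic fit of an inhibition dose-response curve.

    ``dose_response`` is a list of (inhibitor concentration μM, activity)
    pairs or a RateSeries; needs >= 5 distinct concentrations spanning the
    transition.
    """
    if isinstance(dose_response, RateSeries):
        series = dose_response
    else:
        series = RateSeries("", [(float(c), float(a), 1) for c, a in dose_response])
    _require_distinct(series, 5)
    s, v = series.concentrations, series.rates
    top0, bottom0 = float(v.max()), float(v.min())
    pos = s[s > 0]
    # inhibitor concentration where activity crosses the top/bottom midpoint
    mid = (top0 + bottom0) / 2.0
    below = s[v <= mid]
    ic0 = float(below.min()) if len(below) and below.min() > 0 else float(np.median(pos))
    p0 = [top0, bottom0, max(ic0, 1e-9), 1.0]
    return _ls_fit("4PL", logistic4, series, p0,
                   ["top", "bottom", "IC50", "hill"],
                   ([-np.inf, -np.inf, 0, 0], [np.inf, np.inf, np.inf, np.inf]))


def read_rate_table(path) -> pd.DataFrame:
    """Read a rate TSV: substrate_id, concentration_uM, rate[, replicate]."""
    return pd.read_csv(path, sep="\t")


def fits_to_frame(fits: dict[str, KineticFit] | list[KineticFit]) -> pd.DataFrame:
    if isinstance(fits, dict):
        fits = list(fits.values())
    rows = []
    for f in fits:
        row = {"model": f.model, "aicc": f.aicc, "converged": f.converged,
               "ambiguous": f.ambiguous}
        for k, v in f.parameters.items():
            row[k] = v
            row[f"{k}_se"] = f.standard_errors.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
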