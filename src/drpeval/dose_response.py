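"""Four-parameter logistic dose-response modelling and standardized areas.

The viability of a cell line exposed to a drug at concentration ``c`` is
modelled with the four-parameter logistic (4PL, Hill) curve

    f(c) = lower + (upper - lower) / (1 + (c / inflection)**hill)

where ``upper`` and ``lower`` are the asymptotic viabilities at vanishing
and saturating dose, ``inflection`` is the EC50 (the concentration at the
midpoint between the asymptotes) and ``hill`` is the slope. The model is
fit by least squares in log10-concentration space with deterministic
multi-start initialization, statsmodels-style: build a
:class:`FourParamLogistic` model from an experiment, call :meth:`fit`, get
a :class:`FourPLResults` carrying estimates and diagnostics.

Two summary statistics are derived from a fitted curve:

* the absolute IC50 — the concentration where the curve crosses a fixed
  viability threshold (0.5 by default), distinct from the EC50 parameter;
* the standardized AUDRC — the mean of the clamped fitted viability over a
  *fixed* log10-concentration window (100 pM to 100 uM by default), so
  that screens run over different experimental ranges become comparable.
  AUDRC is 1 for a drug with no effect and 0 for complete killing across
  the window; AADRC = 1 - AUDRC is the corresponding drug-effect area.

``audrc_trapezoid_experimental`` reproduces the legacy convention
(trapezoids over each experiment's own range) purely to demonstrate why it
is not comparable across ranges.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .datasets import DoseResponseExperiment, ResponseType, TripletDataset

logger = logging.getLogger("drpeval")

__all__ = [
    "StandardRange",
    "FitBounds",
    "FourParamLogistic",
    "FourPLResults",
    "SensitivityCall",
    "four_pl",
    "fit_4pl",
    "absolute_ic50",
    "audrc",
    "aadrc",
    "audrc_trapezoid_experimental",
    "normalize_responses",
    "binarize",
    "fit_table",
]


@dataclass(frozen=True)
class StandardRange:
    """Fixed concentration window for standardized areas (molar).

    Defaults span 100 pM to 100 uM — six orders of magnitude, wide enough
    to cover the therapeutic window of most approved oncology compounds.
    """

    cmin: float = 1e-10
    cmax: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.cmin < self.cmax):
            raise ValueError("require 0 < cmin < cmax")

    @property
    def span_log10(self) -> float:
        """Width of the window in log10 units (orders of magnitude)."""
        return math.log10(self.cmax / self.cmin)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the 4PL fit.

    The Hill slope is kept in [0.1, 10] by default to stop divergence on
    sparse or flat curves; asymptotes may drift moderately outside [0, 1]
    because control-normalized viabilities do. The EC50 bound is expressed
    in log10 molar and widened around the observed concentration range at
    fit time when left at its defaults.
    """

    upper: tuple[float, float] = (-1.0, 3.0)
    lower: tuple[float, float] = (-1.0, 3.0)
    log10_inflection: tuple[float, float] = (-14.0, 0.0)
    hill: tuple[float, float] = (0.1, 10.0)


class SensitivityCall(str, enum.Enum):
    SENSITIVE = "sensitive"
    RESISTANT = "resistant"
    UNDEFINED = "undefined"


def four_pl(
    c: np.ndarray | float,
    upper: float,
    lower: float,
    inflection: float,
    hill: float,
) -> np.ndarray | float:
    """Evaluate the 4PL curve at molar concentration(s) ``c``."""
    c = np.asarray(c, dtype=float)
    # (c / e)**h computed in log space for numerical range
    t = hill * (np.log10(c) - math.log10(inflection))
    return lower + (upper - lower) / (1.0 + 10.0 ** t)


def _four_pl_logx(x: np.ndarray, upper: float, lower: float, m: float, hill: float):
    """4PL evaluated at x = log10(c), m = log10(inflection)."""
    return lower + (upper - lower) / (1.0 + 10.0 ** (hill * (x - m)))


class FourParamLogistic:
    """4PL dose-response model for one experiment.

    Parameters
    ----------
    experiment : DoseResponseExperiment
        At least four strictly increasing positive molar concentrations
        with their viabilities.
    bounds : FitBounds, optional
        Box constraints; Hill default [0.1, 10].

    Examples
    --------
    >>> import numpy as np
    >>> from drpeval.datasets import DoseResponseExperiment
    >>> conc = np.logspace(-10, -4, 9)
    >>> viab = 1.0 / (1.0 + conc / 1e-7)
    >>> exp = DoseResponseExperiment("e1", "C1", "D1", conc, viab)
    >>> res = FourParamLogistic(exp).fit()
    >>> round(res.audrc(), 6)
    0.5
    """

    def __init__(
        self,
        experiment: DoseResponseExperiment,
        bounds: FitBounds | None = None,
    ) -> None:
        self.experiment = experiment
        self.bounds = bounds or FitBounds()

    @classmethod
    def from_arrays(
        cls,
        concentrations: Sequence[float],
        viabilities: Sequence[float],
        bounds: FitBounds | None = None,
        **ids: str,
    ) -> "FourParamLogistic":
        exp = DoseResponseExperiment(
            experiment_id=ids.get("experiment_id", ""),
            cell_id=ids.get("cell_id", ""),
            drug_id=ids.get("drug_id", ""),
            concentrations=np.asarray(concentrations, dtype=float),
            viabilities=np.asarray(viabilities, dtype=float),
        )
        return cls(exp, bounds=bounds)

    # ------------------------------------------------------------------
    def _starts(self, n_starts: int) -> list[np.ndarray]:
        """Deterministic multi-start points derived from the data.

        EC50 starts at quantiles of the observed log-concentration range,
        asymptotes at the extreme viabilities, Hill slope at 1 and 2. No
        RNG is involved, so fits are reproducible by construction.
        """
        x = self.experiment.log10_concentrations
        v = self.experiment.viabilities
        b = self._effective_bounds()
        qs = np.linspace(0.1, 0.9, max(n_starts, 5))
        u0 = float(np.clip(np.max(v), *b.upper))
        l0 = float(np.clip(np.min(v), *b.lower))
        if u0 == l0:  # keep start strictly inside an open interval
            u0 += 1e-3
        starts = []
        for i, q in enumerate(qs):
            m0 = float(np.clip(np.quantile(x, q), *b.log10_inflection))
            h0 = 1.0 if i % 2 == 0 else 2.0
            starts.append(np.array([u0, l0, m0, h0]))
        return starts

    def _effective_bounds(self) -> FitBounds:
        """Widen the default EC50 bound around the observed range."""
        b = self.bounds
        if b.log10_inflection == FitBounds().log10_inflection:
            x = self.experiment.log10_concentrations
            lo = min(b.log10_inflection[0], x[0] - 3.0)
            hi = max(b.log10_inflection[1], x[-1] + 3.0)
            return FitBounds(b.upper, b.lower, (lo, hi), b.hill)
        return b

    def fit(self, n_starts: int = 7) -> "FourPLResults":
        """Least-squares fit with deterministic multi-start.

        Returns the lowest-RSS converged solution over ``n_starts``
        quantile-derived initializations; if no start converges, the best
        attempt is returned with ``converged=False``. A flat response
        (all viabilities identical) yields a degenerate fit with
        ``upper == lower``, ``hill = 0`` and ``identifiable=False`` rather
        than an exception.
        """
        exp = self.experiment
        x = exp.log10_concentrations
        v = exp.viabilities

        if np.ptp(v) == 0.0:
            val = float(v[0])
            logger.warning(
                "fit_4pl(%s): flat response (all viabilities = %g); "
                "returning non-identifiable degenerate fit", exp.experiment_id, val,
            )
            return FourPLResults(
                model=self, upper=val, lower=val,
                inflection=float(10 ** np.mean(x)), hill=0.0,
                converged=True, identifiable=False, rss=0.0,
                n_points=exp.n_points, n_starts_converged=0,
            )

        b = self._effective_bounds()
        lo = np.array([b.upper[0], b.lower[0], b.log10_inflection[0], b.hill[0]])
        hi = np.array([b.upper[1], b.lower[1], b.log10_inflection[1], b.hill[1]])

        def residuals(p: np.ndarray) -> np.ndarray:
            return _four_pl_logx(x, *p) - v

        best = None
        n_ok = 0
        for p0 in self._starts(n_starts):
            p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
            sol = optimize.least_squares(
                residuals, p0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
            if sol.success:
                n_ok += 1
            if best is None or (sol.success and not best.success) or (
                sol.success == best.success and sol.cost < best.cost
            ):
                best = sol
        assert best is not None
        upper, lower, m, hill = (float(t) for t in best.x)
        return FourPLResults(
            model=self, upper=upper, lower=lower,
            inflection=float(10 ** m), hill=hill,
            converged=bool(n_ok > 0), identifiable=True,
            rss=float(2.0 * best.cost), n_points=exp.n_points,
            n_starts_converged=n_ok,
        )


@dataclass
class FourPLResults:
    """Fitted 4PL parameters with convergence diagnostics.

    ``inflection`` is the EC50 in molar; ``rss`` the residual sum of
    squares; ``identifiable`` is False for degenerate flat-response fits
    (where ``hill`` is reported as 0).
    """

    model: FourParamLogistic | None
    upper: float
    lower: float
    inflection: float
    hill: float
    converged: bool
    identifiable: bool
    rss: float
    n_points: int
    n_starts_converged: int = 0

    # -- curve evaluation ----------------------------------------------
    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        if not self.identifiable:
            return np.full_like(np.asarray(c, dtype=float), self.upper)
        return four_pl(c, self.upper, self.lower, self.inflection, self.hill)

    @property
    def ec50(self) -> float:
        """The inflection parameter (molar)."""
        return self.inflection

    # -- derived pharmacodynamic quantities ------------------------------
    def ic50(self, threshold: float = 0.5) -> float:
        """Absolute IC50: concentration where the curve crosses ``threshold``.

        Solved in closed form from the 4PL:
        ``c = inflection * ((upper - t) / (t - lower)) ** (1 / hill)``.
        Returns ``nan`` when the threshold is not strictly bracketed by the
        asymptotes (the curve never reaches it) or the fit is degenerate.
        """
        if not self.identifiable or self.hill == 0.0:
            return math.nan
        lo, hi = min(self.lower, self.upper), max(self.lower, self.upper)
        if not (lo < threshold < hi):
            return math.nan
        ratio = (self.upper - threshold) / (threshold - self.lower)
        return self.inflection * ratio ** (1.0 / self.hill)

    def ln_ic50(self, threshold: float = 0.5) -> float:
        """Natural log of the absolute IC50 in molar units."""
        v = self.ic50(threshold)
        return math.log(v) if v > 0 else math.nan

    def audrc(self, srange: StandardRange = StandardRange()) -> float:
        """Standardized area under the dose-response curve, in [0, 1]."""
        return audrc(self, srange)

    def aadrc(self, srange: StandardRange = StandardRange()) -> float:
        return 1.0 - audrc(self, srange)

    def summary(self) -> str:
        """Plain-text parameter table in the spirit of a fit report."""
        rows = [
            ("upper asymptote", f"{self.upper:.6g}"),
            ("lower asymptote", f"{self.lower:.6g}"),
            ("EC50 (M)", f"{self.inflection:.6g}"),
            ("Hill slope", f"{self.hill:.6g}"),
            ("abs. IC50 (M)", f"{self.ic50():.6g}"),
            ("AUDRC [100 pM, 100 uM]", f"{self.audrc():.6g}"),
            ("RSS", f"{self.rss:.6g}"),
            ("n points", str(self.n_points)),
            ("converged", str(self.converged)),
            ("identifiable", str(self.identifiable)),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Four-parameter logistic fit", "-" * (width + 14)]
        lines += [f"{k.ljust(width)}  {v.rjust(12)}" for k, v in rows]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_4pl(
    experiment: DoseResponseExperiment,
    bounds: FitBounds | None = None,
    n_starts: int = 7,
) -> FourPLResults:
    """Fit a 4PL curve to one experiment (see :class:`FourParamLogistic`)."""
    return FourParamLogistic(experiment, bounds=bounds).fit(n_starts=n_starts)


def absolute_ic50(fit: FourPLResults, threshold: float = 0.5) -> float:
    """Concentration at which the fitted curve crosses ``threshold`` viability."""
    return fit.ic50(threshold)


def _clamp_crossings(fit: FourPLResults, lo_x: float, hi_x: float) -> list[float]:
    """log10 concentrations where the curve crosses 0 or 1 inside the window.

    Passed to the quadrature as breakpoints, since clamping introduces
    kinks the adaptive rule should not have to discover on its own.
    """
    pts = []
    for bound in (0.0, 1.0):
        lo, hi = min(fit.lower, fit.upper), max(fit.lower, fit.upper)
        if lo < bound < hi and fit.hill != 0.0:
            ratio = (fit.upper - bound) / (bound - fit.lower)
            c = fit.inflection * ratio ** (1.0 / fit.hill)
            x = math.log10(c)
            if lo_x < x < hi_x:
                pts.append(x)
    return sorted(pts)


def audrc(
    fit: FourPLResults,
    srange: StandardRange = StandardRange(),
    epsabs: float = 1e-8,
) -> float:
    """Standardized AUDRC of a fitted curve over a fixed window.

    The fitted viability, clamped to [0, 1], is integrated over
    ``x = log10(c)`` across the window by adaptive quadrature and divided
    by the window width, so the result lies in [0, 1]: 1 means no drug
    effect anywhere in the window, 0 complete killing throughout.
    """
    lo_x, hi_x = math.log10(srange.cmin), math.log10(srange.cmax)
    if not fit.identifiable:
        return float(np.clip(fit.upper, 0.0, 1.0))

    def integrand(x: float) -> float:
        return float(
            np.clip(_four_pl_logx(x, fit.upper, fit.lower,
                                  math.log10(fit.inflection), fit.hill), 0.0, 1.0)
        )

    pts = _clamp_crossings(fit, lo_x, hi_x)
    value, _ = integrate.quad(
        integrand, lo_x, hi_x, points=pts or None, epsabs=epsabs, limit=200
    )
    return value / (hi_x - lo_x)


def aadrc(fit: FourPLResults, srange: StandardRange = StandardRange()) -> float:
    """Standardized area *above* the curve: the drug-effect complement."""
    return 1.0 - audrc(fit, srange)


def audrc_trapezoid_experimental(experiment: DoseResponseExperiment) -> float:
    """Legacy AUDRC: trapezoids over the experiment's own range.

    Observed viabilities are clamped to [0, 1] and integrated over the
    experiment's own log10-concentration span, normalized by that span.
    Kept to demonstrate the pitfall the standardized definition removes:
    identical underlying curves sampled over different windows receive
    different values.
    """
    x = experiment.log10_concentrations
    v = np.clip(experiment.viabilities, 0.0, 1.0)
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def fit_table(
    experiments: Iterable[DoseResponseExperiment],
    bounds: FitBounds | None = None,
    srange: StandardRange = StandardRange(),
    n_starts: int = 7,
) -> pd.DataFrame:
    """Fit every experiment and tabulate curve summaries (CSV-ready)."""
    rows = []
    for e in experiments:
        fit = fit_4pl(e, bounds=bounds, n_starts=n_starts)
        au = audrc(fit, srange)
        rows.append(
            {
                "experiment_id": e.experiment_id,
                "cell_id": e.cell_id,
                "drug_id": e.drug_id,
                "upper": fit.upper,
                "lower": fit.lower,
                "inflection_M": fit.inflection,
                "hill": fit.hill,
                "converged": fit.converged,
                "rss": fit.rss,
                "ic50_M": fit.ic50(),
                "ln_ic50": fit.ln_ic50(),
                "audrc": au,
                "aadrc": 1.0 - au,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Response normalization and binarization
# ---------------------------------------------------------------------------

_NORM_MODES = ("minmax_global", "minmax_per_drug", "center_per_drug", "center_per_cell")


def normalize_responses(dataset: TripletDataset, mode: str) -> TripletDataset:
    """Rescale responses globally or per drug / per cell.

    ``minmax`` modes map each group linearly onto [0, 1]; ``center`` modes
    subtract the group mean (zero-centering each drug highlights which
    cells respond more than typical for that drug). Groups with zero
    variance map to 0.5 (minmax) or 0 (center) with a warning.
    """
    if mode not in _NORM_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; expected {_NORM_MODES}")
    if dataset.n_pairs == 0:
        raise ValueError("cannot normalize an empty dataset")
    df = dataset.df.copy()
    if mode == "minmax_global":
        groups = pd.Series(0, index=df.index)
    elif mode.endswith("per_drug"):
        groups = df["drug_id"]
    else:
        groups = df["cell_id"]

    centering = mode.startswith("center")
    out = np.empty(len(df), dtype=float)
    for _, idx in df.groupby(groups, sort=False).groups.items():
        r = df.loc[idx, "response"].to_numpy()
        if np.ptp(r) == 0.0:
            logger.warning(
                "normalize_responses(%s): zero-variance group; mapped to %s",
                mode, "0" if centering else "0.5",
            )
            out[df.index.get_indexer(idx)] = 0.0 if centering else 0.5
        elif centering:
            out[df.index.get_indexer(idx)] = r - r.mean()
        else:
            out[df.index.get_indexer(idx)] = (r - r.min()) / np.ptp(r)
    df["response"] = out
    if centering:
        # centered values leave any nominal [0, 1] range; skip range checks
        return TripletDataset(df, dataset.response_type, dataset.name, validate=False)
    return TripletDataset(df, ResponseType.NORMALIZED, dataset.name)


def binarize(
    dataset: TripletDataset,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
    scope: str = "per_drug",
) -> pd.DataFrame:
    """Call each pair sensitive / resistant / undefined by percentiles.

    Within each scope group (one drug, or the whole dataset), responses at
    or below the ``low_pct`` percentile are sensitive, at or above the
    ``high_pct`` percentile resistant, and anything in between undefined.
    Percentiles use linear interpolation. Groups with fewer than four
    records are skipped with a warning; a degenerate group (all responses
    identical) satisfies both rules at once and is labelled entirely
    undefined.

    Returns a frame with columns cell_id, drug_id, call.
    """
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    if scope not in ("per_drug", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    df = dataset.df
    groups = df.groupby("drug_id" if scope == "per_drug" else pd.Series(0, index=df.index),
                        sort=False)
    frames = []
    for key, grp in groups:
        if len(grp) < 4:
            logger.warning("binarize: group %r has %d < 4 records; skipped", key, len(grp))
            continue
        r = grp["response"].to_numpy()
        p_low = np.percentile(r, low_pct)
        p_high = np.percentile(r, high_pct)
        calls = np.full(len(grp), SensitivityCall.UNDEFINED.value, dtype=object)
        if np.ptp(r) == 0.0:
            logger.warning(
                "binarize: group %r has constant responses; all labelled undefined", key
            )
        else:
            sens = r <= p_low
            res = r >= p_high
            both = sens & res
            calls[sens & ~both] = SensitivityCall.SENSITIVE.value
            calls[res & ~both] = SensitivityCall.RESISTANT.value
        frames.append(
            pd.DataFrame(
                {"cell_id": grp["cell_id"], "drug_id": grp["drug_id"], "call": calls}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["cell_id", "drug_id", "call"])
    return pd.concat(frames, ignore_index=True)
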