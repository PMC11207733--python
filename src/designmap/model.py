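"""Model-assisted per-pixel mapping: the estimator at the package's core.

The map is built in four steps from the field sample:

1. *Variable selection* — candidates are pre-filtered for collinearity
   (keeping, among highly correlated pairs, the one more correlated with the
   response) and then entered by greedy forward search under the Gaussian
   Akaike information criterion ``n log(RSS/n) + 2k``.
2. *Regression* — ordinary least squares of the response on the selected
   predictors, predicted wall-to-wall.
3. *Residual interpolation* — regression residuals at the sampled pixels are
   spread to every pixel by inverse distance weighting (a sampled pixel gets
   its own residual back exactly), and added to the predictions.
4. *Harmonization* — the map is rescaled by one global ratio so its total
   equals the Horvitz-Thompson estimate of the population total; the design,
   not the model, carries the inference.

The model/results pair (`PixelMapModel` / `PixelMapResults`) wraps these
steps; the step functions are also usable directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import NumericalError, ValidationError
from .population import PixelPopulation, SamplingDesign, detect_scheme
from .design import inclusion_probabilities, horvitz_thompson_total

__all__ = ["RegressionFit", "AttributeMap", "select_variables",
           "fit_regression", "interpolate_residuals", "build_map",
           "PixelMapModel", "PixelMapResults"]


# ---------------------------------------------------------------------------
# step 1: variable selection
# ---------------------------------------------------------------------------

def _gaussian_aic(rss: float, n: int, k: int) -> float:
    # k counts estimated mean parameters (intercept + predictors)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    # X already carries the intercept column
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def select_variables(y: np.ndarray, X: pd.DataFrame,
                     collinearity_r: float = 0.95,
                     max_predictors: int | None = None,
                     ) -> tuple[list[str], list[float]]:
    """Two-phase predictor selection; returns (selected names, AIC trace).

    Phase one ranks candidates by |corr(y, x)| and walks the ranked list,
    dropping any candidate whose absolute pairwise correlation with an
    already-kept candidate exceeds ``collinearity_r``.  Phase two is forward
    stepwise least squares minimizing the Gaussian AIC, stopping when no
    addition lowers it.  Selection is capped at ``floor(n/10)`` predictors
    unless ``max_predictors`` overrides it.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValidationError(f"too few sampled pixels (n={n}) for selection")
    if np.std(y) == 0:
        raise ValidationError("response has zero variance in the sample")
    if max_predictors is None:
        max_predictors = n // 10
    max_predictors = min(max_predictors, max(n - 3, 0))

    names = list(X.columns)
    Xv = X.to_numpy(float)

    # phase 1: collinearity pre-filter on |corr with y| ranking
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = Xv.std(axis=0)
        usable = sd > 0
        corr_y = np.zeros(len(names))
        if usable.any():
            xc = (Xv[:, usable] - Xv[:, usable].mean(0)) / sd[usable]
            yc = (y - y.mean()) / np.std(y)
            corr_y[usable] = np.abs(xc.T @ yc) / n
    order = np.argsort(-corr_y, kind="stable")
    kept: list[int] = []
    for j in order:
        if not usable[j]:
            continue
        ok = True
        for i in kept:
            xi, xj = Xv[:, i], Xv[:, j]
            r = np.corrcoef(xi, xj)[0, 1]
            if np.abs(r) > collinearity_r:
                ok = False
                break
        if ok:
            kept.append(int(j))

    # phase 2: greedy forward AIC
    intercept = np.ones((n, 1))
    rss0 = _ols_rss(y, intercept)
    trace = [_gaussian_aic(rss0, n, 1)]
    selected: list[int] = []
    remaining = list(kept)
    current = intercept
    while remaining and len(selected) < max_predictors:
        best_j, best_aic = None, trace[-1]
        for j in remaining:
            Xtry = np.column_stack([current, Xv[:, j]])
            aic = _gaussian_aic(_ols_rss(y, Xtry), n, Xtry.shape[1])
            if aic < best_aic - 1e-12:
                best_j, best_aic = j, aic
        if best_j is None:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current = np.column_stack([current, Xv[:, best_j]])
        trace.append(best_aic)
    return [names[j] for j in selected], trace


# ---------------------------------------------------------------------------
# step 2: regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """OLS fit at the sampled pixels, usable to predict wall-to-wall."""

    selected_predictors: list[str]
    coefficients: np.ndarray  # intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    criterion_trace: list[float] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        M = np.column_stack(
            [np.ones(len(X))] +
            [X[c].to_numpy(float) for c in self.selected_predictors])
        return M @ self.coefficients


def fit_regression(y: np.ndarray, X_selected: pd.DataFrame,
                   criterion_trace: list[float] | None = None) -> RegressionFit:
    """OLS with intercept; errors on a rank-deficient design matrix.

    An empty predictor set degrades gracefully to the intercept-only model
    (prediction = sample mean).
    """
    y = np.asarray(y, float)
    n = len(y)
    names = list(X_selected.columns)
    M = np.column_stack([np.ones(n)] +
                        [X_selected[c].to_numpy(float) for c in names])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        raise NumericalError(
            f"rank-deficient design matrix (rank {rank} < {M.shape[1]}); "
            f"collinear set among {['intercept'] + names}")
    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    fitted = M @ beta
    return RegressionFit(selected_predictors=names, coefficients=beta,
                         fitted=fitted, residuals=y - fitted,
                         criterion_trace=criterion_trace or [])


# ---------------------------------------------------------------------------
# step 3: inverse distance weighting
# ---------------------------------------------------------------------------

def interpolate_residuals(residuals: np.ndarray, sample_xy: np.ndarray,
                          target_xy: np.ndarray, power: float = 2.0,
                          n_neighbors: int | None = None) -> np.ndarray:
    """IDW of sample residuals onto target coordinates.

    Weights are d^(-power) over the ``n_neighbors`` nearest sampled pixels
    (all of them by default).  A target coinciding with a sampled pixel
    returns that pixel's residual exactly.
    """
    residuals = np.asarray(residuals, float)
    sample_xy = np.asarray(sample_xy, float)
    target_xy = np.asarray(target_xy, float)
    if len(residuals) == 0:
        raise ValidationError("no sampled pixels to interpolate from")
    d = cdist(target_xy, sample_xy)  # (n_targets, n_sample)
    if n_neighbors is not None and n_neighbors < d.shape[1]:
        k = max(int(n_neighbors), 1)
        cutoff = np.partition(d, k - 1, axis=1)[:, k - 1:k]
        mask = d <= cutoff
    else:
        mask = np.ones_like(d, bool)
    out = np.empty(len(target_xy))
    zero = (d == 0) & mask
    has_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = np.where(mask, d, np.inf) ** (-power)
    w[has_zero] = 0.0
    rows = np.nonzero(has_zero)[0]
    if len(rows):
        first = zero[rows].argmax(axis=1)
        out[rows] = residuals[first]
    rest = ~has_zero
    if rest.any():
        wr = w[rest]
        out[rest] = (wr @ residuals) / wr.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# step 4: map assembly and harmonization
# ---------------------------------------------------------------------------

@dataclass
class AttributeMap:
    """Per-pixel harmonized estimates plus the totals that produced them.

    ``estimates`` is aligned with the population table (NaN at ineligible
    pixels).  By construction the eligible estimates sum to ``ht_total``.
    """

    estimates: np.ndarray
    ht_total: float
    map_total_raw: float
    harmonization_factor: float
    fit: RegressionFit
    pre_harmonization: np.ndarray | None = None

    def as_series(self, pop: PixelPopulation) -> pd.Series:
        return pd.Series(self.estimates, index=pop.data["pixel_id"].to_numpy(),
                         name="estimate")


def build_map(pop: PixelPopulation, design: SamplingDesign | None = None,
              collinearity_r: float = 0.95, idw_power: float = 2.0,
              idw_k: int | None = None, clamp: bool = True,
              coords_as_predictors: bool = False,
              max_predictors: int | None = None) -> AttributeMap:
    """Run selection -> regression -> IDW -> harmonization on a population.

    The population must carry responses at the sampled pixels and complete
    predictors.  Negative pre-harmonization estimates are clamped to zero by
    default (the attribute is a non-negative density); clamping happens
    before harmonization so the harmonized total still matches the HT
    estimate exactly.
    """
    pop.require_sampled()
    if design is None:
        design = detect_scheme(pop)
    el = pop.eligible
    smask_el = el["value"].notna().to_numpy()
    y = el.loc[smask_el, "value"].to_numpy(float)

    pred_names = pop.predictor_names
    candidates = list(pred_names)
    if coords_as_predictors:
        candidates += ["x", "y"]
    Xs = el.loc[smask_el, candidates] if candidates else el.loc[smask_el, []]

    # a zero-variance response (e.g. a constant pseudo-population in the
    # bootstrap) carries no signal to select on: intercept-only model
    if not candidates or np.std(y) == 0:
        selected, trace = [], []
    else:
        selected, trace = select_variables(
            y, Xs, collinearity_r=collinearity_r,
            max_predictors=max_predictors)
    fit = fit_regression(y, Xs[selected], criterion_trace=trace)

    pred_all = fit.predict(el[selected] if selected else el[[]])
    res_all = interpolate_residuals(
        fit.residuals, el.loc[smask_el, ["x", "y"]].to_numpy(float),
        el[["x", "y"]].to_numpy(float), power=idw_power, n_neighbors=idw_k)
    raw = pred_all + res_all
    if clamp:
        raw = np.maximum(raw, 0.0)

    pi = inclusion_probabilities(design, pop)
    pi_s = pi.loc[el.loc[smask_el, "pixel_id"].to_numpy()].to_numpy()
    ht = horvitz_thompson_total(y, pi_s)
    raw_total = float(raw.sum())
    if raw_total <= 0:
        raise NumericalError(
            f"harmonization undefined: raw map total {raw_total:.6g} "
            f"non-positive (HT total {ht:.6g})")
    factor = ht / raw_total
    harmonized = raw * factor

    estimates = np.full(pop.n_pixels, np.nan)
    pre = np.full(pop.n_pixels, np.nan)
    estimates[pop.eligible_mask] = harmonized
    pre[pop.eligible_mask] = pred_all + res_all
    return AttributeMap(estimates=estimates, ht_total=ht,
                        map_total_raw=raw_total,
                        harmonization_factor=factor, fit=fit,
                        pre_harmonization=pre)


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------

class PixelMapModel:
    """Model object tying a pixel population to the mapping estimator.

    Parameters mirror the pipeline knobs: IDW power and neighborhood,
    collinearity threshold, negative-value clamping, whether centroid
    coordinates join the candidate pool (they never do by default — they
    exist for the interpolator), and the forward-selection cap.

    Examples
    --------
    >>> model = PixelMapModel(pop)          # scheme auto-detected
    >>> res = model.fit()
    >>> res.ht_total, res.harmonization_factor
    >>> err = res.bootstrap_rmse(B=1000, seed=7)
    """

    def __init__(self, population: PixelPopulation,
                 design: SamplingDesign | None = None,
                 collinearity_r: float = 0.95,
                 idw_power: float = 2.0, idw_k: int | None = None,
                 clamp: bool = True, coords_as_predictors: bool = False,
                 max_predictors: int | None = None):
        population.require_sampled()
        self.population = population
        self.design = design if design is not None else detect_scheme(population)
        self.collinearity_r = collinearity_r
        self.idw_power = idw_power
        self.idw_k = idw_k
        self.clamp = clamp
        self.coords_as_predictors = coords_as_predictors
        self.max_predictors = max_predictors

    @classmethod
    def from_csv(cls, path, block_col="block", value_col="value",
                 **kwargs) -> "PixelMapModel":
        from .population import read_population
        pop = read_population(path, block_col=block_col, value_col=value_col)
        return cls(pop, **kwargs)

    def _map_kwargs(self) -> dict:
        return dict(collinearity_r=self.collinearity_r,
                    idw_power=self.idw_power, idw_k=self.idw_k,
                    clamp=self.clamp,
                    coords_as_predictors=self.coords_as_predictors,
                    max_predictors=self.max_predictors)

    def fit(self) -> "PixelMapResults":
        amap = build_map(self.population, self.design, **self._map_kwargs())
        return PixelMapResults(self, amap)


class PixelMapResults:
    """Fitted map: estimates, totals, the regression behind them.

    Carries the harmonized per-pixel estimates, the Horvitz-Thompson total,
    the harmonization factor, and the selection/regression diagnostics; the
    bootstrap error map hangs off :meth:`bootstrap_rmse`.
    """

    def __init__(self, model: PixelMapModel, attribute_map: AttributeMap):
        self.model = model
        self.attribute_map = attribute_map

    # convenient aliases
    @property
    def estimates(self) -> np.ndarray:
        return self.attribute_map.estimates

    @property
    def ht_total(self) -> float:
        return self.attribute_map.ht_total

    @property
    def map_total_raw(self) -> float:
        return self.attribute_map.map_total_raw

    @property
    def harmonization_factor(self) -> float:
        return self.attribute_map.harmonization_factor

    @property
    def params(self) -> pd.Series:
        fit = self.attribute_map.fit
        return pd.Series(fit.coefficients,
                         index=["intercept"] + fit.selected_predictors)

    @property
    def selected_predictors(self) -> list[str]:
        return self.attribute_map.fit.selected_predictors

    def bootstrap_rmse(self, B: int = 1000, seed=None, workers: int = 1):
        """Pseudo-population bootstrap RMSE map (see :mod:`designmap.bootstrap`)."""
        from .bootstrap import bootstrap_error_map
        return bootstrap_error_map(self.attribute_map, self.model.population,
                                   self.model.design, B=B, seed=seed,
                                   workers=workers,
                                   map_kwargs=self.model._map_kwargs())

    def report(self) -> dict:
        """JSON-serializable run report."""
        fit = self.attribute_map.fit
        el = self.estimates[self.model.population.eligible_mask]
        return {
            "scheme": self.model.design.scheme,
            "n_sampled": self.model.population.n_sampled,
            "n_eligible": int(self.model.population.eligible_mask.sum()),
            "selected_predictors": fit.selected_predictors,
            "coefficients": dict(zip(["intercept"] + fit.selected_predictors,
                                     map(float, fit.coefficients))),
            "criterion_trace": [float(v) for v in fit.criterion_trace],
            "ht_total": float(self.ht_total),
            "map_total_raw": float(self.map_total_raw),
            "harmonization_factor": float(self.harmonization_factor),
            "mean_estimate": float(np.mean(el)),
        }

    def summary(self) -> str:
        rep = self.report()
        lines = [
            "Design-based pixel map",
            "=" * 54,
            f"{'Sampling scheme:':<28}{rep['scheme']}",
            f"{'Sampled / eligible pixels:':<28}{rep['n_sampled']} / {rep['n_eligible']}",
            f"{'HT total:':<28}{rep['ht_total']:.6g}",
            f"{'Raw map total:':<28}{rep['map_total_raw']:.6g}",
            f"{'Harmonization factor:':<28}{rep['harmonization_factor']:.6f}",
            f"{'Mean pixel estimate:':<28}{rep['mean_estimate']:.6g}",
            "-" * 54,
            f"{'coef':<16}{'estimate':>14}",
        ]
        for name, b in rep["coefficients"].items():
            lines.append(f"{name:<16}{b:>14.6g}")
        lines.append("=" * 54)
        return "\n".join(lines)
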