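"""Supervised stepwise linear-regression (SLR) land-use regression.

The classic ESCAPE-style forward procedure used throughout the mobile-
monitoring LUR literature: predictors are added one at a time maximising
adjusted R2, subject to

* a minimum adjusted-R2 gain (default 0.01) per accepted step,
* a priori coefficient sign constraints (traffic up, green space down, ...),
* previously accepted coefficients keeping their signs,
* a variance-inflation-factor cap (default VIF < 3) against collinearity,

followed by removal of predictors with p > 0.10. Deterministic for a fixed
input; ties on adjusted-R2 gain break alphabetically on predictor name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SLRModel", "default_sign_constraints", "fit_slr", "predict_slr",
           "learning_curve"]

#: predictor-name prefixes mapped to a priori coefficient signs
_POSITIVE_PREFIXES = ("traffic", "hd_traffic", "roadlength", "industry",
                     "port", "transportation", "population")
_NEGATIVE_PREFIXES = ("natural", "urban_green", "agricultural")


def default_sign_constraints(columns) -> dict[str, str]:
    """A priori sign map: source-like predictors "+", green/rural "-", rest "any"."""
    out = {}
    for c in columns:
        if c.startswith(_POSITIVE_PREFIXES):
            out[c] = "+"
        elif c.startswith(_NEGATIVE_PREFIXES):
            out[c] = "-"
        else:
            out[c] = "any"
    return out


@dataclass
class SLRModel:
    selected: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    sign_constraints: dict[str, str]
    adj_r2: float
    n: int
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"selected": self.selected,
                       "coefficients": self.coefficients,
                       "sign_constraints": self.sign_constraints,
                       "adj_r2": self.adj_r2, "n": self.n,
                       "thresholds": self.thresholds}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SLRModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _sign_ok(coef: float, constraint: str) -> bool:
    if constraint == "+":
        return coef > 0
    if constraint == "-":
        return coef < 0
    return True


def _fit_ols(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(X[cols].to_numpy(dtype=float), has_constant="add")
    return sm.OLS(y, design).fit()


def _max_vif(X: pd.DataFrame, cols: list[str]) -> float:
    """Largest variance-inflation factor among ``cols`` (1.0 for a single one)."""
    if len(cols) < 2:
        return 1.0
    Z = X[cols].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    R = np.corrcoef(Z, rowvar=False)
    try:
        vifs = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        return np.inf
    return float(vifs.max())


def fit_slr(X: pd.DataFrame, y, constraints: dict[str, str] | None = None,
            gain_min: float = 0.01, p_remove: float = 0.10,
            vif_max: float = 3.0, max_steps: int | None = None) -> SLRModel:
    """Forward stepwise selection maximising adjusted R2 (see module docstring).

    Falls back to an intercept-only model (with a warning) when no candidate
    passes at the first step.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 rows to fit an SLR LUR")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in X")
    if constraints is None:
        constraints = default_sign_constraints(X.columns)

    candidates = sorted(X.columns)  # alphabetical order = deterministic tie-break
    usable = [c for c in candidates if X[c].nunique() > 1]
    selected: list[str] = []
    best_adj = -np.inf
    current_fit = None
    if max_steps is None:
        max_steps = len(usable)

    while len(selected) < max_steps:
        best = None  # (adj_r2, name, fit)
        for cand in usable:
            if cand in selected:
                continue
            cols = selected + [cand]
            if _max_vif(X, cols) > vif_max:
                continue
            fit = _fit_ols(X, y, cols)
            coefs = fit.params[1:]
            if not all(_sign_ok(b, constraints.get(c, "any"))
                       for c, b in zip(cols, coefs)):
                continue
            adj = fit.rsquared_adj
            if best is None or adj > best[0] + 1e-12:
                best = (adj, cand, fit)
        if best is None:
            break
        base = best_adj if np.isfinite(best_adj) else 0.0
        if current_fit is not None and best[0] - best_adj < gain_min:
            break
        if current_fit is None and best[0] < gain_min:
            break
        best_adj, name, current_fit = best
        selected.append(name)

    if current_fit is None:
        import warnings
        warnings.warn("no candidate passed the first selection step; "
                      "returning intercept-only model")
        coefficients = {"intercept": float(y.mean())}
        return SLRModel(selected=[], coefficients=coefficients,
                        sign_constraints=dict(constraints), adj_r2=0.0,
                        n=len(y),
                        thresholds={"gain_min": gain_min, "p_remove": p_remove,
                                    "vif_max": vif_max})

    # backward pruning of insignificant predictors (worst first)
    while selected:
        fit = _fit_ols(X, y, selected)
        pvals = fit.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_remove:
            break
        del selected[worst]
    if selected:
        fit = _fit_ols(X, y, selected)
        coefficients = {"intercept": float(fit.params[0])}
        coefficients.update({c: float(b) for c, b in zip(selected, fit.params[1:])})
        adj = float(fit.rsquared_adj)
    else:
        coefficients = {"intercept": float(y.mean())}
        adj = 0.0
    return SLRModel(selected=list(selected), coefficients=coefficients,
                    sign_constraints=dict(constraints), adj_r2=adj, n=len(y),
                    thresholds={"gain_min": gain_min, "p_remove": p_remove,
                                "vif_max": vif_max})


def predict_slr(model: SLRModel, X_new: pd.DataFrame) -> np.ndarray:
    """Linear prediction on new segments; extrapolates without clipping."""
    missing = [c for c in model.selected if c not in X_new.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    pred = np.full(len(X_new), model.coefficients["intercept"], dtype=float)
    for c in model.selected:
        pred += model.coefficients[c] * X_new[c].to_numpy(dtype=float)
    return pred


def learning_curve(X: pd.DataFrame, snapped: pd.DataFrame, days_grid,
                   X_eval: pd.DataFrame, y_eval, n_resamples: int = 20,
                   seed: int = 0, constraints: dict | None = None,
                   **slr_kwargs) -> pd.DataFrame:
    """Local-model learning curve over campaign duration.

    For each number of collection days D in ``days_grid``: draw D distinct
    drive days without replacement, rebuild the per-segment mean-of-means
    response from those days only, fit an SLR LUR, and evaluate it on the
    held-out sites; repeat ``n_resamples`` times with a seeded generator.

    Returns a tidy frame with columns (days, resample, r2, mae, rmse, n_segments).
    """
    from .metrics import evaluate
    from .preprocess import mean_of_means

    all_days = np.array(sorted(snapped["drive_day"].unique()))
    rng = np.random.default_rng(seed)
    rows = []
    for D in days_grid:
        if D > len(all_days):
            raise ValueError(f"{D} days requested but only {len(all_days)} available")
        for rep in range(n_resamples):
            chosen = rng.choice(all_days, size=D, replace=False)
            sub = snapped[snapped["drive_day"].isin(set(chosen))]
            agg = mean_of_means(sub)
            agg = agg[agg["segment_id"].isin(X.index)]
            Xd = X.loc[agg["segment_id"]]
            model = fit_slr(Xd, agg["value"].to_numpy(), constraints=constraints,
                            **slr_kwargs)
            rep_eval = evaluate(predict_slr(model, X_eval), y_eval)
            rows.append({"days": D, "resample": rep, "r2": rep_eval.r2,
                         "mae": rep_eval.mae, "rmse": rep_eval.rmse,
                         "n_segments": len(Xd)})
    return pd.DataFrame(rows)
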