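"""Year-level binomial mortality model with AICc comparison.

Female deaths per study year (15 May – 14 May) are modelled as
``deaths ~ Binomial(exposure, p_category)`` with a logit-link GLM on the
El Niño category (normal / El Niño / severe El Niño).  Rate ratios are
reported on the probability scale; AICc uses the number of year rows as
the sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MortalityModel", "MortalityResults", "aicc", "aicc_compare"]

CATEGORIES = ("normal", "el_nino", "severe_el_nino")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2·logLik + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_compare(fit: "MortalityResults", null_fit: "MortalityResults") -> float:
    """ΔAICc = AICc(null) − AICc(model); positive favours the model."""
    if fit.n_rows != null_fit.n_rows:
        raise ValueError("fits compare different data")
    return null_fit.aicc - fit.aicc


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"deaths", "exposure", "category"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"mortality table missing columns: {sorted(missing)}")
    t = table.copy()
    if (t["deaths"] > t["exposure"]).any():
        raise ValueError("deaths exceed exposure in some years")
    zero = t.groupby("category")["exposure"].sum()
    if (zero == 0).any():
        raise ValueError(f"category with zero exposure: {zero[zero == 0].index.tolist()}")
    unknown = set(t["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    return t


class MortalityModel:
    """Binomial GLM of yearly female deaths on El Niño category."""

    def __init__(self, table: pd.DataFrame):
        self.table = _validate(table)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def _design(self, null: bool):
        t = self.table
        cols = {"intercept": np.ones(len(t))}
        if not null:
            present = [c for c in CATEGORIES[1:] if (t["category"] == c).any()]
            for c in present:
                cols[c] = (t["category"] == c).to_numpy(float)
        return pd.DataFrame(cols, index=t.index)

    def fit(self, null: bool = False) -> "MortalityResults":
        if not null and self.table["category"].nunique() < 2:
            raise ValueError("need at least 2 categories; fit the null model instead")
        X = self._design(null)
        endog = np.column_stack(
            [self.table["deaths"], self.table["exposure"] - self.table["deaths"]]
        )
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        return MortalityResults(self, res, null=null)

    def fit_null(self) -> "MortalityResults":
        return self.fit(null=True)


class MortalityResults:
    """Coefficients, z statistics, predicted per-category rates, AICc."""

    def __init__(self, model: MortalityModel, glm_results, null: bool):
        self.model = model
        self._res = glm_results
        self.null = null
        self.params = glm_results.params
        self.zvalues = glm_results.tvalues
        self.pvalues = glm_results.pvalues
        self.n_rows = len(model.table)
        self.k = len(glm_results.params)
        self.loglik = float(glm_results.llf)

    @property
    def aicc(self) -> float:
        """AICc with n = number of year rows (undefined for tiny tables)."""
        return aicc(self.loglik, self.k, self.n_rows)

    def predicted_rate(self, category: str) -> float:
        """Model-predicted death probability for a category."""
        eta = self.params["intercept"]
        if not self.null and category != "normal":
            if category not in self.params.index:
                raise KeyError(f"category {category!r} not in fit")
            eta = eta + self.params[category]
        return float(1.0 / (1.0 + np.exp(-eta)))

    def rate_ratio(self, category_a: str, category_b: str) -> float:
        """Ratio of predicted death probabilities (not odds)."""
        return self.predicted_rate(category_a) / self.predicted_rate(category_b)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"estimate": self.params, "z": self.zvalues, "p": self.pvalues}
        )
        if self.n_rows > self.k + 1:
            out.attrs["aicc"] = self.aicc
        return out

    def predicted_rate_table(self) -> pd.DataFrame:
        cats = sorted(self.model.table["category"].unique(), key=CATEGORIES.index)
        return pd.DataFrame(
            {"category": cats, "predicted_rate": [self.predicted_rate(c) for c in cats]}
        )
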