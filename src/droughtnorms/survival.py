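"""BLUPs predicting survival: the two-stage Bernoulli-logit model.

Stage one extracts per-female reaction norms (BLUP intercept and slope
at expected rainfall 1) from the hierarchical GC model; stage two,
implemented here, regresses survival of the El Niño drought on the
scaled BLUPs while controlling for age and rank (both fixed at the
drought start and z-scored across females).

Priors are Normal(0, 2.5) on every coefficient: with 28 females a flat
prior risks an improper posterior under complete separation, which this
model flags but tolerates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import McmcSettings, sample_logistic
from .summaries import posterior_summary, check_diagnostics

__all__ = ["BlupSurvivalModel", "BlupSurvivalResults", "predict_survival_probability"]


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def predict_survival_probability(
    coefficients,
    blup_slope_scaled: float = 0.0,
    blup_intercept_scaled: float = 0.0,
    age_scaled: float = 0.0,
    rank_scaled: float = 0.0,
) -> float:
    """Survival probability at given (scaled) covariate values.

    ``coefficients`` maps coefficient names (``intercept``,
    ``blup_slope``, ``blup_intercept``, ``age``, ``rank``; absent entries
    count as 0) to values.  Each value may be a scalar or an array of
    posterior draws; with draws the returned probability is the
    posterior-draw average of the inverse-logit, the convention used for
    model-based predicted probabilities.
    """
    get = lambda k: np.asarray(coefficients.get(k, 0.0), float)
    eta = (
        get("intercept")
        + get("blup_slope") * blup_slope_scaled
        + get("blup_intercept") * blup_intercept_scaled
        + get("age") * age_scaled
        + get("rank") * rank_scaled
    )
    return float(np.mean(_invlogit(eta)))


class BlupSurvivalModel:
    """Bernoulli-logit model of survival on scaled reaction-norm BLUPs.

    Built from the stage-one reaction-norm table plus per-female
    demography.  Fixed effects only (scaled BLUP slope and intercept,
    age, rank); an optional set of weakly penalized per-group intercepts
    can be included.
    """

    COEF_NAMES = ("intercept", "blup_slope", "blup_intercept", "age", "rank")

    def __init__(self, reaction_norms: pd.DataFrame, females: dict,
                 include_group_intercepts: bool = False):
        from .hormones import DROUGHT_START

        df = reaction_norms.copy()
        recs = []
        for fid in df["female_id"]:
            if fid not in females:
                raise KeyError(f"no demographic record for female {fid}")
            recs.append(females[fid])
        y = np.array(
            [1.0 if r.survived_el_nino else 0.0 for r in recs], float
        )
        if any(r.survived_el_nino is None for r in recs):
            raise ValueError("survival outcome missing for some females")

        def z(x):
            x = np.asarray(x, float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError("constant predictor; survival model is degenerate")
            return (x - x.mean()) / sd

        X = np.column_stack(
            [
                np.ones(len(df)),
                df["blup_slope_scaled"].to_numpy(float),
                df["blup_intercept_scaled"].to_numpy(float),
                z([r.age_at(DROUGHT_START) for r in recs]),
                z([r.rank for r in recs]),
            ]
        )
        names = list(self.COEF_NAMES)
        if include_group_intercepts:
            groups = pd.Categorical([r.group_id for r in recs])
            for j, g in enumerate(groups.categories[1:], start=1):
                X = np.column_stack([X, (groups.codes == j).astype(float)])
                names.append(f"group[{g}]")
        self.X, self.y, self.coef_names = X, y, names
        self.female_ids = df["female_id"].tolist()

    @classmethod
    def from_reaction_norms(cls, reaction_norms, females, **kw):
        return cls(reaction_norms, females, **kw)

    def fit(self, settings: McmcSettings | None = None, prior_sd: float = 2.5):
        settings = settings or McmcSettings()
        draws = sample_logistic(self.y, self.X, settings, prior_sd=prior_sd)
        return BlupSurvivalResults(self, draws, settings)


class BlupSurvivalResults:
    """Posterior for the glucocorticoids-predicting-survival model."""

    def __init__(self, model: BlupSurvivalModel, draws: dict, settings: McmcSettings):
        self.model = model
        self.draws = draws
        self.settings = settings
        self.separation_flag = draws["separation_flag"]
        self.accept_rate = draws["accept_rate"]
        self._summary = None

    def coefficient_draws(self, name: str) -> np.ndarray:
        j = self.model.coef_names.index(name)
        return self.draws["beta"][:, :, j]

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = posterior_summary(
                {
                    name: self.draws["beta"][:, :, j]
                    for j, name in enumerate(self.model.coef_names)
                }
            )
        return self._summary

    def diagnostics(self, rhat_max: float = 1.01, ess_min: float = 600) -> pd.DataFrame:
        return check_diagnostics(self.summary(), rhat_max=rhat_max, ess_min=ess_min)

    @property
    def converged(self) -> bool:
        return self.diagnostics().attrs["overall_pass"]

    def predict_survival_probability(
        self, blup_slope_scaled: float, average_draws: bool = True, **covariates
    ) -> float:
        """Survival probability at the given scaled BLUP slope.

        With ``average_draws`` the inverse-logit is averaged over
        posterior draws; otherwise posterior-mean coefficients are
        plugged in.
        """
        if average_draws:
            coefs = {
                name: self.coefficient_draws(name).reshape(-1)
                for name in self.model.coef_names
                if name in BlupSurvivalModel.COEF_NAMES
            }
        else:
            means = self.summary()["mean"]
            coefs = {name: means[name] for name in BlupSurvivalModel.COEF_NAMES
                     if name in means.index}
        return predict_survival_probability(
            coefs, blup_slope_scaled=blup_slope_scaled, **covariates
        )
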