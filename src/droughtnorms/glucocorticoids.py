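"""Hierarchical Bayesian models of log glucocorticoids.

Three model classes, each a thin statsmodels-style wrapper pairing a
design built from the model frame with the package's Gibbs sampler:

* :class:`CovariateScreenModel` — the preliminary screen of general GC
  covariates (collection time, age, rank, group size, 5-level
  reproductive state, expected rainfall) with female and group random
  intercepts;
* :class:`ReactionNormModel` — log GC on drought risk, expected
  rainfall and their interaction (plus collection time and merged
  reproductive state), with correlated by-female random slopes for every
  fixed effect and a by-group intercept.  Its results expose per-female
  BLUP reaction norms evaluated at a chosen expected-rainfall value;
* :class:`ThreeWayGCModel` — the reverse analysis: the same model with
  survival fully crossed with drought risk × expected rainfall, whose
  results provide survivor-vs-fatality GC contrasts at chosen covariate
  values.

Each ``fit`` returns a results object carrying posterior draws, a
``summary()`` table (mean, estimation error, 89% interval, R̂, ESS) and
a convergence report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import McmcSettings, sample_hierarchical_gaussian
from .summaries import posterior_summary, check_diagnostics

__all__ = ["CovariateScreenModel", "ReactionNormModel", "ThreeWayGCModel"]


def _zscore_safe(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 1e-12 else np.zeros_like(x)


def _codes(values) -> tuple:
    cats = pd.Categorical(values)
    return cats.codes.astype(int), list(cats.categories)


class _GaussianHierarchicalModel:
    """Shared fit machinery; subclasses define the design."""

    def __init__(self, frame: pd.DataFrame, include_group_intercept: bool = True):
        required = set(self.REQUIRED_COLUMNS)
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"model frame missing columns: {sorted(missing)}")
        if frame[list(required)].isna().any().any():
            raise ValueError("model frame contains missing covariates")
        self.frame = frame.reset_index(drop=True)
        self.include_group_intercept = include_group_intercept
        self.subject_idx, self.subjects = _codes(self.frame["female_id"])
        if len(self.subjects) < 2:
            raise ValueError("need at least 2 females to estimate individual effects")
        if include_group_intercept:
            self.group_idx, self.groups = _codes(self.frame["group_id"])
        else:
            self.group_idx, self.groups = None, []
        self.y = self.frame["log_gc"].to_numpy(float)
        self.X, self.fixed_names = self._fixed_design()
        self.Z, self.random_names = self._random_design()

    @classmethod
    def from_model_frame(cls, frame: pd.DataFrame, **kw):
        return cls(frame, **kw)

    def fit(self, settings: McmcSettings | None = None, prior_scale=None):
        settings = settings or McmcSettings()
        draws = sample_hierarchical_gaussian(
            self.y,
            self.X,
            self.Z,
            self.subject_idx,
            self.group_idx,
            settings,
            prior_scale=prior_scale,
        )
        return self.RESULTS_CLASS(self, draws, settings)


class _GaussianResults:
    """Posterior draws plus summary/diagnostic accessors."""

    def __init__(self, model, draws: dict, settings: McmcSettings):
        self.model = model
        self.draws = draws
        self.settings = settings
        self._summary = None

    def _named_scalar_draws(self) -> dict:
        m = self.model
        out = {
            name: self.draws["beta"][:, :, j] for j, name in enumerate(m.fixed_names)
        }
        for j, name in enumerate(m.random_names):
            out[f"sd_female__{name}"] = self.draws["sd_u"][:, :, j]
        if "sigma_group" in self.draws:
            out["sd_group__intercept"] = self.draws["sigma_group"]
        out["sigma_resid"] = self.draws["sigma_resid"]
        return out

    def fixed_effect_draws(self, name: str) -> np.ndarray:
        j = self.model.fixed_names.index(name)
        return self.draws["beta"][:, :, j]

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = posterior_summary(self._named_scalar_draws())
        return self._summary

    def diagnostics(self, rhat_max: float = 1.01, ess_min: float = 600) -> pd.DataFrame:
        return check_diagnostics(self.summary(), rhat_max=rhat_max, ess_min=ess_min)

    @property
    def converged(self) -> bool:
        return self.diagnostics().attrs["overall_pass"]

    def female_effect_draws(self) -> np.ndarray:
        """Per-female deviation draws, shape (chains, kept, n_females, q)."""
        return self.draws["u"]


class CovariateScreenResults(_GaussianResults):
    pass


class CovariateScreenModel(_GaussianHierarchicalModel):
    """Preliminary covariate screen for log GC (random intercepts only)."""

    REQUIRED_COLUMNS = (
        "female_id",
        "group_id",
        "log_gc",
        "collection_time_scaled",
        "age_at_sample_scaled",
        "rank_scaled",
        "group_size_scaled",
        "state",
        "expected_rainfall",
    )
    #: reference level for the 5-level reproductive state
    STATE_BASELINE = "nonpregnant_nonnursing"
    RESULTS_CLASS = CovariateScreenResults

    def _fixed_design(self):
        f = self.frame
        levels = [
            "early_pregnancy",
            "late_pregnancy",
            "nursing",
            "pre_reproductive",
        ]
        cols = [np.ones(len(f))]
        names = ["intercept"]
        for col in (
            "collection_time_scaled",
            "age_at_sample_scaled",
            "rank_scaled",
            "group_size_scaled",
        ):
            cols.append(f[col].to_numpy(float))
            names.append(col.replace("_scaled", ""))
        for lev in levels:
            cols.append((f["state"] == lev).to_numpy(float))
            names.append(f"state_{lev}")
        cols.append(f["expected_rainfall"].to_numpy(float))
        names.append("expected_rainfall")
        return np.column_stack(cols), names

    def _random_design(self):
        return np.ones((len(self.frame), 1)), ["intercept"]


class ReactionNormResults(_GaussianResults):
    """Fit of the reaction-norm extraction model; BLUPs live here."""

    def reaction_norms(self, rain_value: float = 1.0) -> pd.DataFrame:
        """Per-female BLUP intercept and slope at a given expected rainfall.

        The BLUP slope is the posterior mean of the individual deviation
        ``bd_i + bdr_i·rain_value`` (response to drought risk at that
        seasonal point); the BLUP intercept is the posterior mean of
        ``b0_i + br_i·rain_value``.  Group-level intercepts are not
        included.  Scaled columns are z-scored across females.
        """
        rn = self.model.random_names
        i0, i_d = rn.index("intercept"), rn.index("drought_risk")
        i_r = rn.index("expected_rainfall")
        i_dr = rn.index("drought_risk:expected_rainfall")
        u = self.draws["u"]  # (chains, kept, n_females, q)
        slope = (u[..., i_d] + u[..., i_dr] * rain_value).mean(axis=(0, 1))
        intercept = (u[..., i0] + u[..., i_r] * rain_value).mean(axis=(0, 1))
        return pd.DataFrame(
            {
                "female_id": self.model.subjects,
                "blup_intercept": intercept,
                "blup_slope": slope,
                "blup_intercept_scaled": _zscore_safe(intercept),
                "blup_slope_scaled": _zscore_safe(slope),
            }
        )

    def plot_reaction_norms(self, rain_value: float = 1.0, ax=None):
        """Spaghetti plot of per-female fitted log-GC vs drought risk lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        norms = self.reaction_norms(rain_value)
        beta = self.summary()["mean"]
        b_int = beta["intercept"] + beta["expected_rainfall"] * rain_value
        b_slope = (
            beta["drought_risk"] + beta["drought_risk:expected_rainfall"] * rain_value
        )
        d = np.linspace(-2, 2, 50)
        for _, row in norms.iterrows():
            ax.plot(
                d,
                (b_int + row["blup_intercept"]) + (b_slope + row["blup_slope"]) * d,
                color="gray",
                alpha=0.5,
                lw=0.8,
            )
        ax.plot(d, b_int + b_slope * d, color="black", lw=2)
        ax.set_xlabel("drought risk (SD units)")
        ax.set_ylabel(f"log GC at expected rainfall {rain_value:g}")
        return ax


class ReactionNormModel(_GaussianHierarchicalModel):
    """Reaction-norm extraction model for log GC.

    Fixed effects: drought risk, expected rainfall, their interaction,
    collection time, merged reproductive state.  Random: by-female slopes
    for all fixed effects (correlated, with the intercept) and a by-group
    intercept.
    """

    REQUIRED_COLUMNS = (
        "female_id",
        "group_id",
        "log_gc",
        "drought_risk",
        "expected_rainfall",
        "collection_time_scaled",
        "merged_state",
    )
    RESULTS_CLASS = ReactionNormResults

    def _terms(self):
        f = self.frame
        d = f["drought_risk"].to_numpy(float)
        r = f["expected_rainfall"].to_numpy(float)
        return [
            ("intercept", np.ones(len(f))),
            ("drought_risk", d),
            ("expected_rainfall", r),
            ("drought_risk:expected_rainfall", d * r),
            ("collection_time", f["collection_time_scaled"].to_numpy(float)),
            ("state_early_pregnancy", (f["merged_state"] == "early_pregnancy").to_numpy(float)),
            ("state_late_pregnancy", (f["merged_state"] == "late_pregnancy").to_numpy(float)),
        ]

    def _fixed_design(self):
        terms = self._terms()
        return np.column_stack([t[1] for t in terms]), [t[0] for t in terms]

    def _random_design(self):
        # random slopes for every fixed effect, including the interaction
        return self.X.copy(), list(self.fixed_names)


class ThreeWayResults(_GaussianResults):
    """Fit of the survival-predicting-glucocorticoids model."""

    def gc_contrast(
        self, drought_risk: float, expected_rainfall: float, ci: float = 0.89
    ) -> dict:
        """Survivor-minus-fatality log-GC difference at given covariates.

        Per posterior draw, ``Δ = β_surv + β_surv:d·D + β_surv:r·R +
        β_surv:d:r·D·R`` (collection time 0, not-pregnant baseline), and
        the percent contrast divides Δ by the fatality group's predicted
        log GC at the same covariates.  Returns means and equal-tailed
        credible intervals for both.
        """
        D, R = drought_risk, expected_rainfall
        delta = (
            self.fixed_effect_draws("survived")
            + self.fixed_effect_draws("survived:drought_risk") * D
            + self.fixed_effect_draws("survived:expected_rainfall") * R
            + self.fixed_effect_draws("survived:drought_risk:expected_rainfall") * D * R
        )
        fatality_pred = (
            self.fixed_effect_draws("intercept")
            + self.fixed_effect_draws("drought_risk") * D
            + self.fixed_effect_draws("expected_rainfall") * R
            + self.fixed_effect_draws("drought_risk:expected_rainfall") * D * R
        )
        percent = 100.0 * delta / fatality_pred
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        return {
            "delta_log_gc": float(delta.mean()),
            "delta_ci": (float(np.quantile(delta, lo)), float(np.quantile(delta, hi))),
            "percent": float(percent.mean()),
            "percent_ci": (
                float(np.quantile(percent, lo)),
                float(np.quantile(percent, hi)),
            ),
        }


class ThreeWayGCModel(_GaussianHierarchicalModel):
    """Log GC with survival fully crossed with drought risk × expected rainfall.

    Fixed effects: the full factorial expansion of drought risk ×
    expected rainfall × survived, plus collection time and merged
    reproductive state.  Random effects: by-female intercept and slopes
    for drought risk, expected rainfall, their interaction, collection
    time and state; by-group intercept.
    """

    REQUIRED_COLUMNS = (
        "female_id",
        "group_id",
        "log_gc",
        "drought_risk",
        "expected_rainfall",
        "collection_time_scaled",
        "merged_state",
        "survived",
    )
    RESULTS_CLASS = ThreeWayResults

    def _fixed_design(self):
        f = self.frame
        if f["survived"].isna().any():
            raise ValueError("survival outcome missing for some rows")
        d = f["drought_risk"].to_numpy(float)
        r = f["expected_rainfall"].to_numpy(float)
        s = f["survived"].to_numpy(float)
        terms = [
            ("intercept", np.ones(len(f))),
            ("drought_risk", d),
            ("expected_rainfall", r),
            ("survived", s),
            ("drought_risk:expected_rainfall", d * r),
            ("survived:drought_risk", s * d),
            ("survived:expected_rainfall", s * r),
            ("survived:drought_risk:expected_rainfall", s * d * r),
            ("collection_time", f["collection_time_scaled"].to_numpy(float)),
            ("state_early_pregnancy", (f["merged_state"] == "early_pregnancy").to_numpy(float)),
            ("state_late_pregnancy", (f["merged_state"] == "late_pregnancy").to_numpy(float)),
        ]
        return np.column_stack([t[1] for t in terms]), [t[0] for t in terms]

    def _random_design(self):
        f = self.frame
        d = f["drought_risk"].to_numpy(float)
        r = f["expected_rainfall"].to_numpy(float)
        cols = [
            ("intercept", np.ones(len(f))),
            ("drought_risk", d),
            ("expected_rainfall", r),
            ("drought_risk:expected_rainfall", d * r),
            ("collection_time", f["collection_time_scaled"].to_numpy(float)),
            ("state_early_pregnancy", (f["merged_state"] == "early_pregnancy").to_numpy(float)),
            ("state_late_pregnancy", (f["merged_state"] == "late_pregnancy").to_numpy(float)),
        ]
        return np.column_stack([c[1] for c in cols]), [c[0] for c in cols]
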