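"""Posterior summaries and convergence diagnostics.

Summaries follow the reporting convention used throughout the package:
posterior mean, estimation error (posterior SD), an 89% equal-tailed
credible interval (5.5% and 94.5% quantiles), split-R̂, and bulk/tail
effective sample sizes (computed with arviz).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = ["posterior_summary", "check_diagnostics", "CI_LEVEL"]

CI_LEVEL = 0.89
RHAT_MAX = 1.01
ESS_MIN = 600


def posterior_summary(draws: dict, ci: float = CI_LEVEL) -> pd.DataFrame:
    """Summarize named draw arrays of shape (chains, draws).

    Returns a DataFrame indexed by parameter with columns
    ``mean, est_error, ci_lower, ci_upper, rhat, ess_bulk, ess_tail``.
    """
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    names = list(draws)
    for name in names:
        if np.asarray(draws[name]).ndim != 2:
            raise ValueError(f"draws for {name!r} must be (chains, draws)")
    idata = az.from_dict({k: np.asarray(v) for k, v in draws.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess_bulk = az.ess(idata, method="bulk")
        ess_tail = az.ess(idata, method="tail")
    rows = []
    for name in names:
        arr = np.asarray(draws[name])
        flat = arr.reshape(-1)
        rows.append(
            {
                "mean": flat.mean(),
                "est_error": flat.std(ddof=1),
                "ci_lower": np.quantile(flat, lo_q),
                "ci_upper": np.quantile(flat, hi_q),
                "rhat": float(rhat[name].values),
                "ess_bulk": float(ess_bulk[name].values),
                "ess_tail": float(ess_tail[name].values),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(names, name="parameter"))


def check_diagnostics(
    summary: pd.DataFrame, rhat_max: float = RHAT_MAX, ess_min: float = ESS_MIN
) -> pd.DataFrame:
    """Per-parameter convergence verdicts (R̂ ≤ 1.01, bulk/tail ESS ≥ 600).

    The returned frame has one row per parameter with boolean columns
    ``rhat_ok, ess_bulk_ok, ess_tail_ok, passed`` plus a ``passed`` value
    in ``.attrs["overall_pass"]`` that is True iff every parameter passes.
    """
    report = pd.DataFrame(
        {
            "rhat": summary["rhat"],
            "ess_bulk": summary["ess_bulk"],
            "ess_tail": summary["ess_tail"],
            "rhat_ok": summary["rhat"] <= rhat_max,
            "ess_bulk_ok": summary["ess_bulk"] >= ess_min,
            "ess_tail_ok": summary["ess_tail"] >= ess_min,
        }
    )
    report["passed"] = report[["rhat_ok", "ess_bulk_ok", "ess_tail_ok"]].all(axis=1)
    report.attrs["overall_pass"] = bool(report["passed"].all())
    return report
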