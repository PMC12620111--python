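"""Time-since-invasion candidate models and AICc ranking.

Candidate covariate forms for each vital rate are null, linear, quadratic
and log (on ``ln(tsi + 1)``), optionally interacted with age where the rate
is age-structured.  Fits on identical data are ranked by the small-sample
corrected Akaike information criterion,

    AICc = -2 logL + 2k + 2k(k + 1) / (n - k - 1),

with the effective sample size n being the number of individuals (multistate
and breeding models), nest intervals (nest survival) or successful nests
(fledged).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["aicc", "rank_models", "ModelRanking", "DEFAULT_FORMS"]

DEFAULT_FORMS = ("null", "linear", "quadratic", "log")


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected AIC; requires ``n > k + 1`` for the correction to exist."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class ModelRanking:
    """AICc ranking of candidate fits of one vital rate.

    ``table`` is sorted ascending by AICc (ties: smaller k, then label);
    the best model has delta-AICc 0.
    """

    table: pd.DataFrame

    @property
    def best_label(self) -> str:
        return str(self.table.iloc[0]["model"])

    def __len__(self) -> int:
        return len(self.table)


def rank_models(fits: dict[str, object]) -> ModelRanking:
    """Rank fitted models by AICc.

    ``fits`` maps a model label to any object exposing ``loglik``, ``k`` and
    ``n`` (all the package's fit classes do).  All fits must share the same
    data, checked through n; mixed sample sizes raise.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"fits are not on identical data: n values {sorted(ns)}")
    rows = []
    for label, f in fits.items():
        rows.append({"model": label, "logL": float(f.loglik), "k": int(f.k),
                     "n": int(f.n), "AICc": aicc(f.loglik, f.k, f.n)})
    tab = pd.DataFrame(rows).sort_values(
        by=["AICc", "k", "model"], kind="mergesort").reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    return ModelRanking(table=tab)
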