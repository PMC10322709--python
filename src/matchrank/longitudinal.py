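"""Reference-set recentering of timepoint differentials (FMT-style analysis).

Timepoint-pair differentials from an intervention study are only
comparable across intervals once they share a reference frame.  The
frame is a set R of features believed stable (here: features whose
cross-sectional posterior mean log fold change is negative), and each
draw of D is recentered as D* = D - mean_R(D).  Subtracting the
reference mean draw-wise keeps the recentered credible intervals
coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PosteriorDifferentials, summarize_draws

__all__ = [
    "RecenteredDifferentials",
    "reference_feature_set",
    "recenter_differentials",
    "fmt_response_classification",
]


@dataclass
class RecenteredDifferentials:
    """Recentered draws D* = D - mean over the reference set, per draw."""

    feature_ids: list[str]
    chain_draws: np.ndarray        # (chains, draws, d), recentered
    summary: pd.DataFrame
    reference: list[str]
    interval: tuple[str, str] | None = None

    @property
    def draws(self) -> np.ndarray:
        return self.chain_draws.reshape(-1, self.chain_draws.shape[2])

    @property
    def d(self) -> int:
        return self.chain_draws.shape[2]


def reference_feature_set(cross_sectional: PosteriorDifferentials) -> list[str]:
    """Features with negative posterior-mean log fold change cross-sectionally.

    These act as the stable reference frame for longitudinal intervals.
    An empty result is an error: supply a manual reference set instead.
    """
    s = cross_sectional.summary
    ref = s.loc[s["mean"] < 0, "feature"].tolist()
    if not ref:
        raise ValueError(
            "no feature has negative posterior mean; no reference frame is "
            "possible - supply an explicit reference set"
        )
    return ref


def recenter_differentials(
    interval_posterior: PosteriorDifferentials | RecenteredDifferentials,
    reference: list[str],
    interval: tuple[str, str] | None = None,
) -> RecenteredDifferentials:
    """Subtract the per-draw reference-set mean from every feature's draws.

    Pairwise differences between features are preserved exactly, and the
    posterior-mean D* averaged over the reference set is zero.  The
    operation is idempotent.
    """
    fids = list(interval_posterior.feature_ids)
    missing = [f for f in reference if f not in fids]
    if missing:
        raise ValueError(f"reference feature(s) missing from the posterior: {missing}")
    if not reference:
        raise ValueError("reference set is empty")
    idx = [fids.index(f) for f in reference]
    draws = interval_posterior.chain_draws
    ref_mean = draws[:, :, idx].mean(axis=2, keepdims=True)
    recentered = draws - ref_mean
    if interval is None:
        interval = getattr(interval_posterior, "interval", None)
    return RecenteredDifferentials(
        feature_ids=fids,
        chain_draws=recentered,
        summary=summarize_draws(recentered, fids),
        reference=list(reference),
        interval=interval,
    )


def fmt_response_classification(
    recentered: RecenteredDifferentials,
    sd_cut: float = 3.0,
    focal_set: list[str] | None = None,
) -> tuple[pd.Series, dict]:
    """Classify each feature's response over the intervention interval.

    Among features whose posterior sd is below ``sd_cut`` (the
    low-uncertainty filter): decreased when the 95% quantile of D* is
    below 0, increased when the 5% quantile is above 0, stable when the
    central 90% interval covers 0.  Features failing the sd filter are
    labeled uncertain before any call is made.

    When a ``focal_set`` is supplied (e.g. the case-associated consensus
    features), the returned dict reports the fraction of its
    low-uncertainty members with a mean decrease and with a significant
    decrease; fractions are None when the set is empty.
    """
    draws = recentered.draws
    q05, q95 = np.quantile(draws, [0.05, 0.95], axis=0)
    sd = draws.std(axis=0, ddof=1)
    mean = draws.mean(axis=0)
    status = np.full(draws.shape[1], "uncertain", dtype=object)
    low = sd < sd_cut
    status[low & (q05 <= 0) & (q95 >= 0)] = "stable"
    status[low & (q05 > 0)] = "increased"
    status[low & (q95 < 0)] = "decreased"
    calls = pd.Series(status, index=recentered.feature_ids, name="response")

    fractions: dict = {"n_focal": 0, "mean_decrease": None, "significant_decrease": None}
    if focal_set:
        fidx = [recentered.feature_ids.index(f) for f in focal_set
                if f in recentered.feature_ids]
        fidx = [i for i in fidx if low[i]]
        fractions["n_focal"] = len(fidx)
        if fidx:
            fractions["mean_decrease"] = float((mean[fidx] < 0).mean())
            fractions["significant_decrease"] = float((q95[fidx] < 0).mean())
    return calls, fractions
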