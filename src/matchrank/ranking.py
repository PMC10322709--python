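"""Rankings, taxon classification, balances, and the posterior-sphere effect size.

Because sequencing counts are compositional, each differential D_j is
identified only up to a shared additive constant; every statistic here
is therefore either rank-based, ratio-based (balances, CLR), or built
from the joint posterior geometry (the effect size E), all of which are
invariant to that constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable
from .matching import MatchedPairs
from .model import PosteriorDifferentials

__all__ = [
    "ClassificationResult",
    "BalanceResult",
    "EffectSizeResult",
    "rank_differentials",
    "classify_features",
    "consensus_classification",
    "compute_balance",
    "pair_balance_differences",
    "significance_calls",
    "effect_size_and_p",
    "clr_pair_differences",
]

CASE = "case-associated"
CONTROL = "control-associated"
NEUTRAL = "neutral"


@dataclass
class ClassificationResult:
    """Per-study and consensus taxon group labels."""

    per_study: pd.DataFrame        # features x studies, label-valued
    consensus: pd.Series           # feature -> label
    conflicts: list[str]           # features qualifying for both groups
    threshold: float
    min_studies: int

    def to_frame(self) -> pd.DataFrame:
        out = self.per_study.copy()
        out.insert(0, "feature", out.index)
        out["consensus"] = self.consensus
        out["n_case_studies"] = (self.per_study == CASE).sum(axis=1)
        out["n_control_studies"] = (self.per_study == CONTROL).sum(axis=1)
        out["conflict"] = out["feature"].isin(self.conflicts)
        return out.reset_index(drop=True)


@dataclass
class BalanceResult:
    """Per-sample log ratio of geometric-mean abundances of two feature sets."""

    values: pd.Series              # sample -> balance (natural log)
    numerator: list[str]
    denominator: list[str]
    zero_policy: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.values.index, "balance": self.values.to_numpy()})


@dataclass
class EffectSizeResult:
    """Posterior-sphere effect size E = ||mu_D||_2 / r_D with a Bayesian P bound.

    ``r_D`` is the largest Euclidean distance of any posterior draw from
    the posterior mean; E > 1 means the origin lies outside the sphere
    enclosing every stored draw, and the P bound is then 1/m.
    """

    mu: np.ndarray
    radius: float
    effect_size: float
    m: int
    p_bound: float
    degenerate: bool = False


def rank_differentials(posterior: PosteriorDifferentials) -> pd.DataFrame:
    """Features sorted by posterior mean log fold change, descending.

    Ties break by feature id.  Because a global additive offset shifts
    every mean equally, the ranking is invariant to the unidentifiable
    compositional constant.
    """
    s = posterior.summary[["feature", "mean", "sd", "q05", "q95"]].copy()
    s = s.sort_values(["mean", "feature"], ascending=[False, True], kind="mergesort")
    s.insert(0, "rank", np.arange(1, len(s) + 1))
    return s.reset_index(drop=True)


def classify_features(posterior: PosteriorDifferentials, threshold: float = 0.70) -> pd.Series:
    """Three-group taxon classification from posterior sign fractions.

    A feature is case-associated when at least ``threshold`` of its
    posterior draws are greater than 0, control-associated when at least
    ``threshold`` are less than 0, neutral otherwise.  Draws exactly
    equal to zero count toward neither side.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")
    draws = posterior.draws
    if draws.shape[0] < 10:
        raise ValueError("classification requires at least 10 posterior draws")
    m = draws.shape[0]
    frac_pos = (draws > 0).sum(axis=0) / m
    frac_neg = (draws < 0).sum(axis=0) / m
    labels = np.where(frac_pos >= threshold, CASE,
                      np.where(frac_neg >= threshold, CONTROL, NEUTRAL))
    return pd.Series(labels, index=posterior.feature_ids, name="label")


def consensus_classification(
    study_labels: dict[str, pd.Series] | list[pd.Series],
    min_studies: int = 2,
    threshold: float = 0.70,
) -> ClassificationResult:
    """Cross-study consensus: a label must recur in >= ``min_studies`` studies.

    A feature qualifying for both the case- and control-associated
    groups is set neutral and flagged as a conflict.
    """
    if isinstance(study_labels, dict):
        per_study = pd.DataFrame(study_labels)
    else:
        per_study = pd.DataFrame({f"study_{i}": s for i, s in enumerate(study_labels)})
    if per_study.shape[1] < 1:
        raise ValueError("at least one study is required")
    per_study = per_study.fillna(NEUTRAL)
    n_case = (per_study == CASE).sum(axis=1)
    n_ctrl = (per_study == CONTROL).sum(axis=1)
    consensus = pd.Series(NEUTRAL, index=per_study.index, name="consensus")
    consensus[n_case >= min_studies] = CASE
    consensus[n_ctrl >= min_studies] = CONTROL
    conflict_mask = (n_case >= min_studies) & (n_ctrl >= min_studies)
    consensus[conflict_mask] = NEUTRAL
    return ClassificationResult(
        per_study=per_study,
        consensus=consensus,
        conflicts=sorted(per_study.index[conflict_mask]),
        threshold=threshold,
        min_studies=min_studies,
    )


def _zero_adjusted_proportions(table: FeatureTable, zero_policy: str, pseudocount: float,
                               feature_subset: np.ndarray | None = None) -> np.ndarray:
    """Relative abundances with zeros replaced per policy (proportions drop
    the per-sample scale, which the downstream log ratios ignore anyway)."""
    counts = table.counts.astype(float)
    if feature_subset is not None:
        counts = counts[:, feature_subset]
    totals = table.totals().astype(float)[:, None]
    if np.any(totals == 0):
        raise ValueError("sample(s) with zero total count")
    if zero_policy == "pseudocount":
        adj = np.where(counts == 0, pseudocount, counts)
        return adj / totals
    if zero_policy == "mean-impute":
        prop = counts / totals
        col_mean = prop.mean(axis=0)
        return np.where(prop == 0, col_mean[None, :], prop)
    raise ValueError(f"unknown zero policy {zero_policy!r}")


def compute_balance(
    table: FeatureTable,
    numerator: list[str],
    denominator: list[str],
    zero_policy: str = "pseudocount",
    pseudocount: float = 0.5,
) -> BalanceResult:
    """Per-sample balance: log geometric-mean ratio of two feature groups.

    balance = ln gm(numerator abundances) - ln gm(denominator
    abundances), computed on zero-adjusted relative abundances.  The
    value is invariant to rescaling a sample's counts by any positive
    constant (exactly so in the absence of zeros).
    """
    if not numerator or not denominator:
        raise ValueError("numerator and denominator sets must be nonempty")
    fidx = {f: i for i, f in enumerate(table.feature_ids)}
    for f in list(numerator) + list(denominator):
        if f not in fidx:
            raise ValueError(f"unknown feature id {f!r}")
    prop = _zero_adjusted_proportions(table, zero_policy, pseudocount)
    logp = np.log(prop)
    num_idx = [fidx[f] for f in numerator]
    den_idx = [fidx[f] for f in denominator]
    values = logp[:, num_idx].mean(axis=1) - logp[:, den_idx].mean(axis=1)
    return BalanceResult(
        values=pd.Series(values, index=table.sample_ids, name="balance"),
        numerator=list(numerator),
        denominator=list(denominator),
        zero_policy={"policy": zero_policy, "pseudocount": pseudocount},
    )


def pair_balance_differences(balances: BalanceResult, pairs: MatchedPairs) -> pd.DataFrame:
    """Case-minus-control balance per pair, plus the fraction above zero.

    Values greater than 0 indicate the numerator group separates cases
    from controls in that pair.  The positive fraction is attached as
    ``DataFrame.attrs['fraction_positive']``.
    """
    rows = []
    for k, case, ctrl in pairs.pairs:
        for sid in (case, ctrl):
            if sid not in balances.values.index:
                raise ValueError(f"pair {k} has no balance for sample {sid!r}")
        rows.append({
            "pair": k,
            "case_balance": balances.values[case],
            "control_balance": balances.values[ctrl],
            "difference": balances.values[case] - balances.values[ctrl],
        })
    out = pd.DataFrame(rows)
    out.attrs["fraction_positive"] = float((out["difference"] > 0).mean()) if len(out) else np.nan
    return out


def significance_calls(posterior: PosteriorDifferentials, sd_cut: float = 3.0) -> pd.Series:
    """Classify each feature as increased / decreased / stable / uncertain.

    increased: 5% posterior quantile > 0; decreased: 95% quantile < 0;
    stable: central 90% interval covers 0 and posterior sd < ``sd_cut``
    (natural-log scale); everything else is uncertain.
    """
    draws = posterior.draws
    q05, q95 = np.quantile(draws, [0.05, 0.95], axis=0)
    sd = draws.std(axis=0, ddof=1)
    status = np.full(draws.shape[1], "uncertain", dtype=object)
    status[(q05 <= 0) & (q95 >= 0) & (sd < sd_cut)] = "stable"
    status[q05 > 0] = "increased"
    status[q95 < 0] = "decreased"
    return pd.Series(status, index=posterior.feature_ids, name="status")


def effect_size_and_p(draw_matrix: np.ndarray) -> EffectSizeResult:
    """Global effect size E = ||mu_D|| / r_D and its Bayesian P bound.

    ``draw_matrix`` holds m posterior draws of the d-vector D.  r_D is
    the radius of the smallest mean-centered sphere containing every
    draw.  When the origin lies outside that sphere (E > 1) the
    posterior puts no stored draw at 0 and the P bound is 1/m;
    otherwise P is reported as 1 (no evidence).  If all draws coincide
    (r_D = 0) with a nonzero mean, E is reported as +inf with the
    ``degenerate`` flag set.
    """
    draws = np.atleast_2d(np.asarray(draw_matrix, dtype=float))
    m, d = draws.shape
    if m < 2:
        raise ValueError("at least 2 posterior draws are required")
    mu = draws.mean(axis=0)
    radius = float(np.sqrt(((draws - mu) ** 2).sum(axis=1)).max())
    norm = float(np.linalg.norm(mu))
    if radius == 0.0:
        effect = np.inf if norm > 0 else 0.0
        degenerate = True
    else:
        effect = norm / radius
        degenerate = False
    p_bound = 1.0 / m if norm > radius else 1.0
    return EffectSizeResult(mu=mu, radius=radius, effect_size=effect,
                            m=m, p_bound=p_bound, degenerate=degenerate)


def clr_pair_differences(table: FeatureTable, pairs: MatchedPairs) -> pd.DataFrame:
    """Per-pair case-minus-control robust CLR differences (heat-map values).

    Zeros are imputed to the feature's mean relative abundance across
    all samples before the centered log-ratio transform; features that
    are zero everywhere are excluded with a warning (their mean is
    undefined).  Each output row sums to zero by CLR conservation.
    """
    keep = table.counts.sum(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} all-zero feature(s) from CLR: {dropped[:5]}",
                      stacklevel=2)
    prop = _zero_adjusted_proportions(table, "mean-impute", 0.0, feature_subset=np.flatnonzero(keep))
    logp = np.log(prop)
    clr = logp - logp.mean(axis=1, keepdims=True)
    sindex = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for k, case, ctrl in pairs.pairs:
        rows.append(clr[sindex[case]] - clr[sindex[ctrl]])
    features = [f for f, kk in zip(table.feature_ids, keep) if kk]
    return pd.DataFrame(rows, index=[k for k, _, _ in pairs.pairs], columns=features)
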