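"""Optimal case-control and timepoint pairing.

Cases are matched to controls within each cohort by solving an
assignment problem on age (and, by default, sex), maximizing the number
of pairs first and minimizing the total absolute age gap second.
Longitudinal designs instead pair two timepoints of the same subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import MetadataTable

__all__ = [
    "MatchedPairs",
    "match_case_control",
    "match_timepoints",
    "select_first_timepoint",
]

log = logging.getLogger(__name__)


@dataclass
class MatchedPairs:
    """The pairing function k(i).

    ``pairs`` holds ``(pair_index, case_sample_id, control_sample_id)``
    triples; in timepoint mode the later timepoint plays the case role.
    """

    pairs: list[tuple[int, str, str]]
    unmatched: list[str] = field(default_factory=list)
    constraint_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, case, ctrl in self.pairs:
            for s in (case, ctrl):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def case_ids(self) -> list[str]:
        return [c for _, c, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, _, c in self.pairs]

    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for _, case, ctrl in self.pairs:
            out.extend((case, ctrl))
        return out

    def to_frame(self, metadata: MetadataTable | None = None) -> pd.DataFrame:
        rows = []
        for k, case, ctrl in self.pairs:
            row = {"pair": k, "case_sample": case, "control_sample": ctrl}
            if metadata is not None:
                rc, rx = metadata.row(case), metadata.row(ctrl)
                row["age_gap"] = abs(float(rc["age"]) - float(rx["age"]))
                row["sex"] = rc["sex"]
            rows.append(row)
        return pd.DataFrame(rows)


def match_case_control(
    metadata: MetadataTable,
    max_age_gap: float = 0.5,
    require_same_sex: bool = True,
) -> MatchedPairs:
    """Optimal bipartite age/sex matching of cases to controls.

    Matching is performed strictly within each cohort.  Among all
    maximum-cardinality matchings that respect the age-gap and sex
    constraints, the one with minimum total absolute age gap is
    returned (implemented as an assignment solve in which infeasible
    case-control edges carry a prohibitive cost).  Individuals who
    cannot be matched are listed in ``unmatched``.  Ties are broken
    deterministically by lexicographic sample id.
    """
    df = metadata.data
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for cohort in sorted(df["cohort_id"].astype(str).unique()):
        sub = df[df["cohort_id"].astype(str) == cohort]
        cases = sub[sub["group"] == "case"].sort_values("sample_id").reset_index(drop=True)
        controls = sub[sub["group"] == "control"].sort_values("sample_id").reset_index(drop=True)
        if cases.empty or controls.empty:
            log.warning("cohort %s has no %s samples; zero pairs formed", cohort,
                        "case" if cases.empty else "control")
            unmatched.extend(sub["sample_id"].tolist())
            continue
        n, m = len(cases), len(controls)
        gap = np.abs(cases["age"].to_numpy()[:, None] - controls["age"].to_numpy()[None, :])
        feasible = gap <= max_age_gap + 1e-12
        if require_same_sex:
            feasible &= cases["sex"].to_numpy()[:, None] == controls["sex"].to_numpy()[None, :]
        big = max_age_gap * min(n, m) + 1.0
        cost = np.where(feasible, gap, big)
        # deterministic tie-break among equal-cost optima: prefer
        # lexicographically earlier (case, control) id pairs
        eps = np.arange(n)[:, None] * m + np.arange(m)[None, :]
        cost = cost + eps * 1e-12
        rows, cols = linear_sum_assignment(cost)
        chosen = {int(i) for i in rows}
        paired_controls = set()
        for i, j in zip(rows, cols):
            if feasible[i, j]:
                pairs.append((cases.loc[i, "sample_id"], controls.loc[j, "sample_id"]))
                paired_controls.add(int(j))
            else:
                unmatched.append(cases.loc[i, "sample_id"])
        unmatched.extend(cases.loc[i, "sample_id"] for i in range(n) if i not in chosen)
        unmatched.extend(controls.loc[j, "sample_id"] for j in range(m) if j not in paired_controls)
    pairs.sort(key=lambda p: p[0])
    matched = MatchedPairs(
        pairs=[(k, case, ctrl) for k, (case, ctrl) in enumerate(pairs)],
        unmatched=sorted(unmatched),
        constraint_record={"max_age_gap": max_age_gap, "require_same_sex": require_same_sex},
    )
    _assert_constraints(matched, metadata)
    return matched


def _assert_constraints(matched: MatchedPairs, metadata: MetadataTable) -> None:
    """Defensive check: no returned pair violates the sex or gap constraint."""
    gap = matched.constraint_record.get("max_age_gap")
    same_sex = matched.constraint_record.get("require_same_sex", False)
    for k, case, ctrl in matched.pairs:
        rc, rx = metadata.row(case), metadata.row(ctrl)
        if rc["group"] != "case" or rx["group"] != "control":
            raise AssertionError(f"pair {k} has wrong group roles")
        if same_sex and rc["sex"] != rx["sex"]:
            raise AssertionError(f"pair {k} violates the same-sex constraint")
        if gap is not None and abs(float(rc["age"]) - float(rx["age"])) > gap + 1e-9:
            raise AssertionError(f"pair {k} violates the age-gap constraint")


def match_timepoints(
    metadata: MetadataTable,
    interval: tuple[str, str],
) -> MatchedPairs:
    """Pair two timepoints of each subject (the later plays the case role).

    ``interval`` is ``(earlier_label, later_label)``.  Subjects missing
    either timepoint are excluded and reported in ``unmatched``.
    """
    earlier, later = interval
    df = metadata.data
    if "timepoint" not in df.columns:
        raise ValueError("metadata has no 'timepoint' column")
    dup = df[df["timepoint"].isin([earlier, later])].duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        bad = df.loc[dup[dup].index, ["subject_id", "timepoint"]].values.tolist()
        raise ValueError(f"duplicate (subject, timepoint) rows: {bad}")
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for subject in sorted(df["subject_id"].astype(str).unique()):
        sub = df[df["subject_id"].astype(str) == subject]
        s_early = sub[sub["timepoint"] == earlier]
        s_late = sub[sub["timepoint"] == later]
        if len(s_early) == 1 and len(s_late) == 1:
            pairs.append((s_late.iloc[0]["sample_id"], s_early.iloc[0]["sample_id"]))
        else:
            unmatched.extend(sub[sub["timepoint"].isin([earlier, later])]["sample_id"].tolist())
    pairs.sort(key=lambda p: p[0])
    return MatchedPairs(
        pairs=[(k, case, ctrl) for k, (case, ctrl) in enumerate(pairs)],
        unmatched=sorted(unmatched),
        constraint_record={"interval": (earlier, later), "mode": "timepoint"},
    )


def select_first_timepoint(metadata: MetadataTable) -> MetadataTable:
    """Keep only each subject's earliest timepoint.

    The ordering comes from ``metadata.timepoint_order``; cross-sectional
    samples (missing timepoint) pass through unchanged.  A subject with
    duplicated earliest timepoints is an error.
    """
    df = metadata.data
    if "timepoint" not in df.columns or df["timepoint"].isna().all():
        return metadata
    order = metadata.timepoint_order
    if order is None:
        raise ValueError(
            "metadata contains timepoints but no timepoint_order was declared"
        )
    rank = {t: i for i, t in enumerate(order)}
    unknown = set(df["timepoint"].dropna()) - set(rank)
    if unknown:
        raise ValueError(f"timepoint label(s) not in declared ordering: {sorted(unknown)}")
    keep_rows = []
    for _, sub in df.groupby("subject_id", sort=False):
        tps = sub["timepoint"]
        if tps.isna().all():
            keep_rows.append(sub)
            continue
        with_tp = sub[tps.notna()]
        ranks = with_tp["timepoint"].map(rank)
        first = ranks.min()
        earliest = with_tp[ranks == first]
        if len(earliest) > 1:
            raise ValueError(
                f"subject {sub['subject_id'].iloc[0]!r} has duplicated earliest "
                f"timepoint {earliest['timepoint'].iloc[0]!r}"
            )
        keep_rows.append(earliest)
    out = pd.concat(keep_rows).sort_index()
    return MetadataTable(out.copy(), metadata.timepoint_order)
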