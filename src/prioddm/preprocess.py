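"""Participant screening and trial-level RT trimming.

Screening removes whole participants on session-level summaries, then
trimming removes individual trials; both use statistics computed once on
the *input* data (single-pass semantics — rerunning on the filtered
output would use different thresholds and is deliberately not
idempotent).

Participant rules, applied within each session over all input subjects:

(i)   mean accuracy at or below chance (0.5);
(ii)  mean accuracy at or below the group mean minus 2 group SDs;
(iii) mean RT at or beyond 2 group SDs from the group mean (either
      direction).

A subject failing any rule in any session is excluded entirely.  When a
group SD is zero the thresholds collapse onto the mean and the rule
excludes nobody (rules ii/iii only).  Group statistics include every
input subject (no leave-one-out).

Trial rule, applied per subject with mean/SD pooled over that subject's
sessions: drop trials with RT below 0.3 s or above the subject mean plus
3 subject SDs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .design import validate_trials

__all__ = [
    "ExclusionReport",
    "exclude_participants",
    "trim_trials",
    "preprocess",
    "synthetic_screening_cohort",
]

log = logging.getLogger(__name__)

RT_FLOOR_S = 0.3


@dataclass
class ExclusionReport:
    """Auditable record of the screening and trimming pass."""

    n_input_subjects: int
    n_excluded_chance: int
    n_excluded_low_accuracy: int
    n_excluded_rt: int
    n_final_subjects: int
    pct_trials_trimmed: float = float("nan")
    #: subject ids hit by each rule (a subject may appear under several)
    rule_hits: dict = field(default_factory=dict)
    excluded_subjects: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_subjects": self.n_input_subjects,
            "n_excluded_chance": self.n_excluded_chance,
            "n_excluded_low_accuracy": self.n_excluded_low_accuracy,
            "n_excluded_rt": self.n_excluded_rt,
            "n_final_subjects": self.n_final_subjects,
            "pct_trials_trimmed": self.pct_trials_trimmed,
            "rule_hits": {k: sorted(v) for k, v in self.rule_hits.items()},
            "excluded_subjects": sorted(self.excluded_subjects),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def exclude_participants(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the three participant-level rules in a single pass."""
    table = validate_trials(table)
    subjects = table["subject_id"].unique()
    if len(subjects) < 2:
        raise ConfigurationError("participant screening needs at least 2 subjects")

    cell = (
        table.groupby(["subject_id", "session"], sort=True)
        .agg(acc=("correct", "mean"), mrt=("rt_s", "mean"))
        .reset_index()
    )
    hits: dict[str, set] = {"chance": set(), "low_accuracy": set(), "rt": set()}
    for _, grp in cell.groupby("session"):
        acc = grp["acc"].to_numpy()
        mrt = grp["mrt"].to_numpy()
        sid = grp["subject_id"].to_numpy()
        acc_m, acc_sd = acc.mean(), acc.std(ddof=1)
        rt_m, rt_sd = mrt.mean(), mrt.std(ddof=1)
        hits["chance"].update(sid[acc <= 0.5])
        if acc_sd > 0:
            hits["low_accuracy"].update(sid[acc <= acc_m - 2 * acc_sd])
        if rt_sd > 0:
            hits["rt"].update(sid[np.abs(mrt - rt_m) >= 2 * rt_sd])

    # attribute each excluded subject to the first rule that caught it
    n_chance = len(hits["chance"])
    low = hits["low_accuracy"] - hits["chance"]
    rt_only = hits["rt"] - hits["chance"] - hits["low_accuracy"]
    excluded = hits["chance"] | hits["low_accuracy"] | hits["rt"]
    kept = table[~table["subject_id"].isin(excluded)].reset_index(drop=True)
    report = ExclusionReport(
        n_input_subjects=len(subjects),
        n_excluded_chance=n_chance,
        n_excluded_low_accuracy=len(low),
        n_excluded_rt=len(rt_only),
        n_final_subjects=len(subjects) - len(excluded),
        rule_hits={k: list(v) for k, v in hits.items()},
        excluded_subjects=list(excluded),
    )
    log.info(
        "participant screening: %d in, %d excluded (chance=%d, low-accuracy=%d, rt=%d), %d kept",
        report.n_input_subjects,
        len(excluded),
        report.n_excluded_chance,
        report.n_excluded_low_accuracy,
        report.n_excluded_rt,
        report.n_final_subjects,
    )
    return kept, report


def trim_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop fast-guess and slow-outlier trials; returns (table, pct dropped).

    Thresholds (0.3 s floor; subject mean + 3 subject SDs ceiling, pooled
    across sessions) are computed once on the incoming trials.
    """
    table = validate_trials(table)
    stats = table.groupby("subject_id")["rt_s"].agg(["mean", "std"])
    ceiling = (stats["mean"] + 3 * stats["std"].fillna(0.0)).reindex(table["subject_id"])
    keep = (table["rt_s"] >= RT_FLOOR_S) & (table["rt_s"] <= ceiling.to_numpy())
    pct = 100.0 * (1.0 - keep.mean()) if len(table) else 0.0
    log.info("trial trimming: %.2f%% of %d trials removed", pct, len(table))
    return table[keep].reset_index(drop=True), float(pct)


def preprocess(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Participant screening followed by trial trimming (fixed order)."""
    kept, report = exclude_participants(table)
    trimmed, pct = trim_trials(kept)
    report.pct_trials_trimmed = pct
    return trimmed, report


def synthetic_screening_cohort(
    n_clean: int = 49,
    n_chance: int = 1,
    n_low_accuracy: int = 7,
    n_rt_outlier: int = 4,
    n_sessions: int = 3,
    trials_per_session: int = 408,
) -> pd.DataFrame:
    """Synthetic cohort with planted screening failures (demo/worked example).

    Constructs a deterministic trial table in which ``n_clean`` subjects
    perform well, one group is at chance, one is above chance but far
    below the group accuracy, and one responds with extreme mean RTs —
    so each planted group is caught by exactly one rule.  With the
    defaults this mirrors the 61-subject screening bookkeeping: 1 + 7 +
    4 exclusions leaving 49.
    """
    n_total = n_clean + n_chance + n_low_accuracy + n_rt_outlier
    rows = []
    sid_width = max(2, len(str(n_total)))

    def add_subject(i: int, accuracy: float, rt: float) -> None:
        sid = f"c{i:0{sid_width}d}"
        n_corr = int(round(accuracy * trials_per_session))
        for sess in range(1, n_sessions + 1):
            for t in range(trials_per_session):
                cond = ("control", "first", "middle", "last")[t % 4]
                probe = (t % 3) + 1
                rows.append((sid, sess, cond, probe, int(t < n_corr), rt))

    i = 1
    for k in range(n_clean):
        # spread clean accuracies/RTs so group SDs are realistic but tight
        add_subject(i, 0.83 + 0.04 * (k % 5) / 4, 0.75 + 0.10 * (k % 7) / 6)
        i += 1
    for _ in range(n_chance):
        add_subject(i, 0.48, 0.80)
        i += 1
    for _ in range(n_low_accuracy):
        add_subject(i, 0.65, 0.80)
        i += 1
    for _ in range(n_rt_outlier):
        add_subject(i, 0.85, 2.0)
        i += 1
    return pd.DataFrame(rows, columns=["subject_id", "session", "prioritization", "probe_position", "correct", "rt_s"])
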