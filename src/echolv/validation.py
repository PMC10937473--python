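"""Multi-expert consensus validation of a candidate measurer.

The framework: every validation frame is measured many times by a panel of
experts (here 13 experts, twice each, giving 26 labels per frame).  The
per-frame consensus is the arithmetic mean of the expert values; the signed
deviation of each label from its frame's consensus quantifies individual
disagreement.  Pooled across frames, these deviations have mean exactly zero
by construction; their SD (equivalently root-mean-square) is the index of
expert dispersion.  A candidate measurer (e.g. the network, one value per
frame) is judged by comparing the dispersion of its deviations from the same
consensus with that of the individual experts (Levene's test on absolute
deviations from a group center) and by testing its mean bias with a paired t
test against the consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measure import SITES

__all__ = [
    "DegenerateDispersionError",
    "BiasResult",
    "consensus",
    "deviations",
    "rms_dispersion",
    "levene_dispersion_test",
    "bias_test",
    "build_summary",
    "measurement_table",
]

PHASES = ("ED", "ES")


class DegenerateDispersionError(ValueError):
    """Raised when Levene's test denominator is zero (no within-group spread)."""


def consensus(values: Sequence[float]) -> float:
    """Arithmetic mean of a panel's measurements (the reference standard)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("consensus needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("consensus values must all be finite")
    return float(arr.mean())


def deviations(values: Sequence[float], consensus_value: float) -> np.ndarray:
    """Signed deviations value - consensus, order preserved."""
    if not np.isfinite(consensus_value):
        raise ValueError("consensus must be finite")
    return np.asarray(values, dtype=np.float64) - consensus_value


def rms_dispersion(devs: Sequence[float]) -> float:
    """Root-mean-square of deviations (population form).

    Equals the population SD when the deviations are mean-zero, which pooled
    deviations from per-frame mean consensus are by construction.
    """
    arr = np.asarray(devs, dtype=np.float64)
    if arr.size < 1:
        raise ValueError("rms_dispersion needs at least 1 value")
    return float(np.sqrt(np.mean(arr ** 2)))


def levene_dispersion_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    center: str = "median",
) -> tuple[float, float]:
    """Two-group Levene test of equal dispersion.

    ``center="median"`` is the Brown-Forsythe variant (the default of the
    scipy routine); ``"mean"`` gives the classic test.  Returns (W, p) with p
    from the upper tail of F(1, N-2).  Raises
    :class:`DegenerateDispersionError` when the within-group spread of the
    absolute centered scores is zero (W undefined).
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    cfun = np.median if center == "median" else np.mean
    denom = 0.0
    for g in (a, b):
        z = np.abs(g - cfun(g))
        denom += float(((z - z.mean()) ** 2).sum())
    if denom == 0.0:
        raise DegenerateDispersionError(
            "DEGENERATE_DISPERSION: zero within-group spread of |centered| scores")
    w, p = stats.levene(a, b, center=center)
    return float(w), float(p)


@dataclass(frozen=True)
class BiasResult:
    mean_bias: float
    t: float
    p: float
    n: int
    degenerate: bool = False


def bias_test(candidate: Sequence[float], consensus_values: Sequence[float]) -> BiasResult:
    """Paired t test of the candidate against the per-frame consensus.

    Pairs are (candidate, consensus) on the same frame.  Zero-variance
    differences make the t statistic undefined: all-zero differences report
    (bias 0, t 0, p 1); constant nonzero differences are flagged degenerate
    with p reported as NaN.
    """
    c = np.asarray(candidate, dtype=np.float64)
    r = np.asarray(consensus_values, dtype=np.float64)
    if c.shape != r.shape:
        raise ValueError("candidate and consensus lengths differ")
    n = c.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = c - r
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return BiasResult(mean_bias=0.0, t=0.0, p=1.0, n=n)
        return BiasResult(mean_bias=mean, t=math.inf if mean > 0 else -math.inf,
                          p=math.nan, n=n, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return BiasResult(mean_bias=mean, t=t, p=p, n=n)


_TABLE_COLUMNS = ["frame_id", "phase", "site", "rater_id", "repeat_index", "value_cm"]


def measurement_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build a validated long-format measurement table.

    Rows are (frame_id, phase, site, rater_id, repeat_index, value_cm);
    (frame, site, rater, repeat) must be unique.
    """
    df = pd.DataFrame(list(rows), columns=_TABLE_COLUMNS)
    bad_phase = set(df["phase"]) - set(PHASES)
    if bad_phase:
        raise ValueError(f"unknown phase(s): {sorted(bad_phase)}")
    bad_site = set(df["site"]) - set(SITES)
    if bad_site:
        raise ValueError(f"unknown site(s): {sorted(bad_site)}")
    key = ["frame_id", "site", "rater_id", "repeat_index"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicate measurement rows: {df.loc[dup, key].values[:5]}")
    return df


@dataclass
class ValidationResult:
    """Machine twin of the published validation tables plus per-frame records."""

    summary: pd.DataFrame
    records: pd.DataFrame
    excluded_frames: dict[str, list[str]] = field(default_factory=dict)
    levene_center: str = "median"

    def summary_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def records_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def build_summary(
    table: pd.DataFrame,
    candidate_id: str = "AI",
    levene_center: str = "median",
) -> ValidationResult:
    """Run the full consensus-validation procedure on a measurement table.

    Per (phase, site): the consensus of each frame is the mean of its expert
    values (all raters except ``candidate_id``; repeats count as independent
    labels); expert deviations are pooled across frames; the candidate
    contributes one deviation per frame.  Dispersion is compared candidate vs
    pooled experts with Levene's test, bias with a paired t test.  Frames
    without a candidate value are excluded from candidate statistics and
    listed in ``excluded_frames``, never silently dropped.
    """
    if not isinstance(table, pd.DataFrame):
        table = measurement_table(table)
    expert = table[table["rater_id"] != candidate_id]
    cand = table[table["rater_id"] == candidate_id]
    if cand.duplicated(subset=["frame_id", "site"]).any():
        raise ValueError("candidate must have at most one value per frame and site")

    summary_rows = []
    record_rows = []
    excluded: dict[str, list[str]] = {}
    for phase in PHASES:
        for site in SITES:
            esub = expert[(expert["phase"] == phase) & (expert["site"] == site)]
            if esub.empty:
                continue
            csub = cand[(cand["phase"] == phase) & (cand["site"] == site)]
            cand_by_frame = dict(zip(csub["frame_id"], csub["value_cm"]))
            expert_devs: list[float] = []
            cand_devs: list[float] = []
            cons_paired: list[float] = []
            cand_paired: list[float] = []
            missing_cand: list[str] = []
            for frame_id, grp in sorted(esub.groupby("frame_id"), key=lambda kv: kv[0]):
                vals = grp["value_cm"].to_numpy()
                if vals.size < 2:
                    raise ValueError(
                        f"frame {frame_id} {phase}/{site}: needs >= 2 expert labels")
                cons = consensus(vals)
                devs = deviations(vals, cons)
                expert_devs.extend(devs.tolist())
                cv = cand_by_frame.get(frame_id)
                record_rows.append({
                    "frame_id": frame_id, "phase": phase, "site": site,
                    "consensus_cm": cons,
                    "n_expert_labels": int(vals.size),
                    "candidate_deviation_cm": (math.nan if cv is None else cv - cons),
                })
                if cv is None:
                    missing_cand.append(frame_id)
                else:
                    cand_devs.append(cv - cons)
                    cand_paired.append(cv)
                    cons_paired.append(cons)
            if missing_cand:
                excluded[f"{phase}/{site}"] = missing_cand
            ed = np.array(expert_devs)
            row = {
                "phase": phase, "site": site,
                "expert_dev_mean": float(ed.mean()),
                "expert_dev_sd": rms_dispersion(ed),
                "expert_dev_median": float(np.median(ed)),
                "n_frames": int(esub["frame_id"].nunique()),
                "n_expert_labels": int(ed.size),
                "n_candidate": len(cand_devs),
                "levene_center": levene_center,
            }
            if cand_devs:
                cd = np.array(cand_devs)
                row.update(
                    cand_dev_mean=float(cd.mean()),
                    cand_dev_sd=rms_dispersion(cd - cd.mean()),
                    cand_dev_rms=rms_dispersion(cd),
                    cand_dev_median=float(np.median(cd)),
                )
                try:
                    w, p = levene_dispersion_test(cd, ed, center=levene_center)
                    row.update(levene_W=w, levene_p=p)
                except DegenerateDispersionError:
                    row.update(levene_W=math.nan, levene_p=math.nan,
                               degenerate_dispersion=True)
                if len(cand_devs) >= 2:
                    bias = bias_test(cand_paired, cons_paired)
                    row.update(bias_mean=bias.mean_bias, bias_t=bias.t,
                               bias_p=bias.p, bias_degenerate=bias.degenerate)
            summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    records = pd.DataFrame(record_rows)
    return ValidationResult(summary=summary, records=records,
                            excluded_frames=excluded, levene_center=levene_center)
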