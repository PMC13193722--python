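"""Label-free quantification and chirality assignment of 2HG-modified peptides.

The analysis chain mirrors a dose-gradient metabolite-feeding experiment:
peak areas are normalized to total ion current (TIC) per sample; a peptide is
classified as responding to a treatment when its fold change against vehicle
exceeds 1.2 with a two-tailed t-test p below 0.05 (no multiple-testing
adjustment); a peptide is assigned to the D or L enantiomer series when that
series — and not the other — shows a reproducible, dose-consistent response.
Cohort-level utilities cover cross-group high-confidence filtering, overlap
(D-specific / L-specific / shared) set analysis, semi-quantitative occupancy,
and the paired retention-time shift test for modified vs unmodified
counterparts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceMatrix",
    "OverlapResult",
    "RTShiftResult",
    "tic_normalize",
    "classify_modified",
    "chirality_call",
    "high_confidence_filter",
    "overlap_sets",
    "occupancy",
    "paired_rt_test",
]

SAMPLE_COLUMNS = ("condition", "series", "dose", "replicate")


@dataclass
class AbundanceMatrix:
    """Peptide × sample peak areas plus the sample design.

    ``data`` is a DataFrame indexed by peptide identifier (sequence plus mod
    site label) with one column per sample; ``samples`` is indexed by sample
    name with columns ``condition`` (group label), ``series`` (e.g. ``D2HG``,
    ``L2HG``, ``vehicle``), ``dose`` (numeric, ordered) and ``replicate``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        unknown = [s for s in self.data.columns if s not in self.samples.index]
        if unknown:
            raise ValueError(f"samples without metadata: {unknown}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        return [s for s in sel if s in self.data.columns]

    def series_conditions(self, series: str) -> pd.DataFrame:
        """Condition labels of a series with their doses, ordered by dose."""
        sub = self.samples[self.samples["series"] == series]
        out = (
            sub[["condition", "dose"]]
            .drop_duplicates()
            .sort_values("dose")
            .reset_index(drop=True)
        )
        return out

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.samples.copy())


def tic_normalize(
    matrix: AbundanceMatrix, tic: Mapping[str, float] | None = None
) -> AbundanceMatrix:
    """Normalize peak areas to total ion current.

    The TIC of a sample defaults to its column sum. Each column is divided by
    its TIC and rescaled by the median TIC, so when TIC = column sum all
    normalized columns sum to the same value.
    """
    data = matrix.data
    if tic is None:
        tic_s = data.sum(axis=0)
    else:
        tic_s = pd.Series({s: tic[s] for s in data.columns}, dtype=float)
    bad = tic_s[tic_s <= 0]
    if len(bad):
        raise ValueError(f"non-positive TIC for sample(s): {list(bad.index)}")
    scale = float(tic_s.median())
    return AbundanceMatrix(data.div(tic_s, axis=1) * scale, matrix.samples.copy())


def classify_modified(
    matrix: AbundanceMatrix,
    treated: str,
    control: str,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    equal_var: bool = False,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-peptide fold-change / t-test classification of one comparison.

    fold_change = mean(treated) / mean(control) on (already normalized)
    areas; p from a two-tailed two-sample t-test (Welch by default);
    ``passed`` ⇔ fold_change > ``fc_threshold`` and p < ``alpha``. No
    multiple-testing adjustment by default; ``adjust="bh"`` applies
    Benjamini–Hochberg to the p column before gating.

    Peptides with a zero control mean get ``fold_change = NaN`` and
    ``flagged = True`` rather than a classification.
    """
    t_cols = matrix.condition_samples(treated)
    c_cols = matrix.condition_samples(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    tvals = matrix.data[t_cols].to_numpy(dtype=float)
    cvals = matrix.data[c_cols].to_numpy(dtype=float)
    tmean = tvals.mean(axis=1)
    cmean = cvals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(cmean > 0, tmean / cmean, np.nan)
    tt = stats.ttest_ind(tvals, cvals, axis=1, equal_var=equal_var)
    p = np.asarray(tt.pvalue, dtype=float)
    if adjust == "bh":
        p = _benjamini_hochberg(p)
    flagged = ~np.isfinite(fc)
    passed = np.isfinite(fc) & (fc > fc_threshold) & (p < alpha)
    return pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "passed": passed,
            "flagged": flagged,
        },
        index=matrix.data.index,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n, dtype=float)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def _monotone_nondecreasing(values: Sequence[float], rel_tol: float) -> bool:
    """Non-decreasing up to a relative tolerance absorbing replicate noise."""
    vals = [v for v in values if np.isfinite(v)]
    if len(vals) != len(values):
        return False
    return all(b >= a * (1.0 - rel_tol) for a, b in zip(vals, vals[1:]))


def chirality_call(
    matrix: AbundanceMatrix,
    d_series: str = "D2HG",
    l_series: str = "L2HG",
    vehicle: str = "vehicle",
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    min_passing_doses: int = 2,
    mono_rel_tol: float = 0.10,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each peptide to the D or L enantiomer series (or shared/ambiguous).

    A series *responds* when at least ``min_passing_doses`` of its dose
    levels pass the fold-change/p gate against vehicle AND the fold changes
    are non-decreasing with dose (ties and dips within ``mono_rel_tol``
    allowed, absorbing replicate noise). Calls: ``D`` — only the D series
    responds; ``L`` — only L; ``shared`` — both; ``ambiguous`` — neither.

    Returns ``(calls, evidence)``: calls indexed by peptide with the call and
    per-series response flags; evidence in long form with one row per
    peptide × series × dose carrying fold change, p and the gate outcome.
    """
    vehicle_cond = matrix.series_conditions(vehicle)
    if vehicle_cond.empty:
        raise ValueError(f"no samples in vehicle series {vehicle!r}")
    control = vehicle_cond["condition"].iloc[0]

    evidence_rows = []
    responds: dict[str, pd.Series] = {}
    fcs: dict[str, pd.DataFrame] = {}
    for series in (d_series, l_series):
        conds = matrix.series_conditions(series)
        conds = conds[conds["dose"] > 0]
        if len(conds) < 2:
            raise ValueError(f"series {series!r} needs >= 2 nonzero dose levels")
        per_dose = {}
        for _, row in conds.iterrows():
            res = classify_modified(
                matrix, row["condition"], control,
                fc_threshold=fc_threshold, alpha=alpha, equal_var=equal_var,
            )
            per_dose[row["dose"]] = res
            ev = res.reset_index(names="peptide")
            ev.insert(1, "series", series)
            ev.insert(2, "dose", row["dose"])
            evidence_rows.append(ev)
        doses = sorted(per_dose)
        n_pass = sum((per_dose[d]["passed"] for d in doses))
        fc_frame = pd.DataFrame({d: per_dose[d]["fold_change"] for d in doses})
        mono = fc_frame.apply(
            lambda r: _monotone_nondecreasing(list(r), mono_rel_tol), axis=1
        )
        responds[series] = (n_pass >= min_passing_doses) & mono
        fcs[series] = fc_frame

    d_ok, l_ok = responds[d_series], responds[l_series]
    call = pd.Series("ambiguous", index=matrix.data.index, dtype=object)
    call[d_ok & ~l_ok] = "D"
    call[~d_ok & l_ok] = "L"
    call[d_ok & l_ok] = "shared"
    calls = pd.DataFrame(
        {
            "call": call,
            "d_responds": d_ok,
            "l_responds": l_ok,
            "d_top_fc": fcs[d_series].iloc[:, -1],
            "l_top_fc": fcs[l_series].iloc[:, -1],
        }
    )
    evidence = pd.concat(evidence_rows, ignore_index=True)
    return calls, evidence


def high_confidence_filter(
    calls_by_group: Mapping[str, pd.DataFrame] | pd.DataFrame,
    min_groups: int = 2,
) -> pd.DataFrame:
    """Cross-validate calls across independent dataset groups.

    Accepts either a mapping group→calls DataFrame (as returned by
    :func:`chirality_call`) or a long DataFrame with columns ``group``,
    ``peptide``, ``call``. Retains peptides with the same non-ambiguous call
    in at least ``min_groups`` groups; peptides called to different
    enantiomers in different groups are dropped as conflicts.
    """
    if isinstance(calls_by_group, pd.DataFrame):
        long = calls_by_group[["group", "peptide", "call"]].copy()
    else:
        rows = []
        for group, calls in calls_by_group.items():
            rows.append(
                pd.DataFrame(
                    {"group": group, "peptide": calls.index, "call": calls["call"]}
                )
            )
        long = pd.concat(rows, ignore_index=True)
    long = long[long["call"].isin(["D", "L", "shared"])]
    out = []
    for peptide, sub in long.groupby("peptide", sort=True):
        enantiomer_calls = set(sub.loc[sub["call"].isin(["D", "L"]), "call"])
        if len(enantiomer_calls) > 1:
            continue  # conflicting enantiomer assignment across groups
        call = enantiomer_calls.pop() if enantiomer_calls else "shared"
        n = int(len(sub))
        if n >= min_groups:
            out.append({"peptide": peptide, "call": call, "n_groups": n})
    return pd.DataFrame(out, columns=["peptide", "call", "n_groups"])


@dataclass(frozen=True)
class OverlapResult:
    a_specific: frozenset
    b_specific: frozenset
    shared: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_specific), len(self.b_specific), len(self.shared)


def overlap_sets(set_a: Iterable, set_b: Iterable) -> OverlapResult:
    """Specific/shared partition of two identifier sets (Venn counts)."""
    a, b = frozenset(set_a), frozenset(set_b)
    return OverlapResult(a - b, b - a, a & b)


def occupancy(modified_area: float, unmodified_area: float) -> float:
    """Semi-quantitative modification occupancy: modified/(modified+unmodified).

    Returns NaN when both areas are zero (undefined).
    """
    if modified_area < 0 or unmodified_area < 0:
        raise ValueError("areas must be non-negative")
    total = modified_area + unmodified_area
    if total == 0:
        return math.nan
    return modified_area / total


@dataclass(frozen=True)
class RTShiftResult:
    mean_delta: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def paired_rt_test(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
) -> RTShiftResult:
    """Paired two-tailed t-test on retention-time shifts of modified peptides.

    ``pairs`` holds (rt_modified, rt_unmodified) in minutes; the delta is
    modified − unmodified. With zero-variance deltas the test statistic is
    undefined and the result is flagged degenerate (p = NaN).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (rt_modified, rt_unmodified) pairs")
    deltas = arr[:, 0] - arr[:, 1]
    mean_delta = float(deltas.mean())
    if float(deltas.std(ddof=1)) == 0.0:
        return RTShiftResult(mean_delta, math.nan, math.nan, len(deltas), True)
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return RTShiftResult(mean_delta, float(t), float(p), len(deltas), False)
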