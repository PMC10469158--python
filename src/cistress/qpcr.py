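"""Relative qPCR quantification (Livak 2^-ddCt) and group statistics.

The workflow mirrors standard qRT-PCR practice: technical replicates of
each (group, gene, biological replicate) cell are averaged; dCt is the
target Ct minus the reference-gene Ct of the same cell; ddCt subtracts the
mean dCt of the calibrator group; relative quantity is rq = 2^-ddCt (and
-ddCt = log2(rq) for log-scale presentation).  Group differences are then
assessed by one-way ANOVA followed by Duncan's multiple range test with a
compact letter display, or by a two-sample t-test.

Duncan's test compares ordered group means: a pair spanning ``p``
consecutive ordered means is significant when its difference exceeds the
critical range ``R_p = q_{alpha_p}(p, df_error) * sqrt(MSE / n_h)`` where
``alpha_p = 1 - (1 - alpha)**(p - 1)`` is Duncan's protection level, ``q``
the studentized-range quantile and ``n_h`` the harmonic mean of the two
group sizes — subject to the step-down rule that no pair inside a
non-significant wider range is declared significant.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "AnovaResult",
    "DuncanResult",
    "RelativeExpressionResult",
    "read_ct_table",
    "collapse_technical",
    "relative_quantities",
    "anova_oneway",
    "duncan_mrt",
    "compact_letter_display",
    "ttest_two_sample",
]

CT_COLUMNS = ["sample_id", "group", "gene", "biorep", "techrep", "ct"]


class CtTableError(ValueError):
    """Raised for structurally invalid Ct tables."""


def read_ct_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a Ct table (CSV/TSV with the documented header; '' or NA missing)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     na_values=["NA", ""])
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise CtTableError(f"Ct table missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    dup = df.duplicated(subset=["sample_id", "gene", "biorep", "techrep"])
    if dup.any():
        raise CtTableError(
            f"duplicate (sample_id, gene, biorep, techrep) rows: "
            f"{df.loc[dup, ['sample_id', 'gene', 'biorep', 'techrep']].values.tolist()}"
        )
    if (df["ct"].dropna() <= 0).any():
        raise CtTableError("Ct values must be positive")
    return df


def collapse_technical(records: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Average technical replicates per (group, gene, biorep) cell.

    Missing Ct values are ignored; a cell whose technical-replicate SD
    exceeds ``max_sd`` cycles is flagged (kept, not dropped).  A cell with
    no non-missing replicate is an error naming the cell.
    """
    out = []
    for (group, gene, biorep), cell in records.groupby(
            ["group", "gene", "biorep"], sort=True):
        vals = cell["ct"].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise CtTableError(
                f"all technical replicates missing for "
                f"(group={group!r}, gene={gene!r}, biorep={biorep})"
            )
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append({"group": group, "gene": gene, "biorep": biorep,
                    "ct": float(np.mean(vals)), "flagged": sd > max_sd})
    return pd.DataFrame(out, columns=["group", "gene", "biorep", "ct", "flagged"])


@dataclass(frozen=True)
class RelativeExpressionResult:
    """Per-biological-replicate relative quantities and per-group summary.

    ``per_replicate`` columns: group, gene, biorep, delta_ct,
    delta_delta_ct, rq, neg_ddct.  ``summary`` columns: group, gene, n,
    mean_rq, sem_rq, mean_neg_ddct (SEM is SD/sqrt(n) over biological
    replicates of rq).
    """

    target: str
    reference: str
    calibrator_group: str
    per_replicate: pd.DataFrame
    summary: pd.DataFrame


def relative_quantities(ct_means: pd.DataFrame, target: str, reference: str,
                        calibrator_group: str) -> RelativeExpressionResult:
    """Livak relative quantification for one target gene.

    ``ct_means`` is the output of :func:`collapse_technical`.  The
    calibrator dCt is the mean dCt over the calibrator group's biological
    replicates; bioreps missing the reference measurement are excluded with
    a warning.
    """
    tgt = ct_means[ct_means["gene"] == target].set_index(["group", "biorep"])["ct"]
    ref = ct_means[ct_means["gene"] == reference].set_index(["group", "biorep"])["ct"]
    if tgt.empty:
        raise CtTableError(f"no measurements for target gene {target!r}")
    rows = []
    for (group, biorep), ct_t in tgt.items():
        if (group, biorep) not in ref.index:
            warnings.warn(
                f"reference {reference!r} missing for (group={group!r}, "
                f"biorep={biorep}); biorep excluded", stacklevel=2)
            continue
        rows.append({"group": group, "biorep": biorep,
                     "delta_ct": ct_t - ref[(group, biorep)]})
    per = pd.DataFrame(rows)
    cal = per[per["group"] == calibrator_group]
    if cal.empty:
        raise CtTableError(
            f"calibrator group {calibrator_group!r} has no usable bioreps")
    cal_dct = float(cal["delta_ct"].mean())
    per["delta_delta_ct"] = per["delta_ct"] - cal_dct
    per["rq"] = np.exp2(-per["delta_delta_ct"])
    per["neg_ddct"] = -per["delta_delta_ct"]
    per.insert(1, "gene", target)
    summary = (per.groupby("group", sort=True)
               .agg(n=("rq", "size"), mean_rq=("rq", "mean"),
                    sem_rq=("rq", lambda x: x.std(ddof=1) / math.sqrt(len(x))
                            if len(x) > 1 else float("nan")),
                    mean_neg_ddct=("neg_ddct", "mean"))
               .reset_index())
    summary.insert(1, "gene", target)
    return RelativeExpressionResult(
        target=target, reference=reference, calibrator_group=calibrator_group,
        per_replicate=per.reset_index(drop=True), summary=summary)


@dataclass(frozen=True)
class AnovaResult:
    """Classical fixed-effects one-way ANOVA with the pooled within-group
    mean square (MSE) that range tests need."""

    F: float
    df1: int
    df2: int
    p: float
    MSE: float


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the between/within sum-of-squares
    decomposition.

    Special cases: zero within-group variance with separated means gives
    F = inf, p = 0; all observations identical gives F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
        if not np.isfinite(a).all():
            raise ValueError(f"group {k!r} contains non-finite values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df1 = len(arrays) - 1
    df2 = all_vals.size - len(arrays)
    msb = ssb / df1
    mse = ssw / df2
    if mse == 0.0:
        if ssb == 0.0:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0, MSE=0.0)
        return AnovaResult(F=math.inf, df1=df1, df2=df2, p=0.0, MSE=0.0)
    f = msb / mse
    p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(F=float(f), df1=df1, df2=df2, p=p, MSE=float(mse))


@lru_cache(maxsize=4096)
def _duncan_q(alpha_p: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level."""
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


@dataclass(frozen=True)
class DuncanResult:
    """Duncan multiple-range-test decisions.

    ``significant_pairs`` holds unordered group-name pairs declared
    different at level alpha; ``critical_ranges`` maps span width p to the
    critical range computed with the harmonic-mean sample size of that
    span's endpoint groups (so ranges can differ across pairs of the same
    width under unequal n; the stored value uses the span actually tested).
    """

    alpha: float
    means: dict[str, float]
    n: dict[str, int]
    anova: AnovaResult
    significant_pairs: frozenset[frozenset[str]]
    letters: dict[str, str]


def duncan_mrt(groups: Mapping[str, Sequence[float]],
               alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test over all group pairs.

    Groups are ordered by mean; each pair corresponds to the span of
    consecutive ordered means it encloses.  Spans are tested widest-first
    and a span contained in a non-significant wider span is declared
    non-significant without testing (step-down protection).  With unequal
    group sizes the critical range uses the harmonic mean of the two
    endpoint groups' sizes.
    """
    an = anova_oneway(groups)
    if an.df2 < 1:
        raise ValueError("error degrees of freedom must be >= 1")
    means = {k: float(np.mean(np.asarray(v, dtype=float)))
             for k, v in groups.items()}
    sizes = {k: len(groups[k]) for k in groups}
    ordered = sorted(means, key=means.get)  # ascending means
    k = len(ordered)
    nonsig_spans: list[tuple[int, int]] = []
    significant: set[frozenset[str]] = set()
    for p in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        for i in range(0, k - p + 1):
            j = i + p - 1
            gi, gj = ordered[i], ordered[j]
            if any(a <= i and j <= b for a, b in nonsig_spans):
                continue
            n_h = 2.0 / (1.0 / sizes[gi] + 1.0 / sizes[gj])
            if an.MSE == 0.0:
                sig = means[gj] > means[gi]
            else:
                r_p = _duncan_q(alpha_p, p, an.df2) * math.sqrt(an.MSE / n_h)
                sig = (means[gj] - means[gi]) > r_p
            if sig:
                significant.add(frozenset((gi, gj)))
            else:
                nonsig_spans.append((i, j))
    letters = compact_letter_display(means, significant)
    return DuncanResult(alpha=alpha, means=means, n=sizes, anova=an,
                        significant_pairs=frozenset(significant),
                        letters=letters)


def compact_letter_display(means: Mapping[str, float],
                           significant_pairs) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Produces letter sets such that significantly different groups share no
    letter and every other pair shares at least one; letters are assigned
    a, b, c, ... walking groups in order of descending mean.
    """
    pairs = {frozenset(p) for p in significant_pairs}
    for p in pairs:
        if len(p) != 2:
            raise ValueError("pairs must be irreflexive two-element sets")
    groups_desc = sorted(means, key=means.get, reverse=True)
    letters: list[set[str]] = [set(groups_desc)]
    for pair in sorted(pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        for col in [c for c in letters if a in c and b in c]:
            letters.remove(col)
            letters.append(col - {a})
            letters.append(col - {b})
        # absorb columns that became subsets of others
        letters = [c for c in letters
                   if c and not any(c < d for d in letters)]
        # drop exact duplicates
        uniq: list[set[str]] = []
        for c in letters:
            if c not in uniq:
                uniq.append(c)
        letters = uniq
    # order letter columns by the best (largest-mean) group they contain
    rank = {g: i for i, g in enumerate(groups_desc)}
    letters.sort(key=lambda c: sorted(rank[g] for g in c))
    symbols = _letter_symbols(len(letters))
    out = {g: "".join(sym for col, sym in zip(letters, symbols) if g in col)
           for g in groups_desc}
    # soundness of the display (always holds for step-down range tests)
    for a, b in itertools.combinations(groups_desc, 2):
        shared = set(out[a]) & set(out[b])
        if frozenset((a, b)) in pairs:
            assert not shared, "significant pair shares a letter"
        else:
            assert shared, "non-significant pair shares no letter"
    return out


def _letter_symbols(n: int) -> list[str]:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    syms = list(alphabet)
    while len(syms) < n:
        syms.append(alphabet[len(syms) // 26 - 1] + alphabet[len(syms) % 26])
    return syms[:n]


def ttest_two_sample(x: Sequence[float], y: Sequence[float],
                     welch: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: Student (pooled) by default, Welch on flag.

    Returns (t, df, p).  Degenerate zero-variance input with equal means is
    reported as (0, df, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
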