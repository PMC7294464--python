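"""Reaction-time statistics: error-trial filtering, 2x2x2 within-subject
ANOVA, and planned paired contrasts.

The ANOVA engine computes the classical balanced within-subject decomposition
directly from sums of squares: reaction times are first aggregated to subject
x cell means, and each effect (3 mains, 3 two-way, 1 three-way interaction)
is tested against its own subject-by-effect interaction error term, giving
F with df (1, n-1) for 2-level factors.  No sphericity correction is needed
since every factor has two levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialTable

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "ContrastResult",
    "FilterReport",
    "filter_trials",
    "rm_anova_factorial",
    "rm_anova_2x2x2",
    "planned_contrasts",
    "underline_position_anova",
    "DEFAULT_CONTRASTS",
]

ACCURACY_SCREEN = 0.85

# the study's four planned comparisons: (cell_a, cell_b, task); a cell is
# (global_lex, local_lex) and the difference reported is mean(a) - mean(b)
DEFAULT_CONTRASTS: tuple[tuple[str, tuple[str, str], tuple[str, str], str], ...] = (
    ("GnLw-GwLw (local task)", ("n", "w"), ("w", "w"), "local"),
    ("GwLn-GnLn (local task)", ("w", "n"), ("n", "n"), "local"),
    ("GwLw-GwLn (global task)", ("w", "w"), ("w", "n"), "global"),
    ("GnLw-GnLn (global task)", ("n", "w"), ("n", "n"), "global"),
)


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    cell_means: pd.DataFrame  # subject x cell means used
    n_subjects: int

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


@dataclass(frozen=True)
class ContrastResult:
    name: str
    mean_diff_ms: float
    t: float
    df: int
    p: float


@dataclass
class FilterReport:
    per_subject_accuracy: dict[str, float]
    below_screen: list[str] = field(default_factory=list)
    flagged_empty_cell: list[tuple[str, tuple]] = field(default_factory=list)


def filter_trials(t: TrialTable) -> tuple[TrialTable, FilterReport]:
    """Remove error trials; report per-subject accuracy.

    Subjects below the 85% accuracy screen are listed (not removed — in the
    study this screen excluded no one); subjects left with an empty
    (global_lex, local_lex, task) cell after filtering are flagged so the
    ANOVA can exclude them explicitly.
    """
    df = t.df
    acc = df.groupby("subject")["correct"].mean().astype(float).to_dict()
    report = FilterReport(per_subject_accuracy=acc,
                          below_screen=[s for s, a in acc.items()
                                        if a < ACCURACY_SCREEN])
    kept = df[df["correct"] == 1].copy()
    cells = list(product("wn", "wn", ("global", "local")))
    for subj, sub in kept.groupby("subject"):
        present = set(zip(sub["global_lex"], sub["local_lex"], sub["task"]))
        for cell in cells:
            if cell not in present:
                report.flagged_empty_cell.append((str(subj), cell))
    return TrialTable(kept), report


# ---------------------------------------------------------------------------
# Balanced within-subject factorial ANOVA from sums of squares
# ---------------------------------------------------------------------------

def _effect_ss(M: np.ndarray, in_effect: tuple[bool, ...]) -> float:
    """SS of one term of the balanced decomposition.

    ``M`` is the subject x factor-levels cell-mean tensor; axis 0 is the
    subject.  For each axis, the centering operator (x - mean) is applied if
    the axis belongs to the term, the averaging operator otherwise; the SS is
    the squared effect tensor summed over the full grid.
    """
    eff = M
    scale = 1.0
    for ax, inside in enumerate(in_effect):
        if inside:
            eff = eff - eff.mean(axis=ax, keepdims=True)
        else:
            scale *= M.shape[ax]
            eff = eff.mean(axis=ax, keepdims=True)
    return float((eff ** 2).sum() * scale)


def rm_anova_factorial(M: np.ndarray,
                       factor_names: tuple[str, ...]) -> dict[str, AnovaEffect]:
    """Fully within-subject factorial ANOVA on a balanced cell-mean tensor.

    ``M`` has shape (n_subjects, l1, ..., lk).  Every non-empty subset of the
    factors is tested against its own factor(s)-by-subject interaction.
    """
    if M.ndim != len(factor_names) + 1:
        raise ValueError("tensor rank must be n_factors + 1 (subjects first)")
    n = M.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    k = len(factor_names)
    effects: dict[str, AnovaEffect] = {}
    for r in range(1, k + 1):
        for combo in _subsets(k, r):
            in_eff = (False,) + tuple(i in combo for i in range(k))
            in_err = (True,) + tuple(i in combo for i in range(k))
            df1 = int(np.prod([M.shape[i + 1] - 1 for i in combo]))
            df2 = df1 * (n - 1)
            ss_eff = _effect_ss(M, in_eff)
            ss_err = _effect_ss(M, in_err)
            if ss_err == 0:
                F = 0.0 if ss_eff == 0 else np.inf
            else:
                F = (ss_eff / df1) / (ss_err / df2)
            p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            name = " x ".join(factor_names[i] for i in combo)
            effects[name] = AnovaEffect(name=name, F=float(F), df1=df1,
                                        df2=df2, p=min(max(p, 0.0), 1.0))
    return effects


def _subsets(k: int, r: int):
    from itertools import combinations
    return combinations(range(k), r)


def _cell_mean_tensor(df: pd.DataFrame, factors: list[str],
                      levels: list[tuple[str, ...]]) -> tuple[np.ndarray,
                                                              list[str]]:
    """Aggregate rt_ms to subject x cell means; error on any missing cell."""
    subjects = sorted(df["subject"].unique())
    shape = (len(subjects),) + tuple(len(lv) for lv in levels)
    M = np.full(shape, np.nan)
    grouped = df.groupby(["subject", *factors])["rt_ms"].mean()
    for si, subj in enumerate(subjects):
        for combo in product(*levels):
            key = (subj, *combo)
            if key not in grouped.index:
                raise ValueError(f"subject {subj!r} has no trials in cell "
                                 f"{dict(zip(factors, combo))}")
            idx = (si,) + tuple(lv.index(c) for lv, c in zip(levels, combo))
            M[idx] = grouped[key]
    return M, subjects


def rm_anova_2x2x2(t: TrialTable) -> AnovaResult:
    """Three-way within-subject ANOVA on RT with factors global-level
    lexicality, local-level lexicality, and task."""
    factors = ["global_lex", "local_lex", "task"]
    levels = [("w", "n"), ("w", "n"), ("global", "local")]
    M, subjects = _cell_mean_tensor(t.df, factors, levels)
    effects = rm_anova_factorial(M, tuple(factors))
    cm = (t.df.groupby(factors)["rt_ms"].mean().rename("mean_rt_ms")
          .reset_index())
    return AnovaResult(effects=effects, cell_means=cm,
                       n_subjects=len(subjects))


def planned_contrasts(t: TrialTable,
                      contrasts=DEFAULT_CONTRASTS) -> list[ContrastResult]:
    """Paired t-tests on subject cell means for the planned comparisons."""
    df = t.df
    out = []
    for name, cell_a, cell_b, task in contrasts:
        res = []
        for cell in (cell_a, cell_b):
            sub = df[(df["global_lex"] == cell[0])
                     & (df["local_lex"] == cell[1]) & (df["task"] == task)]
            if sub.empty:
                raise ValueError(f"contrast {name!r}: no trials in cell "
                                 f"{cell} / task {task!r}")
            res.append(sub.groupby("subject")["rt_ms"].mean())
        a, b = res[0].align(res[1], join="inner")
        if len(a) < 2:
            raise ValueError(f"contrast {name!r}: needs >= 2 subjects with "
                             "both cells")
        diffs = (a - b).to_numpy()
        n = diffs.size
        mean = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        if sd == 0:
            tval, p = (0.0, 1.0) if mean == 0 else (np.inf * np.sign(mean), 0.0)
        else:
            tval = mean / (sd / np.sqrt(n))
            p = float(2.0 * stats.t.sf(abs(tval), df=n - 1))
        out.append(ContrastResult(name=name, mean_diff_ms=mean, t=float(tval),
                                  df=n - 1, p=p))
    return out


def underline_position_anova(t: TrialTable) -> AnovaResult:
    """Control analysis on local-task trials only: global-level lexicality x
    local-level lexicality x underline position (first vs last pair)."""
    local = t.df[t.df["task"] == "local"]
    if local.empty:
        raise ValueError("no local-task trials: underline-position ANOVA "
                         "needs two-character-underline trials")
    factors = ["global_lex", "local_lex", "underline_pos"]
    levels = [("w", "n"), ("w", "n"), ("first", "last")]
    M, subjects = _cell_mean_tensor(local, factors, levels)
    effects = rm_anova_factorial(M, tuple(factors))
    cm = (local.groupby(factors)["rt_ms"].mean().rename("mean_rt_ms")
          .reset_index())
    return AnovaResult(effects=effects, cell_means=cm,
                       n_subjects=len(subjects))
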