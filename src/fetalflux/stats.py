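"""Statistical layer: normality, mixed repeated-measures ANOVA, pairwise tests.

The study design is a split plot: group (control vs FGR) varies between
subjects, oxygenation state (normoxia vs acute hypoxia) within subjects.
The ANOVA therefore uses two error strata:

* between stratum — the group effect is tested on per-subject means against
  subjects-within-group variability;
* within stratum — state and group x state are tested against the
  state x subject-within-group residual.

With unequal group sizes (12 vs 9) the within-stratum sums of squares are
Type III (partial) SS, computed by effect-coded model comparison, so each
effect is adjusted for the others; with a single between factor the
between-stratum SS is unaffected by the choice of SS type.  State has two
levels, so no sphericity correction is needed (epsilon is identically 1).

Pairwise comparisons are fixed to the four cell contrasts the design
implies: group within each state (unpaired pooled-variance t) and state
within each group (paired t), Bonferroni-corrected with m = 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

__all__ = [
    "AnovaResult", "PairwiseComparison", "shapiro_wilk", "mixed_anova",
    "mixed_anova_cells", "unpaired_t_test", "paired_t_test", "bonferroni",
    "pairwise_cell_comparisons",
]


@dataclass
class PairwiseComparison:
    comparison: str
    p_raw: float
    p_adjusted: float
    significant: bool
    statistic: float = np.nan


@dataclass
class AnovaResult:
    f_group: float
    f_state: float
    f_interaction: float
    df_group: tuple[int, int]
    df_state: tuple[int, int]
    df_interaction: tuple[int, int]
    p_group: float
    p_state: float
    p_interaction: float
    ss: Dict[str, float] = field(default_factory=dict)
    pairwise: List[PairwiseComparison] = field(default_factory=list)


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation, via scipy)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("sample is constant")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def unpaired_t_test(a: Sequence[float], b: Sequence[float],
                    ) -> tuple[float, int, float]:
    """Two-sided pooled-variance (Student) unpaired t-test: (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs n >= 2")
    df = len(a) + len(b) - 2
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValidationError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def paired_t_test(a: Sequence[float], b: Sequence[float],
                  ) -> tuple[float, int, float]:
    """Two-sided paired t-test on matched samples: (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValidationError("paired test needs matched samples, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    df = len(d) - 1
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        raise ValidationError("zero variance of differences with nonzero mean")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def bonferroni(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m < len(p):
        raise ValidationError("m must cover the number of p-values")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

def _effect_codes(n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding matrix, n_levels x (n_levels - 1)."""
    codes = np.eye(n_levels, n_levels - 1)
    codes[-1, :] = -1.0
    return codes


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def mixed_anova_cells(y_by_group: Sequence[np.ndarray]) -> AnovaResult:
    """Split-plot ANOVA from per-group (n_j, b) response matrices.

    Row i of ``y_by_group[j]`` holds subject i's responses across the b
    within-subject levels (complete data required).  This array form is the
    fast path used by the simulation studies; :func:`mixed_anova` wraps it
    for tidy tables.
    """
    y_by_group = [np.asarray(yj, dtype=float) for yj in y_by_group]
    a = len(y_by_group)
    if a < 2:
        raise ValidationError("need at least two groups")
    b = y_by_group[0].shape[1]
    if b < 2:
        raise ValidationError("need at least two within-subject levels")
    n_j = np.array([yj.shape[0] for yj in y_by_group])
    if np.any(n_j < 2):
        raise ValidationError("need at least two subjects per group")
    N = int(n_j.sum())

    Y = np.vstack(y_by_group)                      # (N, b)
    g = np.repeat(np.arange(a), n_j)               # group index per subject

    # --- between stratum: ANOVA on subject means, scaled by b
    S = Y.mean(axis=1)
    G = np.array([S[g == j].mean() for j in range(a)])
    W = S.mean()
    ss_group = b * float(np.sum(n_j * (G - W) ** 2))
    ss_subj = b * float(sum(np.sum((S[g == j] - G[j]) ** 2) for j in range(a)))
    df_group, df_subj = a - 1, N - a
    if df_subj == 0:
        raise ValidationError("zero error degrees of freedom (between stratum)")

    # --- within stratum error: state x subject-within-group residual
    M = np.array([y_by_group[j].mean(axis=0) for j in range(a)])   # cell means
    resid = Y - S[:, None] - M[g] + M[g].mean(axis=1)[:, None]
    ss_err_within = float(np.sum(resid**2))
    df_err_within = (N - a) * (b - 1)
    if df_err_within == 0:
        raise ValidationError("zero error degrees of freedom (within stratum)")

    # --- Type III SS for state and interaction via effect-coded OLS
    gc = _effect_codes(a)[g]                       # (N, a-1)
    sc = _effect_codes(b)                          # (b, b-1)
    rows_g = np.repeat(gc, b, axis=0)              # flatten subject-major
    rows_s = np.tile(sc, (N, 1))
    inter = rows_g[:, :, None] * rows_s[:, None, :]
    inter = inter.reshape(N * b, (a - 1) * (b - 1))
    ones = np.ones((N * b, 1))
    yf = Y.ravel()

    X_full = np.hstack([ones, rows_g, rows_s, inter])
    rss_full = _rss(X_full, yf)
    ss_state = _rss(np.hstack([ones, rows_g, inter]), yf) - rss_full
    ss_inter = _rss(np.hstack([ones, rows_g, rows_s]), yf) - rss_full
    df_state = b - 1
    df_inter = (a - 1) * (b - 1)

    ms_subj = ss_subj / df_subj
    ms_err = ss_err_within / df_err_within
    f_group = (ss_group / df_group) / ms_subj
    f_state = (ss_state / df_state) / ms_err
    f_inter = (ss_inter / df_inter) / ms_err

    return AnovaResult(
        f_group=f_group, f_state=f_state, f_interaction=f_inter,
        df_group=(df_group, df_subj), df_state=(df_state, df_err_within),
        df_interaction=(df_inter, df_err_within),
        p_group=float(sps.f.sf(f_group, df_group, df_subj)),
        p_state=float(sps.f.sf(f_state, df_state, df_err_within)),
        p_interaction=float(sps.f.sf(f_inter, df_inter, df_err_within)),
        ss={"group": ss_group, "subjects_within_group": ss_subj,
            "state": ss_state, "interaction": ss_inter,
            "error_within": ss_err_within},
    )


def mixed_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                between: str = "group", within: str = "state",
                pairwise: bool = True, alpha: float = 0.05) -> AnovaResult:
    """Mixed two-way repeated-measures ANOVA on a tidy table.

    ``data`` needs one row per subject x within-level with columns for the
    subject id, the between-group label, the within-state label and the
    response.  Every subject must appear at every within level.
    """
    wide = data.pivot_table(index=[between, subject], columns=within,
                            values=dv, aggfunc="mean")
    wide = wide[list(dict.fromkeys(data[within]))]   # keep data order
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        sid = incomplete[0][1]
        raise ValidationError(f"subject {sid!r} is missing a {within} level")

    groups = list(dict.fromkeys(data[between]))
    y_by_group = [wide.loc[grp].to_numpy() for grp in groups]
    result = mixed_anova_cells(y_by_group)

    if pairwise and len(groups) == 2 and wide.shape[1] == 2:
        states = list(wide.columns)
        result.pairwise = pairwise_cell_comparisons(
            {(grp, st): wide.loc[grp, st].to_numpy()
             for grp in groups for st in states},
            groups=groups, states=states, alpha=alpha)
    return result


def pairwise_cell_comparisons(cells: Dict[tuple, np.ndarray], groups: list,
                              states: list, alpha: float = 0.05,
                              ) -> List[PairwiseComparison]:
    """The four Bonferroni-corrected cell contrasts of the 2x2 design."""
    raw: List[tuple[str, float, float]] = []
    for st in states:
        t, _, p = unpaired_t_test(cells[(groups[0], st)], cells[(groups[1], st)])
        raw.append((f"{groups[0]} vs {groups[1]} @ {st}", t, p))
    for grp in groups:
        t, _, p = paired_t_test(cells[(grp, states[0])], cells[(grp, states[1])])
        raw.append((f"{states[0]} vs {states[1]} @ {grp}", t, p))
    m = len(raw)
    adj = bonferroni([p for _, _, p in raw], m)
    return [PairwiseComparison(comparison=name, p_raw=p, p_adjusted=float(pa),
                               significant=bool(pa < alpha), statistic=t)
            for (name, t, p), pa in zip(raw, adj)]
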