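"""Shared test utilities: independent oracles and dataset builders."""

from __future__ import annotations

import numpy as np
import pandas as pd


def split_plot_ss_oracle(y_by_group) -> dict:
    """Brute-force split-plot sums of squares, independent of the package.

    Between stratum: one-way ANOVA on per-subject means (times the number of
    within levels).  Within stratum: project each subject onto an orthonormal
    within-contrast basis and accumulate, per contrast variable, the partial
    (Type III) SS of the intercept (state effect), of the group factor
    (interaction) and the full-model residual (within error).
    """
    y_by_group = [np.asarray(y, float) for y in y_by_group]
    a = len(y_by_group)
    b = y_by_group[0].shape[1]
    n = [y.shape[0] for y in y_by_group]
    N = sum(n)

    S = [y.mean(axis=1) for y in y_by_group]
    G = [s.mean() for s in S]
    W = sum(s.sum() for s in S) / N
    ss_group = b * sum(nj * (gj - W) ** 2 for nj, gj in zip(n, G))
    ss_subj = b * sum(((s - g) ** 2).sum() for s, g in zip(S, G))

    # orthonormal contrasts spanning the within-subject space
    C = np.linalg.qr(np.hstack([np.ones((b, 1)), np.eye(b)[:, :b - 1]]))[0][:, 1:]
    gc = np.eye(a, a - 1)
    gc[-1, :] = -1.0
    X_group = np.vstack([np.tile(gc[j], (n[j], 1)) for j in range(a)])

    ss_state = ss_inter = ss_err = 0.0
    for c in C.T:
        d = [y @ c for y in y_by_group]
        dd = np.concatenate(d)
        rss_full = sum(((x - x.mean()) ** 2).sum() for x in d)
        beta, *_ = np.linalg.lstsq(X_group, dd, rcond=None)
        rss_no_intercept = ((dd - X_group @ beta) ** 2).sum()
        rss_no_group = ((dd - dd.mean()) ** 2).sum()
        ss_state += rss_no_intercept - rss_full
        ss_inter += rss_no_group - rss_full
        ss_err += rss_full
    return dict(group=ss_group, subjects_within_group=ss_subj,
                state=ss_state, interaction=ss_inter, error_within=ss_err)


def tidy_from_cells(y_by_group, groups=("control", "FGR"),
                    states=("normoxia", "hypoxia")) -> pd.DataFrame:
    """Tidy subject x group x state x value table from per-group matrices."""
    rows = []
    for grp, y in zip(groups, y_by_group):
        for i, subj in enumerate(np.asarray(y, float)):
            for st, v in zip(states, subj):
                rows.append(dict(subject=f"{grp}{i}", group=grp, state=st,
                                 value=float(v)))
    return pd.DataFrame(rows)


def anova_test_cohort(seed: int, n1: int = 12, n2: int = 9) -> pd.DataFrame:
    """The reference dataset used for cross-implementation ANOVA checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for j, (grp, n) in enumerate([("control", n1), ("FGR", n2)]):
        for i in range(n):
            sid = f"{grp}{i}"
            base = rng.normal(0, 1)
            for k, st in enumerate(["normoxia", "hypoxia"]):
                rows.append(dict(subject=sid, group=grp, state=st,
                                 value=base + 0.5 * j + 0.8 * k + 0.4 * j * k
                                 + rng.normal(0, 1)))
    return pd.DataFrame(rows)
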