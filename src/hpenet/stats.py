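"""Inferential layer: paired contrasts and repeated-measures correlation.

The best-vs-worst contrasts use a paired two-tailed t-test with Cohen's d on
the paired differences; association between per-minute HPE and performance
across a cohort uses the repeated-measures correlation (rmcorr), the common
within-subject slope from an ANCOVA with subject as a factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cte import BinaryAdjacency

__all__ = [
    "PairedContrast",
    "RmcorrResult",
    "paired_ttest",
    "rmcorr",
    "link_count_contrast",
]


@dataclass
class PairedContrast:
    t: float
    p: float
    d: float
    n: int
    mean_diff: float
    d_convention: str = "diff_sd"


@dataclass
class RmcorrResult:
    r: float
    p: float
    df: int
    n_subjects: int
    dropped_subjects: tuple = ()


def paired_ttest(a, b, d_convention: str = "diff_sd") -> PairedContrast:
    """Paired two-tailed t-test of a vs b with Cohen's d.

    ``d_convention="diff_sd"`` (default): d = mean(diff) / sd(diff), the
    convention matching a paired design; ``"avg_sd"`` divides by the pooled
    within-condition SD instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D vectors of equal length")
    if len(a) < 2:
        raise ValueError("at least two pairs are required")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("no variance in the paired differences; t-test undefined")
    t, p = sps.ttest_rel(a, b)
    if d_convention == "diff_sd":
        d = diff.mean() / sd
    elif d_convention == "avg_sd":
        d = diff.mean() / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    else:
        raise ValueError(f"unknown Cohen's d convention {d_convention!r}")
    return PairedContrast(
        t=float(t), p=float(p), d=float(d), n=len(a),
        mean_diff=float(diff.mean()), d_convention=d_convention,
    )


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Repeated-measures correlation (common within-subject association).

    Centres x and y within each subject (removing between-subject level
    differences — the ANCOVA subject factor) and correlates the residuals;
    R = S_xy / sqrt(S_xx S_yy) on the centred data, with degrees of freedom
    df = n_obs - n_subjects - 1 and the p-value from F(1, df).  Subjects
    with constant x contribute nothing to the slope and are dropped with a
    warning.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subjects.shape == x.shape == y.shape):
        raise ValueError("subjects, x and y must be aligned 1-D vectors")
    uniq = list(dict.fromkeys(subjects.tolist()))
    keep = np.ones(len(x), dtype=bool)
    dropped = []
    for s in uniq:
        m = subjects == s
        if m.sum() < 2 or np.ptp(x[m]) == 0:
            keep &= ~m
            dropped.append(s)
    if dropped:
        warnings.warn(
            f"dropping subjects with constant or singleton x: {dropped}", stacklevel=2
        )
    subjects, x, y = subjects[keep], x[keep], y[keep]
    uniq = list(dict.fromkeys(subjects.tolist()))
    if len(uniq) < 2:
        raise ValueError("rmcorr needs at least two usable subjects")
    xc = x.copy()
    yc = y.copy()
    for s in uniq:
        m = subjects == s
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    s_xx = float(xc @ xc)
    s_yy = float(yc @ yc)
    s_xy = float(xc @ yc)
    if s_yy == 0:
        raise ValueError("y has no within-subject variance")
    r = s_xy / np.sqrt(s_xx * s_yy)
    df = len(x) - len(uniq) - 1
    if df < 1:
        raise ValueError("not enough observations for the rmcorr F test")
    r2 = min(r * r, 1.0 - 1e-15)
    f = r2 * df / (1.0 - r2)
    p = float(sps.f.sf(f, 1, df))
    return RmcorrResult(
        r=float(r), p=p, df=df, n_subjects=len(uniq), dropped_subjects=tuple(dropped)
    )


def link_count_contrast(
    best: list[BinaryAdjacency | int], worst: list[BinaryAdjacency | int]
) -> PairedContrast:
    """Paired t-test on per-subject edge counts at the best vs worst frame."""
    def count(g):
        return g.n_edges if isinstance(g, BinaryAdjacency) else int(g)

    return paired_ttest([count(g) for g in best], [count(g) for g in worst])
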