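"""Within-subject inference: repeated-measures ANOVA, paired t-tests, and
false-discovery-rate correction.

The repeated-measures ANOVA handles fully crossed within-subject designs
with one observation per cell per subject and one to three factors. Sums
of squares follow the classical uncorrected-sums-of-squares partitioning:
for every effect (subset of factors) the error term is that effect's
interaction with subjects, ``F = MS_effect / MS_(effect x subject)``.
The implementation is hand-verifiable (plain marginal totals and
inclusion-exclusion) so the whole pipeline can be tested end-to-end;
an external library serves as a cross-check in the test suite only.

Greenhouse-Geisser sphericity correction is available per effect but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def _subsets(items):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def _uncorrected_ss(df: pd.DataFrame, value: str, by: tuple) -> float:
    """T-term: sum over cells of ``by`` of (cell total)^2 / cell size."""
    if not by:
        tot = df[value].sum()
        return tot**2 / len(df)
    g = df.groupby(list(by), observed=True)[value]
    return float((g.sum() ** 2 / g.size()).sum())


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             correction: bool = False) -> pd.DataFrame:
    """Repeated-measures ANOVA for 1-3 within-subject factors.

    Parameters
    ----------
    data : long-format DataFrame
        One row per (subject, cell); exactly one value per cell.
    dv : str
        Dependent-variable column.
    within : str or sequence of str
        Within-subject factor column(s).
    subject : str
        Subject-id column.
    correction : bool
        Apply the Greenhouse-Geisser sphericity correction to each
        effect's p-value (reported in ``p_gg``/``eps`` columns).

    Returns
    -------
    DataFrame with one row per effect (main effects and all
    interactions): sums of squares, dfs, F and p. Effects with zero sum
    of squares report F = 0, p = 1.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("rm_anova supports 1-3 within-subject factors")
    cols = [subject] + within
    df = data[cols + [dv]].copy()

    levels = {f: sorted(df[f].unique()) for f in within}
    subjects = sorted(df[subject].unique())
    expected = len(subjects) * int(np.prod([len(levels[f]) for f in within]))
    counts = df.groupby(cols, observed=True).size()
    if len(counts) != expected or (counts != 1).any():
        full = pd.MultiIndex.from_product(
            [subjects] + [levels[f] for f in within], names=cols)
        missing = full.difference(counts.index)
        raise ValueError(
            f"design not fully crossed with one value per cell; "
            f"missing/duplicated cells include: {list(missing[:10])}"
        )

    T = {by: _uncorrected_ss(df, dv, by)
         for by in _subsets(cols)}

    def ss(effect: tuple) -> float:
        return sum((-1) ** (len(effect) - len(s)) * T[s] for s in _subsets(effect))

    n_s = len(subjects)
    rows = []
    effects = [e for e in _subsets(tuple(within)) if e]
    for eff in effects:
        ss_eff = ss(eff)
        ss_err = ss(tuple([subject]) + eff)
        df_eff = int(np.prod([len(levels[f]) - 1 for f in eff]))
        df_err = df_eff * (n_s - 1)
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if ss_eff <= 1e-12 * max(T[()], 1.0):
            F, p = 0.0, 1.0
        elif ms_err == 0 or not np.isfinite(ms_err):
            F, p = np.inf, 0.0
        else:
            F = ms_eff / ms_err
            p = float(sps.f.sf(F, df_eff, df_err))
        row = dict(effect=" * ".join(eff), ss=ss_eff, ss_error=ss_err,
                   df=df_eff, df_error=df_err, F=F, p=p)
        if correction:
            eps = _gg_epsilon(df, dv, list(eff), subject, levels)
            row["eps"] = eps
            row["p_gg"] = (1.0 if F == 0 else
                           float(sps.f.sf(F, df_eff * eps, df_err * eps)))
        rows.append(row)
    return pd.DataFrame(rows)


def _gg_epsilon(df, dv, effect, subject, levels) -> float:
    """Greenhouse-Geisser epsilon from the subject x cell covariance of
    the effect's cell means (averaged over other factors)."""
    wide = (df.groupby([subject] + effect, observed=True)[dv].mean()
              .unstack(effect))
    S = np.cov(wide.to_numpy(), rowvar=False)
    k = S.shape[0]
    if k < 2:
        return 1.0
    mean_all = S.mean()
    mean_diag = np.diag(S).mean()
    row_means = S.mean(axis=0)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def paired_t(a, b) -> PairedTResult:
    """Paired t-test on matched samples (df = n - 1).

    Zero-variance, nonzero-mean differences are degenerate: t is signed
    infinity with p = 0 and the ``degenerate`` flag set. Identical
    samples give t = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0)
        return PairedTResult(t=float(np.sign(d.mean()) * np.inf), df=n - 1,
                             p=0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
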