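"""AP-MS spectral-count interactor scoring.

The pipeline order is fixed: keep preys quantified in enough replicates,
impute missing (zero) spectral counts from the low-abundance tail,
normalize each run by its bait spectral count, then test.  High-confidence
interactors versus the empty-vector control require p < 0.05 and a
bait/control spectral-count ratio > 1.5.  Differential interaction between
two bait variants uses a two-tailed t-statistic stabilized by an additive
zero-correction constant (0.1, a Perseus-s0-style softener) in the
denominator, BH-adjusted, and calls significance at FDR < 0.05 with a mean
fold change beyond ±2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from pausekit.stats import bh_fdr

__all__ = [
    "impute_zeros",
    "bait_normalize",
    "keep_quantified",
    "call_interactors",
    "compare_baits",
]


def impute_zeros(
    matrix: pd.DataFrame, rng: np.random.Generator, tail_fraction: float = 0.2
) -> pd.DataFrame:
    """Replace zero spectral counts by draws from the low-abundance tail.

    The pool is the lowest ``tail_fraction`` (20%) of the nonzero values in
    the matrix; zeros are replaced by Normal(mean, sd) draws from that pool,
    truncated at 0 by rejection (counts cannot be negative).  Nonzero
    entries are untouched.  Needs at least 5 nonzero values.
    """
    values = matrix.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size < 5:
        raise ValueError("need at least 5 nonzero spectral counts to impute")
    k = max(1, int(np.ceil(tail_fraction * nonzero.size)))
    pool = np.sort(nonzero)[:k]
    mean, sd = float(pool.mean()), float(pool.std(ddof=0))
    out = values.copy()
    zero_idx = np.argwhere(values == 0)
    n = len(zero_idx)
    if n:
        draws = np.empty(n)
        filled = 0
        while filled < n:
            batch = rng.normal(mean, sd, size=(n - filled) * 2 + 8)
            batch = batch[batch > 0]
            take = min(len(batch), n - filled)
            draws[filled : filled + take] = batch[:take]
            filled += take
        out[zero_idx[:, 0], zero_idx[:, 1]] = draws
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def bait_normalize(matrix: pd.DataFrame, bait: str) -> pd.DataFrame:
    """Divide every prey count by that run's bait count (bait row becomes 1)."""
    if bait not in matrix.index:
        raise KeyError(f"bait {bait!r} not in matrix")
    bait_counts = matrix.loc[bait]
    zero_runs = list(bait_counts.index[bait_counts <= 0])
    if zero_runs:
        raise ValueError(f"bait count is zero in runs {zero_runs}")
    return matrix.div(bait_counts, axis=1)


def keep_quantified(
    cond_a: pd.DataFrame, cond_b: pd.DataFrame, min_runs: int = 3
) -> pd.Index:
    """Preys quantified (nonzero) in at least ``min_runs`` runs of either condition."""
    ok = ((cond_a > 0).sum(axis=1) >= min_runs) | ((cond_b > 0).sum(axis=1) >= min_runs)
    return cond_a.index[ok]


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-tailed pooled t-test with an additive s0 stabilizer."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    t = (ma - mb) / (se + s0)
    df = na + nb - 2
    p = 2 * sps.t.sf(np.abs(t), df=df)
    return t, p


def call_interactors(
    bait_runs: pd.DataFrame,
    control_runs: pd.DataFrame,
    p_threshold: float = 0.05,
    ratio_threshold: float = 1.5,
) -> pd.DataFrame:
    """Score preys against the empty-vector control.

    Per prey: two-tailed t-test of normalized counts and the ratio of mean
    bait to mean control signal.  High confidence requires p below the
    threshold AND ratio above 1.5.
    """
    if bait_runs.shape[1] < 3 or control_runs.shape[1] < 3:
        raise ValueError("need at least 3 replicates per condition")
    common = bait_runs.index.intersection(control_runs.index)
    a = bait_runs.loc[common].to_numpy(dtype=float)
    b = control_runs.loc[common].to_numpy(dtype=float)
    _, p = _two_sample_t(a, b)
    with np.errstate(divide="ignore"):
        ratio = a.mean(axis=1) / b.mean(axis=1)
    return pd.DataFrame(
        {
            "p": p,
            "ratio": ratio,
            "high_confidence": (p < p_threshold) & (ratio > ratio_threshold),
        },
        index=common,
    )


def compare_baits(
    wt_runs: pd.DataFrame,
    mutant_runs: pd.DataFrame,
    s0: float = 0.1,
    fdr: float = 0.05,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Differential interaction between two bait variants.

    The test runs on log2-transformed (imputed, bait-normalized) counts —
    the scale on which the additive zero-correction constant ``s0`` in the
    t denominator is meaningful — followed by BH FDR and a mean
    fold-change requirement beyond ±2.  ``fold`` is 2^(mean log2
    difference), i.e. the geometric-mean WT/mutant ratio.
    """
    if wt_runs.shape[1] < 3 or mutant_runs.shape[1] < 3:
        raise ValueError("need at least 3 replicates per condition")
    common = wt_runs.index.intersection(mutant_runs.index)
    a = wt_runs.loc[common].to_numpy(dtype=float)
    b = mutant_runs.loc[common].to_numpy(dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("compare_baits expects imputed (strictly positive) counts")
    la, lb = np.log2(a), np.log2(b)
    _, p = _two_sample_t(la, lb, s0=s0)
    q = bh_fdr(p)
    fold = 2.0 ** (la.mean(axis=1) - lb.mean(axis=1))
    beyond = (fold > fold_threshold) | (fold < 1.0 / fold_threshold)
    return pd.DataFrame(
        {"p": p, "fdr": q, "fold": fold, "significant": (q < fdr) & beyond},
        index=common,
    )
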