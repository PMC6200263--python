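"""Exact Wilcoxon signed-rank test, fully-within repeated-measures ANOVA with
Greenhouse-Geisser correction, and leave-one-out jackknife over subjects.

The Wilcoxon statistic V is the sum of ranks of positive differences; for
n <= 25 effective pairs the two-sided p-value is exact, computed by
enumerating the 2^n sign-assignment null via a rank-sum convolution
(mid-ranks under ties are handled exactly by doubling the ranks to
integers). Larger samples fall back to the tie-corrected normal
approximation with a warning.

The repeated-measures ANOVA handles any number of fully-crossed within-
subject factors on a balanced design. Each effect is tested against its own
effect-by-subject error term, constructed by projecting every subject's cell
vector onto orthonormal (Helmert) contrasts. Sphericity is never assumed:
the Greenhouse-Geisser epsilon is estimated from the covariance of the
contrast scores and corrected degrees of freedom and p-values are reported
alongside the uncorrected ones, together with partial eta squared.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .errors import InsufficientDataError

EXACT_LIMIT = 25


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test result: V, two-sided p, effective n, p-value method."""

    V: float
    p_two_sided: float
    n_effective: int
    method: str  # "exact" | "normal-approx"


def _exact_signed_rank_p(ranks: np.ndarray, v: float) -> float:
    """Two-sided exact p under the 2^n sign-assignment null (mid-ranks OK)."""
    r2 = np.rint(2.0 * ranks).astype(np.int64)  # mid-ranks are multiples of 1/2
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    v2 = int(np.rint(2.0 * v))
    cdf = counts[: v2 + 1].sum()
    sf = counts[v2:].sum()  # inclusive upper tail
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_exact(x, y=None, *, exact_limit: int = EXACT_LIMIT) -> WilcoxonResult:
    """Wilcoxon signed-rank test of paired samples (or one sample about 0).

    Zero differences are dropped (standard convention). V is the sum of the
    mid-ranks of the positive differences of ``x - y``.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise InsufficientDataError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if n <= exact_limit:
        p = _exact_signed_rank_p(ranks, v)
        return WilcoxonResult(V=v, p_two_sided=p, n_effective=n, method="exact")

    warnings.warn(
        f"n={n} exceeds the exact enumeration limit ({exact_limit}); "
        "using the normal approximation",
        stacklevel=2,
    )
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if has_ties:
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (v - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(V=v, p_two_sided=p, n_effective=n, method="normal-approx")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, all orthogonal to the unit vector."""
    return linalg.helmert(k, full=False)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
    *,
    effects: list[tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Fully-within repeated-measures ANOVA on a balanced long-format table.

    Parameters
    ----------
    data : long table with one or more observations per subject x cell
        (duplicates are averaged first).
    dv : dependent-variable column.
    within : within-subject factor columns, fully crossed.
    subject : subject-id column.
    effects : optional subset of effects to report (tuples of factor names);
        default is every main effect and interaction.

    Returns a table with, per effect: sums of squares, F, dfs, p, partial eta
    squared, the Greenhouse-Geisser epsilon and GG-corrected dfs/p. Missing
    subject cells are imputed by the cell mean over the remaining subjects,
    with a warning.
    """
    if not within:
        raise ValueError("need at least one within-subject factor")
    levels = {f: sorted(pd.unique(data[f].astype(str))) for f in within}
    wide = data.pivot_table(
        index=subject,
        columns=within,
        values=dv,
        aggfunc="mean",
        observed=True,
    )
    full_cols = (
        pd.MultiIndex.from_product([levels[f] for f in within], names=within)
        if len(within) > 1
        else pd.Index(levels[within[0]], name=within[0])
    )
    wide = wide.reindex(columns=full_cols)
    if wide.isna().all(axis=0).any():
        raise InsufficientDataError("a design cell is empty for every subject")
    if wide.isna().any().any():
        n_missing = int(wide.isna().sum().sum())
        warnings.warn(
            f"{n_missing} missing subject cells imputed by the cell mean",
            stacklevel=2,
        )
        wide = wide.fillna(wide.mean(axis=0))
    n_subjects = wide.shape[0]
    if n_subjects < 3:
        raise InsufficientDataError(f"need >= 3 subjects, got {n_subjects}")

    X = wide.to_numpy(dtype=float)  # (n, prod(k_f)), kron-ordered like the columns
    ks = [len(levels[f]) for f in within]
    contrasts = {f: _orthonormal_contrasts(k) for f, k in zip(within, ks)}
    means = {f: np.full((1, k), 1.0 / np.sqrt(k)) for f, k in zip(within, ks)}

    if effects is None:
        effects = [
            combo
            for r in range(1, len(within) + 1)
            for combo in itertools.combinations(within, r)
        ]

    rows = []
    for effect in effects:
        M = np.ones((1, 1))
        for f in within:
            M = np.kron(M, contrasts[f] if f in effect else means[f])
        T = X @ M.T  # (n_subjects, q) contrast scores
        q = T.shape[1]
        tbar = T.mean(axis=0)
        ss_effect = float(n_subjects * (tbar**2).sum())
        ss_error = float(((T - tbar) ** 2).sum())
        df1 = q
        df2 = (n_subjects - 1) * q

        # rounding floor: constant data must give 0, not 0/0
        tiny = 1e-12 * max(1.0, float((X**2).sum()))
        if ss_effect < tiny:
            ss_effect = 0.0
        if ss_error < tiny:
            ss_error = 0.0

        if ss_error > 0:
            F = (ss_effect / df1) / (ss_error / df2)
            p = float(sps.f.sf(F, df1, df2))
        elif ss_effect == 0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
        pes = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0

        if q == 1:
            eps = 1.0
        else:
            sigma = np.cov(T, rowvar=False)
            denom = q * float((sigma * sigma.T).sum())
            eps = float(np.trace(sigma) ** 2 / denom) if denom > 0 else 1.0
            eps = float(np.clip(eps, 1.0 / q, 1.0))
        df1_gg, df2_gg = eps * df1, eps * df2
        if np.isfinite(F):
            p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if F > 0 else 1.0
        else:
            p_gg = 0.0

        rows.append(
            {
                "effect": ":".join(effect),
                "ss": ss_effect,
                "ss_error": ss_error,
                "df_num": df1,
                "df_den": df2,
                "F": F,
                "p": p,
                "pes": pes,
                "eps_gg": eps,
                "df_num_gg": df1_gg,
                "df_den_gg": df2_gg,
                "p_gg": p_gg,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeRun:
    left_out: str
    result: object | None
    error: str | None = None


@dataclass
class JackknifeReport:
    runs: list[JackknifeRun]
    significance: list[bool | None]

    @property
    def n_resamples(self) -> int:
        return len(self.runs)

    @property
    def consistent(self) -> bool:
        """True iff the effect is present (significant) in every resample."""
        return all(s is True for s in self.significance)


def jackknife(
    data: pd.DataFrame,
    subject: str,
    analysis: Callable[[pd.DataFrame], object],
    *,
    significance: Callable[[object], bool] | None = None,
) -> JackknifeReport:
    """Run ``analysis`` on every leave-one-subject-out resample.

    Analysis failures on individual resamples are recorded, not fatal. When
    ``significance`` is given, each successful result is reduced to a boolean
    and the report carries an all-resamples consistency verdict.
    """
    subjects = sorted(pd.unique(data[subject].astype(str)))
    if len(subjects) < 3:
        raise InsufficientDataError(f"need >= 3 subjects, got {len(subjects)}")
    runs: list[JackknifeRun] = []
    flags: list[bool | None] = []
    for left_out in subjects:
        subset = data[data[subject].astype(str) != left_out]
        try:
            result = analysis(subset)
        except Exception as exc:  # noqa: BLE001 - resample failures are data
            runs.append(JackknifeRun(left_out, None, error=repr(exc)))
            flags.append(None)
            continue
        runs.append(JackknifeRun(left_out, result))
        flags.append(bool(significance(result)) if significance is not None else None)
    return JackknifeReport(runs=runs, significance=flags)
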