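"""Inferential statistics: Spearman correlations with Benjamini-Hochberg
correction, Welch's t-test (from raw vectors or printed summary values),
the Freeman-Halton exact test for r x c contingency tables, and the
median split used to form high/low polygenic-score subgroups.

The exact r x c test uses the probability-ordering ("at least as extreme
by table probability") convention, which specializes to the usual
two-sided Fisher exact test for 2 x 2 tables.  Spearman p-values are
exact by full permutation enumeration for 3 < n <= 10 and use the
t-approximation above that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EnumerationCapError, ValidationError

EXACT_SPEARMAN_MAX_N = 10


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str
    flagged: bool = False


def spearman(x, y, *, method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  ``method`` is ``'exact'`` (full
    enumeration over all n! pairings), ``'t'`` (t approximation on n - 2
    df), or ``'auto'`` (exact for 3 < n <= 10, t above).  Zero variance
    in either vector leaves rho undefined and flags the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-D vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("x and y must be finite")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(np.nan, np.nan, n, "undefined", flagged=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "auto":
        method = "exact" if n <= EXACT_SPEARMAN_MAX_N else "t"
    if method == "exact":
        if n > EXACT_SPEARMAN_MAX_N:
            raise ValidationError(f"exact enumeration limited to n <= {EXACT_SPEARMAN_MAX_N}")
        p = _exact_spearman_p(rx, ry, rho)
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    else:
        raise ValidationError(f"unknown spearman method {method!r}")
    return CorrelationResult(rho, min(p, 1.0), n, method)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p over all n! pairings of the (tied) rank vectors."""
    n = rx.size
    mx, my = rx.mean(), ry.mean()
    sx = rx.std()
    sy = ry.std()
    count = 0
    total = 0
    chunk = []
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _count_extreme(np.array(chunk), rx, mx, my, sx, sy, target)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(np.array(chunk), rx, mx, my, sx, sy, target)
        total += len(chunk)
    return count / total


def _count_extreme(perms, rx, mx, my, sx, sy, target) -> int:
    rhos = (perms @ rx / rx.size - mx * my) / (sx * sy)
    return int((np.abs(rhos) >= target).sum())


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Step-up BH adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-values must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    flagged: bool = False


def welch_t(n1: int, mean1: float, sd1: float,
            n2: int, mean2: float, sd2: float) -> WelchResult:
    """Welch's unequal-variance t-test from summary statistics.

    Works directly off printed group sizes, means and SDs (as in a
    demographics table), so reported p-values can be recomputed without
    the raw data.  Both variances zero with equal means returns p = 1 by
    convention, flagged.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, flagged=True)
        return WelchResult(np.inf if mean1 > mean2 else -np.inf,
                           float(n1 + n2 - 2), 0.0, flagged=True)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


def welch_t_raw(x, y) -> WelchResult:
    """Welch's t-test from raw vectors (summarized with ddof=1 SDs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t(x.size, x.mean(), x.std(ddof=1), y.size, y.mean(), y.std(ddof=1))


# ---------------------------------------------------------------------------
# Freeman-Halton exact test
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, lg_margin_const: float) -> float:
    return lg_margin_const - sum(lgamma(v + 1.0) for v in table.ravel())


def _enumerate_tables(row_sums, col_sums, cap):
    """Yield all non-negative integer tables with the given margins."""
    R, C = len(row_sums), len(col_sums)
    table = np.zeros((R, C), dtype=int)
    count = 0

    def rec(r, remaining_cols):
        nonlocal count
        if r == R - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all() and last.sum() == row_sums[r]:
                table[r] = last
                count += 1
                if count > cap:
                    raise EnumerationCapError(
                        f"more than {cap:.0f} tables with these margins; "
                        "use method='mc'")
                yield table
            return
        target = row_sums[r]

        def fill(c, left, rem):
            if c == C - 1:
                if 0 <= left <= rem[c]:
                    table[r, c] = left
                    new_rem = [rem[k] - table[r, k] for k in range(C)]
                    yield from rec(r + 1, new_rem)
                return
            for v in range(min(left, rem[c]) + 1):
                table[r, c] = v
                yield from fill(c + 1, left - v, rem)

        yield from fill(0, target, remaining_cols)

    yield from rec(0, list(col_sums))


def exact_rxc(table, *, cap: float = 1e7, method: str = "exact",
              n_mc: int = 100_000, seed: int = 0) -> float:
    """Freeman-Halton exact test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    (multivariate hypergeometric) probabilities of tables whose
    probability does not exceed the observed table's, with a relative
    tie tolerance of 1e-12.  A zero margin makes the table degenerate
    and returns 1.  For 2 x 2 tables this is Fisher's two-sided exact
    test.  ``method='mc'`` estimates the same p by sampling tables under
    the margins (add-one Monte-Carlo estimate) when enumeration would
    exceed ``cap``.
    """
    t = np.asarray(table)
    if t.ndim != 2 or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("table must be a 2-D array of non-negative integers")
    if t.sum() < 1:
        raise ValidationError("table total must be at least 1")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        return 1.0
    n = int(t.sum())
    lg_const = (sum(lgamma(v + 1.0) for v in row_sums)
                + sum(lgamma(v + 1.0) for v in col_sums) - lgamma(n + 1.0))
    logp_obs = _log_table_prob(t, lg_const)

    if method == "mc":
        rng = np.random.default_rng(seed)
        row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
        col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(col_labels)
            sim = np.zeros_like(t)
            np.add.at(sim, (row_labels, perm), 1)
            if _log_table_prob(sim, lg_const) <= logp_obs + 1e-12:
                hits += 1
        return (hits + 1) / (n_mc + 1)

    total = 0.0
    for cand in _enumerate_tables(row_sums, col_sums, cap):
        lp = _log_table_prob(cand, lg_const)
        if lp <= logp_obs + 1e-12:
            total += np.exp(lp)
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(scores: pd.Series) -> pd.Series:
    """Label scores strictly above the median 'high', the rest 'low'.

    With odd n and distinct scores this puts the median patient in the
    low group, producing the (n-1)/2 vs (n+1)/2 split.  All-identical
    scores yield an all-'low' labelling (with a warning attribute).
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 2:
        raise ValidationError("median split needs at least 2 scores")
    med = s.median()
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index,
                       name="group")
    labels.attrs["all_identical"] = bool(s.nunique() == 1)
    return labels


# ---------------------------------------------------------------------------
# the study's correlation battery and demographics comparison
# ---------------------------------------------------------------------------

def run_association_battery(prs_scores: dict[str, pd.Series],
                            ars_table: pd.DataFrame,
                            clinical: pd.DataFrame, *,
                            family: str = "per-prs") -> pd.DataFrame:
    """Spearman correlations of each PRS against the three DIBS subscale
    severities and the three subscale ARS values, BH-corrected.

    ``prs_scores`` maps a score name (e.g. 'ADHD') to a per-patient
    Series; ``ars_table`` is the output of
    :func:`nddprs.ars.build_ars_table`; ``clinical`` supplies the
    ``dibs_<s>_max`` severities.  ``family`` chooses the BH family:
    ``'per-prs'`` adjusts the six tests of each PRS together (the
    per-panel presentation); ``'global'`` adjusts all tests as one
    family.  Patient id sets must agree across tables.  Cells with fewer
    than 3 complete pairs are flagged, not computed.
    """
    if family not in ("per-prs", "global"):
        raise ValidationError("family must be 'per-prs' or 'global'")
    ars_ids = set(ars_table["id"])
    clin_ids = set(clinical["id"])
    if ars_ids != clin_ids:
        raise ValidationError("patient ids differ between ARS and clinical tables")
    for name, s in prs_scores.items():
        if not ars_ids.issubset(set(s.index)):
            raise ValidationError(f"PRS table '{name}' is missing patients")

    targets = {f"dibs_{s}": clinical.set_index("id")[f"dibs_{s}_max"]
               for s in ("pos", "neg", "gen")}
    targets.update({f"ars_{s}": ars_table.set_index("id")[f"ars_{s}"]
                    for s in ("pos", "neg", "gen")})

    rows = []
    for prs_name, svec in prs_scores.items():
        for var_name, tvec in targets.items():
            joined = pd.concat([svec.rename("x"), tvec.rename("y")],
                               axis=1, join="inner").dropna()
            if len(joined) < 3:
                rows.append((prs_name, var_name, np.nan, np.nan, len(joined),
                             "insufficient-n", True))
                continue
            res = spearman(joined["x"], joined["y"],
                           method="t" if len(joined) > EXACT_SPEARMAN_MAX_N else "exact")
            rows.append((prs_name, var_name, res.rho, res.p, res.n,
                         res.method, res.flagged))
    out = pd.DataFrame(rows, columns=["prs", "variable", "rho", "p", "n",
                                      "method", "flagged"])
    out["p_adj"] = np.nan
    if family == "global":
        ok = out["p"].notna()
        if ok.any():
            out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
        out["family"] = "global"
    else:
        out["family"] = out["prs"]
        for prs_name in prs_scores:
            ok = (out["prs"] == prs_name) & out["p"].notna()
            if ok.any():
                out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def demographics_table(clinical: pd.DataFrame, groups: pd.Series, *,
                       continuous: tuple[str, ...] = ("age", "doi", "cpeq_3mo"),
                       ) -> pd.DataFrame:
    """Demographics comparison between the high/low subgroups.

    Sex is tested with the Freeman-Halton exact test; continuous
    variables (and the DIBS subscale severities) with Welch's t-test.
    Values are reported as mean +/- SD per group.
    """
    df = clinical.set_index("id").join(groups.rename("group"), how="inner")
    if df["group"].isna().any() or len(df) != len(clinical):
        raise ValidationError("group labels do not cover the clinical patients")
    hi = df[df["group"] == "high"]
    lo = df[df["group"] == "low"]
    rows = [("n", f"{len(hi)}", f"{len(lo)}", np.nan, "count")]
    if "sex" in df.columns:
        tab = pd.crosstab(df["sex"], df["group"]).reindex(columns=["high", "low"],
                                                          fill_value=0)
        p = exact_rxc(tab.to_numpy())
        rows.append(("sex", f"{(hi['sex'] == 'M').sum()}M/{(hi['sex'] == 'F').sum()}F",
                     f"{(lo['sex'] == 'M').sum()}M/{(lo['sex'] == 'F').sum()}F",
                     p, "freeman-halton"))
    cont = list(continuous) + [f"dibs_{s}_max" for s in ("pos", "neg", "gen")
                               if f"dibs_{s}_max" in df.columns]
    for var in cont:
        if var not in df.columns:
            continue
        res = welch_t_raw(hi[var].dropna(), lo[var].dropna())
        rows.append((var,
                     f"{hi[var].mean():.3g} ± {hi[var].std(ddof=1):.3g}",
                     f"{lo[var].mean():.3g} ± {lo[var].std(ddof=1):.3g}",
                     res.p, "welch"))
    return pd.DataFrame(rows, columns=["variable", "high", "low", "p", "test"])
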