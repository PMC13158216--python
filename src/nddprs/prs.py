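"""Clumping-and-thresholding polygenic risk scores.

Discovery summary statistics are harmonized to the target panel
(INFO >= 0.8; direct, swapped-allele and strand-complement matching, with
records still ambiguous after complementing dropped), greedily clumped on
target-sample LD (pairwise r^2 > 0.1 within a 200 kb window removes the
weaker variant), scored at p-value thresholds {0.01, 0.03, 0.05, 1.00},
and the working threshold is chosen as the one whose score explains the
most case/control variance (Nagelkerke pseudo-R^2 of a logistic fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import NddprsError, ValidationError
from .genio import GenotypeMatrix, complement_allele, is_ambiguous

DEFAULT_THRESHOLDS = (0.01, 0.03, 0.05, 1.00)


class EmptyOverlapError(NddprsError):
    """No summary-stat variant could be matched to the target panel."""


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(stats_df: pd.DataFrame, g: GenotypeMatrix, *,
              info_min: float = 0.8) -> tuple[pd.DataFrame, dict]:
    """Align discovery records to the target panel's allele orientation.

    After dropping records with INFO < ``info_min``, each record is
    matched to the panel variant with the same id:

    * effect/other == target B/A  -> keep beta;
    * effect/other == target A/B  -> flip beta sign;
    * same after strand complement (non-ambiguous pairs only) -> resolve
      likewise;
    * anything else -> dropped as a mismatch.

    Returns the harmonized table (columns ``SNP, CHR, BP, BETA, P`` with
    beta expressed per copy of the target's alleleB) and a per-category
    count report.
    """
    report = {"input": len(stats_df)}
    ss = stats_df.copy()
    if "INFO" in ss.columns:
        keep = ss["INFO"].fillna(1.0) >= info_min
        report["info_filtered"] = int((~keep).sum())
        ss = ss[keep]
    else:
        report["info_filtered"] = 0

    vm = g.variant_meta.set_index("id")
    ss = ss[ss["SNP"].isin(vm.index)]
    report["unmatched"] = report["input"] - report["info_filtered"] - len(ss)

    ta = vm.loc[ss["SNP"], "alleleA"].str.upper().to_numpy()
    tb = vm.loc[ss["SNP"], "alleleB"].str.upper().to_numpy()
    a1 = ss["A1"].str.upper().to_numpy()
    a2 = ss["A2"].str.upper().to_numpy()
    ca1 = np.array([complement_allele(x) for x in a1])
    ca2 = np.array([complement_allele(x) for x in a2])
    ss_ambig = is_ambiguous(pd.Series(a1), pd.Series(a2))

    direct = (a1 == tb) & (a2 == ta)
    swapped = (a1 == ta) & (a2 == tb) & ~direct
    comp = (ca1 == tb) & (ca2 == ta) & ~ss_ambig & ~(direct | swapped)
    comp_swapped = (ca1 == ta) & (ca2 == tb) & ~ss_ambig & ~(direct | swapped | comp)
    matched = direct | swapped | comp | comp_swapped

    report["direct"] = int(direct.sum())
    report["swapped"] = int(swapped.sum())
    report["complement"] = int(comp.sum())
    report["complement_swapped"] = int(comp_swapped.sum())
    report["mismatch"] = int((~matched).sum())

    sign = np.where(swapped | comp_swapped, -1.0, 1.0)
    out = pd.DataFrame({
        "SNP": ss["SNP"].to_numpy(),
        "CHR": vm.loc[ss["SNP"], "chrom"].to_numpy(),
        "BP": vm.loc[ss["SNP"], "pos"].to_numpy(),
        "BETA": ss["BETA"].to_numpy() * sign,
        "P": ss["P"].to_numpy(),
    })[matched].reset_index(drop=True)
    if out.empty:
        raise EmptyOverlapError("no summary-stat variant matched the target panel")
    if (out["P"] <= 0).any() or (out["P"] > 1).any():
        raise ValidationError("summary-stat p-values must lie in (0, 1]")
    return out, report


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosage
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    return np.where(np.isnan(d), col_mean, d)


def clump(stats_df: pd.DataFrame, g: GenotypeMatrix, *,
          r2_thresh: float = 0.1, window_bp: int = 200_000) -> list[str]:
    """Greedy LD clumping on target-sample dosage correlations.

    Repeatedly take the unclumped variant with the smallest GWAS p as an
    index (ties broken by chromosome then position), retain it, and
    remove every remaining variant on the same chromosome within
    ``window_bp`` (center-to-center, boundary inclusive) whose squared
    Pearson dosage correlation with the index is strictly above
    ``r2_thresh``.  Returns the retained ids in index order.
    """
    vm = g.variant_meta.set_index("id")
    missing_ids = [s for s in stats_df["SNP"] if s not in vm.index]
    if missing_ids:
        raise ValidationError(f"clump: {len(missing_ids)} variants absent from panel")
    sub = stats_df.reset_index(drop=True)
    chrom = vm.loc[sub["SNP"], "chrom"].to_numpy()
    pos = vm.loc[sub["SNP"], "pos"].to_numpy(dtype=np.int64)
    col_of = {vid: j for j, vid in enumerate(g.variant_meta["id"])}
    dose = _imputed_dosage(g)
    dose = dose - dose.mean(axis=0)
    norms = np.sqrt((dose ** 2).sum(axis=0))

    chrom_sortable = pd.Series(chrom).astype(str)
    order = np.lexsort((pos, chrom_sortable.to_numpy(), sub["P"].to_numpy()))
    alive = np.ones(len(sub), dtype=bool)
    kept: list[str] = []
    for i in order:
        if not alive[i]:
            continue
        alive[i] = False
        kept.append(sub["SNP"].iloc[i])
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        if not near.any():
            continue
        ci = col_of[sub["SNP"].iloc[i]]
        cj = np.array([col_of[s] for s in sub["SNP"][near]])
        denom = norms[ci] * norms[cj]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (dose[:, ci] @ dose[:, cj]) / denom
        r2 = np.where(denom > 0, r * r, 0.0)
        kill = np.flatnonzero(near)[r2 > r2_thresh]
        alive[kill] = False
    return kept


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(stats_df: pd.DataFrame, g: GenotypeMatrix, clumped_ids: list[str],
          threshold: float) -> pd.DataFrame:
    """Per-sample score over clumped variants passing the p threshold.

    For sample i, ``score_i = sum_j beta_j * dosage_ij / (2 m_i)`` with
    missing dosages mean-imputed into the numerator and ``m_i`` the
    number of variants genotyped (non-missing) in sample i.  The raw
    (unnormalized) weighted sum is emitted alongside.
    """
    ss = stats_df.set_index("SNP")
    use = [v for v in clumped_ids if ss.loc[v, "P"] <= threshold]
    if not use:
        raise ValidationError(f"no variants pass p <= {threshold}")
    cols = {vid: j for j, vid in enumerate(g.variant_meta["id"])}
    idx = np.array([cols[v] for v in use])
    beta = ss.loc[use, "BETA"].to_numpy(dtype=float)
    dose = g.dosage[:, idx]
    m_i = (~np.isnan(dose)).sum(axis=1)
    col_mean = np.nanmean(dose, axis=0)
    filled = np.where(np.isnan(dose), col_mean, dose)
    raw = filled @ beta
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(m_i > 0, raw / (2.0 * m_i), np.nan)
    return pd.DataFrame({
        "id": g.sample_meta["id"].to_numpy(),
        "score": normed,
        "score_raw": raw,
        "n_variants": len(use),
        "n_nonmissing": m_i,
    })


# ---------------------------------------------------------------------------
# threshold selection by Nagelkerke R^2
# ---------------------------------------------------------------------------

def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke rescaled pseudo-R^2 from two log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    if max_r2 <= 0:
        return 0.0
    return float(cox_snell / max_r2)


def _logistic_r2(score_vec: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """(Nagelkerke R^2, separation/convergence flag) for diagnosis ~ score.

    The score is z-standardized before the fit (the pseudo-R^2 is
    invariant to linear rescaling) so the diverging-coefficient check for
    separation works regardless of the score's raw magnitude.
    """
    s = np.asarray(score_vec, dtype=float)
    sd = s.std()
    if sd == 0:
        return 0.0, True
    x = sm.add_constant((s - s.mean()) / sd)
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, x).fit(disp=0, maxiter=100, tol=1e-8)
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0, maxiter=100)
        except Exception:
            return np.nan, True
    if not full.mle_retvals.get("converged", False) or np.abs(full.params).max() > 1e3:
        flagged = True
    r2 = nagelkerke_r2(null.llf, full.llf, len(y))
    return r2, flagged


@dataclass
class PRSResult:
    """Scores at every threshold plus the selected working threshold."""

    scores: pd.DataFrame            # columns: id, threshold, score, score_raw, n_variants
    r2_by_threshold: pd.DataFrame   # columns: threshold, r2_nagelkerke, n_variants, flagged
    best_threshold: float
    harmonization_report: dict = field(default_factory=dict)

    def best_scores(self) -> pd.Series:
        sub = self.scores[self.scores["threshold"] == self.best_threshold]
        return sub.set_index("id")["score"]


def select_threshold(scores_by_threshold: dict[float, pd.DataFrame],
                     diagnosis: pd.Series) -> pd.DataFrame:
    """Nagelkerke R^2 of diagnosis on the score, per threshold.

    ``diagnosis`` maps sample id -> 'SCZ'/'CTL' (or 1/0).  Thresholds
    whose logistic fit fails to converge (separation) are flagged and
    excluded from best-threshold selection.
    """
    rows = []
    for t, sdf in sorted(scores_by_threshold.items()):
        joined = sdf.set_index("id").join(diagnosis.rename("dx"), how="inner")
        y = joined["dx"].astype(str).str.upper().isin(["SCZ", "CASE", "1"]).to_numpy(int)
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ValidationError("need at least 2 cases and 2 controls")
        r2, flagged = _logistic_r2(joined["score"].to_numpy(), y)
        rows.append((t, r2, int(sdf["n_variants"].iloc[0]), flagged))
    return pd.DataFrame(rows, columns=["threshold", "r2_nagelkerke",
                                       "n_variants", "flagged"])


def compute_prs(stats_df: pd.DataFrame, g: GenotypeMatrix, *,
                thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                info_min: float = 0.8, r2_thresh: float = 0.1,
                window_bp: int = 200_000,
                diagnosis: pd.Series | None = None) -> PRSResult:
    """Full C+T pipeline: harmonize, clump, score, select threshold."""
    harm, report = harmonize(stats_df, g, info_min=info_min)
    kept = clump(harm, g, r2_thresh=r2_thresh, window_bp=window_bp)
    per_t = {}
    frames = []
    for t in thresholds:
        try:
            sdf = score(harm, g, kept, t)
        except ValidationError:
            continue
        per_t[t] = sdf
        frames.append(sdf.assign(threshold=t))
    if not per_t:
        raise ValidationError("no threshold retained any variant")
    scores = pd.concat(frames, ignore_index=True)

    if diagnosis is None and "diagnosis" in g.sample_meta.columns:
        diagnosis = g.sample_meta.set_index("id")["diagnosis"]
    if diagnosis is not None:
        r2_tab = select_threshold(per_t, diagnosis)
        ok = r2_tab[~r2_tab["flagged"] & r2_tab["r2_nagelkerke"].notna()]
        pick = ok.sort_values(["r2_nagelkerke", "threshold"],
                              ascending=[False, True])
        best = float(pick["threshold"].iloc[0]) if len(pick) else min(per_t)
    else:
        r2_tab = pd.DataFrame(columns=["threshold", "r2_nagelkerke",
                                       "n_variants", "flagged"])
        best = max(per_t)
    return PRSResult(scores, r2_tab, best, report)
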