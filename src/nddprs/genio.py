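"""Genotype container, VCF / dosage-TSV input-output, and cohort QC.

The QC follows the target-study recipe for imputed genotype panels:

* variant level, in order — autosomal region; call rate > 90%; no
  duplicated site (same chrom:pos with the same unordered allele pair);
  no strand-ambiguous alleles (A/T or C/G); minor allele frequency
  >= 0.01; Hardy-Weinberg exact p >= 1e-5 (computed in controls by
  default);
* sample level — total genotyping rate >= 0.99, then pairwise
  relatedness on a MAF-standardized genomic relationship matrix with
  any pair above 0.2 losing its lower-call-rate member.

Missing dosages are never imputed for QC statistics; mean imputation
happens only at scoring time (see :mod:`nddprs.prs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (EmptyPanelError, InsufficientCohortError, ParseError,
                     ValidationError)

AUTOSOMES = {str(i) for i in range(1, 23)}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

VARIANT_META_COLUMNS = ["id", "chrom", "pos", "alleleA", "alleleB", "info"]


def is_autosomal(chrom: pd.Series | np.ndarray) -> np.ndarray:
    """True where the chromosome label (with or without 'chr' prefix) is 1..22."""
    s = pd.Series(chrom).astype(str).str.removeprefix("chr")
    return s.isin(AUTOSOMES).to_numpy()


def is_ambiguous(a: pd.Series, b: pd.Series) -> np.ndarray:
    """True for strand-ambiguous (palindromic) allele pairs A/T and C/G."""
    a = pd.Series(a).astype(str).str.upper()
    b = pd.Series(b).astype(str).str.upper()
    return (b == a.map(_COMPLEMENT)).to_numpy()


def complement_allele(a: str) -> str:
    return _COMPLEMENT.get(a.upper(), "N")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant and per-sample metadata.

    ``dosage`` holds alternate-allele (``alleleB``) counts in [0, 2] as
    floats with ``nan`` marking missing calls.  ``variant_meta`` has one
    row per variant (columns ``id, chrom, pos, alleleA, alleleB, info``);
    ``sample_meta`` has one row per sample and at least an ``id`` column,
    with ``diagnosis``, ``sex`` and ``age`` attached when a phenotype
    table is available.
    """

    dosage: np.ndarray
    variant_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D samples x variants array")
        n, m = self.dosage.shape
        if len(self.sample_meta) != n or len(self.variant_meta) != m:
            raise ValidationError(
                f"metadata shape mismatch: dosage {n}x{m}, "
                f"{len(self.sample_meta)} samples, {len(self.variant_meta)} variants"
            )
        self.variant_meta = self.variant_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            raise ValidationError("dosages must lie in [0, 2] or be missing (nan)")
        if (self.variant_meta["pos"] <= 0).any():
            raise ValidationError("variant positions must be 1-based positive")

    # -- basic summaries ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def alt_allele_freq(self) -> np.ndarray:
        """Frequency of alleleB among non-missing calls (nan if all missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_allele_freq()
        return np.minimum(f, 1.0 - f)

    def take_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.dosage[:, idx],
                              self.variant_meta.iloc[idx],
                              self.sample_meta)

    def take_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.dosage[idx, :],
                              self.variant_meta,
                              self.sample_meta.iloc[idx])

    def attach_phenotypes(self, pheno: pd.DataFrame) -> "GenotypeMatrix":
        """Left-join a phenotype table (keyed by sample ``id``) onto sample_meta."""
        if "id" not in pheno.columns:
            raise ValidationError("phenotype table must carry an 'id' column")
        merged = self.sample_meta[["id"]].merge(pheno, on="id", how="left")
        return GenotypeMatrix(self.dosage, self.variant_meta, merged)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT and/or DS) or a dosage TSV.

    ``fmt`` is ``'vcf'`` or ``'dosage-tsv'``; when omitted it is inferred
    from the file suffix.  For VCF, the DS FORMAT field is preferred when
    present; otherwise GT is converted to an alternate-allele count, with
    half-calls and missing genotypes mapped to missing.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValidationError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise ParseError(f"multi-allelic record at {v.CHROM}:{v.POS}; split first")
        fmts = v.FORMAT
        if "DS" in fmts:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        else:
            gts = v.genotypes  # [a0, a1, phased]
            ds = np.array(
                [a0 + a1 if (a0 >= 0 and a1 >= 0) else np.nan
                 for a0, a1, *_ in gts], dtype=float)
        rows.append(ds)
        info = v.INFO.get("INFO", v.INFO.get("R2", np.nan))
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM).removeprefix("chr"),
                     int(v.POS), v.REF, v.ALT[0], float(info) if info is not None else np.nan))
    if not rows:
        raise ParseError(f"no variant records in {path}")
    dosage = np.vstack(rows).T  # samples x variants
    variant_meta = pd.DataFrame(meta, columns=VARIANT_META_COLUMNS)
    sample_meta = pd.DataFrame({"id": samples})
    return GenotypeMatrix(dosage, variant_meta, sample_meta)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    required = ["SNP", "CHR", "BP", "A1", "A2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"dosage TSV missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required + ["INFO"]]
    if not sample_cols:
        raise ParseError("dosage TSV has no sample columns")
    dosage = df[sample_cols].to_numpy(dtype=float).T
    variant_meta = pd.DataFrame({
        "id": df["SNP"].astype(str),
        "chrom": df["CHR"].astype(str).str.removeprefix("chr"),
        "pos": df["BP"].astype(int),
        "alleleA": df["A1"].astype(str),
        "alleleB": df["A2"].astype(str),
        "info": df["INFO"].astype(float) if "INFO" in df.columns else np.nan,
    })
    return GenotypeMatrix(dosage, variant_meta, pd.DataFrame({"id": sample_cols}))


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame({
        "SNP": g.variant_meta["id"],
        "CHR": g.variant_meta["chrom"],
        "BP": g.variant_meta["pos"],
        "A1": g.variant_meta["alleleA"],
        "A2": g.variant_meta["alleleB"],
        "INFO": g.variant_meta["info"],
    })
    for j, sid in enumerate(g.sample_meta["id"]):
        df[sid] = g.dosage[j, :]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT (hard call from rounded dosage) and DS."""
    vm, sm = g.variant_meta, g.sample_meta
    order = np.lexsort((vm["pos"].to_numpy(),
                        pd.to_numeric(vm["chrom"], errors="coerce").fillna(99).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        for c in sorted({str(c) for c in vm["chrom"]}, key=lambda s: (len(s), s)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sm["id"].astype(str)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in order:
            row = vm.iloc[j]
            info = row["info"]
            info_s = f"INFO={info:.4f}" if np.isfinite(info) else "."
            cells = []
            for d in g.dosage[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(round(d))]}:{d:.3f}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['alleleA']}\t"
                     f"{row['alleleB']}\t.\tPASS\t{info_s}\tGT:DS\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic variant.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (of matching parity) whose conditional
    probability does not exceed that of the observed count.  Probabilities
    are built by the standard recurrence over heterozygote counts, so the
    test is exact for any sample size.  Degenerate inputs (monomorphic or
    empty) return 1.
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValidationError(f"genotype counts must be non-negative integers: {counts}")
    n = sum(counts)
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het
    if rare > n:  # fold so 'rare' really is the minor allele count
        rare = 2 * n - rare
    if rare == 0:
        return 1.0

    # P(h + 2) / P(h) = 4 * hom_r(h) * hom_c(h) / ((h + 1) * (h + 2))
    h0 = rare % 2
    hs = np.arange(h0, rare + 1, 2)
    probs = np.empty(hs.size)
    probs[0] = 1.0
    for k in range(hs.size - 1):
        h = hs[k]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((h + 1.0) * (h + 2.0))
        if probs[k + 1] > 1e250:  # renormalize early to dodge overflow
            probs[: k + 2] /= probs[k + 1]
    probs /= probs.sum()
    obs = probs[(hs == n_het).argmax()] if n_het in hs else 0.0
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_exact_p_from_dosage(dosage_col: np.ndarray) -> float:
    """HWE exact p from one variant's dosages, hard-calling by rounding."""
    d = dosage_col[~np.isnan(dosage_col)]
    if d.size == 0:
        return 1.0
    hard = np.rint(d).astype(int)
    return hwe_exact_p(int((hard == 2).sum()), int((hard == 1).sum()),
                       int((hard == 0).sum()))


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    steps: list = field(default_factory=list)  # (name, n_removed, n_retained)

    def add(self, name: str, removed: int, retained: int) -> None:
        self.steps.append((name, int(removed), int(retained)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_removed", "n_retained"])

    def total_removed(self) -> int:
        return sum(r for _, r, _ in self.steps)


# ---------------------------------------------------------------------------
# variant-level QC
# ---------------------------------------------------------------------------

def filter_variants(g: GenotypeMatrix, *, call_rate: float = 0.90,
                    maf_min: float = 0.01, hwe_p_min: float = 1.0e-5,
                    hwe_mode: str = "controls") -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant QC filters in their fixed order.

    Order: autosomal -> call rate (strict >) -> duplicate removal (first
    occurrence kept) -> strand-ambiguous removal -> MAF (retain >= maf_min)
    -> HWE exact (retain p >= hwe_p_min).  HWE is computed in control
    samples when a ``diagnosis`` column distinguishes them (``hwe_mode=
    'controls'``, the default) and in all samples otherwise.
    """
    if g.n_variants == 0:
        raise EmptyPanelError("no variants to filter")
    report = QCReport()
    vm = g.variant_meta

    keep = is_autosomal(vm["chrom"])
    report.add("autosomal", (~keep).sum(), keep.sum())
    g = g.take_variants(keep)

    cr = g.variant_call_rate()
    keep = cr > call_rate
    report.add("call_rate", (~keep).sum(), keep.sum())
    g = g.take_variants(keep)

    vm = g.variant_meta
    pair = [frozenset((a.upper(), b.upper()))
            for a, b in zip(vm["alleleA"], vm["alleleB"])]
    key = pd.Series(list(zip(vm["chrom"], vm["pos"], pair)))
    keep = (~key.duplicated(keep="first")).to_numpy()
    report.add("duplicated", (~keep).sum(), keep.sum())
    g = g.take_variants(keep)

    vm = g.variant_meta
    keep = ~is_ambiguous(vm["alleleA"], vm["alleleB"])
    report.add("ambiguous", (~keep).sum(), keep.sum())
    g = g.take_variants(keep)

    keep = g.maf() >= maf_min
    report.add("maf", (~keep).sum(), keep.sum())
    g = g.take_variants(keep)

    if hwe_mode == "controls" and "diagnosis" in g.sample_meta.columns:
        ctrl = g.sample_meta["diagnosis"].astype(str).str.upper().isin(
            ["CTL", "CONTROL", "CON", "0"]).to_numpy()
        dose = g.dosage[ctrl] if ctrl.any() else g.dosage
    else:
        dose = g.dosage
    hwe_p = np.array([hwe_exact_p_from_dosage(dose[:, j]) for j in range(g.n_variants)])
    keep = hwe_p >= hwe_p_min
    report.add("hwe", (~keep).sum(), keep.sum())
    g = g.take_variants(keep)

    if g.n_variants == 0:
        raise EmptyPanelError("variant QC removed every variant")
    if g.variant_meta["id"].duplicated().any():
        raise ValidationError("variant ids not unique after QC")
    return g, report


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

def relatedness_matrix(g: GenotypeMatrix) -> np.ndarray:
    """MAF-standardized genomic relationship matrix (GRM).

    Entry (i, k) is ``mean_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j))``
    over variants non-missing in both samples; monomorphic variants are
    skipped.  The diagonal is near 1 for outbred samples and off-diagonal
    entries estimate twice the kinship coefficient.
    """
    p = g.alt_allele_freq()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    x = g.dosage[:, ok]
    p = p[ok]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    miss = np.isnan(z)
    z0 = np.where(miss, 0.0, z)
    obs = (~miss).astype(float)
    num = z0 @ z0.T
    den = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        grm = num / den
    return grm


def filter_samples(g: GenotypeMatrix, *, call_rate: float = 0.99,
                   relatedness_max: float = 0.2) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate samples, then break up related pairs.

    Samples with genotyping rate strictly below ``call_rate`` go first.
    Then, while any off-diagonal GRM entry exceeds ``relatedness_max``,
    the member of the worst pair with the lower call rate (ties broken
    by lexicographically larger id) is dropped.
    """
    report = QCReport()
    cr = g.sample_call_rate()
    keep = cr >= call_rate
    report.add("sample_call_rate", (~keep).sum(), keep.sum())
    g = g.take_samples(keep)
    if g.n_samples < 2:
        raise InsufficientCohortError("fewer than 2 samples after call-rate filter")

    grm = relatedness_matrix(g)
    np.fill_diagonal(grm, 0.0)
    cr = g.sample_call_rate()
    ids = g.sample_meta["id"].astype(str).to_numpy()
    active = np.ones(g.n_samples, dtype=bool)
    drop: list[int] = []
    while True:
        sub = np.where(active[:, None] & active[None, :], grm, -np.inf)
        i, k = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, k] <= relatedness_max:
            break
        # drop the lower-call-rate member; tie -> larger id
        if (cr[i], ids[k]) < (cr[k], ids[i]):
            victim = i
        else:
            victim = k
        active[victim] = False
        drop.append(victim)
    report.add("relatedness", len(drop), active.sum())
    g = g.take_samples(active)
    if g.n_samples < 2:
        raise InsufficientCohortError("fewer than 2 samples after relatedness filter")
    return g, report
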