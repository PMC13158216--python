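"""Hypergeometric over-representation analysis (ORA) of DEG lists.

A transparent replacement for proprietary canonical-pathway tools: for
each user-supplied gene set, the p-value is the upper tail of the
hypergeometric distribution — the probability of drawing at least the
observed overlap when ``|deg_set|`` genes are sampled without
replacement from the analysis universe containing ``|gene_set|``
members.  The universe is fixed to the analyzed (autosomal, expressed)
genes, and gene sets are intersected with it before testing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParseError, ValidationError


def parse_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name <tab> description <tab> genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs name, description and >= 1 gene",
                                 line=i)
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ParseError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def ora_test(deg_set, gene_set, universe) -> tuple[int, float, float]:
    """(overlap count, upper-tail hypergeometric p, enrichment ratio).

    The enrichment ratio is observed overlap over its expectation
    ``|deg_set| * |gene_set| / |universe|``.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    deg = set(deg_set) & universe  # ids outside the universe are ignored
    gs = set(gene_set) & universe
    k = len(deg & gs)
    N, K, n = len(universe), len(gs), len(deg)
    p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
    expected = n * K / N
    ratio = k / expected if expected > 0 else np.nan
    return k, min(p, 1.0), ratio


def ora_all(deg_set, gene_sets: dict[str, list[str]], universe) -> pd.DataFrame:
    """ORA over a GMT collection with BH correction across sets.

    Sets that are empty after intersecting with the universe are skipped
    (reported with NaN p).
    """
    universe = set(universe)
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & universe
        if not gs:
            rows.append((name, 0, 0, np.nan, np.nan))
            continue
        k, p, ratio = ora_test(deg_set, gs, universe)
        rows.append((name, len(gs), k, p, ratio))
    out = pd.DataFrame(rows, columns=["pathway", "set_size", "overlap", "p",
                                      "enrichment_ratio"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        from .stats import bh_adjust
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def rank_pathways(results: pd.DataFrame, *, top_n: int = 10) -> pd.DataFrame:
    """Top pathways by ascending p, ties broken by descending enrichment ratio."""
    if results.empty:
        raise ValidationError("no enrichment results to rank")
    ranked = results.sort_values(["p", "enrichment_ratio"],
                                 ascending=[True, False],
                                 na_position="last")
    return ranked.head(top_n).reset_index(drop=True)
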