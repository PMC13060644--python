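"""Gene-set over-representation analysis (ORA).

One-sided Fisher exact / hypergeometric upper-tail tests ask whether the
selected genes (those passing differential cutoffs) overlap each gene set more
than expected when drawing from the background of all quantified genes — the
conservative background convention.  P-values are Benjamini–Hochberg adjusted
across sets, and a set is selected when its adjusted p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

EXACT_N_LIMIT = 1000  # exact combinatorics below, stable scipy tail above
SELECTION_ALPHA = 0.05


def fisher_ora(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p = P(X >= k) for X ~ Hypergeom(N, K, n).

    ``k`` selected genes fall in a set of size ``K`` within a background of
    ``N`` genes from which ``n`` were selected.  Exact combinatorics for
    N <= 1000, numerically stable survival function above.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    if N <= EXACT_N_LIMIT:
        total = math.comb(N, n)
        acc = 0
        for i in range(k, min(K, n) + 1):
            acc += math.comb(K, i) * math.comb(N - K, n - i)
        return acc / total
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjustment, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class EnrichmentResults:
    """Per-set over-representation table sorted by adjusted p, then name."""

    table: pd.DataFrame  # set_name, k, K, n, N, fold_enrichment, p, p_adj, selected

    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def summary(self) -> str:
        sel = self.selected()
        lines = [
            f"Over-representation: {len(self.table)} sets tested, "
            f"{len(sel)} selected at BH-adjusted p < {SELECTION_ALPHA}",
        ]
        for row in sel.head(10).itertuples():
            lines.append(
                f"  {row.set_name}: k={row.k}/{row.K}, fold={row.fold_enrichment:.2f}, "
                f"p_adj={row.p_adj:.3g}"
            )
        return "\n".join(lines)


class EnrichmentAnalysis:
    """Model object: Fisher/hypergeometric ORA over a gene-set collection."""

    def __init__(
        self,
        selected_genes: Iterable[str],
        background_genes: Iterable[str],
        collection: GeneSetCollection,
        alpha: float = SELECTION_ALPHA,
    ) -> None:
        self.selected = {str(g).upper() for g in selected_genes}
        self.background = {str(g).upper() for g in background_genes}
        stray = self.selected - self.background
        if stray:
            raise ValueError(
                f"selected genes not in background: {sorted(stray)[:10]}"
            )
        self.collection = collection
        self.alpha = alpha

    def fit(self) -> EnrichmentResults:
        N = len(self.background)
        n = len(self.selected)
        rows = []
        for name, members in self.collection.sets.items():
            in_bg = self.background.intersection(members)
            K = len(in_bg)
            if K == 0:
                continue  # set does not intersect the quantified universe
            k = len(self.selected.intersection(in_bg))
            p = fisher_ora(k, K, n, N)
            fold = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
            rows.append(
                {"set_name": name, "k": k, "K": K, "n": n, "N": N,
                 "fold_enrichment": fold, "p": p}
            )
        table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                            "fold_enrichment", "p"])
        if len(table):
            table["p_adj"] = bh_adjust(table["p"].to_numpy())
            table["selected"] = table["p_adj"] < self.alpha
            table = table.sort_values(["p_adj", "set_name"], kind="stable").reset_index(drop=True)
        else:
            table["p_adj"] = []
            table["selected"] = []
        return EnrichmentResults(table=table)


def run_enrichment(
    selected_genes: Iterable[str],
    background_genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = SELECTION_ALPHA,
) -> EnrichmentResults:
    """Functional wrapper around :class:`EnrichmentAnalysis`."""
    return EnrichmentAnalysis(selected_genes, background_genes, collection, alpha).fit()
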