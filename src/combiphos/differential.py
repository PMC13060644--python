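"""Per-feature condition contrasts: Welch tests, signed priority Scores, cutoffs.

For each feature and contrast (numerator condition vs denominator condition,
e.g. combination vs vehicle) the analysis computes the log2 ratio as the
difference of condition means over biological replicates, a two-sided
unequal-variance Welch t-test on the per-sample injection-averaged log2 values,
and a signed priority score

    S = sign(delta) * sqrt(|delta| * -log10(p)),

the geometric mean of the absolute log2 ratio and -log10(p) carrying the sign
of the change.  Features pass a contrast when |delta| exceeds the dataset-kind
cutoff (phosphosites: 1, i.e. 2-fold; protein expression: 0.585, i.e. 1.5-fold)
and p < 0.05, both strict.  No multiple-testing correction gates the pass flag
(the selection operates on raw p); a BH-adjusted column is emitted for
information only.

Rows are sorted to bring the strongest signals to the top: number of passing
contrasts (descending), then max |S| across contrasts (descending), positive
changes before negative at the deciding contrast, then feature id.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleDesign
from .normalize import BridgedAbundance

#: smallest positive double, reported for zero-variance unequal-mean degeneracies
TINY_P = sys.float_info.min

CUTOFFS = {
    "phosphosite": {"abs_log2": 1.0, "p": 0.05},
    "protein": {"abs_log2": 0.585, "p": 0.05},
}
# accepted aliases for dataset kinds
KIND_ALIASES = {"psty": "phosphosite", "phosphosite": "phosphosite",
                "expression": "protein", "protein": "protein"}


@dataclass(frozen=True)
class ContrastSpec:
    """A named condition contrast: numerator vs denominator (e.g. combo vs DMSO)."""

    name: str
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator must differ")

    def reversed(self) -> "ContrastSpec":
        return ContrastSpec(f"{self.name}_rev", self.denominator, self.numerator)


def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided unequal-variance Welch t-test; returns (t, df, p).

    Zero variance in both groups gives (0, df, 1) when the means are equal and
    (+/-inf, df, smallest positive double) when they differ — callers flag the
    degenerate case.  Requires >= 2 non-missing values per group.
    """
    xa = np.asarray([v for v in x if not np.isnan(v)], dtype=float)
    ya = np.asarray([v for v in y if not np.isnan(v)], dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("welch_test needs >= 2 non-missing values per group")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    nx, ny = xa.size, ya.size
    if vx == 0.0 and vy == 0.0:
        df = float(nx + ny - 2)
        if xa.mean() == ya.mean():
            return 0.0, df, 1.0
        t = np.inf if xa.mean() > ya.mean() else -np.inf
        return float(t), df, TINY_P
    se2 = vx / nx + vy / ny
    t = (xa.mean() - ya.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(max(p, TINY_P), 1.0))


def priority_score(delta: float, p: float) -> float:
    """Signed geometric mean of |log2 ratio| and -log10(p)."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    if p <= 0:
        raise ValueError("p must lie in (0, 1]")
    if p >= 1.0 or delta == 0.0:
        return 0.0
    return float(np.sign(delta) * np.sqrt(abs(delta) * (-np.log10(p))))


def apply_cutoffs(delta: float, p: float, dataset_kind: str) -> bool:
    """Strict-inequality pass rule: |delta| > kind cutoff and p < 0.05."""
    kind = KIND_ALIASES[dataset_kind]
    c = CUTOFFS[kind]
    return bool(abs(delta) > c["abs_log2"] and p < c["p"])


class DifferentialAnalysis:
    """Model object: per-feature contrasts on bridged per-sample log2 abundances.

    Parameters
    ----------
    abundance : BridgedAbundance or DataFrame
        features x sample_ids log2 abundances (injection replicates already
        averaged).
    design : SampleDesign
        maps sample_ids to conditions.
    contrasts : sequence of ContrastSpec
    dataset_kind : "phosphosite" (2-fold cutoff) or "protein" (1.5-fold cutoff)
    """

    def __init__(
        self,
        abundance: BridgedAbundance | pd.DataFrame,
        design: SampleDesign,
        contrasts: Sequence[ContrastSpec],
        dataset_kind: str = "phosphosite",
    ) -> None:
        self.abundance = (
            abundance.log2_abundance if isinstance(abundance, BridgedAbundance) else abundance
        )
        self.design = design
        self.contrasts = list(contrasts)
        if dataset_kind not in KIND_ALIASES:
            raise ValueError(f"unknown dataset kind {dataset_kind!r}")
        self.dataset_kind = KIND_ALIASES[dataset_kind]
        known = set(design.conditions)
        for c in self.contrasts:
            for cond in (c.numerator, c.denominator):
                if cond not in known:
                    raise ValueError(f"contrast condition {cond!r} not in design")

    def fit(self) -> "DifferentialResults":
        samples_of = {c: self.design.samples_of(c) for c in self.design.conditions}
        rows: list[dict] = []
        skipped: list[tuple[str, str, str]] = []
        for fid, vals in self.abundance.iterrows():
            row: dict = {"feature_id": fid}
            n_passed = 0
            best_abs_score = -np.inf
            best_delta = 0.0
            for c in self.contrasts:
                x = vals[[s for s in samples_of[c.numerator] if s in vals.index]].to_numpy(float)
                y = vals[[s for s in samples_of[c.denominator] if s in vals.index]].to_numpy(float)
                x = x[~np.isnan(x)]
                y = y[~np.isnan(y)]
                if x.size < 2 or y.size < 2:
                    skipped.append((str(fid), c.name, "fewer than 2 values in a group"))
                    row[f"{c.name}.n_num"] = x.size
                    row[f"{c.name}.n_den"] = y.size
                    for suffix in ("mean_num", "mean_den", "log2_ratio", "t", "df", "p", "score"):
                        row[f"{c.name}.{suffix}"] = np.nan
                    row[f"{c.name}.passed"] = False
                    row[f"{c.name}.degenerate"] = False
                    continue
                t, df, p = welch_test(x, y)
                degenerate = not np.isfinite(t)
                delta = float(x.mean() - y.mean())
                s = priority_score(delta, p)
                passed = apply_cutoffs(delta, p, self.dataset_kind)
                n_passed += passed
                if abs(s) > best_abs_score:
                    best_abs_score = abs(s)
                    best_delta = delta
                row.update(
                    {
                        f"{c.name}.n_num": x.size,
                        f"{c.name}.n_den": y.size,
                        f"{c.name}.mean_num": x.mean(),
                        f"{c.name}.mean_den": y.mean(),
                        f"{c.name}.log2_ratio": delta,
                        f"{c.name}.t": t,
                        f"{c.name}.df": df,
                        f"{c.name}.p": p,
                        f"{c.name}.score": s,
                        f"{c.name}.passed": passed,
                        f"{c.name}.degenerate": degenerate,
                    }
                )
            row["n_conditions_passed"] = n_passed
            row["max_abs_score"] = best_abs_score if np.isfinite(best_abs_score) else np.nan
            row["max_score_direction"] = int(np.sign(best_delta))
            rows.append(row)

        table = pd.DataFrame(rows)
        # informational BH column per contrast (raw p drives the pass flags)
        for c in self.contrasts:
            pcol = table[f"{c.name}.p"]
            ok = pcol.notna()
            adj = pd.Series(np.nan, index=table.index)
            if ok.any():
                adj[ok] = multipletests(pcol[ok], method="fdr_bh")[1]
            table[f"{c.name}.p_bh"] = adj
        table = table.sort_values(
            by=["n_conditions_passed", "max_abs_score", "max_score_direction", "feature_id"],
            ascending=[False, False, False, True],
            kind="stable",
        ).reset_index(drop=True)
        return DifferentialResults(self, table, skipped)


class DifferentialResults:
    """Fitted differential table plus accessors for plotting and selection."""

    def __init__(
        self,
        model: DifferentialAnalysis,
        table: pd.DataFrame,
        skipped: list[tuple[str, str, str]],
    ) -> None:
        self.model = model
        self.table = table
        self.skipped = skipped

    @property
    def contrasts(self) -> list[ContrastSpec]:
        return self.model.contrasts

    def passing(self, contrast: str) -> pd.DataFrame:
        return self.table[self.table[f"{contrast}.passed"]]

    def volcano_data(self, contrast: str) -> pd.DataFrame:
        """Scatter-ready (log2 ratio, -log10 p, passed) per feature."""
        return pd.DataFrame(
            {
                "feature_id": self.table["feature_id"],
                "log2_ratio": self.table[f"{contrast}.log2_ratio"],
                "neg_log10_p": -np.log10(self.table[f"{contrast}.p"]),
                "passed": self.table[f"{contrast}.passed"],
            }
        )

    def plot_volcano(self, contrast: str, ax=None):
        import matplotlib.pyplot as plt

        data = self.volcano_data(contrast)
        if ax is None:
            _, ax = plt.subplots()
        colors = np.where(data["passed"], "crimson", "grey")
        ax.scatter(data["log2_ratio"], data["neg_log10_p"], s=6, c=colors, alpha=0.6)
        ax.set_xlabel("log2 ratio")
        ax.set_ylabel("-log10 p")
        ax.set_title(contrast)
        return ax

    def summary(self) -> str:
        lines = [
            f"Differential analysis ({self.model.dataset_kind}): "
            f"{len(self.table)} features, {len(self.contrasts)} contrasts",
            f"cutoffs: |log2 ratio| > {CUTOFFS[self.model.dataset_kind]['abs_log2']}, p < 0.05",
        ]
        for c in self.contrasts:
            n = int(self.table[f"{c.name}.passed"].sum())
            lines.append(f"  {c.name} ({c.numerator} vs {c.denominator}): {n} passing features")
        if self.skipped:
            lines.append(f"  skipped {len(self.skipped)} (feature, contrast) pairs with <2 values")
        return "\n".join(lines)


def run_differential(
    abundance: BridgedAbundance | pd.DataFrame,
    design: SampleDesign,
    contrasts: Sequence[ContrastSpec],
    dataset_kind: str = "phosphosite",
) -> DifferentialResults:
    """Functional wrapper: fit a DifferentialAnalysis and return its results."""
    return DifferentialAnalysis(abundance, design, contrasts, dataset_kind).fit()
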