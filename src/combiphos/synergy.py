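"""Bliss-independence evaluation of drug-combination viability grids.

Effects are expressed as fraction affected relative to vehicle,
f = clamp(1 - viability%/100, 0, 1).  Under Bliss independence two
non-interacting drugs combine to an expected fraction affected

    E = fA + fB - fA * fB,

and the excess over independence is ΔBliss = f_obs - E.  Cells with
ΔBliss > 0.05 are called synergistic, < -0.05 antagonistic, and anything in
[-0.05, 0.05] additive (boundaries inclusive to additive).

Replicates are averaged on the viability scale before ΔBliss is computed
(classification follows the means); per-replicate ΔBliss values are also
reported for transparency.  Clonogenicity absorbance grids normalised to % of
vehicle are handled identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYNERGY_THRESHOLD = 0.05


def fraction_affected(viability_pct: float | np.ndarray) -> float | np.ndarray:
    """clamp(1 - viability%/100, 0, 1); rejects negative viabilities."""
    v = np.asarray(viability_pct, dtype=float)
    if (v < 0).any():
        raise ValueError("viability % must be >= 0")
    f = np.clip(1.0 - v / 100.0, 0.0, 1.0)
    return float(f) if np.isscalar(viability_pct) or v.ndim == 0 else f


def bliss_expected(fa: float, fb: float) -> float:
    """Bliss-independent expected fraction affected: fa + fb - fa*fb."""
    if not (0 <= fa <= 1 and 0 <= fb <= 1):
        raise ValueError("fractions affected must lie in [0, 1]")
    return fa + fb - fa * fb


def classify(delta_bliss: float, threshold: float = SYNERGY_THRESHOLD) -> str:
    if delta_bliss > threshold:
        return "synergistic"
    if delta_bliss < -threshold:
        return "antagonistic"
    return "additive"


def score_combination(
    f_obs: float, fa: float, fb: float, threshold: float = SYNERGY_THRESHOLD
) -> tuple[float, str]:
    """ΔBliss = f_obs - E and its class (boundaries +/-threshold -> additive)."""
    if not 0 <= f_obs <= 1:
        raise ValueError("f_obs must lie in [0, 1]")
    delta = f_obs - bliss_expected(fa, fb)
    return delta, classify(delta, threshold)


@dataclass
class BlissResults:
    """Per-cell Bliss grid plus the mean ΔBliss summary."""

    grid: pd.DataFrame  # per (dose_a, dose_b): fa, fb, f_obs, expected, delta_bliss, class
    per_replicate: pd.DataFrame
    skipped: list[str]

    @property
    def mean_delta_bliss(self) -> float:
        return float(self.grid["delta_bliss"].mean())

    def summary(self) -> str:
        counts = self.grid["class"].value_counts().to_dict()
        return (
            f"Bliss analysis: {len(self.grid)} combination cells, "
            f"mean ΔBliss = {self.mean_delta_bliss:+.4f} "
            f"({counts.get('synergistic', 0)} synergistic, "
            f"{counts.get('additive', 0)} additive, "
            f"{counts.get('antagonistic', 0)} antagonistic)"
        )


class BlissAnalysis:
    """Model object: Bliss evaluation of a long-format dose-response grid.

    ``data`` columns: dose_a, dose_b, replicate, viability_pct (% of vehicle;
    the vehicle cell (0, 0) defines 100%).  Single-dose designs — one dose of
    drug B crossed with a titration of drug A — are simply 1 x k grids.
    """

    REQUIRED = ("dose_a", "dose_b", "replicate", "viability_pct")

    def __init__(self, data: pd.DataFrame, threshold: float = SYNERGY_THRESHOLD) -> None:
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"grid lacks columns: {missing}")
        if (data["viability_pct"] < 0).any():
            raise ValueError("viability % must be >= 0")
        if not ((data["dose_a"] == 0) & (data["dose_b"] == 0)).any():
            raise ValueError("vehicle cell (0, 0) is required")
        self.data = data.copy()
        self.threshold = threshold

    def fit(self) -> BlissResults:
        means = (
            self.data.groupby(["dose_a", "dose_b"])["viability_pct"].mean().reset_index()
        )
        f_of = {
            (row.dose_a, row.dose_b): fraction_affected(row.viability_pct)
            for row in means.itertuples()
        }
        rows, rep_rows, skipped = [], [], []
        combos = means[(means["dose_a"] > 0) & (means["dose_b"] > 0)]
        for row in combos.itertuples():
            da, db = row.dose_a, row.dose_b
            if (da, 0.0) not in f_of or (0.0, db) not in f_of:
                skipped.append(f"({da:g}, {db:g}): missing single-agent cell")
                logger.warning("skipping combination (%g, %g): no matching single-agent cell", da, db)
                continue
            fa, fb = f_of[(da, 0.0)], f_of[(0.0, db)]
            f_obs = f_of[(da, db)]
            delta, cls = score_combination(f_obs, fa, fb, self.threshold)
            rows.append(
                {
                    "dose_a": da,
                    "dose_b": db,
                    "fa": fa,
                    "fb": fb,
                    "f_obs": f_obs,
                    "expected": bliss_expected(fa, fb),
                    "delta_bliss": delta,
                    "class": cls,
                }
            )
            reps = self.data[(self.data["dose_a"] == da) & (self.data["dose_b"] == db)]
            for rep in reps.itertuples():
                f_rep = fraction_affected(rep.viability_pct)
                rep_rows.append(
                    {
                        "dose_a": da,
                        "dose_b": db,
                        "replicate": rep.replicate,
                        "delta_bliss": f_rep - bliss_expected(fa, fb),
                    }
                )
        grid = pd.DataFrame(rows, columns=[
            "dose_a", "dose_b", "fa", "fb", "f_obs", "expected", "delta_bliss", "class",
        ])
        per_rep = pd.DataFrame(rep_rows, columns=["dose_a", "dose_b", "replicate", "delta_bliss"])
        return BlissResults(grid=grid, per_replicate=per_rep, skipped=skipped)


def evaluate_grid(data: pd.DataFrame, threshold: float = SYNERGY_THRESHOLD) -> BlissResults:
    """Functional wrapper: fit a BlissAnalysis and return its results."""
    return BlissAnalysis(data, threshold).fit()
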