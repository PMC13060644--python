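"""Multiplex normalization and cross-run bridging for isobaric reporter data.

The chain mirrors a standard TMT workflow:

1. pick, per multiplex, the reference channel least different from the others
   (highest mean pairwise Pearson correlation of log2 intensities);
2. normalize every other channel against the reference with an iterative
   rank-invariant procedure (IRON-style): select features whose ranks agree
   between the two channels, then remove either a single global log2 shift
   (``mode="global"``) or an intensity-dependent running-median correction
   curve (``mode="curve"``, the default);
3. bridge multiplexes run as separate injections of the same pooled sample:
   convert each run to ratios against its all-channel computational pool
   (per-row geometric mean), normalize the pools against each other, and scale
   the ratios back with the stored pool row means — this removes run-level
   systematic differences while leaving within-run channel contrasts untouched;
4. log2-transform and average injection replicates per sample.

Missing cells are excluded from pools, ratios and means; nothing is imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MultiplexMatrix, SampleDesign

logger = logging.getLogger(__name__)

# rank-invariant selection schedule: t halves from T0 until the kept set changes
# by < REL_CHANGE or would fall below max(MIN_KEEP, MIN_KEEP_FRAC * n)
T0 = 0.5
REL_CHANGE = 0.01
MIN_KEEP = 20
MIN_KEEP_FRAC = 0.05
MIN_PAIRWISE = 8  # features quantified in both channels required for pairwise fit


@dataclass
class CorrectionCurve:
    """Piecewise-linear log2 correction: knots (x = log2 intensity, y = log2 shift)."""

    knots_x: np.ndarray
    knots_y: np.ndarray

    def __call__(self, x: np.ndarray) -> np.ndarray:
        # np.interp is flat beyond the outermost knots, as required
        return np.interp(x, self.knots_x, self.knots_y)

    @property
    def is_zero(self) -> bool:
        return bool(np.allclose(self.knots_y, 0.0))


@dataclass
class NormalizedMultiplex:
    """A multiplex after per-channel correction against its reference channel."""

    run_id: str
    intensities: pd.DataFrame  # corrected, NaN = missing
    reference_channel: str
    curves: dict[str, CorrectionCurve] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.intensities.columns)


@dataclass
class BridgedAbundance:
    """Per-sample log2 abundances after bridging and injection-replicate averaging."""

    log2_abundance: pd.DataFrame  # features x sample_ids
    pool_row_means: pd.Series | None = None  # geometric-mean of normalized pools (M_f)


# ---------------------------------------------------------------------------
# reference-channel selection
# ---------------------------------------------------------------------------


def find_median_channel(matrix: MultiplexMatrix | pd.DataFrame) -> str:
    """Channel with the highest mean pairwise-complete Pearson correlation (log2).

    Ties break by channel order.  Raises ValueError when no channel pair has at
    least 3 pairwise-complete features.
    """
    df = matrix.intensities if isinstance(matrix, MultiplexMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    log2 = np.log2(df)
    corr = log2.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, np.nan)
    if corr.isna().all().all():
        raise ValueError("no channel pair has >= 3 pairwise-complete features")
    mean_corr = corr.mean(axis=1, skipna=True).to_numpy()
    # argmax keeps the first maximum -> channel-order tie-break
    best = int(np.nanargmax(mean_corr))
    return str(df.columns[best])


# ---------------------------------------------------------------------------
# pairwise rank-invariant normalization
# ---------------------------------------------------------------------------


def _rank_invariant_set(t_log2: np.ndarray, r_log2: np.ndarray) -> np.ndarray:
    """Indices (into the pairwise-complete arrays) of the rank-invariant features."""
    n0 = t_log2.size
    floor = max(MIN_KEEP, int(np.ceil(MIN_KEEP_FRAC * n0)))
    keep = np.arange(n0)
    t = T0
    while True:
        rt = stats.rankdata(t_log2[keep])
        rr = stats.rankdata(r_log2[keep])
        sel = np.abs(rt - rr) <= t * keep.size
        new_keep = keep[sel]
        if new_keep.size < floor:
            break  # keep previous set
        changed = keep.size - new_keep.size
        keep = new_keep
        if changed < REL_CHANGE * max(keep.size, 1) or t <= T0 / 2**20:
            break
        t /= 2.0
    return keep


def iron_pairwise(
    target: pd.Series | np.ndarray,
    reference: pd.Series | np.ndarray,
    mode: str = "curve",
) -> tuple[np.ndarray, CorrectionCurve]:
    """Normalize ``target`` against ``reference`` (raw intensities, NaN missing).

    Returns the corrected target intensities and the fitted log2 correction
    curve (subtracted from the target on the log2 scale).  ``mode="global"``
    removes the median log2 ratio of the rank-invariant set; ``mode="curve"``
    removes a running-median curve of log2 ratio against mean log2 intensity
    (window ``max(11, 10%)`` of the invariant set, linear interpolation between
    window-centre knots, flat extrapolation), re-centred so the invariant-set
    median residual is ~0.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.shape != r.shape:
        raise ValueError("target and reference must have equal length")
    both = ~np.isnan(t) & ~np.isnan(r)
    if both.sum() < MIN_PAIRWISE:
        raise ValueError(
            f"only {int(both.sum())} features quantified in both channels "
            f"(need >= {MIN_PAIRWISE})"
        )
    tl = np.log2(t[both])
    rl = np.log2(r[both])
    inv = _rank_invariant_set(tl, rl)
    ratios = tl[inv] - rl[inv]

    if mode == "curve" and inv.size < max(MIN_KEEP, MIN_PAIRWISE):
        logger.warning(
            "invariant set too small (%d); falling back to mode='global'", inv.size
        )
        mode = "global"

    if mode == "global":
        shift = float(np.median(ratios))
        anchor = float(np.median((tl[inv] + rl[inv]) / 2.0))
        curve = CorrectionCurve(np.array([anchor]), np.array([shift]))
    elif mode == "curve":
        x = (tl[inv] + rl[inv]) / 2.0
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], ratios[order]
        w = max(11, int(np.ceil(0.10 * inv.size)))
        w = min(w, xs.size)
        if xs.size - w + 1 < 2:
            shift = float(np.median(ratios))
            curve = CorrectionCurve(np.array([float(np.median(x))]), np.array([shift]))
        else:
            kx, ky = [], []
            for i in range(xs.size - w + 1):
                kx.append(float(np.median(xs[i : i + w])))
                ky.append(float(np.median(ys[i : i + w])))
            kx = np.asarray(kx)
            ky = np.asarray(ky)
            # collapse duplicate knot positions (ties in x) keeping the mean shift
            ux, inv_idx = np.unique(kx, return_inverse=True)
            uy = np.zeros_like(ux)
            counts = np.zeros_like(ux)
            np.add.at(uy, inv_idx, ky)
            np.add.at(counts, inv_idx, 1.0)
            uy = uy / counts
            curve = CorrectionCurve(ux, uy)
            # re-centre so the invariant-set median residual is ~0
            resid_med = float(np.median(ratios - curve(x)))
            curve = CorrectionCurve(curve.knots_x, curve.knots_y + resid_med)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # apply: x-position is the channel-pair mean log2 where both are present,
    # the target's own log2 intensity otherwise
    out = t.copy()
    present = ~np.isnan(t)
    tl_all = np.log2(np.where(present, t, 1.0))
    rl_all = np.where(~np.isnan(r), np.log2(np.where(np.isnan(r), 1.0, r)), np.nan)
    x_all = np.where(~np.isnan(rl_all), (tl_all + rl_all) / 2.0, tl_all)
    corr = curve(x_all)
    out[present] = 2.0 ** (tl_all[present] - corr[present])
    return out, curve


def normalize_multiplex(
    matrix: MultiplexMatrix | NormalizedMultiplex,
    reference: str | None = None,
    mode: str = "curve",
) -> NormalizedMultiplex:
    """Correct every channel of a multiplex against its reference channel.

    The reference defaults to :func:`find_median_channel`; it can be overridden
    (e.g. to mirror a previously chosen channel).  The reference channel's
    correction is identically zero.
    """
    df = matrix.intensities
    ref = reference if reference is not None else find_median_channel(
        df if isinstance(matrix, NormalizedMultiplex) else matrix
    )
    if ref not in df.columns:
        raise ValueError(f"reference channel {ref!r} not in matrix")
    out = df.copy()
    curves: dict[str, CorrectionCurve] = {}
    for ch in df.columns:
        if ch == ref:
            curves[ch] = CorrectionCurve(np.array([0.0]), np.array([0.0]))
            continue
        corrected, curve = iron_pairwise(df[ch].to_numpy(), df[ref].to_numpy(), mode=mode)
        out[ch] = corrected
        curves[ch] = curve
    return NormalizedMultiplex(
        run_id=matrix.run_id, intensities=out, reference_channel=ref, curves=curves
    )


# ---------------------------------------------------------------------------
# computational pools and bridging
# ---------------------------------------------------------------------------


def compute_pool(matrix: NormalizedMultiplex | MultiplexMatrix) -> pd.Series:
    """Per-row geometric mean across non-missing channels (the computational pool)."""
    log2 = np.log2(matrix.intensities)
    pool = 2.0 ** log2.mean(axis=1, skipna=True)
    pool.name = getattr(matrix, "run_id", "pool")
    return pool


def bridge_multiplexes(
    runs: list[NormalizedMultiplex], mode: str = "curve"
) -> dict[str, pd.DataFrame]:
    """Place runs on a common abundance scale via computational-pool bridging.

    Per run: ratios R = A / P against the run's pool; the pools of all runs are
    normalized together against their median pool; each feature's stored pool
    row mean M_f (geometric mean of normalized pools over runs) scales the
    ratios back to abundances A' = R * M_f.  Within-run channel ratios are
    preserved exactly.  A single run passes through unchanged.
    """
    if len(runs) == 1:
        return {runs[0].run_id: runs[0].intensities.copy()}
    pools = {r.run_id: compute_pool(r) for r in runs}
    pool_df = pd.DataFrame(pools)
    shared = pool_df.dropna().index
    if shared.size < MIN_PAIRWISE:
        raise ValueError(
            f"runs share only {shared.size} pooled features (need >= {MIN_PAIRWISE})"
        )
    ref = find_median_channel(pool_df)
    norm_pools = pool_df.copy()
    for run_id in pool_df.columns:
        if run_id == ref:
            continue
        corrected, _ = iron_pairwise(
            pool_df[run_id].to_numpy(), pool_df[ref].to_numpy(), mode=mode
        )
        norm_pools[run_id] = corrected
    m_f = 2.0 ** np.log2(norm_pools).mean(axis=1, skipna=True)  # stored pool row means

    bridged: dict[str, pd.DataFrame] = {}
    for r in runs:
        ratios = r.intensities.div(pools[r.run_id], axis=0)
        bridged[r.run_id] = ratios.mul(m_f.reindex(r.intensities.index), axis=0)
    return bridged


def collapse_replicates(
    bridged: dict[str, pd.DataFrame], design: SampleDesign
) -> BridgedAbundance:
    """log2-transform and average injection replicates per sample.

    Every matrix channel must be assigned in the design; offenders are listed.
    Missing injection measurements are skipped, so a sample keeps a value as
    long as at least one injection quantified it.
    """
    offenders: list[str] = []
    columns: dict[str, list[pd.Series]] = {}
    for run_id, df in bridged.items():
        run_design = design.channels_for_run(run_id)
        assigned = dict(zip(run_design["channel_id"], run_design["sample_id"]))
        for ch in df.columns:
            if ch not in assigned:
                offenders.append(f"{run_id}.{ch}")
                continue
            columns.setdefault(assigned[ch], []).append(np.log2(df[ch]))
    if offenders:
        raise ValueError(f"matrix channels not assigned in design: {offenders}")
    data = {
        sample: pd.concat(series, axis=1).mean(axis=1, skipna=True)
        for sample, series in columns.items()
    }
    out = pd.DataFrame(data)
    return BridgedAbundance(log2_abundance=out)
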