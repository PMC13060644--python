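"""Synthetic data generators with recorded ground truth.

Three generators emulate the structure of the study's inputs:

``simulate_tmt``
    One TMTPro 18plex experiment — by default 6 treatment conditions x 3
    biological replicates (vehicle, single agents, combinations), quantified in
    one or more injection runs.  Each run draws its own per-channel systematic
    bias and intensity-dependent distortion slope, which is exactly the
    structure pool-bridging is designed to remove.  Planted condition effects,
    log-normal noise and intensity-dependent (logistic) missingness complete
    the model; all latent parameters are returned as a truth object.

``simulate_dose_response``
    Hill-curve single-agent viability grids plus a combination arm whose
    fraction affected carries an additive interaction term eps on the Bliss
    scale, so the downstream ΔBliss estimate identifies eps exactly absent
    noise and clamping.

``simulate_network``
    A connected scale-free interaction backbone with planted dense modules and
    an optional planted hub, with STRING-style confidence scores.

All generators are deterministic for a fixed config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import EdgeList, FeatureAnnotation, MultiplexMatrix, SampleDesign

#: TMTPro 18plex reporter channel labels, in label order
TMTPRO_18PLEX = (
    "126C", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C",
    "131N", "131C", "132N", "132C", "133N", "133C", "134N", "134C", "135N",
)

DEFAULT_CONDITIONS = ("DMSO", "drugA", "drugB", "comboAB", "drugC", "comboAC")


# ---------------------------------------------------------------------------
# TMT experiment
# ---------------------------------------------------------------------------


@dataclass
class TmtSimConfig:
    """Parameters of the simulated 18plex experiment.

    Defaults reproduce the analysed design: 6 conditions x 3 biological
    replicates filling one 18plex, two injection runs (as for phosphosite
    data; use ``n_injection_runs=1`` for total-protein expression data),
    baseline log2 intensities ~ N(20, 2), per-channel bias sd 0.3 log2 units,
    distortion slopes uniform in +/-0.03 per log2-intensity unit, measurement
    noise sd 0.25 log2 units, and 10% of features responsive at |delta| = 2
    log2 units in every non-vehicle condition.
    """

    n_features: int = 2000
    n_conditions: int = 6
    n_bio_reps: int = 3
    n_injection_runs: int = 2
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    channel_bias_sd: float = 0.3
    distortion_slope: float = 0.03  # slopes drawn uniform in [-s, s]
    noise_sd: float = 0.25
    responsive_fraction: float = 0.10
    effect_size: float = 2.0  # |delta| in log2 units, sign random per feature
    dropout_midpoint: float = 15.0
    dropout_steepness: float = 1.0
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    kind: str = "phosphosite"  # or "protein"
    run_prefix: str = "psty_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions * self.n_bio_reps > len(TMTPRO_18PLEX):
            raise ValueError("n_conditions * n_bio_reps must fit one TMTPro 18plex (18)")
        if self.n_conditions < 2 or self.n_bio_reps < 1 or self.n_injection_runs < 1:
            raise ValueError("need >= 2 conditions, >= 1 bio rep, >= 1 injection run")
        for name, v in (
            ("baseline_log2_sd", self.baseline_log2_sd),
            ("channel_bias_sd", self.channel_bias_sd),
            ("noise_sd", self.noise_sd),
            ("distortion_slope", self.distortion_slope),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.responsive_fraction <= 1:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if len(self.conditions) < self.n_conditions:
            raise ValueError("not enough condition labels for n_conditions")
        self.conditions = tuple(self.conditions[: self.n_conditions])


@dataclass
class TmtTruth:
    """Latent parameters of a simulated TMT experiment."""

    mu: pd.Series  # per-feature baseline log2 intensity
    delta: pd.DataFrame  # features x conditions, true log2 effects (vehicle == 0)
    bias: pd.DataFrame  # runs x channels, per-channel log2 bias
    slope: pd.DataFrame  # runs x channels, intensity-dependent distortion slope
    responsive: pd.Series  # bool per feature: carries a non-zero effect

    def true_log2_ratio(self, numerator: str, denominator: str) -> pd.Series:
        return self.delta[numerator] - self.delta[denominator]


def simulate_tmt(
    config: TmtSimConfig,
) -> tuple[list[MultiplexMatrix], SampleDesign, list[FeatureAnnotation], TmtTruth]:
    """Simulate one multiplexed experiment; see :class:`TmtSimConfig`.

    The reporter intensity of feature f in channel c of run r is
    ``2 ** (mu_f + delta_{f, cond(c)} + bias_{r,c} + slope_{r,c} * (mu_f - mean mu)
    + noise)`` and is then masked missing with probability logistic in the true
    (noise-free) log2 intensity.  All injection runs carry the same samples.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_conditions * cfg.n_bio_reps
    channels = list(TMTPRO_18PLEX[:n_samples])
    conditions = list(cfg.conditions)
    feature_ids = [f"F{i:05d}" for i in range(cfg.n_features)]
    genes = [f"GENE{i:05d}" for i in range(cfg.n_features)]

    mu = pd.Series(
        rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_features),
        index=feature_ids,
        name="mu",
    )

    n_resp = int(round(cfg.responsive_fraction * cfg.n_features))
    resp_idx = rng.choice(cfg.n_features, size=n_resp, replace=False)
    responsive = pd.Series(False, index=feature_ids)
    responsive.iloc[resp_idx] = True
    signs = rng.choice([-1.0, 1.0], size=n_resp)

    delta = pd.DataFrame(0.0, index=feature_ids, columns=conditions)
    for cond in conditions[1:]:  # first condition is the vehicle: delta == 0
        delta.loc[responsive, cond] = signs * cfg.effect_size

    # design: samples laid out condition-major across channels, identically in all runs
    sample_ids, sample_cond = [], {}
    for c in conditions:
        for b in range(1, cfg.n_bio_reps + 1):
            sid = f"{c}_r{b}"
            sample_ids.append(sid)
            sample_cond[sid] = (c, b)
    design_rows = []
    run_ids = [f"{cfg.run_prefix}{r + 1}" for r in range(cfg.n_injection_runs)]
    for r_i, run_id in enumerate(run_ids):
        for ch, sid in zip(channels, sample_ids):
            cond, bio = sample_cond[sid]
            design_rows.append(
                {
                    "run_id": run_id,
                    "channel_id": ch,
                    "sample_id": sid,
                    "condition": cond,
                    "bio_rep": bio,
                    "injection_rep": r_i + 1,
                }
            )
    design = SampleDesign(pd.DataFrame(design_rows))

    cond_of_channel = np.array([sample_cond[sid][0] for sid in sample_ids])
    delta_mat = delta[list(cond_of_channel)].to_numpy()  # features x channels
    centered_mu = (mu - mu.mean()).to_numpy()[:, None]

    bias = pd.DataFrame(
        rng.normal(0.0, cfg.channel_bias_sd, (cfg.n_injection_runs, n_samples)),
        index=run_ids,
        columns=channels,
    )
    slope = pd.DataFrame(
        rng.uniform(-cfg.distortion_slope, cfg.distortion_slope, (cfg.n_injection_runs, n_samples)),
        index=run_ids,
        columns=channels,
    )

    true_log2 = mu.to_numpy()[:, None] + delta_mat  # noise- and bias-free signal
    p_miss = 1.0 / (1.0 + np.exp(cfg.dropout_steepness * (true_log2 - cfg.dropout_midpoint)))

    matrices: list[MultiplexMatrix] = []
    for run_id in run_ids:
        noise = rng.normal(0.0, cfg.noise_sd, (cfg.n_features, n_samples))
        log2_int = (
            true_log2
            + bias.loc[run_id].to_numpy()[None, :]
            + slope.loc[run_id].to_numpy()[None, :] * centered_mu
            + noise
        )
        intensities = 2.0**log2_int
        mask = rng.random((cfg.n_features, n_samples)) < p_miss
        intensities = np.where(mask, np.nan, intensities)
        matrices.append(
            MultiplexMatrix(
                run_id=run_id,
                intensities=pd.DataFrame(intensities, index=feature_ids, columns=channels),
            )
        )

    residues = rng.choice(["S", "T", "Y"], size=cfg.n_features, p=[0.7, 0.2, 0.1])
    positions = rng.integers(1, 2000, size=cfg.n_features)
    annotations = [
        FeatureAnnotation(
            feature_id=fid,
            protein_id=f"P{i:05d}",
            gene_symbol=genes[i],
            site_position=int(positions[i]) if cfg.kind == "phosphosite" else None,
            residue=str(residues[i]) if cfg.kind == "phosphosite" else None,
            kind=cfg.kind,
        )
        for i, fid in enumerate(feature_ids)
    ]
    truth = TmtTruth(mu=mu, delta=delta, bias=bias, slope=slope, responsive=responsive)
    return matrices, design, annotations, truth


# ---------------------------------------------------------------------------
# dose-response grids
# ---------------------------------------------------------------------------


@dataclass
class HillParams:
    """Single-agent Hill inhibition curve: f(d) = max_inh * d^h / (ec50^h + d^h)."""

    ec50: float
    slope: float = 1.0
    max_inhibition: float = 1.0

    def fraction_affected(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.max_inhibition * d**self.slope / (self.ec50**self.slope + d**self.slope)
        return np.where(d == 0, 0.0, f)


@dataclass
class DoseSimConfig:
    """Viability-grid generator parameters.

    Doses are molar; 0 is the vehicle.  ``interaction_eps`` is added to the
    Bliss-expected fraction affected of every combination cell, and the noise
    sd is in viability percentage points (measured values as % of vehicle).
    """

    doses_a: Sequence[float] = (0.0, 3.9e-8, 1.56e-7, 6.25e-7, 2.5e-6, 1e-5)
    doses_b: Sequence[float] = (0.0, 1e-7)
    hill_a: HillParams = field(default_factory=lambda: HillParams(ec50=6.25e-7, slope=1.2))
    hill_b: HillParams = field(default_factory=lambda: HillParams(ec50=4e-7, slope=1.0, max_inhibition=0.5))
    interaction_eps: float = 0.0
    n_replicates: int = 3
    noise_sd_pct: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for d in list(self.doses_a) + list(self.doses_b):
            if d < 0:
                raise ValueError("doses must be >= 0 (0 is the vehicle)")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.noise_sd_pct < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class DoseTruth:
    interaction_eps: float
    hill_a: HillParams
    hill_b: HillParams


def simulate_dose_response(config: DoseSimConfig) -> tuple[pd.DataFrame, DoseTruth]:
    """Long-format grid (dose_a, dose_b, replicate, viability_pct) plus truth.

    Single agents follow their Hill curves; the combination fraction affected is
    ``clamp(fA + fB - fA*fB + eps, 0, 1)``; Gaussian noise is added on the
    viability % scale and values are clipped at 0 (viability cannot be negative).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for da in cfg.doses_a:
        fa = float(cfg.hill_a.fraction_affected(np.array([da]))[0])
        for db in cfg.doses_b:
            fb = float(cfg.hill_b.fraction_affected(np.array([db]))[0])
            if da > 0 and db > 0:
                f = fa + fb - fa * fb + cfg.interaction_eps
            else:
                f = fa + fb - fa * fb  # one of them is 0
            f = min(max(f, 0.0), 1.0)
            viability = 100.0 * (1.0 - f)
            for rep in range(1, cfg.n_replicates + 1):
                v = viability + rng.normal(0.0, cfg.noise_sd_pct)
                rows.append(
                    {
                        "dose_a": da,
                        "dose_b": db,
                        "replicate": rep,
                        "viability_pct": max(v, 0.0),
                    }
                )
    table = pd.DataFrame(rows)
    return table, DoseTruth(cfg.interaction_eps, cfg.hill_a, cfg.hill_b)


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------


@dataclass
class NetSimConfig:
    """Scale-free interaction network with planted dense modules.

    ``module_sizes`` node groups are carved out of the backbone and densified
    with intra-module edge probability ``module_p``; scores are uniform in
    ``score_range``.
    """

    n_nodes: int = 60
    attachment: int = 2  # Barabasi-Albert m
    module_sizes: Sequence[int] = (10, 10)
    module_p: float = 0.8
    hub_degree_fraction: float = 0.5  # planted hub is wired to this fraction of nodes
    score_range: tuple[float, float] = (0.15, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need >= 3 nodes")
        if not 0 <= self.hub_degree_fraction <= 1:
            raise ValueError("hub_degree_fraction must lie in [0, 1]")
        if sum(self.module_sizes) > self.n_nodes:
            raise ValueError("planted modules exceed n_nodes")
        if not 0 <= self.module_p <= 1:
            raise ValueError("module_p must lie in [0, 1]")
        lo, hi = self.score_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("score_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class NetTruth:
    hub: str  # top-degree node of the generated graph
    modules: dict[str, int]  # node -> planted module id (only planted nodes)


def simulate_network(config: NetSimConfig) -> tuple[EdgeList, NetTruth]:
    """Connected scale-free backbone + planted dense modules, as a scored EdgeList."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment, seed=int(rng.integers(2**31)))
    names = {i: f"GENE{i:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, names)

    modules: dict[str, int] = {}
    start = 0
    for mid, size in enumerate(cfg.module_sizes):
        members = [f"GENE{i:04d}" for i in range(start, start + size)]
        start += size
        for i, a in enumerate(members):
            modules[a] = mid
            for b in members[i + 1 :]:
                if rng.random() < cfg.module_p:
                    g.add_edge(a, b)

    # plant the hub: take the backbone's best-connected node and wire it to a
    # fixed fraction of all nodes so it dominates degree and betweenness
    hub = max(sorted(g.nodes), key=lambda n: g.degree[n])
    target_degree = int(round(cfg.hub_degree_fraction * (cfg.n_nodes - 1)))
    others = [n for n in sorted(g.nodes) if n != hub and not g.has_edge(hub, n)]
    extra = max(0, target_degree - g.degree[hub])
    if extra and others:
        chosen = rng.choice(others, size=min(extra, len(others)), replace=False)
        g.add_edges_from((hub, n) for n in chosen)

    lo, hi = cfg.score_range
    rows = [
        {"node_a": a, "node_b": b, "combined_score": float(rng.uniform(lo, hi))}
        for a, b in sorted(g.edges())
    ]
    return EdgeList(pd.DataFrame(rows)), NetTruth(hub=hub, modules=modules)
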