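"""Synthetic cohorts with a market-integration gradient built in.

The generator emulates the statistical structure of a household-economy /
gut-microbiome field study: ~213 participants spread over 5 villages in 2
regions, seven standardized lifestyle indicators driven by 3 latent
"style-of-life" factors (house modernity, subsistence items, power usage),
and 16S OTU count tables whose phylogenetic alpha-diversity and
between-subject heterogeneity respond to the modernity gradient.

Generative model
----------------
* Latent factor scores ``f*`` are standard normal (exactly standardized),
  then shifted per region — the market-proximal region sits higher on
  modernity and power usage and lower on subsistence investment.
* Indicators are ``f* @ loadings.T`` plus Gaussian noise whose variance is
  the indicator's uniqueness, so continuous indicators have unit variance.
  The five house-construction indicators are discretized to ordered codes by
  quantile binning (which preserves their rank correlation with the latent
  factor); the two ownership indicators become proportions of items owned
  (6-item traditional list, 12-item market list) via a probit link and a
  binomial draw, so they always lie in [0, 1].
* Each sample's community is a Dirichlet-multinomial draw over an accessible
  taxon pool. A fraction of taxa is flagged "environmental"; their inclusion
  probability decays with the sample's effective modernity
  ``m_i = f1_i * (1 + interaction * f3_i)`` at rate ``pd_slope`` (negative:
  modern households reach a smaller slice of the environmental pool, so
  expected phylogenetic diversity falls). The Dirichlet concentration
  ``theta_i = exp(base_log_concentration - disp_slope * m_i)`` falls with
  modernity, which provably raises expected pairwise distances among
  high-modernity samples — the beta-dispersion gradient.
* Library sizes are lognormal, truncated below at ``min_depth`` (the cohort
  emulated here is post quality-control, so every library clears the read
  filter); defaults reproduce the order of magnitude of a deeply sequenced
  16S study (median ~1.7e5 reads, range ~2e4 to ~2.6e6).

All randomness flows through named substreams of one seed, so a config
reproduces its dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidArgumentError
from .metrics import OtuTable
from .trees import PhyloTree, simulate_tree

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_metadata",
           "simulate_communities", "simulate_dataset",
           "INDICATOR_COLUMNS", "DEFAULT_LOADINGS"]

INDICATOR_COLUMNS = [
    "wall_code", "floor_code", "bathroom_code", "water_code",
    "electricity_code", "sol_traditional", "sol_market",
]

#: indicator x factor loading pattern: house construction on factor 1
#: (modernity), traditional-item ownership on factor 2 (subsistence),
#: electricity + market-item ownership on factor 3 (power usage).
DEFAULT_LOADINGS = np.array([
    [0.80, 0.00, 0.10],   # wall
    [0.80, 0.00, 0.10],   # floor
    [0.55, -0.35, 0.15],  # bathroom
    [0.55, -0.35, 0.10],  # water
    [0.25, 0.00, 0.70],   # electricity
    [-0.10, 0.85, -0.05], # sol_traditional
    [0.30, -0.35, 0.65],  # sol_market
])

_VILLAGES = ["UV1", "UV2", "CC1", "CC2", "CC3"]
_REGION_OF = {"UV1": "UpanoValley", "UV2": "UpanoValley",
              "CC1": "CrossCutucu", "CC2": "CrossCutucu", "CC3": "CrossCutucu"}
_TRAVEL_RANK = {"UV1": 1, "UV2": 2, "CC1": 3, "CC2": 4, "CC3": 5}


def _default_region_shift() -> dict:
    # Upano Valley (2/5 of villages) vs Cross-Cutucu (3/5); weighted mean 0.
    return {"UpanoValley": (0.6, -0.45, 0.6),
            "CrossCutucu": (-0.4, 0.3, -0.4)}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults are the study conditions
    every downstream test runs under."""

    n_samples: int = 213
    n_villages: int = 5
    n_taxa: int = 500
    seed: int = 0
    true_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_LOADINGS.copy())
    #: log change in environmental-taxon accessibility per unit modernity
    pd_slope: float = -0.25
    #: log decrease in Dirichlet concentration per unit modernity
    disp_slope: float = 0.25
    #: power-usage modulation of the modernity effect
    interaction: float = 0.3
    region_shift: Mapping[str, tuple] = field(
        default_factory=_default_region_shift)
    depth_log_mean: float = float(np.log(168_951))
    depth_log_sd: float = 0.95
    min_depth: int = 20_843
    env_fraction: float = 0.5
    env_base_inclusion: float = 0.7
    #: sd of per-sample lognormal noise on environmental-pool accessibility
    #: (individual exposure heterogeneity unrelated to the gradient)
    pool_noise_sd: float = 0.3
    base_log_concentration: float = float(np.log(50.0))
    #: None -> noise sd = sqrt(1 - communality); a float fixes it for all
    indicator_noise: float | None = None

    def __post_init__(self):
        self.true_loadings = np.asarray(self.true_loadings, dtype=float)
        if self.n_samples < 4:
            raise InvalidArgumentError("n_samples must be >= 4")
        if self.n_taxa < 8:
            raise InvalidArgumentError("n_taxa must be >= 8")
        if self.depth_log_sd < 0:
            raise InvalidArgumentError("depth_log_sd must be >= 0")
        if self.true_loadings.shape != (7, 3):
            raise InvalidArgumentError("true_loadings must be 7x3")
        if not 1 <= self.n_villages <= len(_VILLAGES):
            raise InvalidArgumentError("n_villages must be in 1..5")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth behind one synthetic dataset (for recovery tests)."""

    factor_scores: np.ndarray          # n x 3, after region shifts
    factor_scores_raw: np.ndarray      # n x 3, exactly standardized
    indicators_continuous: pd.DataFrame  # pre-discretization indicators
    env_taxon: np.ndarray | None = None  # per-leaf environmental flag
    theta: np.ndarray | None = None      # per-sample Dirichlet concentration

    def to_frame(self, sample_ids) -> pd.DataFrame:
        df = pd.DataFrame(self.factor_scores, index=sample_ids,
                          columns=["f1_modernity", "f2_subsistence", "f3_power"])
        if self.theta is not None:
            df["theta"] = self.theta
        return df


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # named substreams: 1 = metadata, 2 = communities, 3 = depths
    return np.random.default_rng([cfg.seed, stage])


def simulate_metadata(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-sample covariates and lifestyle indicators.

    Returns the metadata table (village, region, age, travel rank, five
    ordered house codes, two ownership proportions) and the ground truth
    (latent factor scores and the continuous indicators before coding).
    """
    rng = _rng(cfg, 1)
    n = cfg.n_samples
    lam = cfg.true_loadings

    villages = np.concatenate([
        np.full(len(chunk), _VILLAGES[v])
        for v, chunk in enumerate(np.array_split(np.arange(n), cfg.n_villages))
    ])
    regions = np.array([_REGION_OF[v] for v in villages])

    f_raw = rng.standard_normal((n, 3))
    f_raw = (f_raw - f_raw.mean(axis=0)) / f_raw.std(axis=0)
    shifts = np.array([cfg.region_shift[r] for r in regions], dtype=float)
    f = f_raw + shifts

    if cfg.indicator_noise is None:
        noise_sd = np.sqrt(np.clip(1.0 - (lam ** 2).sum(axis=1), 0.0, None))
    else:
        noise_sd = np.full(7, float(cfg.indicator_noise))
    y = f @ lam.T + rng.standard_normal((n, 7)) * noise_sd[None, :]
    y_cont = pd.DataFrame(y, columns=INDICATOR_COLUMNS)

    meta = pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "village": villages,
        "region": regions,
        "age": np.clip(np.rint(rng.gamma(2.2, 13.0, size=n)), 1, 100).astype(int),
        "travel_rank": [_TRAVEL_RANK[v] for v in villages],
    }).set_index("sample_id")
    y_cont.index = meta.index

    # ordered construction codes by quantile binning (4 levels; 3 for
    # electricity access: none / shared or generator / grid)
    levels = {"wall_code": 4, "floor_code": 4, "bathroom_code": 4,
              "water_code": 4, "electricity_code": 3}
    for col, k in levels.items():
        qs = np.quantile(y_cont[col], np.arange(1, k) / k)
        meta[col] = np.searchsorted(qs, y_cont[col], side="left").astype(int)

    # ownership proportions: probit link, binomial over the item list
    meta["sol_traditional"] = rng.binomial(6, norm.cdf(y_cont["sol_traditional"])) / 6
    meta["sol_market"] = rng.binomial(12, norm.cdf(y_cont["sol_market"])) / 12

    truth = SimTruth(factor_scores=f, factor_scores_raw=f_raw,
                     indicators_continuous=y_cont)
    return meta, truth


def simulate_communities(tree: PhyloTree, truth: SimTruth,
                         cfg: SimConfig) -> OtuTable:
    """Draw one OTU count table given a tree and latent factor scores.

    Fills ``truth.env_taxon`` and ``truth.theta`` as a side effect so
    recovery tests can see the generative state.
    """
    if tree.n_leaves < cfg.n_taxa:
        raise InvalidArgumentError("tree has fewer leaves than n_taxa")
    rng = _rng(cfg, 2)
    n = truth.factor_scores.shape[0]
    f1 = truth.factor_scores[:, 0]
    f3 = truth.factor_scores[:, 2]
    modern = f1 * (1.0 + cfg.interaction * f3)

    m = cfg.n_taxa
    env = rng.random(m) < cfg.env_fraction
    weights = rng.lognormal(0.0, 1.25, size=m)
    pool_noise = rng.normal(0.0, cfg.pool_noise_sd, size=n)
    incl_prob = np.clip(
        cfg.env_base_inclusion * np.exp(cfg.pd_slope * modern + pool_noise),
        0.02, 1.0)
    theta = np.exp(cfg.base_log_concentration - cfg.disp_slope * modern)

    depths = _draw_depths(cfg, n)
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        in_pool = ~env | (rng.random(m) < incl_prob[i])
        w = weights * in_pool
        alpha = theta[i] * w / w.sum()
        p = rng.dirichlet(np.clip(alpha, 1e-9, None))
        counts[i] = rng.multinomial(depths[i], p)

    truth.env_taxon = env
    truth.theta = theta
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    otu_ids = tree.leaf_names[:m]
    return OtuTable(pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                                 columns=otu_ids))


def _draw_depths(cfg: SimConfig, n: int) -> np.ndarray:
    """Lognormal library sizes, truncated below at ``min_depth`` by
    resampling (the emulated cohort already passed the read filter)."""
    rng = _rng(cfg, 3)
    depths = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        if filled >= n:
            break
        draw = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=n)
        ok = draw[draw >= cfg.min_depth]
        take = min(len(ok), n - filled)
        depths[filled:filled + take] = ok[:take].astype(np.int64)
        filled += take
    if filled < n:
        raise InvalidArgumentError(
            "min_depth lies too far above the library-size distribution; "
            "lower min_depth or raise depth_log_mean")
    return depths


def simulate_dataset(cfg: SimConfig):
    """Convenience: tree + metadata + truth + OTU table from one config."""
    tree = simulate_tree(cfg.n_taxa, cfg.seed)
    meta, truth = simulate_metadata(cfg)
    table = simulate_communities(tree, truth, cfg)
    return tree, meta, truth, table
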