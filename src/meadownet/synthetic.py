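"""Synthetic multi-domain soil-community generator with known ground truth.

Emulates a blocked herbivore-disturbance field survey: treatments C (natural
meadow), P (pika disturbance only) and PL (pika + livestock), each with two
blocks of five sites; P/PL sites contribute one quadrat per surface type
(G grassland, N new mound, O old mound, B bare land, I inside mound), C sites
a single meadow quadrat, giving 110 samples under the defaults.

Counts come from a latent Gaussian model: each OTU has a fixed expected
log-abundance taken from a log-normal quantile ladder, plus a correlated
cross-sample latent deviate (block-structured, the planted co-occurrence
signal), plus independent noise, plus planted group-specific enrichment
shifts; the softmax of the log-abundances gives the composition, from which
counts are drawn multinomially at a negative-binomial library size. The
planted pairs and enriched OTUs are exposed through :func:`planted_truth` so
downstream edge and enrichment recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import DOMAINS, CountTable, ENV_COLUMNS

TREATMENTS = ("C", "P", "PL")
SURFACES = ("G", "N", "O", "B", "I")

#: default OTU richness per domain; bacteria >> fungi ~ archaea, mirroring
#: the typical Chao1 ordering of alpine meadow soils.
DEFAULT_RICHNESS = {"bacteria": 500, "fungi": 150, "archaea": 60}


class ConfigurationError(ValueError):
    pass


@dataclass
class DesignConfig:
    """Blocked sampling design: treatments x blocks x sites x surfaces."""

    treatments: tuple[str, ...] = TREATMENTS
    surfaces: tuple[str, ...] = SURFACES
    n_blocks_per_treatment: int = 2
    n_sites_per_block: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.treatments:
            raise ConfigurationError("treatment list is empty")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ConfigurationError(f"unknown treatments: {sorted(unknown)}")


@dataclass
class CorrelationBlock:
    """A set of OTUs sharing a latent factor with correlation ``rho``.

    For ``rho >= 0`` every within-block pair has latent correlation rho.
    A negative rho gives members alternating factor loadings, so
    opposite-sign members correlate at -|rho| and same-sign members at
    +|rho| (a fully negative block of more than two members is not a valid
    correlation structure).
    """

    otus: tuple[str, ...]
    rho: float
    domain: str = "bacteria"

    def __post_init__(self):
        if len(self.otus) < 2:
            raise ConfigurationError("correlation block needs >= 2 OTUs")
        if not -1 <= self.rho <= 1:
            raise ConfigurationError("|rho| must be <= 1")

    def member_signs(self) -> np.ndarray:
        if self.rho >= 0:
            return np.ones(len(self.otus))
        return np.array([1 if k % 2 == 0 else -1 for k in range(len(self.otus))])


@dataclass
class EnrichmentSet:
    """OTUs shifted by ``log2fc`` in samples matching ``group``.

    ``group`` maps metadata columns to required values, e.g.
    ``{"disturbance": "P", "surface": "G"}``.
    """

    group: dict[str, str]
    otus: tuple[str, ...]
    log2fc: float
    domain: str = "bacteria"

    def __post_init__(self):
        if not np.isfinite(self.log2fc):
            raise ConfigurationError("fold-change must be finite")


@dataclass
class CommunityConfig:
    """Per-domain community model.

    Parameters
    ----------
    n_otus
        Richness of the domain.
    depth_mean, depth_dispersion
        Negative-binomial library-size model (mean and size parameter).
    base_abundance_shape
        Log-normal sigma of the expected relative abundances; expected
        log-abundances sit on the corresponding deterministic Gaussian
        quantile ladder.
    latent_scale
        SD of the correlated cross-sample latent deviate (the biological
        signal carrying the planted correlation blocks).
    noise_sd
        SD of additional independent log-abundance noise.
    """

    n_otus: int = 100
    depth_mean: float = 10_000.0
    depth_dispersion: float = 20.0
    base_abundance_shape: float = 1.0
    latent_scale: float = 0.7
    noise_sd: float = 0.15
    correlation_blocks: list[CorrelationBlock] = field(default_factory=list)
    enriched_sets: list[EnrichmentSet] = field(default_factory=list)
    seed: int = 0

    def otu_ids(self) -> list[str]:
        width = len(str(self.n_otus))
        return [f"OTU{k + 1:0{width}d}" for k in range(self.n_otus)]

    def validate(self) -> None:
        known = set(self.otu_ids())
        for blk in self.correlation_blocks:
            missing = set(blk.otus) - known
            if missing:
                raise ConfigurationError(f"block references missing OTUs: {sorted(missing)}")
        for es in self.enriched_sets:
            missing = set(es.otus) - known
            if missing:
                raise ConfigurationError(f"enriched set references missing OTUs: {sorted(missing)}")


@dataclass
class GradientConfig:
    """Environment / function gradients along the surface succession.

    ``intercepts`` give the natural-meadow level of each variable;
    ``surface_offsets`` the mean shift per surface type; ``residual_sd``
    the sampling noise. Defaults plant monotone declines of vegetation and
    the carbon/nitrogen pools along G -> N -> O -> B, with pH and
    conductivity rising, qualitatively matching pika-disturbance surveys.
    """

    intercepts: dict[str, float] = field(default_factory=lambda: {
        "pH": 7.9, "CON": 120.0, "NH4N": 18.0, "NO3N": 8.0, "SOC": 45.0,
        "TN": 4.0, "total_coverage": 80.0, "wet_weight": 60.0, "dry_weight": 25.0,
    })
    surface_offsets: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "pH": {"G": 0.0, "N": 0.2, "O": 0.35, "B": 0.5, "I": 0.3},
        "CON": {"G": 0.0, "N": 15.0, "O": 25.0, "B": 40.0, "I": 20.0},
        "NH4N": {"G": 2.0, "N": -2.0, "O": -4.5, "B": -7.0, "I": -3.0},
        "NO3N": {"G": 0.0, "N": 3.0, "O": 1.5, "B": 0.5, "I": 1.0},
        "SOC": {"G": 3.0, "N": -5.0, "O": -10.0, "B": -15.0, "I": -7.0},
        "TN": {"G": 0.3, "N": -0.5, "O": -1.0, "B": -1.5, "I": -0.7},
        "total_coverage": {"G": 8.0, "N": -30.0, "O": -45.0, "B": -60.0, "I": -40.0},
        "wet_weight": {"G": 5.0, "N": -25.0, "O": -35.0, "B": -45.0, "I": -30.0},
        "dry_weight": {"G": 2.0, "N": -10.0, "O": -14.0, "B": -18.0, "I": -12.0},
    })
    residual_sd: dict[str, float] = field(default_factory=lambda: {
        "pH": 0.1, "CON": 10.0, "NH4N": 2.0, "NO3N": 1.5, "SOC": 5.0,
        "TN": 0.4, "total_coverage": 8.0, "wet_weight": 8.0, "dry_weight": 4.0,
    })

    def validate(self) -> None:
        for var in ENV_COLUMNS:
            for mapping, what in ((self.intercepts, "intercept"),
                                  (self.surface_offsets, "surface offsets"),
                                  (self.residual_sd, "residual sd")):
                if var not in mapping:
                    raise ConfigurationError(f"missing {what} for variable {var!r}")
            if self.residual_sd[var] <= 0:
                raise ConfigurationError(f"residual sd for {var!r} must be > 0")


@dataclass
class TruthRecord:
    """Ground truth planted in a community: correlated pairs and enriched OTUs."""

    correlated_pairs: dict[tuple[str, str], float]
    enriched: list[tuple[dict[str, str], str]]

    def positive_pairs(self) -> set[tuple[str, str]]:
        return {p for p, r in self.correlated_pairs.items() if r > 0}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """One metadata row per sample.

    C blocks contribute one natural-meadow quadrat per site (labelled
    surface G so surface-level contrasts include the undisturbed meadow);
    P and PL blocks one quadrat per surface type per site.
    """
    rows = []
    for treat in cfg.treatments:
        for b in range(1, cfg.n_blocks_per_treatment + 1):
            block_id = f"{treat}{b}"
            for s in range(1, cfg.n_sites_per_block + 1):
                surfaces = ("G",) if treat == "C" else cfg.surfaces
                for surf in surfaces:
                    sid = f"{block_id}.s{s}.{surf}"
                    rows.append((sid, treat, surf, block_id, f"s{s}"))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "disturbance", "surface", "block", "site"]
    ).set_index("sample_id")
    if not frame.index.is_unique:
        raise ConfigurationError("design produced duplicate sample ids")
    return frame


def _log_abundance(design: pd.DataFrame, cfg: CommunityConfig,
                   rng: np.random.Generator) -> np.ndarray:
    n, m = len(design), cfg.n_otus
    otus = cfg.otu_ids()
    idx = {o: k for k, o in enumerate(otus)}
    # deterministic quantile ladder of expected log abundances
    q = (np.arange(m) + 0.5) / m
    base = cfg.base_abundance_shape * stats.norm.ppf(q)
    z = rng.normal(size=(n, m))
    for blk in cfg.correlation_blocks:
        cols = [idx[o] for o in blk.otus]
        shared = rng.normal(size=n)
        signs = blk.member_signs()
        a = np.sqrt(abs(blk.rho))
        z[:, cols] = signs * a * shared[:, None] + np.sqrt(1 - abs(blk.rho)) * z[:, cols]
    la = base + cfg.latent_scale * z + cfg.noise_sd * rng.normal(size=(n, m))
    for es in cfg.enriched_sets:
        mask = np.ones(n, dtype=bool)
        for col, val in es.group.items():
            mask &= (design[col] == val).to_numpy()
        cols = [idx[o] for o in es.otus]
        la[np.ix_(mask, cols)] += es.log2fc * np.log(2)
    return la


def generate_counts(design: pd.DataFrame, cfg: CommunityConfig, domain: str) -> CountTable:
    """Draw a count table for one domain under the planted model."""
    if domain not in DOMAINS:
        raise ConfigurationError(f"unknown domain label: {domain!r}")
    if design.empty:
        raise ConfigurationError("empty design")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    la = _log_abundance(design, cfg, rng)
    comp = np.exp(la - la.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    k = cfg.depth_dispersion
    depths = rng.negative_binomial(k, k / (k + cfg.depth_mean), size=len(design))
    depths = np.maximum(depths, 1)
    counts = np.vstack([
        rng.multinomial(d, p) for d, p in zip(depths, comp)
    ])
    data = pd.DataFrame(counts, index=design.index, columns=cfg.otu_ids())
    return CountTable(data, domain=domain)


def generate_env(design: pd.DataFrame, cfg: GradientConfig, seed) -> pd.DataFrame:
    """Environment / function table: intercept + surface offset + noise."""
    if design.empty:
        raise ConfigurationError("empty design")
    cfg.validate()
    rng = np.random.default_rng(seed)
    surf = design["surface"]
    cols = {}
    for var in ENV_COLUMNS:
        mean = cfg.intercepts[var] + surf.map(cfg.surface_offsets[var]).to_numpy()
        cols[var] = mean + cfg.residual_sd[var] * rng.normal(size=len(design))
    env = pd.DataFrame(cols, index=design.index)
    env["total_coverage"] = env["total_coverage"].clip(0, 100)
    return env


def planted_truth(cfg: CommunityConfig) -> TruthRecord:
    """Enumerate the planted correlated pairs (with signed rho) and enrichments."""
    cfg.validate()
    pairs: dict[tuple[str, str], float] = {}
    for blk in cfg.correlation_blocks:
        signs = blk.member_signs()
        for a in range(len(blk.otus)):
            for b in range(a + 1, len(blk.otus)):
                i, j = sorted((blk.otus[a], blk.otus[b]))
                pairs[(i, j)] = signs[a] * signs[b] * abs(blk.rho)
    enriched = [
        (es.group, otu) for es in cfg.enriched_sets for otu in es.otus
    ]
    return TruthRecord(correlated_pairs=pairs, enriched=enriched)


def default_community_configs(seed: int = 0) -> dict[str, CommunityConfig]:
    """One config per domain at the default richness, seeded per domain."""
    return {
        domain: CommunityConfig(n_otus=DEFAULT_RICHNESS[domain], seed=seed + k)
        for k, domain in enumerate(DOMAINS)
    }
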