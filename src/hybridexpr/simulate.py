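"""Synthetic data with known truth for every pipeline stage.

The count generator emulates a three-group hybrid-zone design (two
parental species plus hybrids, a few biological replicates each):
negative-binomial counts with edgeR-style dispersion (variance
mu + phi * mu^2), log-normal baseline expression across transcripts,
log-uniform library sizes, a configurable mix of inheritance modes,
latent confounder axes, and an environmental gradient acting on a subset
of transcripts.  The soil generator draws multivariate-normal site rows
for the fixed 14-variable panel; the GO generator builds a random
single-rooted DAG with direct gene annotations and p-value-like gene
scores optionally enriched on chosen terms.

Reproducibility: one RNG stream handles the sample-level draws and each
transcript owns a sub-stream derived from (seed, transcript index), so
enlarging ``n_transcripts`` never reshuffles earlier transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GODag
from .envassoc import SOIL_VARIABLES
from .normalization import CountMatrix

#: Inheritance modes the generator can plant, in assignment order.
SIM_MODES = (
    "conserved",
    "additive",
    "dominantA",
    "dominantB",
    "transgressive_up",
    "transgressive_down",
)

DEFAULT_MODE_FRACTIONS = {
    "conserved": 0.70,
    "additive": 0.05,
    "dominantA": 0.05,
    "dominantB": 0.10,
    "transgressive_up": 0.07,
    "transgressive_down": 0.03,
}

GROUPS = ("parentA", "parentB", "hybrid")


@dataclass
class SimConfig:
    """Study conditions for one synthetic hybrid zone.

    effect_log2fc is the true absolute log2 fold change planted for
    non-conserved modes; env_effect_size is the log2-scale slope per unit
    of the environmental predictor (uniform on [-1, 1] across samples).
    latent_env_corr correlates the first latent confounder with the
    environmental predictor, emulating spatial structure aligned with the
    gradient (the confounding LFMM exists to remove).
    """

    n_transcripts: int = 2000
    replicates_per_group: int = 4
    mode_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_FRACTIONS)
    )
    base_mean: float = 100.0
    base_log_sd: float = 1.0
    dispersion: float = 0.2
    effect_log2fc: float = 6.0
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    n_latent: int = 2
    latent_sd: float = 0.5
    latent_env_corr: float = 0.5
    env_effect_fraction: float = 0.05
    env_effect_size: float = 1.0
    length_range: tuple[int, int] = (300, 3000)
    zone_label: str = "HZ1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if int(self.replicates_per_group) != self.replicates_per_group:
            raise ValueError("replicate count must be an integer")
        unknown = set(self.mode_fractions) - set(SIM_MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")
        vals = list(self.mode_fractions.values())
        if any(v < 0 for v in vals):
            raise ValueError("mode fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("mode fractions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.env_effect_fraction <= 1:
            raise ValueError("env_effect_fraction must be a proportion")
        if not -1 <= self.latent_env_corr <= 1:
            raise ValueError("latent_env_corr must be in [-1, 1]")


@dataclass
class SyntheticTruth:
    modes: np.ndarray  # per-transcript true mode
    group_means: pd.DataFrame  # transcripts x groups, unit library share
    env_flags: np.ndarray  # per-transcript bool
    latent: np.ndarray  # samples x n_latent factor values
    env_predictor: np.ndarray  # per-sample gradient position


# true group offsets on the log2 scale, as (parentA, parentB, hybrid)
# multiples of effect_log2fc
_MODE_OFFSETS = {
    "conserved": (0.0, 0.0, 0.0),
    "dominantA": (0.5, -0.5, 0.5),
    "dominantB": (0.5, -0.5, -0.5),
    "additive": (1.0, -1.0, 0.0),
    "transgressive_up": (0.0, 0.0, 1.0),
    "transgressive_down": (0.0, 0.0, -1.0),
}


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _assign_modes(config: SimConfig) -> np.ndarray:
    """Deterministic mode counts: round(fraction * n) per non-conserved
    mode in fixed order; remainder transcripts become conserved."""
    n = config.n_transcripts
    counts = {}
    for mode in SIM_MODES:
        if mode == "conserved":
            continue
        counts[mode] = int(round(config.mode_fractions.get(mode, 0.0) * n))
    n_other = sum(counts.values())
    if n_other > n:
        raise ValueError("mode fractions round to more transcripts than exist")
    counts["conserved"] = n - n_other
    modes = np.concatenate(
        [np.repeat(m, counts[m]) for m in SIM_MODES if counts[m] > 0]
    )
    return modes


def generate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate one zone's count matrix, sample metadata, and truth."""
    n = config.n_transcripts
    reps = int(config.replicates_per_group)
    n_samples = 3 * reps
    sample_rng = np.random.default_rng([config.seed, 0])

    sample_ids = [f"{g}_{r + 1}" for g in GROUPS for r in range(reps)]
    group_idx = np.repeat(np.arange(3), reps)
    metadata = pd.DataFrame(
        {
            "sample": sample_ids,
            "taxon": [GROUPS[k] for k in group_idx],
            "zone": config.zone_label,
        }
    )

    lo, hi = config.lib_size_range
    lib_sizes = np.exp(sample_rng.uniform(math.log(lo), math.log(hi), n_samples))
    share = lib_sizes / lib_sizes.mean()

    env = sample_rng.uniform(-1.0, 1.0, n_samples)
    latent = sample_rng.standard_normal((n_samples, config.n_latent))
    if config.n_latent > 0 and config.latent_env_corr != 0.0:
        # plant the first confounder at exactly the requested sample
        # correlation with the gradient: residualize the noise against
        # env, standardize both parts, then mix
        x_std = _standardize(env)
        noise = latent[:, 0]
        noise = noise - (noise @ x_std / (x_std @ x_std)) * x_std
        noise = _standardize(noise)
        rho = config.latent_env_corr
        latent[:, 0] = rho * x_std + math.sqrt(1 - rho**2) * noise

    modes = sample_rng.permutation(_assign_modes(config))
    n_env = int(round(config.env_effect_fraction * n))
    env_flags = np.zeros(n, dtype=bool)
    env_flags[sample_rng.choice(n, size=n_env, replace=False)] = True

    lengths = sample_rng.integers(
        config.length_range[0], config.length_range[1] + 1, size=n
    )

    ln2 = math.log(2.0)
    counts = np.empty((n, n_samples), dtype=np.int64)
    group_means = np.empty((n, 3))
    phi = config.dispersion
    for i in range(n):
        rng_i = np.random.default_rng([config.seed, 1, i])
        log_base = math.log(config.base_mean) + rng_i.normal(
            0.0, config.base_log_sd
        )
        offsets = np.array(_MODE_OFFSETS[modes[i]]) * config.effect_log2fc
        group_means[i] = np.exp(log_base + ln2 * offsets)
        log_mu = log_base + ln2 * offsets[group_idx] + np.log(share)
        if config.n_latent > 0:
            w = config.latent_sd * rng_i.standard_normal(config.n_latent)
            log_mu = log_mu + latent @ w
        if env_flags[i]:
            log_mu = log_mu + ln2 * config.env_effect_size * env
        mu = np.exp(log_mu)
        if phi <= 1e-12:
            counts[i] = rng_i.poisson(mu)
        else:
            r = 1.0 / phi
            counts[i] = rng_i.negative_binomial(r, r / (r + mu))

    ids = [f"TR{i:06d}" for i in range(n)]
    cm = CountMatrix(
        transcript_ids=ids, sample_ids=sample_ids, counts=counts, lengths=lengths
    )
    truth = SyntheticTruth(
        modes=modes,
        group_means=pd.DataFrame(group_means, index=ids, columns=list(GROUPS)),
        env_flags=env_flags,
        latent=latent,
        env_predictor=env,
    )
    return cm, metadata, truth


def generate_soil(
    group_sites: dict[str, int],
    group_means: dict[str, dict[str, float]],
    covariance: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Multivariate-normal soil table with group-specific means.

    ``group_means`` must name all 14 panel variables per group; a None
    covariance means exact group means (zero noise).
    """
    p = len(SOIL_VARIABLES)
    if covariance is None:
        covariance = np.zeros((p, p))
    covariance = np.asarray(covariance, dtype=float)
    if covariance.shape != (p, p):
        raise ValueError(f"covariance must be {p}x{p}")
    evals = np.linalg.eigvalsh((covariance + covariance.T) / 2)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("covariance is not positive-semidefinite")
    rng = np.random.default_rng([seed, 2])
    rows = []
    index = []
    for group, n_sites in group_sites.items():
        means = group_means[group]
        missing = [v for v in SOIL_VARIABLES if v not in means]
        if missing:
            raise ValueError(f"group {group!r} missing variables: {missing}")
        mu = np.array([means[v] for v in SOIL_VARIABLES])
        draws = rng.multivariate_normal(mu, covariance, size=n_sites, method="svd")
        for k in range(n_sites):
            index.append(f"{group}_site{k + 1}")
            rows.append({"group": group, **dict(zip(SOIL_VARIABLES, draws[k]))})
    return pd.DataFrame(rows, index=index)


#: Plausible restinga-scale baselines for the 14 soil variables
#: (pH in units, OM g/dm3, CEC/SB/PA mmolc/dm3, BSP/ASP %, elements mg/dm3).
SOIL_BASE_MEANS = {
    "pH": 5.0, "OM": 30.0, "CEC": 80.0, "SB": 40.0, "BSP": 50.0,
    "ASP": 20.0, "PA": 40.0, "P": 10.0, "K": 1.5, "Ca": 20.0,
    "Na": 3.0, "S": 15.0, "Al": 5.0, "Mg": 10.0,
}

#: Per-unit-gradient slopes: the dune -> swale transition raises salinity,
#: organic matter and exchangeable bases and slightly lowers pH and Al.
SOIL_GRADIENT = {
    "pH": -0.4, "OM": 10.0, "CEC": 20.0, "SB": 10.0, "BSP": 10.0,
    "ASP": -5.0, "PA": 0.5, "P": 2.0, "K": 0.3, "Ca": 5.0,
    "Na": 1.5, "S": 4.0, "Al": -1.5, "Mg": 3.0,
}


def soil_for_samples(
    metadata: pd.DataFrame,
    env_predictor: np.ndarray,
    noise_scale: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample soil rows whose leading variation tracks the gradient.

    Each variable moves along ``env_predictor`` with its slope from
    SOIL_GRADIENT plus Gaussian noise, so PC1 of the standardized panel
    recovers the gradient the count generator used.  Site ids equal
    sample ids (one root-proximal soil sample per plant).
    """
    rng = np.random.default_rng([seed, 4])
    rows = []
    for j, sample in enumerate(metadata["sample"]):
        x = float(env_predictor[j])
        row = {"group": metadata["taxon"].iloc[j]}
        for var in SOIL_VARIABLES:
            sd = noise_scale * abs(SOIL_GRADIENT[var]) + 0.01 * abs(
                SOIL_BASE_MEANS[var]
            )
            row[var] = SOIL_BASE_MEANS[var] + SOIL_GRADIENT[var] * x + rng.normal(
                0.0, sd
            )
        rows.append(row)
    return pd.DataFrame(rows, index=list(metadata["sample"]))


def generate_go(
    n_terms: int,
    max_depth: int,
    genes: list[str],
    annotation_density: float,
    enriched_terms: list[tuple[str, float]] | None = None,
    seed: int = 0,
) -> tuple[GODag, dict[str, set[str]], dict[str, float]]:
    """Random single-rooted GO-like DAG, direct annotations, gene scores.

    Every non-root term gets 1-2 parents among shallower terms.  Direct
    annotations are independent Bernoulli(annotation_density) per
    (gene, term) pair; propagation is left to the enrichment module.
    Scores are uniform on [0, 1] except for genes under an enriched term
    (directly or via a descendant), which get u**(1 + strength) — smaller
    scores for positive strengths, uniform again at strength 0.
    """
    if max_depth < 2:
        raise ValueError("max_depth must be >= 2")
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng([seed, 3])
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    depths = {term_ids[0]: 0}
    edges = []
    for i in range(1, n_terms):
        candidates = [t for t in term_ids[:i] if depths[t] < max_depth]
        n_par = int(rng.integers(1, min(2, len(candidates)) + 1))
        parents = rng.choice(candidates, size=n_par, replace=False)
        for par in parents:
            edges.append((term_ids[i], str(par)))
        depths[term_ids[i]] = 1 + max(depths[str(par)] for par in parents)
    if edges:
        dag = GODag.from_edges(edges)
    else:
        g = nx.DiGraph()
        g.add_node(term_ids[0])
        dag = GODag(graph=g)

    direct: dict[str, set[str]] = {}
    for gene in genes:
        mask = rng.random(n_terms) < annotation_density
        terms = {t for t, m in zip(term_ids, mask) if m}
        if terms:
            direct[gene] = terms

    # genes reachable from each enriched term (term itself or descendants)
    scores = {g: float(u) for g, u in zip(genes, rng.random(len(genes)))}
    for term, strength in enriched_terms or []:
        if term not in dag.graph:
            raise ValueError(f"enriched term {term!r} not in DAG")
        # edges point child->parent, so graph-ancestors are DAG descendants
        covered = {term} | set(nx.ancestors(dag.graph, term))
        for gene, tset in direct.items():
            if tset & covered:
                scores[gene] = scores[gene] ** (1.0 + strength)
    return dag, direct, scores
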