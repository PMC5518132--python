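"""Dirichlet-multinomial simulator for pooled CRISPR screen counts.

Read counts under one condition are modeled as a multinomial draw over
sgRNA categories whose probability vector is itself Dirichlet-distributed —
a Dirichlet-multinomial (DM) with intensity parameters gamma_ij. Relative
to a plain multinomial, the DM variance is inflated by the factor
(Y_i+ + gamma_i+)/(1 + gamma_i+): for fixed sequencing depth Y_i+, a smaller
total intensity gamma_i+ means more overdispersion, which is how NGS count
noise beyond Poisson/multinomial is emulated.

Control intensities gamma_0j come from a zero-truncated negative binomial
NB(q, p) (right-skewed library abundances); the treatment intensity is
linked to the sgRNA effect through gamma_ij = exp(alpha_j + beta_j * i),
i.e. gamma_1j = gamma_0j * exp(beta_j). True-hit genes draw their sgRNA
effects beta_j ~ N(mu_g, sigma^2), sign-forced to match mu_g; null genes
have beta_j = 0; a configurable fraction of sgRNAs is replaced by zero-mean
off-target effects. Ground truth is recorded alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .screen_io import ScreenCountTable

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedScreen",
    "draw_gamma0",
    "draw_effects",
    "draw_dm_counts",
    "simulate_screen",
]

DEFAULT_MU_LEVELS = (1.5, 1.0, 0.5, -1.0, -2.0, -3.0)
DEFAULT_COVERAGE = 300  # reads per sgRNA per condition when depth is unset


@dataclass
class SimulationConfig:
    """Parameters of one simulated screen experiment.

    Attributes
    ----------
    n_genes : int
        G, the library size in genes (default 10,000, genome scale).
    sgrnas_per_gene : int
        Guides per gene (screens typically carry 2-6).
    mu_levels : tuple of float
        Gene-effect means mu_g; positive values are genes whose knockout
        promotes growth (positive selection), negative values are genes
        required for growth (negative selection). The default
        (1.5, 1, 0.5, -1, -2, -3) spans high/medium/low effects per sign.
    genes_per_level : int
        True-hit genes drawn at each mu level (default 50, so the default
        grid yields 150 positively and 150 negatively selected genes).
    sigma : float
        SD of sgRNA effects around their gene mean, and of off-target
        effects around 0 (default 0.4, on the natural-log scale).
    nb_q, nb_p : number of successes / success probability of the NB(q, p)
        generating the control intensities (defaults 3 and 0.08 give a
        right-skewed library with mean intensity about 34.5).
    off_target_rate : float
        Fraction of sgRNAs, selected library-wide, whose effect is replaced
        by an N(0, sigma^2) off-target draw.
    depth : int or None
        Total reads per condition Y_i+; None means 300 reads of coverage
        per sgRNA (depth = 300 * J).
    overdispersion_divisor : float
        d >= 1; every gamma_ij is divided by d before sampling, lowering
        gamma_i+ and hence raising overdispersion (d = 10 is the
        high-overdispersion setting, d = 5 the low-quality replicate
        setting).
    n_replicates : int
        Replicate screens sharing one truth table and one intensity vector,
        differing only in DM sampling noise.
    seed : int or None
        Master seed; a fixed seed reproduces the screen exactly.
    """

    n_genes: int = 10_000
    sgrnas_per_gene: int = 3
    mu_levels: tuple[float, ...] = DEFAULT_MU_LEVELS
    genes_per_level: int = 50
    sigma: float = 0.4
    nb_q: int = 3
    nb_p: float = 0.08
    off_target_rate: float = 0.0
    depth: int | None = None
    overdispersion_divisor: float = 1.0
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.mu_levels = tuple(float(m) for m in self.mu_levels)
        if self.n_genes < len(self.mu_levels) * self.genes_per_level:
            raise ValueError("n_genes too small for the requested true hits")
        if self.sgrnas_per_gene < 1:
            raise ValueError("sgrnas_per_gene must be >= 1")
        if not 0 <= self.off_target_rate <= 1:
            raise ValueError("off_target_rate must be in [0, 1]")
        if self.nb_q < 1 or not 0 < self.nb_p < 1:
            raise ValueError("require nb_q >= 1 and 0 < nb_p < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.overdispersion_divisor <= 0:
            raise ValueError("overdispersion_divisor must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.depth is not None and self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene

    def resolved_depth(self) -> int:
        return self.depth if self.depth is not None else DEFAULT_COVERAGE * self.n_sgrnas

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mu_levels"] = list(self.mu_levels)
        return d


@dataclass
class TruthTable:
    """Ground truth of a simulated screen.

    Per gene: selection direction ("positive", "negative" or "null") and
    effect mean mu_g. Per sgRNA: baseline log-intensity alpha_j, effect
    beta_j, and whether the effect was replaced by an off-target draw.
    """

    gene_ids: np.ndarray        # G unique gene labels
    direction: np.ndarray       # per gene
    mu: np.ndarray              # per gene
    sgrna_gene: np.ndarray      # per sgRNA: owning gene label
    alpha: np.ndarray           # per sgRNA, filled by simulate_screen
    beta: np.ndarray            # per sgRNA
    off_target: np.ndarray      # per sgRNA, bool

    def genes_of(self, direction: str) -> np.ndarray:
        return self.gene_ids[self.direction == direction]

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Gene": self.gene_ids, "direction": self.direction, "mu": self.mu}
        )

    def sgrna_frame(self, sgrna_ids: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgRNA": sgrna_ids,
                "Gene": self.sgrna_gene,
                "alpha": self.alpha,
                "beta": self.beta,
                "off_target": self.off_target,
            }
        )


@dataclass
class SimulatedScreen:
    """Simulated counts plus ground truth and the DM intensities used."""

    tables: list[ScreenCountTable]
    truth: TruthTable
    gamma0: np.ndarray
    gamma1: np.ndarray
    config: SimulationConfig

    @property
    def table(self) -> ScreenCountTable:
        return self.tables[0]


def draw_gamma0(
    n_sgrnas: int, q: int, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw control intensities from a zero-truncated NB(q, p).

    Counts follow the failures-before-the-q-th-success convention (mean
    q(1-p)/p); zero draws are resampled until positive because the
    intensities parameterize a Dirichlet, which requires gamma > 0. At the
    default (3, 0.08) zeros are rare and the truncation shifts the mean
    negligibly.
    """
    if q < 1 or not 0 < p < 1:
        raise ValueError("require q >= 1 and 0 < p < 1")
    gamma = rng.negative_binomial(q, p, size=n_sgrnas).astype(float)
    while True:
        zero = gamma == 0
        if not zero.any():
            return gamma
        gamma[zero] = rng.negative_binomial(q, p, size=int(zero.sum()))


def draw_effects(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    """Assign true-hit genes and draw per-sgRNA effects.

    ``genes_per_level`` genes are assigned uniformly at random (without
    replacement, anywhere in the library) to each mu level; their sgRNA
    effects are N(mu_g, sigma^2) draws reflected to the sign of mu_g, so a
    knockout's guides all push the same way. Null genes get beta = 0.
    Finally a fraction ``off_target_rate`` of all sgRNAs — hit and null
    genes alike — have beta replaced by fresh N(0, sigma^2) draws and are
    flagged as off-target.
    """
    G, n = config.n_genes, config.sgrnas_per_gene
    width = len(str(G))
    gene_ids = np.array([f"gene_{i:0{width}d}" for i in range(1, G + 1)], dtype=object)

    mu = np.zeros(G)
    direction = np.full(G, "null", dtype=object)
    n_true = len(config.mu_levels) * config.genes_per_level
    true_idx = rng.choice(G, size=n_true, replace=False)
    for k, level in enumerate(config.mu_levels):
        idx = true_idx[k * config.genes_per_level : (k + 1) * config.genes_per_level]
        mu[idx] = level
        direction[idx] = "positive" if level > 0 else "negative"

    sgrna_gene = np.repeat(gene_ids, n)
    mu_per_sgrna = np.repeat(mu, n)
    beta = np.zeros(G * n)
    hit = mu_per_sgrna != 0
    raw = rng.normal(mu_per_sgrna[hit], config.sigma)
    beta[hit] = np.sign(mu_per_sgrna[hit]) * np.abs(raw)

    off_target = np.zeros(G * n, dtype=bool)
    n_off = int(round(config.off_target_rate * G * n))
    if n_off > 0:
        off_idx = rng.choice(G * n, size=n_off, replace=False)
        beta[off_idx] = rng.normal(0.0, config.sigma, size=n_off)
        off_target[off_idx] = True

    return TruthTable(
        gene_ids=gene_ids,
        direction=np.asarray(direction),
        mu=mu,
        sgrna_gene=sgrna_gene,
        alpha=np.full(G * n, np.nan),
        beta=beta,
        off_target=off_target,
    )


def draw_dm_counts(
    gamma: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet-multinomial draw: counts over sgRNAs summing to depth."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("all Dirichlet intensities must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    probs = rng.dirichlet(gamma)
    # guard against floating underflow producing a non-normalized vector
    probs = probs / probs.sum()
    return rng.multinomial(depth, probs)


def simulate_screen(config: SimulationConfig | None = None) -> SimulatedScreen:
    """Generate a full screen: intensities, truth, and replicate counts.

    gamma_0 is drawn once, effects are drawn once, gamma_1j =
    gamma_0j * exp(beta_j) exactly; both intensity vectors are divided by
    the overdispersion divisor; each replicate then takes independent DM
    draws for control and treatment at the configured depth.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    J = config.n_sgrnas
    depth = config.resolved_depth()

    gamma0 = draw_gamma0(J, config.nb_q, config.nb_p, rng)
    truth = draw_effects(config, rng)
    truth.alpha = np.log(gamma0)
    gamma1 = gamma0 * np.exp(truth.beta)

    d = config.overdispersion_divisor
    gamma0_eff = gamma0 / d
    gamma1_eff = gamma1 / d

    width = len(str(J))
    sgrna_ids = np.array(
        [f"sg_{i:0{width}d}" for i in range(1, J + 1)], dtype=object
    )
    tables = []
    for s in range(1, config.n_replicates + 1):
        y0 = draw_dm_counts(gamma0_eff, depth, rng)
        y1 = draw_dm_counts(gamma1_eff, depth, rng)
        tables.append(
            ScreenCountTable(
                sgrna_ids=sgrna_ids,
                gene_ids=truth.sgrna_gene,
                control=y0,
                treatment=y1,
                replicate_id=s if config.n_replicates > 1 else None,
            )
        )
    return SimulatedScreen(
        tables=tables, truth=truth, gamma0=gamma0_eff, gamma1=gamma1_eff,
        config=config,
    )
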