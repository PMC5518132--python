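"""The PBNPA test: permutation-based non-parametric analysis of screens.

Given per-sgRNA read counts under a control and a treatment condition, the
test scores each gene by the median natural-log fold change of its sgRNAs
(robust to outlying guides and off-target effects) and assesses significance
against a *common* permutation null: gene labels are shuffled across sgRNAs
while (control, treatment) count pairs stay glued together, gene medians are
recomputed, and the scores from all genes and all T permutations are pooled
into one null multiset of size G x T. A second round rebuilds the null with
first-round significant genes removed, so strong hits do not contaminate it.
One-sided empirical p-values (enrichment = positive selection, depletion =
negative selection) are floored at 1/(null size + 1) and BH-adjusted
separately per direction. Replicates are analyzed independently and combined
per gene with Fisher's method (chi-square with 2S degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen_io import ScreenCountTable

__all__ = [
    "PBNPAConfig",
    "NormalizedCounts",
    "GeneScores",
    "NullDistribution",
    "GeneInference",
    "PBNPAResult",
    "normalize",
    "log_fold_changes",
    "gene_scores",
    "permuted_null",
    "empirical_p",
    "bh_adjust",
    "fisher_combine",
    "pbnpa",
    "pbnpa_replicates",
]


@dataclass
class PBNPAConfig:
    """Tuning parameters of the permutation test.

    Attributes
    ----------
    n_permutations : int
        T, the number of label permutations pooled into the common null
        (null size = G x T). Default 10: with genome-scale libraries
        (G ~ 10,000) this already gives a 100,000-value null; small custom
        libraries need a larger T for p-value resolution.
    removal_threshold : float
        Unadjusted first-round p-value below which (in either direction) a
        gene is excluded from the second-round null construction.
    pseudocount : float
        Added to every raw count before normalization so log fold changes
        are finite for sgRNAs with zero reads.
    fdr_level : float
        BH level used when reporting significant genes.
    seed : int or None
        Seed for the permutation RNG; fixing it makes results bit-identical.
    """

    n_permutations: int = 10
    removal_threshold: float = 0.05
    pseudocount: float = 1.0
    fdr_level: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.removal_threshold < 1:
            raise ValueError("removal_threshold must be in [0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


@dataclass
class NormalizedCounts:
    """Depth-normalized counts; the two condition totals are equal."""

    control: np.ndarray
    treatment: np.ndarray
    factors: tuple[float, float]


@dataclass
class GeneScores:
    """Per-sgRNA log fold changes r_j and per-gene median scores R_g."""

    gene_ids: np.ndarray  # unique genes, order of first appearance
    r: np.ndarray         # per sgRNA
    R: np.ndarray         # per gene


@dataclass
class NullDistribution:
    """Pooled multiset of permuted gene scores forming the common null."""

    values: np.ndarray

    @property
    def size(self) -> int:
        return len(self.values)


@dataclass
class GeneInference:
    """Final per-gene report: score, one-sided p-values, BH q-values."""

    gene_id: str
    R: float
    p_pos: float
    p_neg: float
    fdr_pos: float
    fdr_neg: float
    removed_round1: bool


@dataclass
class PBNPAResult:
    """Sequence of :class:`GeneInference` plus run diagnostics."""

    genes: list[GeneInference]
    null_size_round1: int
    null_size_round2: int
    n_removed_round1: int

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, i):
        return self.genes[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Gene": [g.gene_id for g in self.genes],
                "R": [g.R for g in self.genes],
                "p.pos": [g.p_pos for g in self.genes],
                "fdr.pos": [g.fdr_pos for g in self.genes],
                "p.neg": [g.p_neg for g in self.genes],
                "fdr.neg": [g.fdr_neg for g in self.genes],
                "removed.round1": [g.removed_round1 for g in self.genes],
            }
        )


# ---------------------------------------------------------------------------
# elementary operations


def normalize(table: ScreenCountTable, pseudocount: float = 1.0) -> NormalizedCounts:
    """Equalize sequencing depth between the two conditions.

    The pseudocount is added to every raw count first; condition i is then
    scaled by mean(total_0, total_1) / total_i, which makes the two totals
    equal without discarding information.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    y0 = table.control.astype(float) + pseudocount
    y1 = table.treatment.astype(float) + pseudocount
    t0, t1 = y0.sum(), y1.sum()
    if t0 <= 0 or t1 <= 0:
        raise ValueError(
            "a condition has zero total count after the pseudocount; "
            "the library is degenerate"
        )
    m = 0.5 * (t0 + t1)
    f0, f1 = m / t0, m / t1
    return NormalizedCounts(control=y0 * f0, treatment=y1 * f1, factors=(f0, f1))


def log_fold_changes(norm: NormalizedCounts) -> np.ndarray:
    """r_j = ln(Y_1j / Y_0j) on normalized counts; all values finite."""
    if np.any(norm.control <= 0) or np.any(norm.treatment <= 0):
        raise ValueError(
            "normalized counts must be strictly positive; use a pseudocount "
            "> 0 when raw counts contain zeros"
        )
    return np.log(norm.treatment) - np.log(norm.control)


class _GeneBlocks:
    """Stable gene grouping of the sgRNA axis, with fast grouped medians.

    Genes are ordered by first appearance. ``order`` sorts sgRNAs into
    contiguous per-gene blocks whose lengths are ``sizes``; a grouped median
    of any sgRNA-length vector is then a set of block medians, vectorized
    over genes sharing a block size.
    """

    def __init__(self, gene_ids: Sequence[str]):
        codes, uniques = pd.factorize(np.asarray(gene_ids, dtype=object))
        self.gene_ids = np.asarray(uniques, dtype=object)
        self.sizes = np.bincount(codes)
        self.order = np.argsort(codes, kind="stable")
        self._offsets = np.concatenate(([0], np.cumsum(self.sizes)))
        # genes grouped by block size, for vectorized medians
        self._by_size = [
            (s, np.flatnonzero(self.sizes == s)) for s in np.unique(self.sizes)
        ]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def grouped_median(self, blocked: np.ndarray) -> np.ndarray:
        """Median per gene of a vector already laid out in gene blocks."""
        out = np.empty(self.n_genes)
        for s, idx in self._by_size:
            rows = self._offsets[idx][:, None] + np.arange(s)
            out[idx] = np.median(blocked[rows], axis=1)
        return out

    def observed_scores(self, r: np.ndarray) -> np.ndarray:
        return self.grouped_median(r[self.order])


def gene_scores(r: np.ndarray, gene_ids: Sequence[str]) -> GeneScores:
    """Score each gene by the median of its sgRNAs' log fold changes.

    The median (even cardinality: midpoint of the two central values) makes
    the gene score robust to a single outlying or off-target sgRNA.
    """
    blocks = _GeneBlocks(gene_ids)
    return GeneScores(gene_ids=blocks.gene_ids, r=np.asarray(r, dtype=float),
                      R=blocks.observed_scores(np.asarray(r, dtype=float)))


def permuted_null(
    r: np.ndarray,
    gene_ids: Sequence[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> NullDistribution:
    """Build the common null by permuting gene labels T times.

    Each permutation uniformly shuffles the gene-label vector across sgRNAs
    while keeping each sgRNA's (control, treatment) pair — hence its r_j —
    intact; the multiset of gene sizes is preserved. All G x T permuted
    gene medians are pooled into a single null shared by every gene.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    blocks = _GeneBlocks(gene_ids)
    r = np.asarray(r, dtype=float)
    pooled = np.empty((n_permutations, blocks.n_genes))
    for t in range(n_permutations):
        pooled[t] = blocks.grouped_median(rng.permutation(r))
    return NullDistribution(values=pooled.ravel())


def empirical_p(
    R: np.ndarray | float, null: NullDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided empirical p-values of gene scores against the common null.

    p_pos is the fraction of null values strictly greater than R_g, p_neg
    the fraction strictly smaller; ties count toward neither tail. Both are
    floored at 1/(size + 1) so that no gene reports p = 0, which a finite
    permutation null cannot justify and which would break Fisher combination.
    """
    if null.size == 0:
        raise ValueError("null distribution is empty")
    sorted_null = np.sort(null.values)
    R_arr = np.atleast_1d(np.asarray(R, dtype=float))
    n = sorted_null.size
    p_pos = (n - np.searchsorted(sorted_null, R_arr, side="right")) / n
    p_neg = np.searchsorted(sorted_null, R_arr, side="left") / n
    floor = 1.0 / (n + 1)
    p_pos = np.maximum(p_pos, floor)
    p_neg = np.maximum(p_neg, floor)
    if np.isscalar(R) or np.ndim(R) == 0:
        return float(p_pos[0]), float(p_neg[0])
    return p_pos, p_neg


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in (0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(p_matrix: np.ndarray) -> np.ndarray:
    """Combine replicate p-values per gene with Fisher's method.

    For gene g with p-values p_g1..p_gS from S independently analyzed
    replicates, the statistic -2 * sum_s ln(p_gs) follows a chi-square
    distribution with 2S degrees of freedom under the null of no effect;
    the combined p-value is its upper-tail probability.
    """
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if p.shape[1] < 1:
        raise ValueError("need at least one replicate")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]; p = 0 is not allowed")
    statistic = -2.0 * np.log(p).sum(axis=1)
    return stats.chi2.sf(statistic, df=2 * p.shape[1])


# ---------------------------------------------------------------------------
# full procedure


def pbnpa(table: ScreenCountTable, config: PBNPAConfig | None = None) -> PBNPAResult:
    """Run the full two-round permutation test on one replicate.

    Round 1 builds the common null from all genes and flags genes whose
    unadjusted p-value in either direction falls below the removal
    threshold. Round 2 rebuilds the null by permuting labels only among the
    retained genes' sgRNAs (the retained gene-size multiset is preserved),
    which removes the distortion strong hits induce in the null; final
    p-values for *all* genes — including removed ones — are taken against
    this cleaned null, then BH-adjusted separately per direction.
    """
    config = config or PBNPAConfig()
    rng = np.random.default_rng(config.seed)

    norm = normalize(table, config.pseudocount)
    r = log_fold_changes(norm)
    blocks = _GeneBlocks(table.gene_ids)
    R = blocks.observed_scores(r)

    null1 = permuted_null(r, table.gene_ids, config.n_permutations, rng)
    p1_pos, p1_neg = empirical_p(R, null1)
    removed = (p1_pos < config.removal_threshold) | (p1_neg < config.removal_threshold)

    if removed.all():
        # degenerate: nothing left to estimate a null from; keep round 1
        null2 = null1
    else:
        keep_gene = ~removed
        # sgRNAs belonging to retained genes, via the blocked layout
        keep_sgrna_blocked = np.repeat(keep_gene, blocks.sizes)
        r_kept = r[blocks.order][keep_sgrna_blocked]
        genes_kept = np.repeat(blocks.gene_ids[keep_gene], blocks.sizes[keep_gene])
        null2 = permuted_null(r_kept, genes_kept, config.n_permutations, rng)

    p_pos, p_neg = empirical_p(R, null2)
    fdr_pos = bh_adjust(p_pos)
    fdr_neg = bh_adjust(p_neg)

    genes = [
        GeneInference(
            gene_id=blocks.gene_ids[g],
            R=float(R[g]),
            p_pos=float(p_pos[g]),
            p_neg=float(p_neg[g]),
            fdr_pos=float(fdr_pos[g]),
            fdr_neg=float(fdr_neg[g]),
            removed_round1=bool(removed[g]),
        )
        for g in range(blocks.n_genes)
    ]
    return PBNPAResult(
        genes=genes,
        null_size_round1=null1.size,
        null_size_round2=null2.size,
        n_removed_round1=int(removed.sum()),
    )


def pbnpa_replicates(
    tables: Sequence[ScreenCountTable], config: PBNPAConfig | None = None
) -> PBNPAResult:
    """Analyze S replicates independently, then Fisher-combine per gene.

    Each replicate gets its own normalization, permutation null, and
    two-round p-values (seeded independently from ``config.seed``); the
    per-direction p-values are then combined across replicates with
    Fisher's method and BH is applied to the combined values. All
    replicates must share the same sgRNA/gene universe. The reported R is
    the mean of the per-replicate gene scores.
    """
    config = config or PBNPAConfig()
    if not tables:
        raise ValueError("need at least one replicate")
    ref = tables[0]
    for t in tables[1:]:
        if not (
            np.array_equal(t.sgrna_ids, ref.sgrna_ids)
            and np.array_equal(t.gene_ids, ref.gene_ids)
        ):
            raise ValueError(
                "replicates must share an identical sgRNA -> gene universe; "
                "Fisher combination assumes the same genes in every replicate"
            )
    seeds = np.random.SeedSequence(config.seed).spawn(len(tables))
    results = []
    for t, ss in zip(tables, seeds):
        rep_config = PBNPAConfig(
            n_permutations=config.n_permutations,
            removal_threshold=config.removal_threshold,
            pseudocount=config.pseudocount,
            fdr_level=config.fdr_level,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        results.append(pbnpa(t, rep_config))
    if len(results) == 1:
        return results[0]

    p_pos = np.column_stack([[g.p_pos for g in res] for res in results])
    p_neg = np.column_stack([[g.p_neg for g in res] for res in results])
    R_mean = np.column_stack([[g.R for g in res] for res in results]).mean(axis=1)
    comb_pos = np.clip(fisher_combine(p_pos), np.finfo(float).tiny, 1.0)
    comb_neg = np.clip(fisher_combine(p_neg), np.finfo(float).tiny, 1.0)
    fdr_pos = bh_adjust(comb_pos)
    fdr_neg = bh_adjust(comb_neg)
    gene_ids = [g.gene_id for g in results[0]]
    removed_any = np.any(
        np.column_stack([[g.removed_round1 for g in res] for res in results]), axis=1
    )
    genes = [
        GeneInference(
            gene_id=gene_ids[g],
            R=float(R_mean[g]),
            p_pos=float(comb_pos[g]),
            p_neg=float(comb_neg[g]),
            fdr_pos=float(fdr_pos[g]),
            fdr_neg=float(fdr_neg[g]),
            removed_round1=bool(removed_any[g]),
        )
        for g in range(len(gene_ids))
    ]
    return PBNPAResult(
        genes=genes,
        null_size_round1=results[0].null_size_round1,
        null_size_round2=results[0].null_size_round2,
        n_removed_round1=int(removed_any.sum()),
    )
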