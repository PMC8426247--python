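"""Negative-binomial RNA-seq count tables with planted expression patterns.

The design mirrors the four-genotype, three-replicate wing-disc
experiment: genotype means follow a planted (up/down/none) triple applied
cumulatively along the genotype chain wt -> ASH1WT -> dBAH -> dBAHmutAT1,
multiplying by ``effect_fold`` (up) or ``1/effect_fold`` (down).  A
configurable share of short (< 200 bp) and near-zero-expression genes is
planted to exercise the downstream filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GENOTYPES", "CountSimParams", "CountTruth", "generate_count_table"]

GENOTYPES = ("wt", "ASH1WT", "dBAH", "dBAHmutAT1")
N_REPLICATES = 3
CALLS = ("down", "none", "up")


@dataclass(frozen=True)
class CountSimParams:
    """Parameters of a synthetic count table."""

    n_genes: int = 500
    genotypes: tuple = GENOTYPES
    replicates: int = N_REPLICATES
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05     # var = mu + disp * mu^2
    effect_fold: float = 4.0
    pattern_counts: dict = field(default_factory=dict)  # {(c1,c2,c3): n_genes}
    short_gene_frac: float = 0.0    # planted genes with length < 200 bp
    low_expr_frac: float = 0.0      # planted near-zero-expression genes
    gene_length_range: tuple = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates != N_REPLICATES:
            raise ValueError("the design is fixed at three replicates")
        if len(self.genotypes) != 4:
            raise ValueError("the design is fixed at four genotypes")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        for pat in self.pattern_counts:
            if len(pat) != 3 or any(c not in CALLS for c in pat):
                raise ValueError(f"invalid pattern {pat!r}")
        if sum(self.pattern_counts.values()) > self.n_genes:
            raise ValueError("more planted patterned genes than genes")
        if self.short_gene_frac + self.low_expr_frac > 1:
            raise ValueError("planted filter fractions exceed 1")


@dataclass
class CountTruth:
    """Ground truth of a generated count table."""

    params: CountSimParams
    patterns: list          # per-gene (c1, c2, c3) triples
    genotype_means: np.ndarray  # (n_genes, 4) expected counts
    planted_short: np.ndarray   # boolean masks
    planted_low: np.ndarray


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    if disp < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / disp
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_count_table(params: CountSimParams) -> tuple[pd.DataFrame, CountTruth]:
    """Generate a gene x sample count table with its ground truth.

    Returns a DataFrame with columns ``gene_id``, ``length`` and one
    count column per ``<genotype>_r<replicate>`` sample.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes

    patterns: list[tuple[str, str, str]] = [("none", "none", "none")] * n
    idx = 0
    for pat, count in params.pattern_counts.items():
        for _ in range(count):
            patterns[idx] = tuple(pat)
            idx += 1

    n_short = int(round(params.short_gene_frac * n))
    n_low = int(round(params.low_expr_frac * n))
    # filter-fodder genes are appended after the patterned block; disjoint
    if idx + n_short + n_low > n:
        raise ValueError("not enough genes for the planted filter classes")
    planted_short = np.zeros(n, dtype=bool)
    planted_low = np.zeros(n, dtype=bool)
    planted_short[idx : idx + n_short] = True
    planted_low[idx + n_short : idx + n_short + n_low] = True

    lo, hi = params.gene_length_range
    lengths = rng.integers(max(lo, 200), hi, size=n)
    lengths[planted_short] = rng.integers(50, 200, size=n_short)

    base = rng.gamma(4.0, params.baseline_mean / 4.0, size=n)  # gene-level spread
    base[planted_low] = 5e-4  # essentially silent in every sample
    mult = {"up": params.effect_fold, "down": 1.0 / params.effect_fold, "none": 1.0}
    means = np.empty((n, 4))
    means[:, 0] = base
    for j in range(3):
        step = np.array([mult[patterns[i][j]] for i in range(n)])
        means[:, j + 1] = means[:, j] * step

    data = {"gene_id": [f"gene{i:05d}" for i in range(n)], "length": lengths}
    for j, g in enumerate(params.genotypes):
        for r in range(1, params.replicates + 1):
            data[f"{g}_r{r}"] = _nb_draw(rng, means[:, j], params.nb_dispersion)
    table = pd.DataFrame(data)
    truth = CountTruth(
        params=params,
        patterns=patterns,
        genotype_means=means,
        planted_short=planted_short,
        planted_low=planted_low,
    )
    return table, truth
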