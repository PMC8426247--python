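"""Genetic-rescue scoring for balanced-heterozygote intercrosses.

A transgene's ability to rescue a lethal transheterozygous allele
combination is scored from the adult progeny of mut1/TM3 x mut2/TM3
crosses: balancer homozygotes die, so with full rescue one third of
scored adults carry the transheterozygous combination.  "Full rescue"
(100%) is defined as the observed transheterozygote fraction reaching
that expected 1/3.  Homeotic-phenotype frequencies (ectopic bristle on
the third leg) are compared between lines with two-sided Fisher exact
tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CrossCounts",
    "RescueScore",
    "PhenotypeLine",
    "EXPECTED_TRANSHET_FRACTION",
    "enumerate_intercross",
    "expected_survivor_fractions",
    "rescue_percent",
    "phenotype_frequency_test",
    "fisher_exact_enumeration",
    "score_simulated_cross",
]

EXPECTED_TRANSHET_FRACTION = 1.0 / 3.0  # exact value behind the quoted "33%"


@dataclass
class CrossCounts:
    """Scored adult progeny of one intercross."""

    n_balanced_mut1: int
    n_balanced_mut2: int
    n_transhet: int
    line_label: str = ""

    def __post_init__(self) -> None:
        for f in (self.n_balanced_mut1, self.n_balanced_mut2, self.n_transhet):
            if f < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_total_scored(self) -> int:
        return self.n_balanced_mut1 + self.n_balanced_mut2 + self.n_transhet


@dataclass
class RescueScore:
    observed_transhet_fraction: float
    expected_fraction: float
    percent_rescue: float
    line_label: str = ""


@dataclass
class PhenotypeLine:
    """Bristle-phenotype scoring of one rescued line."""

    line_label: str
    n_flies_scored: int
    n_with_bristle: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_with_bristle <= self.n_flies_scored:
            raise ValueError("bristle count exceeds flies scored")


def enumerate_intercross() -> dict[str, float]:
    """Exhaustively enumerate the Punnett square of mut1/TM3 x mut2/TM3.

    Each parent transmits its two chromosomes with equal probability;
    the four zygote classes are therefore equiprobable.  Serves as the
    brute-force oracle for :func:`expected_survivor_fractions`.
    """
    probs: dict[str, float] = {}
    for g1 in ("mut1", "TM3"):
        for g2 in ("mut2", "TM3"):
            geno = "/".join(sorted((g1, g2)))
            probs[geno] = probs.get(geno, 0.0) + 0.25
    return probs


def expected_survivor_fractions(transhet_viability: float = 1.0) -> dict[str, float]:
    """Expected adult class fractions after balancer-homozygote lethality.

    (balanced1, balanced2, transhet) = (1, 1, v) / (2 + v); at full
    viability the transheterozygote fraction is exactly 1/3.
    """
    if not 0 <= transhet_viability <= 1:
        raise ValueError("viability must lie in [0, 1]")
    v = transhet_viability
    z = 2.0 + v
    return {"balanced_mut1": 1.0 / z, "balanced_mut2": 1.0 / z, "transhet": v / z}


def rescue_percent(counts: CrossCounts) -> RescueScore:
    """Percent rescue: 100 x (observed transhet fraction) / (1/3).

    Sampling noise can push the value above 100%; values above 120%
    trigger a data-quality warning rather than a cap.
    """
    total = counts.n_total_scored
    if total == 0:
        raise ZeroDivisionError("no scored progeny")
    obs = counts.n_transhet / total
    pct = 100.0 * obs / EXPECTED_TRANSHET_FRACTION
    if pct > 120.0:
        warnings.warn(
            f"percent rescue {pct:.1f}% exceeds 120%: check genotype scoring"
        )
    return RescueScore(
        observed_transhet_fraction=obs,
        expected_fraction=EXPECTED_TRANSHET_FRACTION,
        percent_rescue=pct,
        line_label=counts.line_label,
    )


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    hypergeometric probability does not exceed that of the observed
    table (with a small relative tolerance for ties).  Independent
    brute-force oracle for the library implementation.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def phenotype_frequency_test(
    lines: list[PhenotypeLine], reference: str
) -> dict[str, dict]:
    """Two-sided Fisher exact test of each line's bristle frequency
    against the reference line.

    Stars follow the figure-legend thresholds:
    * p < 0.01, ** p < 0.005, **** p < 0.0005.
    """
    by_label = {ln.line_label: ln for ln in lines}
    if reference not in by_label:
        raise KeyError(f"reference line {reference!r} missing")
    ref = by_label[reference]
    if ref.n_flies_scored == 0:
        raise ValueError("empty reference line")
    out: dict[str, dict] = {}
    for ln in lines:
        if ln.line_label == reference:
            continue
        if ln.n_flies_scored == 0:
            raise ValueError(f"empty line {ln.line_label!r}")
        table = [
            [ln.n_with_bristle, ln.n_flies_scored - ln.n_with_bristle],
            [ref.n_with_bristle, ref.n_flies_scored - ref.n_with_bristle],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        if p < 0.0005:
            stars = "****"
        elif p < 0.005:
            stars = "**"
        elif p < 0.01:
            stars = "*"
        else:
            stars = ""
        out[ln.line_label] = {
            "p": float(p),
            "stars": stars,
            "frequency": ln.n_with_bristle / ln.n_flies_scored,
            "reference_frequency": ref.n_with_bristle / ref.n_flies_scored,
        }
    return out


def score_simulated_cross(params, n_seeds: int = 50) -> dict:
    """Simulate ``n_seeds`` independent crosses and summarize percent
    rescue (mean, SD and a normal-approximation 95% CI of the mean)."""
    from .simulate.cross import generate_cross  # local import: avoid cycle

    from dataclasses import replace

    vals = []
    for k in range(n_seeds):
        counts = generate_cross(replace(params, seed=params.seed + k))
        if counts.n_total_scored == 0:
            continue
        vals.append(rescue_percent(counts).percent_rescue)
    arr = np.asarray(vals)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    half = 1.96 * sd / np.sqrt(arr.size) if arr.size > 1 else 0.0
    return {"mean": mean, "sd": sd, "ci95": (mean - half, mean + half), "n": int(arr.size)}
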