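"""Multinomial progeny of a balanced-heterozygote intercross.

Zygotes from mut1/TM3 x mut2/TM3 occur at (1/4, 1/4, 1/4, 1/4) over
{TM3/TM3, mut1/TM3, mut2/TM3, mut1/mut2}.  Balancer homozygotes
(TM3/TM3) die; the transheterozygous class survives with probability
``transhet_viability`` (the rescue strength of the transgene under
test).  Returns the scored adult counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..rescue import CrossCounts

__all__ = ["CrossSimParams", "generate_cross"]


@dataclass(frozen=True)
class CrossSimParams:
    n_zygotes: int = 1200
    transhet_viability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zygotes < 1:
            raise ValueError("need at least one zygote")
        if not 0 <= self.transhet_viability <= 1:
            raise ValueError("viability must lie in [0, 1]")


def generate_cross(params: CrossSimParams, line_label: str = "") -> CrossCounts:
    """Simulate one intercross and return the surviving adult counts."""
    rng = np.random.default_rng(params.seed)
    zygotes = rng.multinomial(params.n_zygotes, [0.25, 0.25, 0.25, 0.25])
    # zygotes = [TM3/TM3, mut1/TM3, mut2/TM3, mut1/mut2]; balancer homozygotes die
    transhet = rng.binomial(zygotes[3], params.transhet_viability)
    return CrossCounts(
        n_balanced_mut1=int(zygotes[1]),
        n_balanced_mut2=int(zygotes[2]),
        n_transhet=int(transhet),
        line_label=line_label,
    )
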