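"""RNA-seq downstream analysis: RPKM, gene filters, pairwise
fold-change/t-test comparisons, and the category decision tree.

The design is four genotypes (wt, ASH1WT, dBAH, dBAHmutAT1) with three
replicates each.  After computing RPKM, genes shorter than 200 bp and
genes whose summed per-genotype mean RPKM is below 1.0 are removed (both
classes give false positives from a handful of reads).  Each retained
gene is then classified by the ordered triple of fold-change calls over
the adjacent genotype comparisons (wt -> ASH1WT, ASH1WT -> dBAH,
dBAH -> dBAHmutAT1): up if the mean RPKM ratio exceeds twofold, down if
below half, else none.  Category counts are reported at two
stringencies: the total (fold change only) and the strict count, which
additionally requires p < 0.01 (two-sample t test over the three
replicates) on every non-"none" comparison of the pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simulate.counts import GENOTYPES, N_REPLICATES

__all__ = [
    "GENOTYPES",
    "CHAIN_COMPARISONS",
    "CATEGORY_IDS",
    "FILTERED_CATEGORY",
    "compute_rpkm",
    "filter_genes",
    "pairwise_comparison",
    "categorize",
    "category_counts",
    "volcano_data",
    "load_supplementary_table",
    "categorize_table",
]

# The three adjacent comparisons of the genotype chain, in order.
CHAIN_COMPARISONS = (("wt", "ASH1WT"), ("ASH1WT", "dBAH"), ("dBAH", "dBAHmutAT1"))

FILTERED_CATEGORY = 16  # short / lowly expressed genes

# Category ids for all 27 (up/down/none)^3 patterns.  Four anchors are
# fixed by the published scheme; the remaining 23 patterns take stable
# ids from the unused pool {1,4,5,7..14,17..28} in lexicographic order
# (down < none < up).
_ANCHORS = {
    ("none", "none", "down"): 2,
    ("none", "down", "none"): 3,
    ("up", "none", "none"): 6,
    ("none", "none", "none"): 15,
}
_POOL = [1, 4, 5, 7, 8, 9, 10, 11, 12, 13, 14] + list(range(17, 29))


def _build_category_ids() -> dict[tuple[str, str, str], int]:
    ids = dict(_ANCHORS)
    pool = iter(_POOL)
    for pat in itertools.product(("down", "none", "up"), repeat=3):
        if pat not in ids:
            ids[pat] = next(pool)
    return ids


CATEGORY_IDS: dict[tuple[str, str, str], int] = _build_category_ids()


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _sample_columns(genotypes=GENOTYPES, replicates=N_REPLICATES) -> list[str]:
    return [f"{g}_r{r}" for g in genotypes for r in range(1, replicates + 1)]


@dataclass
class ExpressionAnalysis:
    """Bundle of all per-gene outputs of the categorization pipeline."""

    rpkm: pd.DataFrame
    comparisons: dict[tuple[str, str], pd.DataFrame]
    assignments: pd.DataFrame
    counts: pd.DataFrame


def compute_rpkm(
    table: pd.DataFrame,
    library_sizes: dict[str, float] | None = None,
    genotypes=GENOTYPES,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per sample.

    ``rpkm = 1e9 * count / (length * library_size)``; the library size
    of each sample defaults to its column sum.  Adds per-genotype mean
    columns ``mean_<genotype>``.
    """
    cols = _sample_columns(genotypes)
    missing = [c for c in ["gene_id", "length", *cols] if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if (table["length"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = table[["gene_id", "length"]].copy()
    for c in cols:
        lib = library_sizes[c] if library_sizes else float(table[c].sum())
        if lib <= 0:
            raise ValueError(f"non-positive library size for sample {c}")
        out[c] = 1e9 * table[c] / (table["length"] * lib)
    for g in genotypes:
        out[f"mean_{g}"] = out[[f"{g}_r{r}" for r in range(1, N_REPLICATES + 1)]].mean(axis=1)
    return out


def filter_genes(
    rpkm: pd.DataFrame,
    min_length: int = 200,
    min_rpkm_sum: float = 1.0,
    genotypes=GENOTYPES,
) -> pd.DataFrame:
    """Flag short and lowly expressed genes (strict-inequality rules).

    ``short_gene``: length < 200 bp.  ``low_expression``: the sum of the
    four per-genotype mean RPKMs < 1.0.  ``retained`` is the conjunction
    of neither flag.  Flag computation is order-independent by
    construction (each flag depends only on the unfiltered table).
    """
    out = rpkm.copy()
    out["short_gene"] = out["length"] < min_length
    mean_cols = [f"mean_{g}" for g in genotypes]
    out["low_expression"] = out[mean_cols].sum(axis=1) < min_rpkm_sum
    out["retained"] = ~(out["short_gene"] | out["low_expression"])
    return out


def pairwise_comparison(
    rpkm: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    pseudocount: float = 0.01,
    equal_var: bool = True,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change and t test between two genotypes.

    Fold change is mean(B)/mean(A) of replicate RPKMs after adding a
    small pseudocount; the p-value is a two-sample t test on the three
    replicate RPKM values per genotype (equal-variance by default,
    optionally Welch or on log-scale values).  ``call`` is the
    fold-change-only call (up / down / none, strict inequalities);
    ``significant`` marks p < ``p_threshold``.  Genes with identical
    replicate sets get p = 1 with ``degenerate = True``.
    """
    a_cols = [f"{genotype_a}_r{r}" for r in range(1, N_REPLICATES + 1)]
    b_cols = [f"{genotype_b}_r{r}" for r in range(1, N_REPLICATES + 1)]
    missing = [c for c in a_cols + b_cols if c not in rpkm.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    a = rpkm[a_cols].to_numpy(dtype=float)
    b = rpkm[b_cols].to_numpy(dtype=float)
    mean_a = a.mean(axis=1) + pseudocount
    mean_b = b.mean(axis=1) + pseudocount
    fc = mean_b / mean_a
    ta, tb = (np.log2(a + pseudocount), np.log2(b + pseudocount)) if log_scale else (a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(tb, ta, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    call = np.where(fc > fc_threshold, "up", np.where(fc < 1.0 / fc_threshold, "down", "none"))
    return pd.DataFrame(
        {
            "gene_id": rpkm["gene_id"].to_numpy(),
            "fold_change": fc,
            "p_value": p,
            "call": call,
            "significant": p < p_threshold,
            "degenerate": degenerate,
        }
    )


def categorize(
    comparisons: dict[tuple[str, str], pd.DataFrame],
    retained: pd.Series,
) -> pd.DataFrame:
    """Map each gene's pattern triple to a category id.

    The pattern is the ordered triple of fold-change calls over the
    chain comparisons; the category id comes from :data:`CATEGORY_IDS`.
    Filtered genes receive the dedicated category 16.  ``strict`` is
    True when every non-"none" comparison of the pattern is significant
    (vacuously True for the all-"none" pattern).
    """
    for pair in CHAIN_COMPARISONS:
        if pair not in comparisons:
            raise KeyError(f"missing comparison {pair}")
    first = comparisons[CHAIN_COMPARISONS[0]]
    gene_ids = first["gene_id"].to_numpy()
    calls = np.stack([comparisons[p]["call"].to_numpy() for p in CHAIN_COMPARISONS], axis=1)
    sig = np.stack(
        [comparisons[p]["significant"].to_numpy() for p in CHAIN_COMPARISONS], axis=1
    )
    retained = np.asarray(retained, dtype=bool)
    cat = np.empty(len(gene_ids), dtype=int)
    strict = np.empty(len(gene_ids), dtype=bool)
    for i in range(len(gene_ids)):
        pat = tuple(calls[i])
        if not retained[i]:
            cat[i] = FILTERED_CATEGORY
            strict[i] = False
            continue
        cat[i] = CATEGORY_IDS[pat]
        strict[i] = all(s for c, s in zip(pat, sig[i]) if c != "none")
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "pattern": ["/".join(c) for c in calls],
            "category": cat,
            "strict": strict,
            "retained": retained,
        }
    )


def category_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-category gene counts: strict (p < 0.01 on every relevant
    change) and total, formatted ``"n_strict (n_total)"``.

    Totals over all non-filtered categories sum to the retained gene
    count (the categories partition the retained genes).
    """
    ret = assignments[assignments["retained"]]
    rows = []
    for cat, grp in ret.groupby("category"):
        rows.append(
            {
                "category": int(cat),
                "n_strict": int(grp["strict"].sum()),
                "n_total": int(len(grp)),
                "label": f"{int(grp['strict'].sum())} ({len(grp)})",
            }
        )
    n_filtered = int((~assignments["retained"]).sum())
    if n_filtered:
        rows.append(
            {
                "category": FILTERED_CATEGORY,
                "n_strict": 0,
                "n_total": n_filtered,
                "label": f"0 ({n_filtered})",
            }
        )
    return pd.DataFrame(rows).sort_values("category").reset_index(drop=True)


def volcano_data(comparison: pd.DataFrame, p_floor: float = 1e-300) -> pd.DataFrame:
    """Plot-ready (log2 FC, -log10 p) per gene; infinities clamped."""
    log2fc = np.log2(comparison["fold_change"].to_numpy())
    p = np.clip(comparison["p_value"].to_numpy(), p_floor, 1.0)
    out = pd.DataFrame(
        {
            "gene_id": comparison["gene_id"].to_numpy(),
            "log2_fc": log2fc,
            "neg_log10_p": -np.log10(p),
        }
    )
    out["clamped"] = comparison["p_value"].to_numpy() < p_floor
    return out


def load_supplementary_table(
    path: str | Path, column_map: dict[str, str]
) -> pd.DataFrame:
    """Load a per-gene supplementary table (XLSX or TSV) into the
    canonical schema.

    ``column_map`` maps canonical names (``gene_id``, ``length``, and
    the 12 ``<genotype>_r<replicate>`` sample columns, or per-genotype
    means plus p-values) to the file's column headers.  Raises
    :class:`SchemaError` naming any missing column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep="\t")
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns in {path.name}: {missing}")
    out = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})
    return out


def categorize_table(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    library_sizes: dict[str, float] | None = None,
) -> ExpressionAnalysis:
    """Full pipeline on a count table: RPKM, filters, chain comparisons,
    categories and category counts."""
    rpkm = compute_rpkm(table, library_sizes=library_sizes)
    flagged = filter_genes(rpkm)
    comparisons = {
        pair: pairwise_comparison(
            rpkm, *pair, fc_threshold=fc_threshold, p_threshold=p_threshold
        )
        for pair in CHAIN_COMPARISONS
    }
    assignments = categorize(comparisons, flagged["retained"])
    return ExpressionAnalysis(
        rpkm=flagged,
        comparisons=comparisons,
        assignments=assignments,
        counts=category_counts(assignments),
    )
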