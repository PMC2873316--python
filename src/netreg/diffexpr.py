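"""Paired differential-expression stage.

Produces the transcriptomics 'list of interest' from a paired
lesional/non-lesional intensity matrix: per-sample median normalization, a
paired t-test on per-pair log2 differences (optionally an unpaired
unequal-variance test), Benjamini-Hochberg adjustment, and a strict
fold-change + FDR filter (defaults: fold change > 2.5, q < 0.01).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network_model import GeneSet

__all__ = [
    "PairedExpression",
    "DEResult",
    "read_expression",
    "median_normalize",
    "paired_de_test",
    "de_gene_set",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PairedExpression:
    """Genes x samples intensity matrix with a lesional/non-lesional pair map."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    pair_map: list[tuple[str, str]]  # (lesional, non_lesional)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for les, non in self.pair_map:
            for sid in (les, non):
                if sid not in self.values.columns:
                    raise ValueError(f"pair sample {sid!r} missing from matrix")
                if sid in seen:
                    raise ValueError(f"sample {sid!r} appears in more than one pair")
                seen.add(sid)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_map)

    def lesional(self) -> pd.DataFrame:
        return self.values[[les for les, _ in self.pair_map]]

    def non_lesional(self) -> pd.DataFrame:
        return self.values[[non for _, non in self.pair_map]]


def read_expression(matrix_path: str | Path, pairs_path: str | Path) -> PairedExpression:
    """Read an expression TSV (first column gene id) and a pair-map TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    pairs_df = pd.read_csv(pairs_path, sep="\t")
    expected = ["lesional", "nonlesional"]
    if list(pairs_df.columns[:2]) != expected:
        raise ValueError(
            f"{pairs_path}: expected columns {expected!r}, got {list(pairs_df.columns)!r}"
        )
    pair_map = [
        (str(row.lesional), str(row.nonlesional)) for row in pairs_df.itertuples()
    ]
    values.columns = [str(c) for c in values.columns]
    values.index = [str(g) for g in values.index]
    return PairedExpression(values=values, pair_map=pair_map)


def median_normalize(x: PairedExpression) -> PairedExpression:
    """Divide each sample column by its own median.

    Every sample median must be strictly positive; after normalization every
    column's median equals 1 (within floating-point tolerance).
    """
    medians = x.values.median(axis=0)
    bad = medians[medians <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive sample medians: {', '.join(map(str, bad.index[:5]))}"
        )
    return PairedExpression(values=x.values / medians, pair_map=list(x.pair_map))


@dataclasses.dataclass
class DEResult:
    """Per-gene differential-expression table with a strict pass filter."""

    table: pd.DataFrame  # columns: fold_change, p_value, q_value, passes
    fc_threshold: float
    q_threshold: float

    def __post_init__(self) -> None:
        required = {"fold_change", "p_value", "q_value", "passes"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")

    def passing_genes(self) -> list[str]:
        return list(self.table.index[self.table["passes"]])

    def gene_passes(self, gene: str, fc_cut: float | None = None) -> bool:
        """Overexpression test for one gene; missing genes fail (logged once)."""
        if gene not in self.table.index:
            logger.debug("gene %r absent from DE table; treated as not overexpressed", gene)
            return False
        row = self.table.loc[gene]
        fc_cut = self.fc_threshold if fc_cut is None else fc_cut
        return bool(row["fold_change"] > fc_cut and row["q_value"] < self.q_threshold)

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out["passes"] = out["passes"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def paired_de_test(
    x: PairedExpression,
    fc_threshold: float = 2.5,
    q_threshold: float = 0.01,
    method: str = "paired",
    fold_change: str = "ratio_of_means",
    direction: str = "up",
) -> DEResult:
    """Per-gene paired differential-expression test with BH adjustment.

    ``method='paired'`` runs a one-sample t-test on per-pair log2
    differences (the standard paired test); ``method='unpaired_welch'``
    runs an unequal-variance two-sample test on log2 intensities.  Fold
    change is mean(lesional)/mean(non-lesional) on the normalized linear
    scale by default; ``fold_change='mean_of_ratios'`` averages per-pair
    ratios instead.  A gene passes iff fold_change > fc_threshold (strict)
    and q < q_threshold; with ``direction='both'`` the fold-change filter
    applies to max(FC, 1/FC).
    """
    if x.n_pairs < 2:
        raise ValueError(f"need at least 2 pairs, got {x.n_pairs}")
    if method not in {"paired", "unpaired_welch"}:
        raise ValueError(f"unknown method {method!r}")
    if direction not in {"up", "both"}:
        raise ValueError(f"unknown direction {direction!r}")

    les = x.lesional().to_numpy(dtype=float)
    non = x.non_lesional().to_numpy(dtype=float)
    eps = np.finfo(float).tiny
    log_les = np.log2(np.maximum(les, eps))
    log_non = np.log2(np.maximum(non, eps))

    with warnings.catch_warnings():
        # constant genes produce 0/0 t statistics; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "paired":
            diffs = log_les - log_non
            tstat, pvals = stats.ttest_1samp(diffs, 0.0, axis=1)
        else:
            tstat, pvals = stats.ttest_ind(log_les, log_non, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    mean_les = les.mean(axis=1)
    mean_non = non.mean(axis=1)
    if fold_change == "ratio_of_means":
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_non > 0, mean_les / mean_non, np.inf)
    elif fold_change == "mean_of_ratios":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(non > 0, les / non, np.inf)
        fc = ratios.mean(axis=1)
    else:
        raise ValueError(f"unknown fold_change convention {fold_change!r}")
    n_inf = int(np.sum(~np.isfinite(fc)))
    if n_inf:
        logger.warning(
            "%d genes have zero non-lesional mean; fold change reported as inf", n_inf
        )

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    effective_fc = np.maximum(fc, 1.0 / np.maximum(fc, eps)) if direction == "both" else fc
    passes = (effective_fc > fc_threshold) & (qvals < q_threshold)

    table = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": pvals,
            "q_value": qvals,
            "passes": passes,
        },
        index=pd.Index(x.gene_ids, name="gene"),
    )
    return DEResult(table=table, fc_threshold=fc_threshold, q_threshold=q_threshold)


def de_gene_set(result: DEResult, name: str = "DE_up") -> GeneSet:
    """Gene set of passing genes; empty sets are returned but logged."""
    genes = result.passing_genes()
    if not genes:
        logger.warning("no genes pass the DE filter; downstream stages will refuse")
    return GeneSet(name, genes)
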