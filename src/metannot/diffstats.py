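"""Differential-metabolite analysis and pathway over-representation.

Given a metabolite quantification table with two sample groups, each
metabolite gets a two-sample t-test p-value (Welch by default), a log2
fold change of group means, and a Benjamini-Hochberg adjusted FDR.  The
default significance call is raw p < 0.05 together with |log2FC| > 1;
an FDR-based rule is selectable.  Significant metabolites then feed a
one-sided hypergeometric over-representation test per pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class QuantTable:
    """Metabolite x sample abundance matrix with a two-group design.

    ``values`` is a DataFrame indexed by metabolite id with one column
    per sample; ``groups`` maps each sample id to its group label.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def group_labels(self) -> tuple[str, str]:
        labels = sorted({self.groups[s] for s in self.values.columns})
        if len(labels) != 2:
            raise ValueError(
                f"differential analysis needs exactly 2 groups, got {labels}"
            )
        return labels[0], labels[1]

    def group_columns(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]

    @classmethod
    def from_csv(cls, quant_path, groups_path) -> "QuantTable":
        """Load from a quant CSV (first column = metabolite id) and a
        two-column groups CSV (sample, group)."""
        values = pd.read_csv(quant_path, index_col=0)
        gdf = pd.read_csv(groups_path)
        groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
        values.columns = values.columns.astype(str)
        return cls(values=values, groups=groups)


def differential_analysis(
    q: QuantTable,
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
    test: str = "welch",
    significance_rule: str = "raw",
    fdr_alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-metabolite two-group comparison.

    Returns a DataFrame with columns ``metabolite``, ``log2fc``
    (second group over first, groups ordered lexicographically),
    ``p_value``, ``fdr`` (Benjamini-Hochberg), and ``significant``.

    ``test`` is ``"welch"`` (unequal variances, default) or
    ``"student"`` (pooled).  ``significance_rule="raw"`` calls a
    metabolite significant when p < ``alpha`` and |log2FC| >
    ``fc_threshold``; ``"fdr"`` uses the adjusted values against
    ``fdr_alpha`` instead of raw p.

    When a group mean is zero, a pseudo-count of half the smallest
    nonzero value in the table is added to both means so the fold change
    stays finite.  Metabolites constant in both groups get p = 1 when the
    constants agree and p = 0 when they differ.
    """
    g1, g2 = q.group_labels
    cols1, cols2 = q.group_columns(g1), q.group_columns(g2)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = q.values[cols1].to_numpy(dtype=float)
    b = q.values[cols2].to_numpy(dtype=float)

    nonzero = q.values.to_numpy()
    nonzero = nonzero[nonzero > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1.0

    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    m1, m2 = mean1.copy(), mean2.copy()
    zero_mask = (m1 == 0) | (m2 == 0)
    m1[zero_mask] += pseudo
    m2[zero_mask] += pseudo
    log2fc = np.log2(m2 / m1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(b, a, axis=1, equal_var=(test == "student"))
    pvals = np.asarray(pvals, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pvals[degenerate & (mean1 == mean2)] = 1.0
    pvals[degenerate & (mean1 != mean2)] = 0.0
    if np.isnan(pvals).any():
        pvals = np.nan_to_num(pvals, nan=1.0)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    if significance_rule == "raw":
        significant = (pvals < alpha) & (np.abs(log2fc) > fc_threshold)
    elif significance_rule == "fdr":
        significant = (fdr < fdr_alpha) & (np.abs(log2fc) > fc_threshold)
    else:
        raise ValueError(f"unknown significance_rule {significance_rule!r}")

    return pd.DataFrame(
        {
            "metabolite": q.values.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "significant": significant,
        }
    ).reset_index(drop=True)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Export-ready volcano-plot table.

    Columns: metabolite, log2fc, neg_log10_p, and class — ``up`` /
    ``down`` for significant metabolites by fold-change sign, else
    ``ns``.
    """
    if results.empty:
        raise ValueError("volcano_table needs a non-empty result table")
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(results["p_value"].to_numpy())
    neg_log10_p = np.where(np.isinf(neg_log10_p), 300.0, neg_log10_p)
    cls = np.where(
        results["significant"] & (results["log2fc"] > 0),
        "up",
        np.where(results["significant"] & (results["log2fc"] < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "metabolite": results["metabolite"],
            "log2fc": results["log2fc"],
            "neg_log10_p": neg_log10_p,
            "class": cls,
        }
    )


def pathway_enrichment(
    significant: set,
    population: set,
    membership: Mapping[str, set],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    For a pathway with K members in the population of size N, and k of
    the n significant metabolites among them, the p-value is the
    upper-tail probability P(X >= k) of the hypergeometric distribution.
    Pathways with no members in the population are skipped.  Results are
    sorted by ascending p (ties by pathway id) with an ``enriched`` flag
    at ``alpha``.

    Columns: pathway, k, K, n, N, p_value, enriched.
    """
    significant = set(significant)
    population = set(population)
    if not significant <= population:
        raise ValueError("significant set must be a subset of the population")
    N, n = len(population), len(significant)
    rows = []
    for pathway, members in membership.items():
        in_pop = set(members) & population
        K = len(in_pop)
        if K == 0:
            continue
        k = len(in_pop & significant)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pathway, k, K, n, N, p, p < alpha))
    rows.sort(key=lambda r: (r[5], r[0]))
    return pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p_value", "enriched"]
    )
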