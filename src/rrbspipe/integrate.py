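"""Methylation-expression integration.

Per-gene differential expression between two groups is the one-way
fixed-effect ANOVA, which for two groups is the pooled-variance two-sample
t-test: F = t^2 on (1, n-2) degrees of freedom.  p-values are converted to
q-values with the Benjamini-Hochberg step-up.  Significant differentially
methylated CpGs are matched to genes whose TSS lies within 10 kb (both
sides), and for each matched pair the Pearson correlation between
per-sample methylation percentage and expression is computed; the summary
tallies the negatively correlated fraction among differentially expressed
matched pairs, the signature of promoter methylation repressing
transcription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diffmeth import DiffMethRecord, MethylMatrix, adjust_fdr
from .simgen import ExpressionMatrix, GeneAnnotation

__all__ = [
    "DEResult",
    "IntegrationRecord",
    "de_test",
    "match_sites_to_genes",
    "methylation_expression_correlation",
    "integration_summary",
]


@dataclass
class DEResult:
    gene_id: str
    mean_diff: float  # group2 mean - group1 mean
    p_value: float
    q_value: float


@dataclass
class IntegrationRecord:
    gene_id: str
    site: tuple[str, int, str]
    dist_to_tss: int
    r: float
    negative_correlation: bool
    de_p_value: float
    de_q_value: float


def de_test(expression: ExpressionMatrix, group1: str, group2: str) -> list[DEResult]:
    """Two-group fixed-effect ANOVA per gene (pooled-variance t-test).

    Degenerate case: zero within-group variance in both groups with equal
    means gives p = 1 (no evidence of difference)."""
    values = expression.values
    cols1 = [s for s in values.columns if expression.groups[s] == group1]
    cols2 = [s for s in values.columns if expression.groups[s] == group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 samples")
    x = values[cols1].to_numpy(float)
    y = values[cols2].to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    dfree = n1 + n2 - 2
    mx, my = x.mean(axis=1), y.mean(axis=1)
    ssx = ((x - mx[:, None]) ** 2).sum(axis=1)
    ssy = ((y - my[:, None]) ** 2).sum(axis=1)
    sp2 = (ssx + ssy) / dfree
    diff = my - mx
    ps = np.ones(len(values))
    nonzero = sp2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = diff**2 / (sp2 * (1 / n1 + 1 / n2))
    ps[nonzero] = stats.f.sf(f[nonzero], 1, dfree)
    # zero pooled variance with unequal means: infinitely strong evidence
    ps[(~nonzero) & (diff != 0)] = 0.0
    qs = adjust_fdr(ps)
    return [
        DEResult(gene_id=g, mean_diff=float(d), p_value=float(p), q_value=float(q))
        for g, d, p, q in zip(values.index, diff, ps, qs)
    ]


def match_sites_to_genes(
    dm_records: list[DiffMethRecord],
    annotation: GeneAnnotation,
    window_bp: int = 10_000,
    significant_only: bool = True,
) -> list[tuple[DiffMethRecord, str, int]]:
    """All (site, gene) pairs with |site - TSS| <= window_bp, both sides.

    Returns (record, gene_id, signed distance on gene strand) triples; one
    site within the window of several TSSs yields several pairs."""
    pairs = []
    for rec in dm_records:
        if significant_only and not rec.significant:
            continue
        contig, pos, _ = rec.site
        for gene in annotation.genes_on(contig):
            if abs(pos - gene.tss) <= window_bp:
                dist = pos - gene.tss if gene.strand == "+" else gene.tss - pos
                pairs.append((rec, gene.gene_id, dist))
    return pairs


def methylation_expression_correlation(
    pairs: list[tuple[DiffMethRecord, str, int]],
    matrix: MethylMatrix,
    expression: ExpressionMatrix,
    de_results: list[DEResult],
) -> list[IntegrationRecord]:
    """Pearson correlation between per-sample methylation percentage and
    expression across the samples shared by both assays (>= 3 required).

    Pairs whose methylation or expression vector is constant are dropped
    with a warning (correlation undefined)."""
    de_by_gene = {r.gene_id: r for r in de_results}
    site_index = {s: i for i, s in enumerate(matrix.sites)}
    pct = matrix.percent()
    shared = [s for s in matrix.samples if s in expression.values.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between methylation and expression")
    meth_cols = [matrix.samples.index(s) for s in shared]
    out = []
    for rec, gene_id, dist in pairs:
        if rec.site not in site_index or gene_id not in de_by_gene:
            continue
        mv = pct[site_index[rec.site], meth_cols]
        ev = expression.values.loc[gene_id, shared].to_numpy(float)
        if np.isclose(mv.std(), 0) or np.isclose(ev.std(), 0):
            warnings.warn(
                f"constant vector for {gene_id} / {rec.site}: correlation undefined", stacklevel=2
            )
            continue
        r = float(np.corrcoef(mv, ev)[0, 1])
        de = de_by_gene[gene_id]
        out.append(
            IntegrationRecord(
                gene_id=gene_id,
                site=rec.site,
                dist_to_tss=dist,
                r=r,
                negative_correlation=r < 0,
                de_p_value=de.p_value,
                de_q_value=de.q_value,
            )
        )
    return out


def integration_summary(
    records: list[IntegrationRecord], de_alpha: float = 0.05
) -> dict[str, float]:
    """Count and fraction of negatively correlated pairs among matched pairs
    whose gene is differentially expressed at p < de_alpha."""
    de_sig = [r for r in records if r.de_p_value < de_alpha]
    n = len(de_sig)
    neg = sum(r.negative_correlation for r in de_sig)
    return {
        "n_pairs": float(len(records)),
        "n_de_significant": float(n),
        "n_negative": float(neg),
        "fraction_negative": (neg / n) if n else float("nan"),
    }
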