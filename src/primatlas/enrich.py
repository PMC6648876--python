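"""Enrichment of OCR state groups against a matched common background.

Annotation overlap (promoters, enhancers, eQTLs), tissue-pleiotropy
comparisons, and nearest-gene expression association. All 2x2 tests are
two-sided Fisher exact tests; families of p-values are controlled with
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import _overlap_mask
from .diffacc import bh_adjust  # noqa: F401  (re-exported; used pipeline-wide)

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    group: str
    annotation: str
    a: int  # group, annotated
    b: int  # group, not annotated
    c: int  # background, annotated
    d: int  # background, not annotated
    odds_ratio: float
    p: float
    q: float = np.nan

    @property
    def group_fraction(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def background_fraction(self) -> float:
        return self.c / (self.c + self.d)


def interval_overlap_flags(atlas: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """True per OCR iff it shares >= 1 bp with any annotation interval."""
    mask = _overlap_mask(atlas, annotation)
    return pd.Series(mask, index=atlas.index)


def fisher_enrichment(
    group_flags: pd.Series,
    background_flags: pd.Series,
    group: str = "group",
    annotation: str = "annotation",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of annotation overlap, group vs background.

    The odds ratio is the sample (a*d)/(b*c), with a Haldane +0.5
    correction applied to all cells only when some cell is zero.
    """
    if len(group_flags) == 0:
        raise ValueError("empty group")
    a = int(group_flags.sum())
    b = int(len(group_flags) - a)
    c = int(background_flags.sum())
    d = int(len(background_flags) - c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(group, annotation, a, b, c, d, odds, float(p))


def enrichment_table(
    flags_by_annotation: dict[str, pd.Series],
    groups: dict[str, list[str]],
    background: list[str],
) -> pd.DataFrame:
    """All group x annotation Fisher tests, BH-adjusted as one family."""
    results: list[EnrichmentResult] = []
    for annot, flags in flags_by_annotation.items():
        for group, ocrs in groups.items():
            results.append(
                fisher_enrichment(
                    flags.loc[ocrs], flags.loc[background], group, annot
                )
            )
    q = bh_adjust([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "annotation": r.annotation,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "group_fraction": r.group_fraction,
                "background_fraction": r.background_fraction,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )


def pleiotropy_compare(
    group_ocrs: list[str],
    background_ocrs: list[str],
    multi_tissue_open: pd.DataFrame,
    k: int | None = None,
) -> dict:
    """Compare tissue-pleiotropy (number of tissues open) between groups.

    Per-OCR pleiotropy is the row sum of the tissue-openness matrix. The
    groups are compared by Fisher's exact test on (pleiotropy > k) x
    (group vs background); k defaults to the background median.
    """
    pleio = multi_tissue_open.sum(axis=1)
    if k is None:
        k = int(np.median(pleio.loc[background_ocrs]))
    g = pleio.loc[group_ocrs] > k
    bg = pleio.loc[background_ocrs] > k
    res = fisher_enrichment(g, bg, "group", f"pleiotropy>{k}")
    return {
        "k": k,
        "group_pleiotropy": pleio.loc[group_ocrs],
        "background_pleiotropy": pleio.loc[background_ocrs],
        "table": (res.a, res.b, res.c, res.d),
        "odds_ratio": res.odds_ratio,
        "p": res.p,
    }


def expression_association(
    group_ocrs: list[str],
    background_ocrs: list[str],
    tss_assignments: pd.DataFrame,
    de_table: pd.DataFrame,
    de_q_threshold: float = 0.05,
    exact_max_n: int = 25,
) -> dict:
    """Wilcoxon rank-sum association between OCR groups and nearest-gene
    differential expression.

    Compares |log2FC| of genes nearest to group OCRs against genes
    nearest to background OCRs (exact null for small samples, normal
    approximation with tie correction otherwise), and reports the
    fraction of group OCRs whose nearest gene is differentially
    expressed at ``de_q_threshold``.
    """
    de = de_table.set_index("gene") if "gene" in de_table.columns else de_table

    def _gene_values(ocrs):
        genes = tss_assignments.loc[ocrs, "gene"]
        known = genes[genes.isin(de.index)]
        dropped = len(genes) - len(known)
        if dropped:
            logger.info("dropped %d OCRs with genes missing from DE table", dropped)
        return known

    g_genes = _gene_values(group_ocrs)
    b_genes = _gene_values(background_ocrs)
    gx = de.loc[g_genes, "log2fc"].abs().to_numpy()
    bx = de.loc[b_genes, "log2fc"].abs().to_numpy()
    combined = np.concatenate([gx, bx])
    has_ties = len(np.unique(combined)) < len(combined)
    small = max(len(gx), len(bx)) <= exact_max_n
    # the exact rank-sum null assumes no ties; fall back to the normal
    # approximation with tie correction when ties are present
    method = "exact" if small and not has_ties else "asymptotic"
    if np.array_equal(np.sort(gx), np.sort(bx)):
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(gx, bx, alternative="two-sided", method=method).pvalue
        )
    frac_de = float((de.loc[g_genes, "q"] < de_q_threshold).mean()) if len(g_genes) else np.nan
    return {
        "p": p,
        "method": method,
        "fraction_near_de": frac_de,
        "n_group": len(gx),
        "n_background": len(bx),
    }
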