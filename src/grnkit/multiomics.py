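"""Linking chromatin accessibility to expression fold changes.

Differentially accessible peaks are assigned to the gene whose transcription
start site is nearest the peak midpoint, within a promoter window (default
±2 kb). Genes that are differentially expressed (padj below a threshold)
and carry a significantly differentially accessible promoter peak enter a
Pearson correlation of expression log2FC against peak log2FC — the
genome-wide concordance statistic — and each gene is classified as
concordantly up- or down-regulated, discordant, or unclassified, with the
fold threshold (default 2-fold) applied on the expression axis and the
accessibility axis required only to be significant and sign-consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AccessibilityTable, DifferentialTable, TssTable

__all__ = [
    "CorrelationReport",
    "assign_peaks_to_genes",
    "correlate_fold_changes",
    "classify_concordance",
]

CLASSES = ("concordant_up", "concordant_down", "discordant", "not_classified")


def assign_peaks_to_genes(
    peaks: AccessibilityTable, tss_table: TssTable, window_bp: int = 2000
) -> AccessibilityTable:
    """Assign each peak to the nearest TSS within ``window_bp``.

    Distance is measured from the peak midpoint ((start+end)//2) to the TSS
    position; ties are broken toward the lexicographically smaller gene id.
    The stored ``tss_distance`` is signed relative to the gene's strand:
    negative = upstream of the TSS. Peaks on chromosomes absent from the
    TSS table trigger a warning and stay unassigned. Deterministic and
    invariant to input row order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    tss = tss_table.table
    by_chrom: dict[str, pd.DataFrame] = {
        c: sub.sort_index() for c, sub in tss.groupby("chrom")
    }
    df = peaks.peaks.copy()
    assigned: list[str | None] = []
    distances: list[float] = []
    warned: set[str] = set()
    for row in df.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            if row.chrom not in warned:
                warnings.warn(
                    f"chromosome {row.chrom!r} absent from TSS table; "
                    "peaks left unassigned",
                    stacklevel=2,
                )
                warned.add(row.chrom)
            assigned.append(None)
            distances.append(math.nan)
            continue
        midpoint = (row.start + row.end) // 2
        dist = np.abs(sub["tss"].to_numpy() - midpoint)
        i = int(dist.argmin())  # first minimum = lexicographically smallest gene
        if dist[i] > window_bp:
            assigned.append(None)
            distances.append(math.nan)
            continue
        gene = sub.index[i]
        signed = midpoint - int(sub["tss"].iloc[i])
        if sub["strand"].iloc[i] == "-":
            signed = -signed
        assigned.append(gene)
        distances.append(float(signed))
    df["assigned_gene"] = assigned
    df["tss_distance"] = distances
    return AccessibilityTable(df)


def classify_concordance(
    expr_log2fc: float, acc_log2fc: float, fold_threshold: float = 2.0
) -> str:
    """Concordance class for one gene that passed the joint filter.

    ``concordant_up`` iff the expression change exceeds ``fold_threshold``
    (log2FC > log2(threshold)) and the promoter peak moves in the same
    (positive) direction; ``concordant_down`` symmetric; ``discordant`` iff
    the expression change exceeds the threshold magnitude but the peak
    moves the opposite way; ``not_classified`` otherwise.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    thr = math.log2(fold_threshold)
    if expr_log2fc > thr:
        if acc_log2fc > 0:
            return "concordant_up"
        if acc_log2fc < 0:
            return "discordant"
    elif expr_log2fc < -thr:
        if acc_log2fc < 0:
            return "concordant_down"
        if acc_log2fc > 0:
            return "discordant"
    return "not_classified"


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of expression vs promoter-accessibility log2FC."""

    r: float
    p: float
    n_genes: int
    slope: float
    intercept: float
    records: pd.DataFrame  # index gene; expr_log2fc, acc_log2fc, tss_distance, class

    def class_counts(self) -> dict[str, int]:
        counts = self.records["class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}


def correlate_fold_changes(
    de_table: DifferentialTable,
    acc_table: AccessibilityTable,
    de_alpha: float = 0.05,
    acc_fdr: float = 0.05,
    fold_threshold: float = 2.0,
    genes: list[str] | None = None,
) -> CorrelationReport:
    """Genome-wide (or targeted) expression/accessibility concordance.

    Genes enter the correlation when padj < ``de_alpha`` AND they carry an
    assigned promoter peak with fdr < ``acc_fdr``; for a gene with several
    assigned peaks, the peak nearest its TSS is used. Pass ``genes`` to
    restrict to a curated marker list (the targeted variant). The p-value
    comes from the t transform t = r·√((n−2)/(1−r²)) on n−2 df; fewer than
    3 qualifying genes, or a zero-variance axis, are hard errors.
    """
    de = de_table.table
    sig_genes = set(de.index[de["padj"] < de_alpha])
    if genes is not None:
        sig_genes &= set(genes)
    peaks = acc_table.assigned()
    peaks = peaks[(peaks["fdr"] < acc_fdr) & peaks["assigned_gene"].isin(sig_genes)]
    if len(peaks):
        peaks = peaks.assign(_absd=peaks["tss_distance"].abs()).sort_values(
            ["_absd", "peak_id"], kind="mergesort"
        )
        peaks = peaks.drop_duplicates(subset="assigned_gene", keep="first")
    n = len(peaks)
    if n < 3:
        raise ValueError(
            f"only {n} genes pass the joint filter (padj < {de_alpha}, "
            f"fdr < {acc_fdr}); need ≥ 3"
        )
    records = pd.DataFrame(
        {
            "expr_log2fc": de.loc[peaks["assigned_gene"], "log2fc"].to_numpy(),
            "acc_log2fc": peaks["log2fc"].to_numpy(),
            "tss_distance": peaks["tss_distance"].to_numpy(),
        },
        index=pd.Index(peaks["assigned_gene"], name="gene_id"),
    ).sort_index()
    x = records["expr_log2fc"].to_numpy()
    y = records["acc_log2fc"].to_numpy()
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero-variance fold-change vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    records["class"] = [
        classify_concordance(e, a, fold_threshold)
        for e, a in zip(records["expr_log2fc"], records["acc_log2fc"])
    ]
    return CorrelationReport(
        r=float(r),
        p=float(p),
        n_genes=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        records=records,
    )
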