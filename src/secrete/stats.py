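"""Enrichment, classification, permutation and distribution statistics.

Covers the quantitative layer of the motif analysis: gene-set fractions and
chi-squared enrichment with BH-FDR, ROC/AUC threshold calibration, the
length-vs-count Pearson check, codon-shuffle permutation Z-scores, ECDF/KS
comparisons against external per-gene values, and region / positional motif
distributions.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .motif_core import MotifHit, ScanConfig, _class_mask, _true_runs, scan_transcript

__all__ = [
    "EnrichmentResult",
    "ROCResult",
    "PermutationResult",
    "ECDFComparison",
    "fraction_with_motif",
    "chi2_enrichment",
    "bh_fdr",
    "roc_auc",
    "plot_roc",
    "threshold_sweep",
    "length_correlation",
    "shuffle_codons",
    "permutation_z",
    "significant_fraction",
    "ecdf_compare",
    "region_distribution",
    "positional_distribution",
    "utr_y_content_comparison",
    "gene_rng",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class EnrichmentResult:
    """2x2 motif-presence contingency between two gene sets."""

    table: np.ndarray  # rows: setA, setB; cols: motif+, motif-
    fraction_a: float
    fraction_b: float
    chi2: float
    p_value: float
    q_value: float | None = None


@dataclass
class ROCResult:
    """Empirical ROC curve and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    score_label: str = "secrete_count"


@dataclass
class PermutationResult:
    """Codon-shuffle permutation outcome for one gene and phase."""

    gene_id: str
    phase: int
    statistic: str
    observed: float
    mean: float
    std: float
    z: float
    n_shuffles: int
    seed: int
    degenerate: bool = False


@dataclass
class ECDFComparison:
    """Two ECDFs on a shared grid plus the two-sample KS summary."""

    grid: np.ndarray
    cdf_with: np.ndarray
    cdf_without: np.ndarray
    ks_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# gene-set fractions and enrichment


def fraction_with_motif(transcripts, cfg: ScanConfig) -> tuple[float, int, int]:
    """Fraction of genes carrying at least one motif under ``cfg``."""
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty gene set")
    n_with = sum(1 for t in transcripts if len(scan_transcript(t, cfg)) >= 1)
    return n_with / len(transcripts), n_with, len(transcripts)


def chi2_enrichment(
    setA_counts: tuple[int, int], setB_counts: tuple[int, int]
) -> EnrichmentResult:
    """Pearson chi-squared (df=1, no continuity correction) on a 2x2 table.

    Each argument is (n motif-positive, n motif-negative) for one gene set.
    """
    table = np.array([setA_counts, setB_counts], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: a table marginal is zero")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        table=table,
        fraction_a=table[0, 0] / table[0].sum(),
        fraction_b=table[1, 0] / table[1].sum(),
        chi2=float(chi2),
        p_value=float(p),
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# ROC / threshold calibration


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> ROCResult:
    """Empirical ROC and AUC with secretome genes as the positive class.

    The AUC equals the normalised Mann-Whitney U statistic with the usual
    one-half credit for ties (identical to the trapezoidal area under the
    empirical ROC curve).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(roc_auc_score(y, s)))


def plot_roc(results: Sequence[ROCResult], path: str | Path, labels=None) -> None:
    """Plot one or more ROC curves to SVG/PNG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for i, r in enumerate(results):
        name = labels[i] if labels else r.score_label
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def threshold_sweep(
    transcripts,
    labels: Sequence[int] | None = None,
    thresholds: Sequence[int] = (5, 7, 10, 12, 15),
    nt_class: str = "Y",
    regions: Iterable[str] = ("CDS",),
    phases: Iterable[int] = (0, 1, 2),
) -> tuple[pd.DataFrame, int]:
    """Evaluate motif thresholds by AUC, per-set fractions and chi-squared p.

    ``labels`` defaults to each transcript's secretome flag.  The per-gene
    ROC score at each threshold is the motif count at that threshold.
    Returns the sweep table and the argmax-AUC threshold.
    """
    transcripts = list(transcripts)
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds to sweep")
    if labels is None:
        labels = [int(t.is_secretome) for t in transcripts]
    y = np.asarray(labels, dtype=int)
    rows = []
    for thr in thresholds:
        cfg = ScanConfig(min_triplets=thr, nt_class=nt_class,
                         regions=frozenset(regions), phases=frozenset(phases))
        counts = np.array([len(scan_transcript(t, cfg)) for t in transcripts])
        auc = roc_auc(y, counts).auc
        pos, neg = counts[y == 1], counts[y == 0]
        try:
            enr = chi2_enrichment(
                (int((pos >= 1).sum()), int((pos < 1).sum())),
                (int((neg >= 1).sum()), int((neg < 1).sum())),
            )
            chi2, p = enr.chi2, enr.p_value
        except ValueError:  # all genes on one side of presence/absence
            chi2, p = float("nan"), float("nan")
        rows.append(
            {
                "threshold": thr,
                "auc": auc,
                "fraction_positive_set": float((pos >= 1).mean()),
                "fraction_negative_set": float((neg >= 1).mean()),
                "chi2": chi2,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    best = int(df.loc[df["auc"].idxmax(), "threshold"])
    return df, best


def length_correlation(transcripts, cfg: ScanConfig) -> float:
    """Pearson r between per-gene motif count and CDS length."""
    transcripts = list(transcripts)
    if len(transcripts) < 3:
        raise ValueError("need at least 3 genes")
    counts = np.array([len(scan_transcript(t, cfg)) for t in transcripts], dtype=float)
    lengths = np.array([len(t.cds) for t in transcripts], dtype=float)
    if np.ptp(counts) == 0 or np.ptp(lengths) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sps.pearsonr(counts, lengths).statistic)


# ---------------------------------------------------------------------------
# codon-shuffle permutation test


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene RNG stream derived from (seed, gene_id), order-independent."""
    return np.random.default_rng([seed, zlib.crc32(gene_id.encode())])


def shuffle_codons(cds: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the codon list (codon multiset preserved)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return "".join(codons[i] for i in rng.permutation(len(codons)))


def _stat_from_flags(flags: np.ndarray, statistic: str, min_triplets: int) -> float:
    runs = _true_runs(flags)
    if statistic == "max_run_length":
        return max((e - s for s, e in runs), default=0)
    return sum(1 for s, e in runs if e - s >= min_triplets)


def permutation_z(
    transcript,
    cfg: ScanConfig = ScanConfig(),
    statistic: str = "max_run_length",
    n: int = 1000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Codon-shuffle permutation Z-score of a CDS, one result per phase.

    The codon order is shuffled ``n`` times with codon usage unchanged and
    Z = (observed - mean) / std of the statistic over the shuffles.  The
    default statistic is the longest run length in triplets (the motif
    length); ``secrete_count`` (number of runs >= cfg.min_triplets) is the
    alternative.  Because codon shuffling merely permutes the per-codon
    class flags, the shuffle statistic is evaluated on permuted flag arrays;
    this is exactly equivalent to scanning the shuffled sequence.  A gene
    whose shuffles all give the same value (std = 0) is flagged degenerate
    with Z = 0.
    """
    if statistic not in ("max_run_length", "secrete_count"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n < 2:
        raise ValueError("need at least 2 shuffles")
    cds = transcript.cds
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(cds) // 3
    mask = _class_mask(cds, cfg.nt_class)
    rng = gene_rng(seed, transcript.gene_id)
    results = []
    for phase in sorted(cfg.phases):
        flags = mask[phase::3][:n_codons]
        observed = _stat_from_flags(flags, statistic, cfg.min_triplets)
        draws = np.empty(n)
        for i in range(n):
            draws[i] = _stat_from_flags(flags[rng.permutation(n_codons)],
                                        statistic, cfg.min_triplets)
        mean = float(draws.mean())
        std = float(draws.std(ddof=0))
        degenerate = std == 0.0
        z = 0.0 if degenerate else (observed - mean) / std
        results.append(
            PermutationResult(
                gene_id=transcript.gene_id,
                phase=phase,
                statistic=statistic,
                observed=float(observed),
                mean=mean,
                std=std,
                z=z,
                n_shuffles=n,
                seed=seed,
                degenerate=degenerate,
            )
        )
    return results


def significant_fraction(
    perm_results: Sequence[PermutationResult],
    cutoff: float = 1.96,
    include_degenerate: bool = False,
) -> float:
    """Share of (non-degenerate) genes with Z >= cutoff."""
    if not perm_results:
        raise ValueError("empty permutation result list")
    pool = [r for r in perm_results if include_degenerate or not r.degenerate]
    if not pool:
        return 0.0
    return sum(1 for r in pool if r.z >= cutoff) / len(pool)


# ---------------------------------------------------------------------------
# distribution comparisons


def ecdf_compare(
    values_with: Sequence[float], values_without: Sequence[float]
) -> ECDFComparison:
    """ECDFs of two value samples on their union grid + two-sample KS test."""
    a = np.asarray(values_with, dtype=float)
    b = np.asarray(values_without, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    grid = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    ks = sps.ks_2samp(a, b)
    return ECDFComparison(
        grid=grid,
        cdf_with=cdf_a,
        cdf_without=cdf_b,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
    )


def region_distribution(hits: Sequence[MotifHit], transcripts) -> pd.DataFrame:
    """Motif counts per region, raw and normalised by mean region length.

    The density divides each region's count by the mean length of that
    region over the genes that have it (genes lacking an annotated UTR do
    not enter that UTR's denominator).
    """
    transcripts = list(transcripts)
    rows = []
    for region, getter in (("5UTR", lambda t: t.utr5),
                           ("CDS", lambda t: t.cds),
                           ("3UTR", lambda t: t.utr3)):
        lengths = [len(getter(t)) for t in transcripts if getter(t)]
        mean_len = float(np.mean(lengths)) if lengths else float("nan")
        count = sum(1 for h in hits if h.region == region)
        rows.append(
            {
                "region": region,
                "count": count,
                "mean_region_length": mean_len,
                "density": count / mean_len if lengths else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def positional_distribution(
    hits: Sequence[MotifHit], transcripts, n_bins: int = 10
) -> np.ndarray:
    """Histogram of motif start positions along the normalised transcript.

    Region-local starts are mapped to the 5'UTR + CDS + 3'UTR concatenation
    and divided by the transcript length, giving relative positions in
    [0, 1); bin counts sum to the number of binnable hits.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    by_gene = {t.gene_id: t for t in transcripts}
    rel = []
    for h in hits:
        t = by_gene.get(h.gene_id)
        if t is None or t.length == 0:
            continue
        offset = {"5UTR": 0, "FULL": 0, "CDS": len(t.utr5),
                  "3UTR": len(t.utr5) + len(t.cds)}[h.region]
        rel.append((offset + h.start_nt) / t.length)
    counts, _ = np.histogram(rel, bins=n_bins, range=(0.0, 1.0))
    return counts


def utr_y_content_comparison(
    transcripts,
    cfg: ScanConfig | None = None,
    exclude_secrete_utrs: bool = False,
) -> pd.DataFrame:
    """Mean UTR pyrimidine content, secretome vs non-secretome, per UTR.

    With ``exclude_secrete_utrs`` set, genes carrying at least one motif in
    a UTR (at the cfg threshold) are dropped from that UTR's comparison, to
    test whether any Y enrichment persists outside the motifs themselves.
    An unpaired two-sided t-test p-value is reported per UTR.
    """
    from .motif_core import find_runs, pyrimidine_content

    cfg = cfg or ScanConfig()
    rows = []
    for region, getter in (("5UTR", lambda t: t.utr5), ("3UTR", lambda t: t.utr3)):
        sec, non = [], []
        n_excluded = 0
        for t in transcripts:
            seq = getter(t)
            if not seq:
                continue
            if exclude_secrete_utrs:
                has_motif = any(
                    find_runs(seq, off, cfg.nt_class, cfg.min_triplets) for off in (0, 1, 2)
                )
                if has_motif:
                    n_excluded += 1
                    continue
            (sec if t.is_secretome else non).append(pyrimidine_content(seq))
        if not sec or not non:
            raise ValueError(f"{region}: both groups must be non-empty")
        test = sps.ttest_ind(sec, non, equal_var=False)
        rows.append(
            {
                "region": region,
                "mean_secretome": float(np.mean(sec)),
                "mean_non_secretome": float(np.mean(non)),
                "n_secretome": len(sec),
                "n_non_secretome": len(non),
                "n_excluded": n_excluded,
                "t_statistic": float(test.statistic),
                "p_value": float(test.pvalue),
            }
        )
    return pd.DataFrame(rows)
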