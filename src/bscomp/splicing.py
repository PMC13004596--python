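"""Percent-unspliced quantification and class-level abundance shifts.

A transcriptome annotated into unspliced pre-mRNA, spliced mRNA and
intronless transcripts is quantified per gene as

    percent unspliced = 100 * unspliced / (unspliced + spliced)

from raw counts (the within-library ratio needs no normalization). A gene's
expression filter uses the DESeq2 convention: base mean = mean over all
samples of the size-factor-normalized total (unspliced + spliced) count,
with median-of-ratios size factors. Treatment-vs-control shifts in percent
unspliced are tested per gene with a two-sided Student's t-test (Welch by
flag); a gene is called significant when p < alpha (default 0.1) and
base mean > expression_min (default 100).

Class-level abundance shifts compare per-transcript log2 fold changes of
normalized means (with a pseudocount) between the three transcript classes
by two-sided Mann-Whitney U.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CLASSES = ("unspliced", "spliced", "intronless")


@dataclass
class CountMatrix:
    """Transcripts x samples counts with class labels and group assignments.

    ``meta`` is indexed by transcript_id with columns ``tx_class`` (one of
    unspliced/spliced/intronless) and ``gene_id``; every unspliced transcript
    must pair with exactly one spliced transcript of the same gene.
    ``sample_groups`` maps sample name to 'control' or 'treatment'.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    sample_groups: dict[str, str]
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same transcript index")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        unknown = set(self.meta["tx_class"]) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown transcript class(es): {unknown}")
        for cls in ("unspliced", "spliced"):
            genes = self.meta.loc[self.meta["tx_class"] == cls, "gene_id"]
            if genes.duplicated().any():
                raise ValueError(f"gene with more than one {cls} transcript")
        u_genes = set(self.meta.loc[self.meta["tx_class"] == "unspliced", "gene_id"])
        s_genes = set(self.meta.loc[self.meta["tx_class"] == "spliced", "gene_id"])
        if u_genes != s_genes:
            raise ValueError("unpaired unspliced/spliced transcripts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == group]


@dataclass
class PuResult:
    gene_id: str
    pu_per_sample: dict[str, float]
    mean_control: float
    mean_treatment: float
    delta_pu: float
    p_value: float
    base_mean: float
    significant: bool


def median_ratio_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq2 normalization scheme).

    The reference is the per-transcript geometric mean across samples,
    excluding transcripts with any zero count; each sample's factor is the
    median over transcripts of count / reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-D (transcripts x samples)")
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no transcript has nonzero counts in every sample")
    sub = mat[nonzero]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return factors


def percent_unspliced(u: float, s: float) -> float:
    """100*u/(u+s); NaN when the gene has no counts in this sample."""
    if u < 0 or s < 0:
        raise ValueError("negative count")
    total = u + s
    if total == 0:
        return float("nan")
    return 100.0 * u / total


def _paired_counts(cm: CountMatrix) -> pd.DataFrame:
    """Long table: gene_id, sample -> (u, s) raw counts."""
    meta = cm.meta
    u_ids = meta.index[meta["tx_class"] == "unspliced"]
    u_map = meta.loc[u_ids, "gene_id"]
    s_map = (
        meta.loc[meta["tx_class"] == "spliced"]
        .reset_index()
        .set_index("gene_id")
        .iloc[:, 0]
    )
    rows = []
    for u_tx, gene in u_map.items():
        s_tx = s_map[gene]
        rows.append((gene, u_tx, s_tx))
    return pd.DataFrame(rows, columns=["gene_id", "u_tx", "s_tx"])


def pu_table(
    cm: CountMatrix,
    alpha: float = 0.1,
    expression_min: float = 100.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene percent-unspliced statistics (treatment vs control).

    Returns a table with per-gene pu means, delta_pu (treatment - control),
    two-sided t-test p, base_mean and the significance call. Genes with a
    missing pu value in either group, or with zero variance in both groups,
    are dropped from the significant set (p reported as NaN) and logged.
    """
    ctrl = cm.group_samples("control")
    trt = cm.group_samples("treatment")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need at least 2 replicates per group")

    factors = median_ratio_size_factors(cm.counts)
    norm = cm.counts / factors

    pairs = _paired_counts(cm)
    records = []
    n_dropped_missing = 0
    n_dropped_novar = 0
    for _, row in pairs.iterrows():
        u = cm.counts.loc[row["u_tx"]]
        s = cm.counts.loc[row["s_tx"]]
        pu = pd.Series(
            {smp: percent_unspliced(u[smp], s[smp]) for smp in cm.samples}
        )
        base_mean = float((norm.loc[row["u_tx"]] + norm.loc[row["s_tx"]]).mean())
        pu_c = pu[ctrl].dropna()
        pu_t = pu[trt].dropna()
        if len(pu_c) < 2 or len(pu_t) < 2:
            n_dropped_missing += 1
            continue
        mean_c, mean_t = float(pu_c.mean()), float(pu_t.mean())
        delta = mean_t - mean_c
        if pu_c.var(ddof=1) == 0 and pu_t.var(ddof=1) == 0:
            n_dropped_novar += 1
            p = float("nan")
        else:
            _, p = stats.ttest_ind(pu_t, pu_c, equal_var=not welch)
            p = float(p)
        significant = bool(p < alpha and base_mean > expression_min) if np.isfinite(p) else False
        records.append(
            {
                "gene_id": row["gene_id"],
                "mean_control": mean_c,
                "mean_treatment": mean_t,
                "delta_pu": delta,
                "p_value": p,
                "base_mean": base_mean,
                "significant": significant,
            }
        )
    if n_dropped_missing:
        logger.info("pu_table: dropped %d gene(s) with <2 usable replicates", n_dropped_missing)
    if n_dropped_novar:
        logger.info("pu_table: %d gene(s) with zero variance in both groups", n_dropped_novar)
    return pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id",
            "mean_control",
            "mean_treatment",
            "delta_pu",
            "p_value",
            "base_mean",
            "significant",
        ],
    )


@dataclass
class ClassShiftResult:
    """Per-class L2FC distributions and pairwise Mann-Whitney comparisons."""

    l2fc: pd.DataFrame  # transcript_id, tx_class, l2fc
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)


def class_abundance_shift(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    tpm_min: float = 0.2,
) -> ClassShiftResult:
    """Compare treatment/control abundance shifts between transcript classes.

    Per transcript, L2FC = log2((mean normalized treatment + pseudocount) /
    (mean normalized control + pseudocount)); transcripts with mean TPM <=
    tpm_min are filtered out when a TPM matrix is present. Each pair of
    classes is compared by two-sided Mann-Whitney U on the L2FC
    distributions; classes with fewer than 3 transcripts are skipped.
    """
    ctrl = cm.group_samples("control")
    trt = cm.group_samples("treatment")
    factors = median_ratio_size_factors(cm.counts)
    norm = cm.counts / factors
    mean_c = norm[ctrl].mean(axis=1)
    mean_t = norm[trt].mean(axis=1)
    l2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    table = pd.DataFrame(
        {"tx_class": cm.meta["tx_class"], "l2fc": l2fc}, index=cm.counts.index
    )
    if cm.tpm is not None:
        keep = cm.tpm.mean(axis=1) > tpm_min
        n_filtered = int((~keep).sum())
        if n_filtered:
            logger.info("class_abundance_shift: filtered %d low-TPM transcript(s)", n_filtered)
        table = table[keep]

    pairwise: dict[tuple[str, str], float] = {}
    medians: dict[str, float] = {}
    groups = {
        cls: table.loc[table["tx_class"] == cls, "l2fc"].to_numpy() for cls in CLASSES
    }
    for cls, vals in groups.items():
        if len(vals):
            medians[cls] = float(np.median(vals))
    for a, b in itertools.combinations(CLASSES, 2):
        if len(groups[a]) < 3 or len(groups[b]) < 3:
            logger.info("class_abundance_shift: skipping %s vs %s (too few transcripts)", a, b)
            continue
        _, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairwise[(a, b)] = float(p)
    return ClassShiftResult(l2fc=table.reset_index(), pairwise_p=pairwise, medians=medians)
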