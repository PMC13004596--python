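"""RNA-affinity-chromatography proteomics scoring.

DDA arm: per-protein normalized spectral counts (NSC) for nuclear-extract
input (NE), four RNA bait substrates (WT, upDEL, dnDEL, 2xDEL) and an
aptamer-only control (APT) are converted to background-corrected enrichment
relative to input,

    score_substrate = (NSC_substrate - NSC_APT) / NSC_NE,

undefined when any needed value is missing or NE is zero. Early-spliceosome /
17S U2 snRNP (E/U2) proteins with a positive score in at least one substrate
are the included set; per substrate, strictly positive and strictly negative
scores among included proteins are counted (zeros and missing in neither).
Row z-scores and average-linkage hierarchical clustering reproduce the
heatmap view.

DIA arm: per-replicate log2 intensities are compared between conditions.
The default test is an empirical-Bayes moderated t: per-protein pooled
variances are squeezed toward a common prior fitted across all proteins
(Smyth's scaled inverse-chi-square scheme), which recovers useful power at
the 2-3 replicates typical of these experiments; a plain Welch t-test is
available by flag. P-values are Benjamini-Hochberg adjusted; proteins pass
at a loose (|log2FC| > 0.2, p < 0.01) or strict (|log2FC| > 0.7, p < 0.01)
threshold. Missing values are never imputed; a protein with a fully missing
group is dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

SUBSTRATES = ["WT", "upDEL", "dnDEL", "2xDEL"]


def bg_corrected_enrichment(nsc: pd.DataFrame, eu2: set[str] | None = None) -> pd.DataFrame:
    """Background-corrected enrichment scores per substrate.

    ``nsc`` needs columns protein_id, NE, APT and the four substrates.
    Returns protein_id, one score column per substrate, eu2_member and the
    inclusion flag (E/U2 member with a positive score in >=1 substrate).
    """
    out = pd.DataFrame({"protein_id": nsc["protein_id"]})
    ne = nsc["NE"].where(nsc["NE"] != 0)
    n_zero_ne = int((nsc["NE"] == 0).sum())
    if n_zero_ne:
        logger.info("bg_corrected_enrichment: %d protein(s) with NE=0 -> missing scores", n_zero_ne)
    for sub in SUBSTRATES:
        out[sub] = (nsc[sub] - nsc["APT"]) / ne
    if eu2 is None:
        out["eu2_member"] = (
            nsc["eu2_member"].astype(bool) if "eu2_member" in nsc.columns else False
        )
    else:
        out["eu2_member"] = nsc["protein_id"].isin(eu2)
    positive_any = (out[SUBSTRATES] > 0).any(axis=1)
    out["included"] = out["eu2_member"] & positive_any
    return out


def eu2_sign_counts(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-substrate (n_pos, n_neg) counts among included E/U2 proteins.

    Strictly positive and strictly negative scores only; zeros and missing
    values count in neither column.
    """
    included = rows[rows["included"]]
    records = []
    for sub in SUBSTRATES:
        scores = included[sub]
        records.append(
            {
                "substrate": sub,
                "n_pos": int((scores > 0).sum()),
                "n_neg": int((scores < 0).sum()),
            }
        )
    return pd.DataFrame.from_records(records)


def row_zscores(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores ((x - mean) / sample sd); degenerate rows dropped.

    Rows with fewer than 2 non-missing values or zero spread cannot be
    z-scored and are dropped with a logged count.
    """
    vals = matrix.astype(float)
    n_ok = vals.notna().sum(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = (n_ok >= 2) & (sd > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("row_zscores: dropped %d constant/degenerate row(s)", n_dropped)
    sub = vals[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)


def cluster_rows(matrix: pd.DataFrame) -> tuple[list, np.ndarray | None]:
    """Agglomerative clustering of rows (Euclidean, average linkage).

    Missing values are imputed as 0 with a logged count. Returns the leaf
    order (row labels) and the linkage matrix (None for <2 rows).
    """
    if len(matrix) < 2:
        return list(matrix.index), None
    vals = matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("cluster_rows: imputed %d missing value(s) as 0", n_missing)
        vals = np.nan_to_num(vals, nan=0.0)
    linkage = hierarchy.linkage(pdist(vals, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(linkage)
    return [matrix.index[i] for i in order], linkage


def benjamini_hochberg(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    from scipy.special import polygamma

    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes squeeze of sample variances toward a fitted prior.

    Fits a scaled inverse-chi-square prior (d0, s2_0) to the observed
    variances by the method of moments on log variances and returns the
    posterior variances (d0*s2_0 + df*s2)/(d0 + df) together with the prior
    df d0 (inf when the observed spread is no larger than sampling noise,
    in which case all posteriors equal the prior mean).
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(s2[ok])
    e = z - float(digamma(df / 2)) + np.log(df / 2)
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
    if e_var <= 0:
        d0 = np.inf
        s2_0 = float(np.exp(np.mean(e)))
        return np.full_like(s2, s2_0), d0
    d0 = 2 * _trigamma_inverse(e_var)
    s2_0 = float(np.exp(np.mean(e) + float(digamma(d0 / 2)) - np.log(d0 / 2)))
    post = (d0 * s2_0 + df * s2) / (d0 + df)
    return post, d0


def dia_differential(
    intensities: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    loose_l2fc: float = 0.2,
    strict_l2fc: float = 0.7,
    p_max: float = 0.01,
    method: str = "moderated",
) -> pd.DataFrame:
    """Differential analysis of log2 intensities (A vs B).

    ``intensities`` is proteins x replicate samples on the log2 scale;
    ``groups`` maps sample name to condition. l2fc = mean(A) - mean(B).
    ``method='moderated'`` (default) uses the empirical-Bayes moderated t on
    pooled variances; ``method='welch'`` uses a per-protein Welch t-test.
    Missing values are not imputed; proteins without >=2 finite replicates in
    each group are dropped and logged. BH adjustment is computed across the
    tested proteins.
    """
    if method not in ("moderated", "welch"):
        raise ValueError(f"unknown method {method!r}")
    cols_a = [s for s in intensities.columns if groups.get(s) == group_a]
    cols_b = [s for s in intensities.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 replicates per group")
    records = []
    n_dropped = 0
    for protein, row in intensities.iterrows():
        a = row[cols_a].dropna().to_numpy(dtype=float)
        b = row[cols_b].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            n_dropped += 1
            continue
        l2fc = float(a.mean() - b.mean())
        na, nb = len(a), len(b)
        s2_pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        if method == "welch":
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p = 1.0 if l2fc == 0 else 0.0
            else:
                _, p = stats.ttest_ind(a, b, equal_var=False)
                p = float(p)
        else:
            p = np.nan  # filled in after the variance squeeze
        records.append(
            {
                "protein_id": protein,
                "l2fc": l2fc,
                "p_value": p,
                "_s2": s2_pooled,
                "_na": na,
                "_nb": nb,
            }
        )
    if n_dropped:
        logger.info("dia_differential: dropped %d protein(s) with <2 usable replicates", n_dropped)
    result = pd.DataFrame.from_records(
        records, columns=["protein_id", "l2fc", "p_value", "_s2", "_na", "_nb"]
    )
    if method == "moderated" and len(result):
        df_res = result["_na"] + result["_nb"] - 2
        if df_res.nunique() == 1:
            post, d0 = squeeze_variances(result["_s2"].to_numpy(), float(df_res.iloc[0]))
        else:  # heterogeneous missingness: squeeze per residual-df stratum
            post = np.empty(len(result))
            d0 = np.inf
            for dfv, idx in result.groupby(df_res).groups.items():
                p_sub, d0_sub = squeeze_variances(
                    result.loc[idx, "_s2"].to_numpy(), float(dfv)
                )
                post[result.index.get_indexer(idx)] = p_sub
                d0 = min(d0, d0_sub)
        df_total = np.where(np.isfinite(d0), df_res + d0, np.inf)
        se = np.sqrt(post * (1.0 / result["_na"] + 1.0 / result["_nb"]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = result["l2fc"].to_numpy() / se
        finite_df = np.where(np.isfinite(df_total), df_total, 1e6)
        result["p_value"] = 2 * stats.t.sf(np.abs(t), finite_df)
    result = result.drop(columns=["_s2", "_na", "_nb"])
    if len(result):
        result["adj_p"] = benjamini_hochberg(result["p_value"].to_numpy())
    else:
        result["adj_p"] = pd.Series(dtype=float)
    result["pass_loose"] = (result["l2fc"].abs() > loose_l2fc) & (result["p_value"] < p_max)
    result["pass_strict"] = (result["l2fc"].abs() > strict_l2fc) & (result["p_value"] < p_max)
    return result
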