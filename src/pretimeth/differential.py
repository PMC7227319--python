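"""Region annotation, Welch-test DML calling and promoter-based DMG rollup.

A differentially methylated locus (DML) must satisfy both conditions:
BH-adjusted Welch p (q) < 0.05 and |Δβ| (group-mean difference) > 0.1.
A differentially methylated gene (DMG) is a gene with at least one DML
probe in its promoter, where the promoter is the union of TSS200,
TSS1500, 5'UTR and 1stExon annotations of that gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrays_io import MethylationMatrix, ProbeManifest

logger = logging.getLogger(__name__)

#: gene-region priority, 5'→3' (highest first); probes with no gene pair are Intergenic
REGION_PRIORITY = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")

PROMOTER_CATEGORIES = frozenset({"TSS200", "TSS1500", "5'UTR", "1stExon"})

DEFAULT_DELTA_THRESHOLD = 0.1
DEFAULT_Q_THRESHOLD = 0.05


@dataclass
class GenomicAnnotation:
    probe_id: str
    region_category: str  # one of REGION_PRIORITY or "Intergenic"
    cgi_relation: str
    associated_genes: list[str]


def annotate_region(probe_id: str, manifest: ProbeManifest) -> GenomicAnnotation:
    """Single prioritized region category for a probe.

    With multiple (gene, category) pairs the 5'-most category wins
    (TSS200 > TSS1500 > 5'UTR > 1stExon > Body > 3'UTR); probes with no
    gene annotation are Intergenic.
    """
    pairs = manifest.gene_pairs(probe_id)
    cgi = str(manifest.table.loc[probe_id, "cgi_relation"])
    if not pairs:
        return GenomicAnnotation(probe_id, "Intergenic", cgi, [])
    for cat in pairs:
        if cat[1] not in REGION_PRIORITY:
            raise ValueError(f"unknown region category {cat[1]!r} for {probe_id!r}")
    best = min(pairs, key=lambda gc: REGION_PRIORITY.index(gc[1]))[1]
    genes = sorted({g for g, _ in pairs})
    return GenomicAnnotation(probe_id, best, cgi, genes)


def welch_t(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Welch-Satterthwaite df, two-sided p).

    Raises ValueError when a group has < 2 finite values or both groups
    are constant (the statistic is undefined).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[~np.isnan(g1)]
    g2 = g2[~np.isnan(g2)]
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if np.var(g1) == 0 and np.var(g2) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untested.

    Missing entries are excluded from the family size m and returned as
    NaN; q-values are clipped at 1 and monotone in p-rank.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    tested = ~np.isnan(p)
    if not tested.any():
        return out
    pt = p[tested]
    if (pt < 0).any() or (pt > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[tested] = multipletests(pt, method="fdr_bh")[1]
    return out


def call_dml(
    predictions: MethylationMatrix,
    group_labels: dict[str, str] | pd.Series,
    group1: str = "group1",
    group2: str = "group2",
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-probe Welch test between two sample groups with BH correction.

    ``group1`` carries tumor semantics for the direction call: a DML is
    ``hypo`` when the group1 mean is below the group2 mean, ``hyper``
    otherwise.  Probes with < 2 usable values in either group (or an
    undefined statistic) are skipped and reported with ``tested=False``;
    the BH family is the set of probes actually tested.
    """
    labels = pd.Series(group_labels)
    extra = set(labels.index) - set(predictions.sample_ids)
    if extra:
        raise ValueError(f"labels reference unknown samples: {sorted(extra)[:5]}")
    s1 = [s for s in predictions.sample_ids if labels.get(s) == group1]
    s2 = [s for s in predictions.sample_ids if labels.get(s) == group2]
    if not s1 or not s2:
        raise ValueError(f"both groups must be non-empty (got {len(s1)} / {len(s2)})")
    m1 = predictions.data[s1].to_numpy(dtype=float)
    m2 = predictions.data[s2].to_numpy(dtype=float)

    n_probes = predictions.data.shape[0]
    mean1 = np.full(n_probes, np.nan)
    mean2 = np.full(n_probes, np.nan)
    tstat = np.full(n_probes, np.nan)
    df = np.full(n_probes, np.nan)
    pval = np.full(n_probes, np.nan)
    tested = np.zeros(n_probes, dtype=bool)
    skip_reason = np.array([""] * n_probes, dtype=object)
    for i in range(n_probes):
        g1 = m1[i][~np.isnan(m1[i])]
        g2 = m2[i][~np.isnan(m2[i])]
        if g1.size:
            mean1[i] = g1.mean()
        if g2.size:
            mean2[i] = g2.mean()
        try:
            tstat[i], df[i], pval[i] = welch_t(g1, g2)
            tested[i] = True
        except ValueError as exc:
            skip_reason[i] = str(exc)
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("call_dml skipped %d of %d probes", n_skipped, n_probes)
    qval = bh_adjust(pval)
    delta = mean1 - mean2
    is_dml = tested & (qval < q_threshold) & (np.abs(delta) > delta_threshold)
    direction = np.where(is_dml, np.where(delta < 0, "hypo", "hyper"), "")
    return pd.DataFrame(
        {
            "probe_id": predictions.probe_ids,
            "mean_beta_group1": mean1,
            "mean_beta_group2": mean2,
            "delta_beta": delta,
            "t_statistic": tstat,
            "df": df,
            "p_value": pval,
            "q_value": qval,
            "tested": tested,
            "is_dml": is_dml,
            "direction": direction,
            "skip_reason": skip_reason,
        }
    )


def call_dmg(dmls: pd.DataFrame, manifest: ProbeManifest) -> pd.DataFrame:
    """Roll DMLs up to differentially methylated genes via promoter membership.

    Uses the raw per-gene (gene, category) pairs — not the prioritized
    single category — because promoter membership is a per-gene notion:
    a probe annotated (G1, Body) and (G2, TSS1500) supports G2 only.
    """
    hits: dict[str, list[tuple[str, str]]] = {}
    for _, row in dmls[dmls["is_dml"]].iterrows():
        probe = row["probe_id"]
        if probe not in manifest:
            continue
        for gene, cat in manifest.gene_pairs(probe):
            if cat in PROMOTER_CATEGORIES:
                hits.setdefault(gene, []).append((probe, row["direction"]))
    rows = [
        {
            "gene": gene,
            "n_supporting_dmls": len(support),
            "probes": ";".join(p for p, _ in support),
            "directions": ";".join(d for _, d in support),
        }
        for gene, support in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "n_supporting_dmls", "probes", "directions"])


def summarize_dml_regions(
    dmls: pd.DataFrame, manifest: ProbeManifest
) -> tuple[pd.Series, pd.Series]:
    """Proportions of DML probes per region category and per CGI relation.

    DML probes absent from the manifest count as Intergenic / open sea
    (with a warning); each proportion vector sums to 1.
    """
    probes = dmls.loc[dmls["is_dml"], "probe_id"].tolist()
    if not probes:
        return pd.Series(dtype=float), pd.Series(dtype=float)
    regions, cgis = [], []
    n_unannotated = 0
    for p in probes:
        if p in manifest:
            ann = annotate_region(p, manifest)
            regions.append(ann.region_category)
            cgis.append(ann.cgi_relation)
        else:
            n_unannotated += 1
            regions.append("Intergenic")
            cgis.append("open sea")
    if n_unannotated:
        logger.warning("%d DML probes missing from manifest; counted as Intergenic/open sea",
                       n_unannotated)
    region_prop = pd.Series(regions).value_counts(normalize=True).sort_index()
    cgi_prop = pd.Series(cgis).value_counts(normalize=True).sort_index()
    return region_prop, cgi_prop


def write_dml_table(dmls: pd.DataFrame, manifest: ProbeManifest, path) -> None:
    """DML TSV with genomic context columns prepended."""
    out = dmls.copy()
    chrom, pos, region, cgi = [], [], [], []
    for p in out["probe_id"]:
        if p in manifest:
            c, x = manifest.position(p)
            ann = annotate_region(p, manifest)
            chrom.append(c)
            pos.append(x)
            region.append(ann.region_category)
            cgi.append(ann.cgi_relation)
        else:
            chrom.append("NA")
            pos.append(-1)
            region.append("Intergenic")
            cgi.append("open sea")
    out.insert(1, "chr", chrom)
    out.insert(2, "pos", pos)
    out.insert(3, "region", region)
    out.insert(4, "cgi_relation", cgi)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
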