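"""Differential repeat-type statistics between genome groups.

For each repeat type annotated in every genome of interest, two per-genome
metrics are compared between groups (e.g. symbiotic vs free-living):
``proportion`` (repeat bases over total assembly bases) and ``kimura`` (mean
Kimura divergence of the type's copies). The decision tree per type is:
Shapiro–Wilk on pooled within-group residuals (alpha 0.05) -> log-transform if
normality is violated; Levene's test (median-centred) -> Welch's t-test if
variances are unequal, otherwise Student's; two-sided p-values are adjusted
across all tested types per metric (Benjamini–Hochberg by default), and
adjusted p <= alpha is called significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from kmerphylo.io_formats import FeatureIndex, GenomeRecord, ValidationError

TABLE_COLUMNS = ["repeat_type", "repeat_class", "genome_id", "proportion", "kimura"]
METRICS = ("proportion", "kimura")


def repeat_type_table(genome: GenomeRecord, features: FeatureIndex) -> pd.DataFrame:
    """Per-repeat-type proportional length and mean Kimura divergence for one genome."""
    rows: dict[str, dict] = {}
    for f in features.by_kind("repeat"):
        rtype = f.attributes.get("repeat_type", "unknown")
        row = rows.setdefault(rtype, {
            "repeat_type": rtype,
            "repeat_class": f.attributes.get("repeat_class", "Unknown"),
            "genome_id": genome.genome_id,
            "bases": 0, "kimuras": [],
        })
        row["bases"] += f.length
        if "kimura_divergence" in f.attributes:
            row["kimuras"].append(float(f.attributes["kimura_divergence"]))
    total = genome.total_bases
    records = []
    for row in rows.values():
        records.append({
            "repeat_type": row["repeat_type"],
            "repeat_class": row["repeat_class"],
            "genome_id": row["genome_id"],
            "proportion": row["bases"] / total,
            "kimura": float(np.mean(row["kimuras"])) if row["kimuras"] else np.nan,
        })
    return pd.DataFrame(records, columns=TABLE_COLUMNS)


def combine_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(tables, ignore_index=True)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"repeat table missing columns: {missing}")
    return df


def shared_repeat_types(table: pd.DataFrame, group: list[str]) -> list[str]:
    """Repeat types present (proportion > 0) in every genome of the group."""
    if not group:
        raise ValidationError("empty genome group")
    present = table[(table["proportion"] > 0) & table["genome_id"].isin(group)]
    by_type = present.groupby("repeat_type")["genome_id"].nunique()
    return sorted(by_type[by_type == len(set(group))].index)


@dataclass
class EnrichmentResult:
    repeat_type: str
    repeat_class: str
    metric: str
    transform_applied: str      # 'none' | 'log'
    shapiro_p: float
    variance_test_p: float
    test_used: str              # 'student' | 'welch' | 'skipped'
    raw_p: float
    adjusted_p: float
    direction: str              # 'A>B' | 'A<B' | 'A=B'
    significant: bool
    reason: str = ""


def _decision_tree(values_a: np.ndarray, values_b: np.ndarray,
                   log_eps: float, gate_alpha: float = 0.05):
    """One type's test path; returns the EnrichmentResult fields before adjustment."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return dict(transform_applied="none", shapiro_p=np.nan,
                    variance_test_p=np.nan, test_used="student",
                    raw_p=1.0, reason="all values identical")
    if np.var(a) == 0 and np.var(b) == 0:
        return dict(transform_applied="none", shapiro_p=np.nan,
                    variance_test_p=np.nan, test_used="skipped",
                    raw_p=np.nan, reason="zero within-group variance in both groups")

    transform = "none"
    shapiro_p = np.nan
    residuals = np.concatenate([a - a.mean(), b - b.mean()])
    if len(residuals) >= 3 and np.ptp(residuals) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_p = float(stats.shapiro(residuals).pvalue)
        if shapiro_p < gate_alpha:
            transform = "log"
            a = np.log(np.where(a > 0, a, log_eps))
            b = np.log(np.where(b > 0, b, log_eps))
            if np.var(a) == 0 and np.var(b) == 0:
                return dict(transform_applied="log", shapiro_p=shapiro_p,
                            variance_test_p=np.nan, test_used="skipped",
                            raw_p=np.nan,
                            reason="zero within-group variance after transform")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        levene_p = float(stats.levene(a, b, center="median").pvalue)
    equal_var = not (levene_p < gate_alpha)
    test_used = "student" if equal_var else "welch"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw_p = float(stats.ttest_ind(a, b, equal_var=equal_var,
                                      alternative="two-sided").pvalue)
    if np.isnan(raw_p):
        return dict(transform_applied=transform, shapiro_p=shapiro_p,
                    variance_test_p=levene_p, test_used="skipped",
                    raw_p=np.nan, reason="t-test undefined")
    return dict(transform_applied=transform, shapiro_p=shapiro_p,
                variance_test_p=levene_p, test_used=test_used,
                raw_p=raw_p, reason="")


def enrichment_test(table: pd.DataFrame, group_a: list[str], group_b: list[str],
                    metric: str = "proportion", alpha: float = 0.05,
                    adjust_method: str = "fdr_bh",
                    types: list[str] | None = None) -> list[EnrichmentResult]:
    """Screen repeat types for a group difference in one metric.

    Only types with values in every genome of both groups are tested (pass
    ``types`` to restrict further, e.g. to the shared types of one group).
    ``adjust_method`` is any statsmodels ``multipletests`` method
    ('fdr_bh' default, 'bonferroni' available). Direction is the sign of the
    group-mean difference on the original scale.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 genomes")
    sub = table.dropna(subset=[metric])
    positives = sub.loc[sub[metric] > 0, metric]
    log_eps = float(positives.min()) / 2.0 if len(positives) else 1e-12

    classes = dict(zip(table["repeat_type"], table["repeat_class"]))
    candidates = types if types is not None else sorted(sub["repeat_type"].unique())

    rows = []
    for rtype in candidates:
        tsub = sub[sub["repeat_type"] == rtype]
        va = tsub[tsub["genome_id"].isin(group_a)].set_index("genome_id")[metric]
        vb = tsub[tsub["genome_id"].isin(group_b)].set_index("genome_id")[metric]
        if len(va) < len(set(group_a)) or len(vb) < len(set(group_b)):
            continue
        fields = _decision_tree(va.to_numpy(), vb.to_numpy(), log_eps)
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        direction = "A=B" if mean_a == mean_b else ("A>B" if mean_a > mean_b else "A<B")
        rows.append((rtype, direction, fields))

    tested = [(i, r) for i, r in enumerate(rows) if not np.isnan(r[2]["raw_p"])]
    adjusted = np.full(len(rows), np.nan)
    if tested:
        raw = [r[2]["raw_p"] for _, r in tested]
        _, adj, _, _ = multipletests(raw, alpha=alpha, method=adjust_method)
        for (i, _), p in zip(tested, adj):
            adjusted[i] = p

    results = []
    for (rtype, direction, fields), adj_p in zip(rows, adjusted):
        significant = bool(not np.isnan(adj_p) and adj_p <= alpha)
        results.append(EnrichmentResult(
            repeat_type=rtype,
            repeat_class=classes.get(rtype, "Unknown"),
            metric=metric,
            transform_applied=fields["transform_applied"],
            shapiro_p=fields["shapiro_p"],
            variance_test_p=fields["variance_test_p"],
            test_used=fields["test_used"],
            raw_p=fields["raw_p"],
            adjusted_p=float(adj_p),
            direction=direction,
            significant=significant,
            reason=fields["reason"],
        ))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summarise_by_class(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Counts and percentages of significant repeat types per repeat class.

    A type significant under both metrics is counted once, with per-metric
    flags recorded.
    """
    sig: dict[str, dict] = {}
    for r in results:
        if not r.significant:
            continue
        entry = sig.setdefault(r.repeat_type, {
            "repeat_class": r.repeat_class, "proportion": False, "kimura": False})
        entry[r.metric] = True
    if not sig:
        return pd.DataFrame(columns=["repeat_class", "n_types", "percent",
                                     "n_proportion", "n_kimura", "n_both"])
    rows = []
    total = len(sig)
    by_class: dict[str, list] = {}
    for rtype, entry in sig.items():
        by_class.setdefault(entry["repeat_class"], []).append(entry)
    for cls in sorted(by_class):
        entries = by_class[cls]
        rows.append({
            "repeat_class": cls,
            "n_types": len(entries),
            "percent": 100.0 * len(entries) / total,
            "n_proportion": sum(e["proportion"] for e in entries),
            "n_kimura": sum(e["kimura"] for e in entries),
            "n_both": sum(e["proportion"] and e["kimura"] for e in entries),
        })
    return pd.DataFrame(rows)
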