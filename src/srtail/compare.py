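"""Between-sample comparison: feature counts, fold changes, ectopic
siRNA-gain calls, and the expression-shift statistic for genes that acquire
siRNAs in tailing-deficient mutants.

The headline biology: in cells lacking the sRNA-degrading nucleotidyl
transferases, new siRNAs appear at euchromatic genes that carry none in
wild type, and those genes' mRNAs shift down — RNAi-mediated silencing.
``sirna_gain_features`` flags the gaining genes (mutant RPM above a floor,
wild-type RPM below a ceiling); ``expression_shift_summary`` compares the
log2 expression fold changes of gain genes against the rest with the
two-sided Welch (unequal-variance) t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from srtail.classify import FeatureDB
from srtail.tailstats import rpm as _rpm


def per_feature_counts(table: pd.DataFrame, db: FeatureDB) -> pd.DataFrame:
    """Read counts and RPM per feature (plus an ``intergenic`` row).

    Input is a classified per-read table; reads count toward the feature
    recorded by the classifier, so feature counts + the intergenic count
    partition the mapped reads.
    """
    m = table[table["mapped"].astype(bool)]
    counts = m["feature_id"].replace("", "intergenic").value_counts()
    meta = {f.feature_id: (f.ftype, f.strand) for f in db.features}
    rows = []
    for fid in sorted(set(counts.index) | {f.feature_id for f in db.features if f.ftype != "exon" and f.ftype != "intron"}):
        c = int(counts.get(fid, 0))
        ftype, strand = meta.get(fid, ("intergenic", "."))
        rows.append({"feature_id": fid, "feature_type": ftype, "strand": strand, "count": c})
    out = pd.DataFrame(rows).set_index("feature_id")
    total = int(m.shape[0])
    out["rpm"] = _rpm(out["count"], total) if total else 0.0
    out.attrs["mapped_reads"] = total
    return out


def fold_change(a, b, pseudocount: float = 0.5):
    """Per-feature ratio (a + pc) / (b + pc).

    ``a`` and ``b`` may be scalars, Series/arrays of per-feature values, or
    2-D replicate matrices (features x replicates), which are averaged
    across replicates first. The pseudocount keeps ratios finite at zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    def prep(x):
        if isinstance(x, pd.DataFrame):
            return x.mean(axis=1)
        x = np.asarray(x, dtype=float) if not isinstance(x, pd.Series) else x
        if getattr(x, "ndim", 0) == 2:
            return x.mean(axis=1)
        return x

    return (prep(a) + pseudocount) / (prep(b) + pseudocount)


def sirna_gain_features(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    min_rpm: float = 5.0,
    max_wt_rpm: float = 0.5,
    feature_types: tuple[str, ...] = ("mRNA",),
) -> pd.DataFrame:
    """Flag features that gain siRNAs in the mutant.

    ``wt``/``mut`` are per-feature tables from :func:`per_feature_counts`
    (aligned on feature_id). gain_flag <=> mut RPM >= min_rpm AND wt RPM <=
    max_wt_rpm, restricted to ``feature_types``. The thresholds used are
    recorded in the result's columns and ``attrs``.
    """
    idx = wt.index.union(mut.index)
    wt_rpm = wt["rpm"].reindex(idx, fill_value=0.0)
    mut_rpm = mut["rpm"].reindex(idx, fill_value=0.0)
    ftype = wt["feature_type"].reindex(idx).fillna(mut["feature_type"].reindex(idx))
    out = pd.DataFrame(
        {
            "feature_type": ftype,
            "wt_rpm": wt_rpm,
            "mut_rpm": mut_rpm,
            "gain_flag": (mut_rpm >= min_rpm)
            & (wt_rpm <= max_wt_rpm)
            & ftype.isin(feature_types),
            "min_rpm": min_rpm,
            "max_wt_rpm": max_wt_rpm,
        }
    )
    out.attrs["min_rpm"] = min_rpm
    out.attrs["max_wt_rpm"] = max_wt_rpm
    return out.sort_index()


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sided Welch t-test for two independent samples.

    Returns (t, Welch-Satterthwaite df, two-sided p). Requires n >= 2 per
    sample. Suited to datasets with unequal ("high") variance; no pooled
    variance is assumed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def expression_shift_summary(fc_all: pd.Series, gain_ids) -> dict:
    """Quartiles of log2 expression fold change, all genes vs siRNA-gain genes.

    ``fc_all`` holds per-gene linear fold changes (mutant / wild type);
    ``gain_ids`` the features flagged by :func:`sirna_gain_features`.
    Reports median/quartiles for all genes and for the gain set, plus the
    two-sided Welch p comparing gain genes with the remaining genes.
    Gene order never matters. With an empty gain set the summary covers all
    genes only and carries an explicit notice instead of a test.
    """
    log2fc = np.log2(fc_all.astype(float)).sort_index()
    gain_ids = [g for g in gain_ids if g in log2fc.index]

    def quartiles(v: pd.Series) -> dict:
        q = v.quantile([0.25, 0.5, 0.75])
        return {"q25": float(q[0.25]), "median": float(q[0.5]), "q75": float(q[0.75]), "n": int(len(v))}

    out = {"all_genes": quartiles(log2fc)}
    if not gain_ids:
        out["notice"] = "no siRNA-gain genes; shift test not performed"
        return out
    gain = log2fc.loc[sorted(gain_ids)]
    rest = log2fc.drop(index=gain.index)
    out["gain_genes"] = quartiles(gain)
    t, df, p = welch_t(gain.values, rest.values)
    out["welch_t"] = {"t": t, "df": df, "p": p}
    return out
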