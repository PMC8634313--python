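"""Family-level TE expression: counting, TPM, differential expression.

TE expression is quantified per family (one consensus = one family):
each read keeps a single alignment, counts are concatenated with gene
counts so library-size normalization sees the full transcriptome, and
abundances are expressed in TPM (reads per kilobase of consensus,
rescaled so each replicate sums to one million).

Differential expression uses median-of-ratios size factors and a
negative-binomial Wald test with method-of-moments dispersion,
Benjamini-Hochberg adjusted; externally computed results tables
(log2 fold change, adjusted p) can be imported instead, in which case
only the thresholding/classification layer of this module applies.
Genes are carried through normalization and testing but dropped from
reporting. A family is differentially expressed when padj < 0.05 and
|log2FC| >= 2; induced/repressed flags additionally track crossings of
the 4-TPM expression threshold between mock and infected conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chimera import ReadAlignment

logger = logging.getLogger(__name__)

TPM_EXPRESSED = 4.0  # below: not expressed / very lowly expressed
TPM_HIGH = 50.0  # at or above: highly expressed (~100 RPKM in these libraries)
DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 2.0
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CountTable:
    """Joint gene + TE-family count table with sample metadata.

    ``counts``: entities x replicates, non-negative integers.
    ``meta``: per-entity ``kind`` ('gene' or 'te_family') and
    ``length`` (bp; consensus length for TE families).
    ``samples``: per-replicate ``condition`` ('mock'/'infected') and
    optional ``time_point`` (hpi).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.index]
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.meta["length"] <= 0).any():
            raise ValueError("every entity needs a positive length")
        bad = set(self.samples["condition"]) - {"mock", "infected"}
        if bad:
            raise ValueError(f"unknown conditions: {bad}")

    @property
    def te_names(self) -> pd.Index:
        return self.meta.index[self.meta["kind"] == "te_family"]


# ---------------------------------------------------------------------------
# counting


def count_reads_per_family(
    alignments: Iterable[ReadAlignment | tuple[str, str]],
    copy_to_family: Mapping[str, str],
) -> pd.Series:
    """Tally reads per TE family, one retained alignment per read.

    ``alignments`` may contain several hits per read; a single one is
    kept (longest alignment, ties broken by sorted family then copy
    name) so multi-mapping reads count once. Plain ``(read_id,
    copy_name)`` tuples are also accepted. Alignments to copies absent
    from ``copy_to_family`` are logged and skipped.
    """
    best: dict[str, tuple] = {}
    for a in alignments:
        if isinstance(a, ReadAlignment):
            read_id, copy_name, length = a.read_id, a.subject_name, a.aligned_length
        else:
            read_id, copy_name = a
            length = 0
        family = copy_to_family.get(copy_name)
        if family is None:
            logger.warning("alignment to unknown copy %s skipped", copy_name)
            continue
        key = (-length, family, copy_name)
        if read_id not in best or key < best[read_id][:3]:
            best[read_id] = (*key, family)
    counts: dict[str, int] = {}
    for *_, family in best.values():
        counts[family] = counts.get(family, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(table: CountTable | pd.DataFrame, lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts per million over genes and TE families jointly.

    Per replicate: RPK = count / (length in kb); TPM = RPK scaled so
    the replicate column sums to 10^6. Replicates with zero total
    counts yield NaN columns and a warning.
    """
    if isinstance(table, CountTable):
        counts, lengths = table.counts, table.meta["length"]
    else:
        counts = table
        if lengths is None:
            raise ValueError("lengths required when passing a bare counts frame")
    rpk = counts.div(lengths / 1e3, axis=0)
    per_million = rpk.sum(axis=0) / 1e6
    zero = per_million == 0
    if zero.any():
        logger.warning("replicates with zero counts, TPM undefined: %s", list(counts.columns[zero]))
        per_million = per_million.replace(0, np.nan)
    return rpk.div(per_million, axis=1)


def classify_expression(mean_tpm: float) -> str:
    """Expression category from mean TPM: <4 not expressed, >=50 high."""
    if mean_tpm < 0 or np.isnan(mean_tpm):
        raise ValueError(f"mean TPM must be non-negative, got {mean_tpm}")
    if mean_tpm < TPM_EXPRESSED:
        return "not_expressed"
    if mean_tpm >= TPM_HIGH:
        return "highly_expressed"
    return "expressed"


def classify_expression_series(mean_tpm: pd.Series) -> pd.Series:
    if (mean_tpm < 0).any() or mean_tpm.isna().any():
        raise ValueError("mean TPM must be non-negative and defined")
    out = pd.Series("expressed", index=mean_tpm.index, dtype=object)
    out[mean_tpm < TPM_EXPRESSED] = "not_expressed"
    out[mean_tpm >= TPM_HIGH] = "highly_expressed"
    return out


# ---------------------------------------------------------------------------
# differential expression


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (computed on genes + TEs).

    Each replicate's factor is the median, over entities with non-zero
    counts in every replicate, of the ratio of its count to the
    entity's geometric mean across replicates.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no entity with non-zero counts in all replicates")
    log_arr = np.log(arr[positive])
    log_geo = log_arr.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_arr - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion, pooled across conditions.

    For each entity, alpha solves var = mu + alpha*mu^2 within each
    condition; contributions are pooled as
    sum(var_c - mu_c) / sum(mu_c^2), floored at zero.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += var - mu
        den += mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, 0.0, None)


def nb_wald_test(
    counts: pd.DataFrame,
    mock_cols: Sequence[str],
    infected_cols: Sequence[str],
    sf: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Negative-binomial Wald test for infected vs mock, per entity.

    Counts are normalized by the size factors; the log2 fold change is
    computed from normalized condition means with a pseudocount, and
    its standard error by the delta method under the NB variance
    var = mu + alpha*mu^2 with method-of-moments alpha. Returns
    ``base_mean``, ``log2fc``, ``se``, ``stat`` and ``pvalue``.
    """
    cols = list(mock_cols) + list(infected_cols)
    norm = (counts[cols] / sf[cols]).to_numpy(dtype=float)
    n_mock = len(mock_cols)
    idx_mock = np.arange(n_mock)
    idx_inf = np.arange(n_mock, norm.shape[1])

    mean_mock = norm[:, idx_mock].mean(axis=1)
    mean_inf = norm[:, idx_inf].mean(axis=1)
    lfc = np.log2(mean_inf + pseudocount) - np.log2(mean_mock + pseudocount)

    alpha = _mom_dispersion(norm, [idx_mock, idx_inf])
    mu_m = mean_mock + pseudocount
    mu_i = mean_inf + pseudocount
    # Var(log2 mean) ~= Var(mean) / (mean * ln2)^2, Var(mean) = (mu + a mu^2)/n
    var_lm = (mu_m + alpha * mu_m**2) / len(idx_mock) / (mu_m * np.log(2)) ** 2
    var_li = (mu_i + alpha * mu_i**2) / len(idx_inf) / (mu_i * np.log(2)) ** 2
    se = np.sqrt(var_lm + var_li)
    stat = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "base_mean": (mean_mock + mean_inf) / 2.0,
            "log2fc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=counts.index,
    )


def apply_de_thresholds(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Flag differential expression: padj < alpha and |log2FC| >= lfc_min.

    ``results`` needs ``log2fc`` and ``padj`` columns (e.g. an imported
    table from an external DE engine); a ``de_flag`` column with values
    up/down/ns is added.
    """
    flags = pd.Series("ns", index=results.index, dtype=object)
    sig = results["padj"] < alpha
    flags[sig & (results["log2fc"] >= lfc_min)] = "up"
    flags[sig & (results["log2fc"] <= -lfc_min)] = "down"
    out = results.copy()
    out["de_flag"] = flags
    return out


def call_de(
    table: CountTable,
    design: str = "matched",
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    report_kinds: tuple[str, ...] = ("te_family",),
) -> pd.DataFrame:
    """Run the per-time-point differential-expression contrasts.

    Two designs are supported: ``matched`` contrasts infected vs mock
    replicates at each time point (the tissue time-course layout), and
    ``baseline`` contrasts each infected time point against the mock at
    the earliest time point (the cell-line layout, where mocks drift as
    uninfected cultures grow). Size factors come from the full gene+TE
    table; BH adjustment is per contrast over all tested entities, and
    genes are dropped from the returned records afterwards.

    Contrasts with fewer than 2 replicates on either side raise, except
    for a missing matched mock time point, which is skipped with a
    warning. Returns one row per (entity, time_point) with base_mean,
    log2fc, pvalue, padj and de_flag.
    """
    if design not in ("matched", "baseline"):
        raise ValueError(f"design must be 'matched' or 'baseline', got {design!r}")
    samples = table.samples
    if "time_point" not in samples.columns:
        raise ValueError("samples need a 'time_point' column")
    sf = size_factors(table.counts)

    infected_tps = sorted(samples.loc[samples["condition"] == "infected", "time_point"].unique())
    if design == "baseline":
        mock_tps = samples.loc[samples["condition"] == "mock", "time_point"]
        if mock_tps.empty:
            raise ValueError("baseline design needs mock replicates")
        baseline_tp = mock_tps.min()
        baseline_cols = samples.index[
            (samples["condition"] == "mock") & (samples["time_point"] == baseline_tp)
        ]
        if len(baseline_cols) < 2:
            raise ValueError("baseline mock needs at least 2 replicates")

    results = []
    for tp in infected_tps:
        inf_cols = samples.index[
            (samples["condition"] == "infected") & (samples["time_point"] == tp)
        ]
        if design == "matched":
            mock_cols = samples.index[
                (samples["condition"] == "mock") & (samples["time_point"] == tp)
            ]
            if len(mock_cols) == 0:
                logger.warning("no mock replicates at %s hpi; contrast skipped", tp)
                continue
        else:
            mock_cols = baseline_cols
        if len(inf_cols) < 2 or len(mock_cols) < 2:
            raise ValueError(f"contrast at {tp} hpi has fewer than 2 replicates per side")
        res = nb_wald_test(table.counts, list(mock_cols), list(inf_cols), sf, pseudocount)
        res["padj"] = multipletests(res["pvalue"].to_numpy(), method="fdr_bh")[1]
        res = apply_de_thresholds(res, alpha=alpha, lfc_min=lfc_min)
        res["time_point"] = tp
        res["entity"] = res.index
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["entity", "time_point", "base_mean", "log2fc", "se", "stat",
                     "pvalue", "padj", "de_flag"]
        )
    out = pd.concat(results, ignore_index=True)
    keep = table.meta.index[table.meta["kind"].isin(report_kinds)]
    out = out[out["entity"].isin(keep)].reset_index(drop=True)
    return out[["entity", "time_point", "base_mean", "log2fc", "se", "stat", "pvalue", "padj", "de_flag"]]


# ---------------------------------------------------------------------------
# induced / repressed classification


def classify_induced_repressed(
    de_flags: pd.DataFrame,
    mock_tpm: pd.DataFrame | pd.Series,
    infected_tpm: pd.DataFrame,
    threshold: float = TPM_EXPRESSED,
) -> pd.DataFrame:
    """Flag families whose expression crosses the 4-TPM threshold.

    ``de_flags``: family x time-point frame of up/down/ns calls.
    ``mock_tpm``: family x time-point mock TPM (matched design) or a
    per-family Series (baseline design). ``infected_tpm``: family x
    time-point TPM in the infected condition.

    Induced: mock TPM below threshold at every mock time point,
    infected TPM at or above threshold at >=1 time point, and
    upregulated at >=1 time point. Repressed: mock TPM at or above
    threshold at every mock time point, infected TPM below threshold at
    >=1 time point, and downregulated at >=1 time point.
    """
    if isinstance(mock_tpm, pd.Series):
        mock_tpm = mock_tpm.to_frame("mock")
    mock_low = (mock_tpm < threshold).all(axis=1)
    mock_high = (mock_tpm >= threshold).all(axis=1)
    inf_on = (infected_tpm >= threshold).any(axis=1)
    inf_off = (infected_tpm < threshold).any(axis=1)
    up_any = (de_flags == "up").any(axis=1)
    down_any = (de_flags == "down").any(axis=1)
    idx = de_flags.index
    return pd.DataFrame(
        {
            "induced": (mock_low & inf_on & up_any).reindex(idx, fill_value=False),
            "repressed": (mock_high & inf_off & down_any).reindex(idx, fill_value=False),
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# factor correlations


def correlate_factors(
    expression: pd.Series, factors: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of family expression with per-family factors.

    Pairwise-complete observations; factors with zero variance (or
    fewer than 3 complete pairs) yield NaN and a warning. Returns a
    frame indexed by factor with columns ``r``, ``p`` and ``n``.
    """
    rows = {}
    for name in factors.columns:
        pair = pd.concat([expression, factors[name]], axis=1, join="inner").dropna()
        x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            logger.warning("correlation with %s undefined (n=%d or zero variance)", name, len(x))
            rows[name] = {"r": np.nan, "p": np.nan, "n": len(x)}
            continue
        r, p = stats.pearsonr(x, y)
        rows[name] = {"r": r, "p": p, "n": len(x)}
    return pd.DataFrame.from_dict(rows, orient="index")


def mean_tpm_by_condition(
    tpm: pd.DataFrame, samples: pd.DataFrame, by_time: bool = True
) -> dict[str, pd.DataFrame]:
    """Average replicate TPM per condition (and time point).

    Returns ``{condition: families x time-point frame}`` (or a single
    mean column when ``by_time`` is false).
    """
    out: dict[str, pd.DataFrame] = {}
    for cond, grp in samples.groupby("condition"):
        if by_time and "time_point" in samples.columns:
            cols = {
                tp: tpm[g.index].mean(axis=1) for tp, g in grp.groupby("time_point")
            }
            out[cond] = pd.DataFrame(cols)
        else:
            out[cond] = tpm[grp.index].mean(axis=1).to_frame("mean_tpm")
    return out
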