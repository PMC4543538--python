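"""Differential-expression calling on replicate log2 ratios.

Significance follows the classic two-color rule: a gene at a time point
is called when the replicate mean passes a 2-fold cut-off (|mean log2
ratio| >= 1) AND a one-sample two-sided t-test of the replicate log2
ratios against zero gives p < 0.05. No multiple-testing correction
gates the call, matching common practice for this design; a
Benjamini-Hochberg adjusted column is emitted alongside for
transparency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionSeries

logger = logging.getLogger(__name__)

#: Sentinel p-value for replicates that are exactly equal and nonzero:
#: the observed change is perfectly reproducible, variance is zero and
#: the t statistic diverges, so the cell is flagged significant by policy.
ZERO_VARIANCE_P = 0.0


@dataclass(frozen=True)
class DECall:
    """Differential-expression call for one gene at one time point."""

    gene_id: str
    time_min: float
    mean_log2_ratio: float
    fold_change: float  # signed: +fold up, -fold down
    p_value: float
    significant: bool
    direction: str  # up | down | none
    n_replicates: int
    testable: bool


def t_test_gene(values, null_mean: float = 0.0):
    """One-sample two-sided t-test of replicate log2 ratios.

    Returns ``(t, p)``; with fewer than two finite values the gene is
    untestable and ``(nan, nan)`` is returned (never silently
    significant). Degenerate zero-variance replicates are resolved by
    policy: all equal to the null mean gives p = 1; all equal elsewhere
    gives the sentinel ``ZERO_VARIANCE_P`` with an infinite t.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan"), float("nan")
    if np.ptp(v) == 0.0:
        if v[0] == null_mean:
            return 0.0, 1.0
        return float(np.sign(v[0] - null_mean)) * np.inf, ZERO_VARIANCE_P
    t, p = stats.ttest_1samp(v, null_mean)
    return float(t), float(p)


def signed_fold(mean_log2: float) -> float:
    """Signed fold change: 2^m for induction, -2^(-m) for repression."""
    if mean_log2 >= 0:
        return float(2.0 ** mean_log2)
    return float(-(2.0 ** (-mean_log2)))


def call_de(series: ExpressionSeries, fold_cutoff: float = 2.0,
            alpha: float = 0.05) -> pd.DataFrame:
    """Per (gene, time) differential-expression calls.

    Returns a DataFrame with columns gene, time_min, mean_log2,
    fold_change, p, p_bh, significant, direction, n_replicates,
    testable. Significance requires |mean_log2| >= log2(fold_cutoff)
    and p < alpha; the BH column is informational only.
    """
    if fold_cutoff < 1:
        raise ValueError("fold cutoff must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    log_cut = np.log2(fold_cutoff)
    rows = []
    for g, gene in enumerate(series.gene_ids):
        for t, tm in enumerate(series.time_points_min):
            v = series.values[g, t, :]
            v = v[np.isfinite(v)]
            n = int(v.size)
            mean = float(v.mean()) if n else float("nan")
            tstat, p = t_test_gene(v)
            testable = n >= 2
            sig = bool(testable and np.isfinite(mean)
                       and abs(mean) >= log_cut and p < alpha)
            direction = "none"
            if sig:
                direction = "up" if mean > 0 else "down"
            rows.append((gene, tm, mean,
                         signed_fold(mean) if n else float("nan"),
                         p, sig, direction, n, testable))
    df = pd.DataFrame(rows, columns=["gene", "time_min", "mean_log2",
                                     "fold_change", "p", "significant",
                                     "direction", "n_replicates",
                                     "testable"])
    ok = df["p"].notna()
    df["p_bh"] = np.nan
    if ok.any():
        df.loc[ok, "p_bh"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    logger.info("differential expression: %d tests, %d significant "
                "(no multiplicity gate; BH column informational)",
                int(ok.sum()), int(df["significant"].sum()))
    return df[["gene", "time_min", "mean_log2", "fold_change", "p", "p_bh",
               "significant", "direction", "n_replicates", "testable"]]


def de_call_records(calls: pd.DataFrame) -> list:
    """View a :func:`call_de` table as a list of :class:`DECall` records."""
    return [
        DECall(gene_id=row.gene, time_min=float(row.time_min),
               mean_log2_ratio=float(row.mean_log2),
               fold_change=float(row.fold_change),
               p_value=float(row.p), significant=bool(row.significant),
               direction=row.direction, n_replicates=int(row.n_replicates),
               testable=bool(row.testable))
        for row in calls.itertuples(index=False)
    ]


class AnnotationMap:
    """Total gene -> (product, category, regulators) lookup.

    Built from a user-supplied TSV (gene, product, category, regulators
    with regulators semicolon-separated); lookups of unknown genes
    return an explicit ``unannotated`` record rather than raising.
    """

    UNANNOTATED = ("unannotated", "unannotated", ())

    def __init__(self, mapping: dict = None):
        self._map = dict(mapping or {})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationMap":
        required = {"gene", "product", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        mapping = {}
        for _, row in df.iterrows():
            regs = row.get("regulators", "")
            regs = tuple(r for r in str(regs).split(";") if r and r != "nan")
            mapping[str(row["gene"])] = (str(row["product"]),
                                         str(row["category"]), regs)
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def __getitem__(self, gene_id: str):
        return self._map.get(gene_id, self.UNANNOTATED)

    def __contains__(self, gene_id: str):
        return gene_id in self._map


def summarize_fold_changes(calls, annot: AnnotationMap = None,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Gene x (condition, time) table of mean signed fold changes.

    ``calls`` maps condition label -> call DataFrame from
    :func:`call_de` (a bare DataFrame is treated as one unnamed
    condition). Cells whose p exceeds ``alpha`` are flagged with a
    trailing ``*`` in the companion flag columns; annotation misses are
    filled with ``unannotated`` and logged.
    """
    if isinstance(calls, pd.DataFrame):
        calls = {"condition": calls}
    if not calls:
        return pd.DataFrame(columns=["gene", "product", "category",
                                     "regulators"])
    frames = []
    for cond, df in calls.items():
        sub = df[["gene", "time_min", "fold_change", "p"]].copy()
        sub["column"] = [f"{cond}@{tm:g}min" for tm in sub["time_min"]]
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    fold = long.pivot(index="gene", columns="column", values="fold_change")
    pvals = long.pivot(index="gene", columns="column", values="p")
    flags = (pvals > alpha) | pvals.isna()
    out = fold.copy()
    for col in flags.columns:
        out[col + " flag"] = np.where(flags[col], "*", "")
    out = out[sorted(out.columns)]
    out.insert(0, "gene", out.index)
    if annot is not None:
        misses = [g for g in out.index if g not in annot]
        if misses:
            logger.warning("%d genes without annotation", len(misses))
        out.insert(1, "product", [annot[g][0] for g in out.index])
        out.insert(2, "category", [annot[g][1] for g in out.index])
        out.insert(3, "regulators", [";".join(annot[g][2])
                                     for g in out.index])
    return out.reset_index(drop=True)
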