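"""Two-color array preprocessing: ratios, LOWESS normalization, assembly.

Raw two-channel fluorescence tables are turned into per-gene log2
expression-ratio time series in three steps:

1. ``compute_ratios`` — per-feature log ratio M = log2(experimental /
   control), oriented by the dye assignment so that positive M always
   means induction, plus the mean log intensity A = 0.5 * log2(Cy3 * Cy5)
   (the MA representation).
2. ``lowess_normalize`` — per-array locally weighted regression of M on A;
   the fitted intensity-dependent trend (dye bias) is subtracted.
3. ``assemble_series`` — normalized arrays are stacked into a
   gene x time x replicate :class:`ExpressionSeries` tensor.

The module also provides the hybridization quality-control calculators
(cDNA yield from A260 and dye specific activity) and their pass rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .design import ExperimentDesign

#: Columns of the long-format two-color array table.
ARRAY_TABLE_COLUMNS = [
    "feature_id",
    "cy3",
    "cy5",
    "exp_dye",
    "replicate_id",
    "time_min",
    "condition",
]

#: Nanograms of single-stranded cDNA per A260 unit per microliter.
CDNA_NG_PER_A260_UL = 330.0


# ---------------------------------------------------------------------------
# Quality control (sample suitability for hybridization)
# ---------------------------------------------------------------------------

def cdna_yield(a260: float, elution_volume_ul: float = 50.0) -> float:
    """Yield of labelled cDNA in nanograms from an A260 reading.

    yield [ng] = A260 x 330 ng/ul x elution volume [ul]
    """
    if a260 < 0:
        raise ValueError("A260 absorbance cannot be negative")
    if elution_volume_ul <= 0:
        raise ValueError("elution volume must be positive")
    return a260 * CDNA_NG_PER_A260_UL * elution_volume_ul


def specific_activity(dye_pmol_per_ul: float, cdna_ng_per_ul: float) -> float:
    """Dye incorporation in pmol Cy3/Cy5 per microgram of cDNA.

    specific activity = (dye [pmol/ul] / cDNA [ng/ul]) x 1000
    """
    if dye_pmol_per_ul < 0:
        raise ValueError("dye concentration cannot be negative")
    if cdna_ng_per_ul <= 0:
        raise ValueError("cDNA concentration must be positive")
    return dye_pmol_per_ul / cdna_ng_per_ul * 1000.0


@dataclass(frozen=True)
class QCRecord:
    """Quality-control summary for one labelled cDNA sample."""

    sample_id: str
    a260: float
    cdna_yield_ng: float
    dye_pmol_per_ul: float
    cdna_ng_per_ul: float
    specific_activity: float
    passed: bool


def evaluate_qc(
    sample_id: str,
    a260: float,
    dye_pmol_per_ul: float,
    elution_volume_ul: float = 50.0,
    yield_threshold_ng: float = 825.0,
    activity_threshold: float = 8.0,
) -> QCRecord:
    """Apply the hybridization suitability rule to one sample.

    A sample passes iff yield > ``yield_threshold_ng`` (default 825 ng)
    and specific activity > ``activity_threshold`` (default 8 pmol/ug);
    both inequalities are strict.
    """
    y = cdna_yield(a260, elution_volume_ul)
    conc = a260 * CDNA_NG_PER_A260_UL
    sa = specific_activity(dye_pmol_per_ul, conc) if conc > 0 else 0.0
    return QCRecord(
        sample_id=sample_id,
        a260=a260,
        cdna_yield_ng=y,
        dye_pmol_per_ul=dye_pmol_per_ul,
        cdna_ng_per_ul=conc,
        specific_activity=sa,
        passed=(y > yield_threshold_ng) and (sa > activity_threshold),
    )


# ---------------------------------------------------------------------------
# Expression series container
# ---------------------------------------------------------------------------

class ExpressionSeries:
    """Per-gene log2 expression-ratio time series with replicate structure.

    Parameters
    ----------
    gene_ids : sequence of str
    time_points_min : sequence of float
    replicate_ids : sequence of str
    values : ndarray, shape (n_genes, n_time, n_replicates)
        log2(experimental / control) ratios, NaN marking missing cells.
    condition : str
        Condition label of the series.
    """

    def __init__(self, gene_ids, time_points_min, replicate_ids, values,
                 condition="condition"):
        self.gene_ids = list(gene_ids)
        self.time_points_min = [float(t) for t in time_points_min]
        self.replicate_ids = list(replicate_ids)
        values = np.asarray(values, dtype=float)
        expected = (len(self.gene_ids), len(self.time_points_min),
                    len(self.replicate_ids))
        if values.shape != expected:
            raise ValueError(f"values shape {values.shape} != {expected}")
        self.values = values
        self.condition = condition

    @property
    def shape(self):
        return self.values.shape

    def replicate_mean(self) -> np.ndarray:
        """Gene x time matrix of replicate means (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=2)

    def centered_at_reference(self) -> "ExpressionSeries":
        """Subtract each gene's replicate-mean value at the first time point.

        Absorbs per-gene baseline offsets so that activity changes are
        expressed relative to the pre-treatment reference.
        """
        baseline = self.replicate_mean()[:, [0]]
        return ExpressionSeries(
            self.gene_ids, self.time_points_min, self.replicate_ids,
            self.values - baseline[:, :, None], self.condition,
        )

    def negated(self) -> "ExpressionSeries":
        return ExpressionSeries(
            self.gene_ids, self.time_points_min, self.replicate_ids,
            -self.values, self.condition,
        )

    def to_long(self) -> pd.DataFrame:
        """Long format: gene, condition, time_min, replicate, M."""
        g, t, r = np.meshgrid(
            np.arange(len(self.gene_ids)),
            np.arange(len(self.time_points_min)),
            np.arange(len(self.replicate_ids)),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "gene": np.asarray(self.gene_ids)[g.ravel()],
                "condition": self.condition,
                "time_min": np.asarray(self.time_points_min)[t.ravel()],
                "replicate": np.asarray(self.replicate_ids)[r.ravel()],
                "M": self.values.ravel(),
            }
        )
        return df[df["M"].notna()].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame, design: ExperimentDesign = None
                  ) -> "ExpressionSeries":
        required = {"gene", "time_min", "replicate", "M"}
        if not required.issubset(df.columns):
            raise ValueError(f"long table must have columns {sorted(required)}")
        conditions = (df["condition"].unique().tolist()
                      if "condition" in df.columns else ["condition"])
        if len(conditions) != 1:
            raise ValueError(
                "one series holds one condition; got " + repr(conditions))
        dup = df.duplicated(subset=["gene", "time_min", "replicate"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate record for gene={first['gene']!r} "
                f"time={first['time_min']} replicate={first['replicate']!r}")
        genes = sorted(df["gene"].astype(str).unique())
        if design is not None:
            times = [float(t) for t in design.time_points_min]
            reps = design.replicate_ids
        else:
            times = sorted(df["time_min"].astype(float).unique())
            reps = sorted(df["replicate"].astype(str).unique())
        gi = {g: i for i, g in enumerate(genes)}
        ti = {t: i for i, t in enumerate(times)}
        ri = {r: i for i, r in enumerate(reps)}
        values = np.full((len(genes), len(times), len(reps)), np.nan)
        for gene, time, rep, m in df[["gene", "time_min", "replicate", "M"]
                                     ].itertuples(index=False):
            try:
                values[gi[str(gene)], ti[float(time)], ri[str(rep)]] = m
            except KeyError as exc:
                raise ValueError(f"record outside design grid: {exc}") from exc
        return cls(genes, times, reps, values, condition=conditions[0])

    @classmethod
    def from_tsv(cls, path, design: ExperimentDesign = None) -> "ExpressionSeries":
        return cls.from_long(pd.read_csv(path, sep="\t"), design=design)


# ---------------------------------------------------------------------------
# Ratio computation and LOWESS normalization
# ---------------------------------------------------------------------------

def compute_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature MA values from a two-color array table.

    M = log2(experimental / control) oriented by ``exp_dye`` so that
    positive M means experimental > control whichever dye carried the
    experimental sample; A = 0.5 * log2(cy3 * cy5).

    Raises
    ------
    ValueError
        If any channel intensity is non-positive (names the feature).
    """
    missing = [c for c in ARRAY_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"array table missing columns {missing}")
    cy3 = table["cy3"].to_numpy(dtype=float)
    cy5 = table["cy5"].to_numpy(dtype=float)
    bad = np.flatnonzero((cy3 <= 0) | (cy5 <= 0))
    if bad.size:
        feat = table["feature_id"].iloc[bad[0]]
        raise ValueError(
            f"non-positive intensity for feature {feat!r} (row {bad[0]})")
    orient = np.where(table["exp_dye"].to_numpy() == "Cy5", 1.0, -1.0)
    out = table[["feature_id", "replicate_id", "time_min", "condition",
                 "exp_dye"]].copy()
    out["M"] = orient * np.log2(cy5 / cy3)
    out["A"] = 0.5 * np.log2(cy3 * cy5)
    return out


def lowess_normalize(
    pairs: pd.DataFrame,
    span: float = 0.3,
    iterations: int = 3,
    min_features: int = 20,
) -> pd.DataFrame:
    """Remove the intensity-dependent trend from M, one fit per array.

    For each array (a ``condition, replicate_id, time_min`` group) a
    locally weighted regression of M on A is fitted and subtracted,
    removing dye artefacts caused by non-linear fluorescence at low
    intensity. Arrays with fewer than ``min_features`` features fall back
    to median-centering with a warning. Row order is preserved.

    Parameters
    ----------
    pairs : DataFrame
        Output of :func:`compute_ratios`.
    span : float in (0, 1]
        Fraction of features used in each local fit.
    iterations : int
        Robustifying reweighting iterations.
    """
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if not {"M", "A"}.issubset(pairs.columns):
        raise ValueError("expected MA table with columns M and A")
    out = pairs.copy()
    m_new = out["M"].to_numpy(dtype=float).copy()
    for key, idx in out.groupby(
            ["condition", "replicate_id", "time_min"], sort=False).indices.items():
        m = out["M"].to_numpy(dtype=float)[idx]
        a = out["A"].to_numpy(dtype=float)[idx]
        if idx.size < min_features:
            warnings.warn(
                f"array {key}: only {idx.size} features; "
                "falling back to median-centering")
            m_new[idx] = m - np.median(m)
            continue
        trend = _sm_lowess(m, a, frac=span, it=iterations,
                           return_sorted=False)
        m_new[idx] = m - trend
    out["M"] = m_new
    return out


def assemble_series(
    normalized: pd.DataFrame,
    design: ExperimentDesign = None,
    condition: str = None,
) -> ExpressionSeries:
    """Stack normalized per-array M values into an ExpressionSeries.

    Missing (gene, time, replicate) cells are represented as NaN, never
    imputed; duplicate cells raise. Genes missing in more than one
    replicate at any time point trigger a warning.
    """
    df = normalized.rename(columns={"feature_id": "gene",
                                    "replicate_id": "replicate"})
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"no rows for condition {condition!r}")
    series = ExpressionSeries.from_long(
        df[["gene", "condition", "time_min", "replicate", "M"]], design=design)
    n_missing = np.isnan(series.values).sum(axis=2)
    n_flag = int((n_missing > 1).sum())
    if n_flag:
        warnings.warn(
            f"{n_flag} gene/time cells are missing in >1 replicate")
    return series
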