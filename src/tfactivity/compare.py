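"""Cross-condition comparison of inferred TF activity profiles.

A TF's inferred profile is *non-responsive* in a condition when some
constant time series fits entirely within its posterior error bars; such
profiles are discarded. For TFs retained in both conditions the
similarity of behaviour is scored by the absolute Pearson correlation of
the posterior mean profiles — absolute, because the model cannot fix the
sign of TF-gene interactions a priori, so either profile may be globally
inverted. A TF retained in exactly one condition receives the sentinel
placeholder score 2, deliberately outside the [0, 1] correlation range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel score for a TF responsive in one condition only.
PLACEHOLDER_SCORE = 2.0


def is_constant_within_errorbars(mean, sd, z: float = 2.0) -> bool:
    """True iff some constant k satisfies |mean[t] - k| <= z*sd[t] for all t.

    Equivalent to the intervals [mean[t] - z*sd[t], mean[t] + z*sd[t]]
    having a common point: max of the lower bounds <= min of the upper
    bounds. Exact — no search needed.
    """
    m = np.asarray(mean, dtype=float)
    s = np.asarray(sd, dtype=float)
    if m.shape != s.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("mean and sd must be equal-length 1-d profiles "
                         "with at least two points")
    if np.any(s <= 0):
        raise ValueError("error bars must be strictly positive")
    if z <= 0:
        raise ValueError("z must be positive")
    return float(np.max(m - z * s)) <= float(np.min(m + z * s))


def flip_profile(post, tf_id: str):
    """Negate a TF's activity profile and its interaction weights.

    Returns a new posterior; the model likelihood is invariant under
    this joint negation (the documented sign gauge), so flipping is pure
    bookkeeping used to match annotated interaction signs.
    """
    return post.flip(tf_id)


@dataclass
class ComparisonScore:
    """Cross-condition outcome for one TF."""

    tf_id: str
    condition_a: str
    condition_b: str
    status: str  # both_retained | a_only | b_only | both_discarded
    score: float = None  # |Pearson r| in [0,1], 2.0 placeholder, or None
    flipped_a: bool = False
    flipped_b: bool = False
    anomalous: bool = False


def _retained(post, f: int, z: float) -> bool:
    return not is_constant_within_errorbars(
        post.activity_mean[f], post.activity_sd[f], z=z)


def compare_conditions(
    post_a,
    post_b,
    z: float = 2.0,
    include_reference_time: bool = False,
    condition_a: str = None,
    condition_b: str = None,
) -> list:
    """Score shared TFs across two fitted conditions.

    Per TF: the discard test runs in each condition on the full profile;
    if both discard, the TF is unresponsive everywhere (no score); if
    exactly one discards, the placeholder 2 is assigned; otherwise the
    score is |Pearson r| between the posterior mean profiles. By default
    the pre-treatment time point (activity fixed at zero by convention
    in both runs, which would inflate the correlation) is excluded from
    r; the discard test always sees the full profile.

    Both posteriors must share the time grid; TFs present in only one
    run are reported via a warning and omitted.
    """
    if list(post_a.time_points_min) != list(post_b.time_points_min):
        raise ValueError("posteriors have different time grids")
    cond_a = condition_a or getattr(post_a, "condition", "A")
    cond_b = condition_b or getattr(post_b, "condition", "B")
    tfs_a = {tf: i for i, tf in enumerate(post_a.tf_ids)}
    tfs_b = {tf: i for i, tf in enumerate(post_b.tf_ids)}
    shared = [tf for tf in post_a.tf_ids if tf in tfs_b]
    only = sorted(set(post_a.tf_ids) ^ set(post_b.tf_ids))
    if only:
        warnings.warn(f"{len(only)} TFs present in one run only: {only[:5]}")
    t_slice = slice(None) if include_reference_time else slice(1, None)

    flips_a = getattr(post_a, "flipped", frozenset())
    flips_b = getattr(post_b, "flipped", frozenset())
    scores = []
    for tf in shared:
        fa, fb = tfs_a[tf], tfs_b[tf]
        ra = _retained(post_a, fa, z)
        rb = _retained(post_b, fb, z)
        rec = ComparisonScore(tf_id=tf, condition_a=cond_a, condition_b=cond_b,
                              status="both_discarded",
                              flipped_a=tf in flips_a, flipped_b=tf in flips_b)
        if ra and rb:
            ma = post_a.activity_mean[fa, t_slice]
            mb = post_b.activity_mean[fb, t_slice]
            rec.status = "both_retained"
            if np.std(ma) == 0 or np.std(mb) == 0:
                # A retained profile with literally zero variance cannot be
                # correlated; report it rather than emit a spurious number.
                rec.score = float("nan")
                rec.anomalous = True
            else:
                r = np.corrcoef(ma, mb)[0, 1]
                rec.score = float(abs(r))
        elif ra or rb:
            rec.status = "a_only" if ra else "b_only"
            rec.score = PLACEHOLDER_SCORE
        scores.append(rec)
    return scores


def rank_tfs(
    scores,
    concordant_threshold: float = 0.8,
    discordant_threshold: float = 0.3,
) -> dict:
    """Partition comparison scores into interpretive groups.

    Returns a dict of lists of :class:`ComparisonScore`:
    ``concordant`` (score >= concordant_threshold), ``discordant``
    (score <= discordant_threshold), ``intermediate`` (in between),
    ``condition_specific`` (placeholder 2), ``unresponsive`` (both
    discarded) and ``anomalous``. Within each group entries are ordered
    by descending score, then lexicographic TF id; the placeholder never
    enters any averaging or thresholding.
    """
    parts = {k: [] for k in ("concordant", "intermediate", "discordant",
                             "condition_specific", "unresponsive",
                             "anomalous")}
    for rec in scores:
        if rec.status == "both_discarded":
            parts["unresponsive"].append(rec)
        elif rec.status in ("a_only", "b_only"):
            parts["condition_specific"].append(rec)
        elif rec.anomalous or rec.score is None or np.isnan(rec.score):
            parts["anomalous"].append(rec)
        elif rec.score >= concordant_threshold:
            parts["concordant"].append(rec)
        elif rec.score <= discordant_threshold:
            parts["discordant"].append(rec)
        else:
            parts["intermediate"].append(rec)
    for key, group in parts.items():
        if key in ("unresponsive", "anomalous", "condition_specific"):
            group.sort(key=lambda r: r.tf_id)
        else:
            group.sort(key=lambda r: (-r.score, r.tf_id))
    return parts


def comparison_frame(scores) -> pd.DataFrame:
    """Tabular view of comparison results (one row per TF)."""
    return pd.DataFrame(
        {
            "tf": [r.tf_id for r in scores],
            "condition_a": [r.condition_a for r in scores],
            "condition_b": [r.condition_b for r in scores],
            "status": [r.status for r in scores],
            "score": [np.nan if r.score is None else r.score for r in scores],
            "flipped_a": [r.flipped_a for r in scores],
            "flipped_b": [r.flipped_b for r in scores],
        }
    )
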