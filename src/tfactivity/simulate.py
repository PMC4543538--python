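"""Synthetic ground truth for the two-color TF-activity pipeline.

Generates sparse signed TF-gene networks, smooth TF activity
trajectories, log-linear gene expression with Gaussian noise, and raw
two-channel array tables carrying a known intensity-dependent dye bias —
everything the downstream stages (normalization, differential expression,
activity inference, cross-condition comparison) assume, so the whole
pipeline can be exercised and validated without any external download.

The generative model matches the inference model exactly:

    x[g, t, r] = mu[g] + sum_f b[g, f] * c[f, t] + eps,   eps ~ N(0, sigma^2)

with ``b`` nonzero only on network edges and ``c[f, 0] = 0`` (activities
are changes relative to the pre-treatment reference). The dye bias enters
on the Cy5/Cy3 log ratio as a smooth, low-intensity inflation ``d(A)``
with a known closed form (:func:`dye_bias`), so normalization accuracy
can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ExperimentDesign
from .network import RegulatoryNetwork
from .preprocess import ARRAY_TABLE_COLUMNS, ExpressionSeries

#: Fixed per-stage seed offsets so one run-level seed reproduces the run.
STAGE_SEED_OFFSETS = {
    "network": 11,
    "activities": 23,
    "weights": 37,
    "expression": 51,
    "render": 67,
}


def derive_seed(run_seed: int, stage: str) -> int:
    """Stage seed derived from a run-level seed by a fixed offset."""
    return (int(run_seed) * 1009 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class GroundTruth:
    """True latent quantities behind a simulated dataset.

    Attributes
    ----------
    activities : ndarray, shape (n_tfs, n_time)
        TF activity change c[f, t]; column 0 is all zeros.
    weights : ndarray, shape (n_genes, n_tfs)
        Regulatory strengths b[g, f], nonzero only on network edges.
    baselines : ndarray, shape (n_genes,)
        Per-gene log2-ratio offset mu[g].
    noise_sd : float
        Standard deviation sigma of the Gaussian log2-ratio noise.
    """

    activities: np.ndarray
    weights: np.ndarray
    baselines: np.ndarray
    noise_sd: float


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def generate_network(
    n_tfs: int,
    n_genes: int,
    mean_regulators_per_gene: float = 2.0,
    frac_signed: float = 0.5,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Random sparse signed TF-gene network.

    The number of regulators per gene is Poisson(mean) clipped to
    [1, n_tfs] (every gene keeps at least one regulator); regulator
    identities are drawn uniformly without replacement. A fraction
    ``frac_signed`` of edges carries a random +/-1 annotation, the rest
    are of unknown sign.
    """
    if n_tfs < 1 or n_genes < n_tfs:
        raise ValueError("need n_genes >= n_tfs >= 1")
    if mean_regulators_per_gene <= 0 or mean_regulators_per_gene > n_tfs:
        raise ValueError("mean regulators per gene must lie in (0, n_tfs]")
    if not (0 <= frac_signed <= 1):
        raise ValueError("frac_signed must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{f + 1:02d}" for f in range(n_tfs)]
    gene_ids = [f"g{g + 1:04d}" for g in range(n_genes)]
    X = np.zeros((n_genes, n_tfs), dtype=np.int8)
    for g in range(n_genes):
        k = int(np.clip(rng.poisson(mean_regulators_per_gene), 1, n_tfs))
        X[g, rng.choice(n_tfs, size=k, replace=False)] = 1
    S = np.zeros_like(X)
    gi, fi = np.nonzero(X)
    signed = rng.random(gi.size) < frac_signed
    S[gi[signed], fi[signed]] = rng.choice((-1, 1), size=int(signed.sum()))
    return RegulatoryNetwork(tf_ids, gene_ids, X, S)


# ---------------------------------------------------------------------------
# Activities, weights, expression
# ---------------------------------------------------------------------------

def simulate_activities(
    network: RegulatoryNetwork,
    design: ExperimentDesign,
    amplitude: float = 2.0,
    frac_responsive: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """TF activity-change trajectories c[f, t] over the design's times.

    Exactly ``round(frac_responsive * n_tfs)`` TFs respond; each gets a
    smooth trajectory — a saturating rise ``1 - exp(-t/tau)`` or a
    transient pulse ``(t/tau) exp(1 - t/tau)`` with a random timescale
    tau — scaled to peak magnitude ``amplitude`` with a random sign. The
    remaining TFs stay identically zero, as does the pre-treatment column
    t = 0 for every TF.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if not (0 <= frac_responsive <= 1):
        raise ValueError("frac_responsive must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.asarray(design.time_points_min, dtype=float)
    c = np.zeros((network.n_tfs, design.n_time))
    n_resp = int(round(frac_responsive * network.n_tfs))
    responsive = rng.choice(network.n_tfs, size=n_resp, replace=False)
    for f in responsive:
        tau = rng.uniform(10.0, 60.0)
        if rng.random() < 0.5:
            shape = 1.0 - np.exp(-t / tau)
        else:
            shape = (t / tau) * np.exp(1.0 - t / tau)
        peak = np.max(np.abs(shape))
        sign = rng.choice((-1.0, 1.0))
        c[f] = sign * amplitude * shape / peak
    c[:, 0] = 0.0
    return c


def simulate_weights(
    network: RegulatoryNetwork,
    seed: int = 0,
    magnitude_range: tuple = (0.5, 1.5),
) -> np.ndarray:
    """Regulatory strengths b[g, f] on the network's edges.

    Magnitudes are uniform on ``magnitude_range``; signs follow the
    network's annotations where present and are random +/-1 on
    unknown-sign edges.
    """
    rng = np.random.default_rng(seed)
    gi, fi = np.nonzero(network.connectivity)
    mag = rng.uniform(*magnitude_range, size=gi.size)
    sign = network.signs[gi, fi].astype(float)
    unknown = sign == 0
    sign[unknown] = rng.choice((-1.0, 1.0), size=int(unknown.sum()))
    b = np.zeros(network.connectivity.shape)
    b[gi, fi] = sign * mag
    return b


def simulate_ground_truth(
    network: RegulatoryNetwork,
    design: ExperimentDesign,
    amplitude: float = 2.0,
    frac_responsive: float = 0.5,
    noise_sd: float = 0.2,
    baseline_sd: float = 0.1,
    seed: int = 0,
) -> GroundTruth:
    """Assemble activities, weights and baselines into a GroundTruth."""
    if noise_sd < 0 or baseline_sd < 0:
        raise ValueError("standard deviations cannot be negative")
    c = simulate_activities(network, design, amplitude, frac_responsive,
                            derive_seed(seed, "activities"))
    b = simulate_weights(network, derive_seed(seed, "weights"))
    rng = np.random.default_rng(derive_seed(seed, "expression") + 1)
    mu = rng.normal(0.0, baseline_sd, size=network.n_genes)
    return GroundTruth(activities=c, weights=b, baselines=mu,
                       noise_sd=float(noise_sd))


def simulate_expression(
    truth: GroundTruth,
    network: RegulatoryNetwork,
    design: ExperimentDesign,
    seed: int = 0,
    condition: str = None,
) -> ExpressionSeries:
    """Noisy log2 expression ratios under the log-linear model.

    x[g, t, r] = mu[g] + sum_f b[g, f] c[f, t] + eps with eps drawn
    independently N(0, sigma^2) for every gene/time/replicate cell.
    """
    c = np.asarray(truth.activities, dtype=float)
    b = np.asarray(truth.weights, dtype=float)
    if b.shape != (network.n_genes, network.n_tfs):
        raise ValueError("weights shape does not match network")
    if c.shape != (network.n_tfs, design.n_time):
        raise ValueError("activities shape does not match network/design")
    rng = np.random.default_rng(seed)
    clean = truth.baselines[:, None] + b @ c  # (genes, time)
    x = clean[:, :, None] + rng.normal(
        0.0, truth.noise_sd,
        size=(network.n_genes, design.n_time, design.n_replicates))
    return ExpressionSeries(
        network.gene_ids, design.time_points_min, design.replicate_ids, x,
        condition=condition or design.conditions[0])


# ---------------------------------------------------------------------------
# Two-color rendering with intensity-dependent dye bias
# ---------------------------------------------------------------------------

def dye_bias(a: np.ndarray, amplitude: float, midpoint: float = 9.0,
             width: float = 1.0) -> np.ndarray:
    """Intensity-dependent bias d(A) on the log2 Cy5/Cy3 ratio.

    A smooth logistic inflation at low mean log intensity A, flat at
    high intensity — the classic "banana" artefact of two-color arrays.
    ``max |d| -> amplitude`` at the low-intensity end.
    """
    return amplitude * expit((midpoint - np.asarray(a, dtype=float)) / width)


def render_two_color(
    expr: ExpressionSeries,
    design: ExperimentDesign,
    bias_amplitude: float = 0.0,
    seed: int = 0,
    abundance_range: tuple = (7.0, 14.0),
    abundance_jitter_sd: float = 0.25,
    intensity_floor: float = 1.0,
) -> pd.DataFrame:
    """Raw two-channel intensities realising an expression series.

    Each gene gets a base abundance (mean log2 intensity A) drawn once,
    jittered per array. The dye-scale log ratio is
    ``log2(Cy5/Cy3) = o * x + d(A)`` where ``o`` is +1 when the
    experimental sample is in Cy5 and -1 on dye-swap arrays, and d is
    :func:`dye_bias` — the bias sticks to the dyes, not to the sample,
    which is what dye-swapping is designed to cancel. Channels are
    floor-clipped at ``intensity_floor``. Knowing the bias amplitude, the
    construction is exactly invertible (see
    :func:`remove_known_bias`).
    """
    if not np.all(np.isfinite(expr.values)):
        raise ValueError("expression values must be finite")
    rng = np.random.default_rng(seed)
    n_g, n_t, n_r = expr.shape
    base_a = rng.uniform(*abundance_range, size=n_g)
    a = base_a[:, None, None] + rng.normal(
        0.0, abundance_jitter_sd, size=(n_g, n_t, n_r))
    orient = np.array([1.0 if design.experimental_dye(r) == "Cy5" else -1.0
                       for r in range(n_r)])
    m_dye = orient[None, None, :] * expr.values + dye_bias(a, bias_amplitude)
    cy5 = np.maximum(2.0 ** (a + m_dye / 2.0), intensity_floor)
    cy3 = np.maximum(2.0 ** (a - m_dye / 2.0), intensity_floor)

    g, t, r = np.meshgrid(np.arange(n_g), np.arange(n_t), np.arange(n_r),
                          indexing="ij")
    return pd.DataFrame(
        {
            "feature_id": np.asarray(expr.gene_ids)[g.ravel()],
            "cy3": cy3.ravel(),
            "cy5": cy5.ravel(),
            "exp_dye": np.where(orient[r.ravel()] > 0, "Cy5", "Cy3"),
            "replicate_id": np.asarray(expr.replicate_ids)[r.ravel()],
            "time_min": np.asarray(expr.time_points_min)[t.ravel()],
            "condition": expr.condition,
        },
        columns=ARRAY_TABLE_COLUMNS,
    )


def remove_known_bias(pairs: pd.DataFrame, bias_amplitude: float,
                      midpoint: float = 9.0, width: float = 1.0) -> pd.DataFrame:
    """Exact de-biasing of oriented M when the true bias curve is known.

    Oriented M equals ``x + o * d(A)``; subtracting ``o * d(A)`` recovers
    the underlying log ratio to machine precision (testing aid).
    """
    out = pairs.copy()
    orient = np.where(out["exp_dye"].to_numpy() == "Cy5", 1.0, -1.0)
    out["M"] = out["M"].to_numpy() - orient * dye_bias(
        out["A"].to_numpy(), bias_amplitude, midpoint, width)
    return out


# ---------------------------------------------------------------------------
# Dataset convenience and ground-truth persistence
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A complete simulated run: truth plus everything a user would see."""

    network: RegulatoryNetwork
    design: ExperimentDesign
    truth: GroundTruth
    expression: ExpressionSeries
    array_table: pd.DataFrame


def simulate_dataset(
    n_tfs: int = 10,
    n_genes: int = 200,
    mean_regulators_per_gene: float = 2.0,
    frac_signed: float = 0.5,
    amplitude: float = 2.0,
    frac_responsive: float = 0.5,
    noise_sd: float = 0.2,
    baseline_sd: float = 0.1,
    bias_amplitude: float = 0.0,
    design: ExperimentDesign = None,
    condition: str = None,
    seed: int = 0,
) -> SimulatedDataset:
    """One-call generation of network, truth, expression and raw arrays.

    Defaults emulate the reference study design scaled to bench size:
    10 TFs regulating 200 genes (about two regulators each), six time
    points (pre-treatment + five), four replicates per condition, half
    the TFs responding with peak activity change 2 on the log2 scale and
    measurement noise sigma = 0.2.
    """
    design = design or ExperimentDesign()
    network = generate_network(n_tfs, n_genes, mean_regulators_per_gene,
                               frac_signed, derive_seed(seed, "network"))
    truth = simulate_ground_truth(network, design, amplitude,
                                  frac_responsive, noise_sd, baseline_sd,
                                  seed=seed)
    expr = simulate_expression(truth, network, design,
                               derive_seed(seed, "expression"),
                               condition=condition)
    table = render_two_color(expr, design, bias_amplitude,
                             derive_seed(seed, "render"))
    return SimulatedDataset(network, design, truth, expr, table)


def write_ground_truth(truth: GroundTruth, network: RegulatoryNetwork,
                       design: ExperimentDesign, outdir) -> None:
    """Persist a GroundTruth as JSON scalars + TSV matrices."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"noise_sd": truth.noise_sd,
                   "design": design.to_dict()}, fh, indent=1)
    pd.DataFrame(truth.activities, index=network.tf_ids,
                 columns=[str(t) for t in design.time_points_min]
                 ).to_csv(outdir / "activities.tsv", sep="\t",
                          index_label="tf")
    pd.DataFrame(truth.weights, index=network.gene_ids,
                 columns=network.tf_ids
                 ).to_csv(outdir / "weights.tsv", sep="\t",
                          index_label="gene")
    pd.DataFrame({"gene": network.gene_ids, "baseline": truth.baselines}
                 ).to_csv(outdir / "baselines.tsv", sep="\t", index=False)


def read_ground_truth(outdir) -> tuple:
    """Load (GroundTruth, ExperimentDesign) written by write_ground_truth."""
    outdir = Path(outdir)
    with open(outdir / "truth.json") as fh:
        meta = json.load(fh)
    design = ExperimentDesign.from_dict(meta["design"])
    acts = pd.read_csv(outdir / "activities.tsv", sep="\t", index_col="tf")
    weights = pd.read_csv(outdir / "weights.tsv", sep="\t", index_col="gene")
    baselines = pd.read_csv(outdir / "baselines.tsv", sep="\t")
    truth = GroundTruth(
        activities=acts.to_numpy(),
        weights=weights.to_numpy(),
        baselines=baselines["baseline"].to_numpy(),
        noise_sd=float(meta["noise_sd"]),
    )
    return truth, design
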