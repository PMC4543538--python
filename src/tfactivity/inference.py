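"""Network-constrained TF activity inference from expression time series.

Model
-----
Each gene's log2 expression change is a weighted linear combination of
the (latent) activity changes of the TFs that regulate it:

    x[g, t, r] = sum_f X[g, f] * b[g, f] * c[f, t] + eps,
    eps ~ N(0, s^2) independently per observation,

where ``X`` is the known binary connectivity, ``b[g, f]`` the regulatory
strength of TF ``f`` on gene ``g`` (nonzero only on network edges),
``c[f, t]`` the activity change of TF ``f`` at time ``t`` relative to
the pre-treatment reference, and replicates are repeated observations of
the same gene/time mean.

Inference is mean-field variational Bayes over the bilinear pair with
zero-mean Gaussian priors on weights and activities: the posterior is
approximated as a product of one Gaussian per gene weight vector and one
Gaussian per time-point activity vector, updated in closed form in
alternation, with an EM-style point update of the noise variance. Each
sweep cannot decrease the evidence lower bound (ELBO), which is recorded
per iteration as the convergence trace.

Two degeneracies of the bilinear likelihood matter downstream: a per-TF
*scale* gauge (b -> b/a, c -> a*c), removed after fitting by rescaling
each TF column to unit root-mean-square weight, and a per-TF *sign*
gauge (joint negation of a TF's profile and weights), which cannot be
removed from data alone and is resolved against annotated interaction
signs (:meth:`TFActivityResults.sign_ambiguity_report`, ``flip``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as _compare
from .network import RegulatoryNetwork
from .preprocess import ExpressionSeries


@dataclass(frozen=True)
class ModelConfig:
    """Fit hyperparameters for :class:`TFActivityModel`.

    All variances are on the log2 scale. ``convergence_tolerance`` is on
    the relative change of the ELBO between sweeps;
    ``prior_var_intercept`` applies only when the model estimates
    per-gene intercepts.
    """

    max_iterations: int = 2000
    convergence_tolerance: float = 1e-6
    prior_var_weights: float = 1.0
    prior_var_activities: float = 1.0
    prior_var_intercept: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if (self.max_iterations < 1 or self.convergence_tolerance <= 0
                or self.prior_var_weights <= 0
                or self.prior_var_activities <= 0
                or self.prior_var_intercept <= 0):
            raise ValueError("config values must be positive")


class TFActivityModel:
    """Bilinear factor model of TF activity, built from data.

    Parameters
    ----------
    series : ExpressionSeries
        Per-gene log2-ratio time series. Genes absent from the network,
        or with no regulator among its TFs, are dropped with a logged
        count; an empty intersection raises.
    network : RegulatoryNetwork
        Known TF-gene connectivity constraining the fit.
    center_baseline : bool
        Subtract each gene's replicate-mean value at the first time
        point before fitting, absorbing the per-gene baseline offset
        (activity changes are relative to that reference). Default True.
    replicates : {"observations", "mean"}
        Whether replicates enter as repeated observations of the same
        gene/time mean (default; increases effective precision) or are
        averaged into a single observation first.
    intercept : bool
        Estimate a per-gene intercept inside the model (default True).
        Centering removes the baseline only up to the sampling noise of
        the reference time point, leaving a small offset that is
        constant in time and correlated across observations of a gene;
        without an explicit intercept that offset is the dominant model
        violation and leaks into the activity profiles of otherwise
        silent TFs, defeating the error-bar calibration the downstream
        discard test relies on.
    """

    def __init__(self, series: ExpressionSeries, network: RegulatoryNetwork,
                 center_baseline: bool = True,
                 replicates: str = "observations",
                 intercept: bool = True):
        if replicates not in ("observations", "mean"):
            raise ValueError("replicates must be 'observations' or 'mean'")
        in_net = set(network.gene_ids)
        keep = [g for g in series.gene_ids if g in in_net]
        sub = network.subset_genes(keep) if keep else None
        if sub is not None:
            has_reg = sub.connectivity.sum(axis=1) >= 1
            keep = [g for g, ok in zip(keep, has_reg) if ok]
        if not keep:
            raise ValueError("no gene in the series has a regulator "
                             "in the network")
        self.n_dropped_genes = len(series.gene_ids) - len(keep)
        if self.n_dropped_genes:
            warnings.warn(f"dropping {self.n_dropped_genes} genes without "
                          "network regulators")
        self.network = network.subset_genes(keep)
        gidx = [series.gene_ids.index(g) for g in keep]
        values = series.values[gidx]
        if center_baseline:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                baseline = np.nanmean(values[:, 0, :], axis=1)
            values = values - baseline[:, None, None]
        if replicates == "mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                values = np.nanmean(values, axis=2, keepdims=True)
        self.series = ExpressionSeries(
            keep, series.time_points_min,
            series.replicate_ids if replicates == "observations" else ["mean"],
            values, condition=series.condition)
        self.center_baseline = center_baseline
        self.replicates = replicates
        self.intercept = intercept

        # sufficient statistics, NaN-aware
        v = self.series.values
        self._n_obs = np.sum(~np.isnan(v), axis=2).astype(float)  # (G,T)
        self._sum_x = np.where(self._n_obs > 0, np.nansum(v, axis=2), 0.0)
        self._sum_xx = np.where(self._n_obs > 0, np.nansum(v**2, axis=2), 0.0)
        self._edges = [np.flatnonzero(row)
                       for row in self.network.connectivity]

    @classmethod
    def from_frames(cls, long_series: pd.DataFrame, edges: pd.DataFrame,
                    **kwargs) -> "TFActivityModel":
        """Build from a long-format series table and an edge list."""
        return cls(ExpressionSeries.from_long(long_series),
                   RegulatoryNetwork.from_frame(edges), **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, config: ModelConfig = None, fix_weights: np.ndarray = None,
            noise_var: float = None, gauge_fix: bool = None,
            **config_overrides) -> "TFActivityResults":
        """Run variational EM and return a results object.

        Parameters
        ----------
        config : ModelConfig, optional
            Hyperparameters; keyword overrides (e.g. ``max_iterations=50``)
            are applied on top.
        fix_weights : ndarray (n_genes, n_tfs), optional
            Hold the regulatory weights fixed at these values (point
            mass) and infer activities only. Used for oracle checks and
            for refitting with known strengths.
        noise_var : float, optional
            Hold the noise variance fixed instead of estimating it.
        gauge_fix : bool, optional
            Rescale each TF to unit RMS weight after fitting. Defaults
            to True when weights are inferred, False when fixed.
        """
        cfg = config or ModelConfig()
        if config_overrides:
            cfg = replace(cfg, **config_overrides)
        if gauge_fix is None:
            gauge_fix = fix_weights is None
        net = self.network
        G, F = net.n_genes, net.n_tfs
        T = len(self.series.time_points_min)
        tau_c = cfg.prior_var_activities
        tau_b = cfg.prior_var_weights
        rng = np.random.default_rng(cfg.seed)

        tau_m = cfg.prior_var_intercept

        # q(b_g): mean + covariance on each gene's regulator subset
        edges = self._edges
        if fix_weights is not None:
            fw = np.asarray(fix_weights, dtype=float)
            if fw.shape != (G, F):
                raise ValueError(f"fix_weights must have shape {(G, F)}")
            mb = [fw[g, e] for g, e in enumerate(edges)]
            Sb = [np.zeros((e.size, e.size)) for e in edges]
        else:
            mb = []
            for g, e in enumerate(edges):
                init = net.signs[g, e].astype(float)
                unk = init == 0
                init[unk] = rng.normal(0.0, 0.3, size=int(unk.sum()))
                mb.append(init)
            Sb = [tau_b * np.eye(e.size) for e in edges]
        # q(c_t): one full Gaussian per time point over all TFs
        mc = np.zeros((T, F))
        Sc = np.array([tau_c * np.eye(F) for _ in range(T)])
        # q(m_g): per-gene intercept (kept at zero when disabled)
        mg = np.zeros(G)
        vg = np.full(G, tau_m) if self.intercept else np.zeros(G)

        n_obs, sum_x, sum_xx = self._n_obs, self._sum_x, self._sum_xx
        n_total = float(n_obs.sum())
        n_gene = n_obs.sum(axis=1)
        if noise_var is not None:
            s2 = float(noise_var)
        else:
            # start from the raw variance of the data
            s2 = max(float(sum_xx.sum() / n_total
                           - (sum_x.sum() / n_total) ** 2), 1e-6)

        def dense_moments():
            """Scatter E[b_g] and E[b_g b_g^T] into dense (G,F[,F]) arrays."""
            mbD = np.zeros((G, F))
            EbbD = np.zeros((G, F, F))
            for g, e in enumerate(edges):
                mbD[g, e] = mb[g]
                EbbD[g, e[:, None], e[None, :]] = Sb[g] + np.outer(mb[g], mb[g])
            return mbD, EbbD

        eye_f = np.eye(F)
        trace = []
        converged = False
        prev = -np.inf
        for it in range(cfg.max_iterations):
            mbD, EbbD = dense_moments()
            sum_x_adj = sum_x - n_obs * mg[:, None]
            # --- update activities c_t (closed-form Gaussian) ---
            for t in range(T):
                prec = eye_f / tau_c + np.einsum(
                    "g,gij->ij", n_obs[:, t], EbbD) / s2
                Sc[t] = np.linalg.inv(prec)
                mc[t] = Sc[t] @ (mbD.T @ sum_x_adj[:, t]) / s2
            Ecc = Sc + np.einsum("ti,tj->tij", mc, mc)  # (T,F,F)
            # --- update weights b_g (closed-form Gaussian per gene) ---
            if fix_weights is None:
                Mg = np.einsum("gt,tij->gij", n_obs, Ecc)
                Rg = sum_x_adj @ mc
                for g, e in enumerate(edges):
                    prec = np.eye(e.size) / tau_b + Mg[g][np.ix_(e, e)] / s2
                    Sb[g] = np.linalg.inv(prec)
                    mb[g] = Sb[g] @ (Rg[g, e] / s2)
                mbD, EbbD = dense_moments()
            fitm = mbD @ mc.T                            # (G,T)
            quad = np.einsum("gij,tij->gt", EbbD, Ecc)   # (G,T)
            # --- update intercepts m_g ---
            if self.intercept:
                vg = 1.0 / (1.0 / tau_m + n_gene / s2)
                mg = vg * (sum_x - n_obs * fitm).sum(axis=1) / s2
            # --- expected sum of squared residuals, noise update ---
            sse = float(np.sum(
                sum_xx - 2.0 * sum_x * (mg[:, None] + fitm)
                + n_obs * ((vg + mg**2)[:, None] + 2.0 * mg[:, None] * fitm
                           + quad)))
            if noise_var is None:
                s2 = max(sse / n_total, 1e-12)
            # --- ELBO ---
            ell = -0.5 * n_total * np.log(2 * np.pi * s2) - sse / (2 * s2)
            kl_c = 0.0
            for t in range(T):
                _, logdet = np.linalg.slogdet(Sc[t])
                kl_c += 0.5 * ((np.trace(Sc[t]) + mc[t] @ mc[t]) / tau_c
                               - F + F * np.log(tau_c) - logdet)
            kl_b = 0.0
            if fix_weights is None:
                for g, e in enumerate(edges):
                    k = e.size
                    _, logdet = np.linalg.slogdet(Sb[g])
                    kl_b += 0.5 * ((np.trace(Sb[g]) + mb[g] @ mb[g]) / tau_b
                                   - k + k * np.log(tau_b) - logdet)
            kl_m = 0.0
            if self.intercept:
                kl_m = 0.5 * float(np.sum(
                    (vg + mg**2) / tau_m - 1.0 + np.log(tau_m) - np.log(vg)))
            elbo = float(ell - kl_c - kl_b - kl_m)
            trace.append(elbo)
            if it > 0 and abs(elbo - prev) <= (
                    cfg.convergence_tolerance * max(1.0, abs(elbo))):
                converged = True
                break
            prev = elbo
        if not converged:
            warnings.warn("TF activity fit did not converge within "
                          f"{cfg.max_iterations} iterations")

        # assemble dense posterior summaries
        act_mean = mc.T.copy()                       # (F,T)
        act_var = np.array([np.diag(S) for S in Sc]).T.copy()  # (F,T)
        # Error bars. The factorized posterior conditions the activities on
        # the weight moments, so its variances miss the weight-activity
        # coupling of the bilinear likelihood — including its nearly flat
        # gauge directions, along which only the prior constrains an
        # activity. A Laplace step repairs this: the joint negative-log-
        # posterior curvature at the solution is assembled and each gene's
        # (weights, intercept) block eliminated by a Schur complement onto
        # the activity block, giving marginal activity variances that are
        # exact for a Gaussian joint. Variances are kept between the
        # conditional value and the prior variance for numerical safety.
        if fix_weights is None:
            lap = self._laplace_activity_var(
                edges, mb, mc, mg, n_obs, sum_x, s2, tau_b, tau_c, tau_m,
                fitm)
            if lap is not None:
                cond = act_var.T.reshape(-1)           # (T*F,) t-major
                lap = np.clip(lap, cond, tau_c)
                act_var = lap.reshape(T, F).T
        act_sd = np.sqrt(act_var)
        w_mean = np.zeros((G, F))
        w_sd = np.zeros((G, F))
        for g, e in enumerate(edges):
            w_mean[g, e] = mb[g]
            w_sd[g, e] = np.sqrt(np.diag(Sb[g])) if Sb[g].size else 0.0
        if gauge_fix:
            for f in range(F):
                on = net.connectivity[:, f] == 1
                if not on.any():
                    continue
                alpha = np.sqrt(np.mean(w_mean[on, f] ** 2))
                if alpha < 1e-8:
                    continue
                w_mean[:, f] /= alpha
                w_sd[:, f] /= alpha
                act_mean[f] *= alpha
                act_sd[f] *= alpha

        return TFActivityResults(
            tf_ids=list(net.tf_ids),
            gene_ids=list(net.gene_ids),
            time_points_min=list(self.series.time_points_min),
            condition=self.series.condition,
            activity_mean=act_mean,
            activity_sd=act_sd,
            weight_mean=w_mean,
            weight_sd=w_sd,
            noise_variance=float(s2),
            objective_trace=trace,
            converged=converged,
            n_iterations=len(trace),
            n_dropped_genes=self.n_dropped_genes,
            connectivity=net.connectivity.copy(),
        )


    def _laplace_activity_var(self, edges, mb, mc, mg, n_obs, sum_x, s2,
                              tau_b, tau_c, tau_m, fitm):
        """Marginal activity variances from the joint curvature.

        Builds the Hessian of the negative log posterior at the current
        point estimates, with gene (weight, intercept) blocks eliminated
        onto the activity block by Schur complements (exact Gaussian
        marginalization). Returns the diagonal of the inverse in t-major
        order (t*F + f), or None if the reduced system is not positive
        definite.
        """
        T, F = mc.shape
        G = len(edges)
        mbD = np.zeros((G, F))
        for g, e in enumerate(edges):
            mbD[g, e] = mb[g]
        H = np.zeros((T * F, T * F))
        for t in range(T):
            block = np.eye(F) / tau_c + np.einsum(
                "g,gi,gj->ij", n_obs[:, t], mbD, mbD) / s2
            H[t * F:(t + 1) * F, t * F:(t + 1) * F] = block
        for g, e in enumerate(edges):
            k = e.size
            dim = k + 1 if self.intercept else k
            B = np.zeros((dim, dim))
            B[:k, :k] = np.eye(k) / tau_b + np.einsum(
                "t,ti,tj->ij", n_obs[g], mc[:, e], mc[:, e]) / s2
            if self.intercept:
                hbm = (n_obs[g][:, None] * mc[:, e]).sum(axis=0) / s2
                B[:k, k] = hbm
                B[k, :k] = hbm
                B[k, k] = 1.0 / tau_m + n_obs[g].sum() / s2
            cols = np.array([t * F + f for t in range(T) for f in e])
            U = np.zeros((dim, T * k))
            for t in range(T):
                s_resid = sum_x[g, t] - n_obs[g, t] * (mg[g] + fitm[g, t])
                U[:k, t * k:(t + 1) * k] = (
                    n_obs[g, t] * np.outer(mc[t, e], mb[g])
                    - s_resid * np.eye(k)) / s2
                if self.intercept:
                    U[k, t * k:(t + 1) * k] = n_obs[g, t] * mb[g] / s2
            try:
                W = np.linalg.solve(B, U)
            except np.linalg.LinAlgError:
                return None
            H[np.ix_(cols, cols)] -= U.T @ W
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        var = np.diag(cov)
        if np.any(~np.isfinite(var)):
            return None
        return var.copy()


def fit_tf_activities(series: ExpressionSeries, network: RegulatoryNetwork,
                      config: ModelConfig = None, **kwargs
                      ) -> "TFActivityResults":
    """Functional one-call interface to :class:`TFActivityModel`."""
    return TFActivityModel(series, network).fit(config=config, **kwargs)


@dataclass
class TFActivityResults:
    """Posterior summaries from a TF activity fit.

    ``activity_mean[f, t]`` / ``activity_sd[f, t]`` are the posterior
    mean and standard deviation (the "error bars") of TF ``f``'s
    activity change at time ``t``; ``weight_mean`` / ``weight_sd``
    likewise for the regulatory strengths, exactly zero off-network.
    """

    tf_ids: list
    time_points_min: list
    activity_mean: np.ndarray
    activity_sd: np.ndarray
    condition: str = "condition"
    gene_ids: list = field(default_factory=list)
    weight_mean: np.ndarray = None
    weight_sd: np.ndarray = None
    noise_variance: float = float("nan")
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0
    n_dropped_genes: int = 0
    connectivity: np.ndarray = None
    flipped: frozenset = frozenset()

    def __post_init__(self):
        self.activity_mean = np.atleast_2d(np.asarray(self.activity_mean,
                                                      dtype=float))
        self.activity_sd = np.atleast_2d(np.asarray(self.activity_sd,
                                                    dtype=float))
        expected = (len(self.tf_ids), len(self.time_points_min))
        if self.activity_mean.shape != expected:
            raise ValueError(f"activity_mean shape != {expected}")
        if self.activity_sd.shape != expected:
            raise ValueError(f"activity_sd shape != {expected}")
        if np.any(self.activity_sd <= 0):
            raise ValueError("posterior sds must be strictly positive")

    # -- gauge bookkeeping -------------------------------------------------

    def flip(self, tf_id: str) -> "TFActivityResults":
        """Negate one TF's profile and weight column (sign gauge).

        Leaves the likelihood unchanged; recorded in ``flipped`` (an
        involution: flipping twice removes the record).
        """
        if tf_id not in self.tf_ids:
            raise KeyError(f"unknown TF {tf_id!r}")
        f = self.tf_ids.index(tf_id)
        new = replace(self)
        new.activity_mean = self.activity_mean.copy()
        new.activity_mean[f] = -new.activity_mean[f]
        new.activity_sd = self.activity_sd.copy()
        if self.weight_mean is not None:
            new.weight_mean = self.weight_mean.copy()
            new.weight_mean[:, f] = -new.weight_mean[:, f]
        new.flipped = frozenset(self.flipped ^ {tf_id})
        return new

    def sign_ambiguity_report(self, network: RegulatoryNetwork) -> dict:
        """Compare inferred weight signs against annotated edge signs.

        Majority vote over a TF's signed edges: ``consistent`` when most
        inferred signs agree with the annotation, ``flipped`` when most
        disagree (the profile should be negated), ``undetermined`` when
        the TF has no signed edges or the vote ties.
        """
        if self.weight_mean is None:
            raise ValueError("results carry no weight estimates")
        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        report = {}
        for f, tf in enumerate(self.tf_ids):
            try:
                col = network.tf_ids.index(tf)
            except ValueError:
                report[tf] = "undetermined"
                continue
            vote = 0.0
            for g_net, gene in enumerate(network.gene_ids):
                s = network.signs[g_net, col]
                if s == 0 or gene not in gene_pos:
                    continue
                w = self.weight_mean[gene_pos[gene], f]
                vote += float(s) * np.sign(w)
            if vote > 0:
                report[tf] = "consistent"
            elif vote < 0:
                report[tf] = "flipped"
            else:
                report[tf] = "undetermined"
        return report

    # -- interrogation -----------------------------------------------------

    def is_responsive(self, tf_id: str, z: float = 2.0) -> bool:
        """False when a constant series fits within the TF's error bars."""
        f = self.tf_ids.index(tf_id)
        return not _compare.is_constant_within_errorbars(
            self.activity_mean[f], self.activity_sd[f], z=z)

    def activities_frame(self) -> pd.DataFrame:
        rows = []
        for f, tf in enumerate(self.tf_ids):
            for t, tm in enumerate(self.time_points_min):
                rows.append((tf, tm, self.activity_mean[f, t],
                             self.activity_sd[f, t]))
        return pd.DataFrame(rows, columns=["tf", "time_min", "mean", "sd"])

    def weights_frame(self) -> pd.DataFrame:
        if self.weight_mean is None:
            raise ValueError("results carry no weight estimates")
        gi, fi = np.nonzero(self.connectivity) if self.connectivity is not None \
            else np.nonzero(self.weight_mean)
        return pd.DataFrame(
            {
                "tf": [self.tf_ids[f] for f in fi],
                "gene": [self.gene_ids[g] for g in gi],
                "mean": self.weight_mean[gi, fi],
                "sd": self.weight_sd[gi, fi],
            }
        )

    def summary(self, z: float = 2.0) -> str:
        """Human-readable per-TF summary table."""
        lines = [
            f"TF activity fit: condition={self.condition!r}  "
            f"{len(self.gene_ids)} genes, {len(self.tf_ids)} TFs, "
            f"{len(self.time_points_min)} time points",
            f"noise sd = {np.sqrt(self.noise_variance):.4f}   "
            f"iterations = {self.n_iterations}   "
            f"converged = {self.converged}   "
            f"dropped genes = {self.n_dropped_genes}",
            "",
            f"{'TF':<10}{'peak |activity|':>16}{'at t (min)':>12}"
            f"{'mean sd':>10}{'responsive':>12}",
        ]
        for f, tf in enumerate(self.tf_ids):
            m = self.activity_mean[f]
            peak = int(np.argmax(np.abs(m)))
            resp = self.is_responsive(tf, z=z)
            lines.append(
                f"{tf:<10}{np.abs(m).max():>16.3f}"
                f"{self.time_points_min[peak]:>12g}"
                f"{self.activity_sd[f].mean():>10.3f}"
                f"{str(resp):>12}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> None:
        """Write activities/weights TSVs and a JSON fit report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.activities_frame().to_csv(outdir / "activities.tsv", sep="\t",
                                       index=False)
        if self.weight_mean is not None:
            self.weights_frame().to_csv(outdir / "weights.tsv", sep="\t",
                                        index=False)
        with open(outdir / "fit_report.json", "w") as fh:
            json.dump(
                {
                    "condition": self.condition,
                    "noise_variance": self.noise_variance,
                    "iterations": self.n_iterations,
                    "converged": self.converged,
                    "dropped_genes": self.n_dropped_genes,
                    "objective_trace": self.objective_trace,
                    "flipped": sorted(self.flipped),
                    "time_points_min": list(self.time_points_min),
                },
                fh, indent=1)

    @classmethod
    def load(cls, outdir) -> "TFActivityResults":
        outdir = Path(outdir)
        acts = pd.read_csv(outdir / "activities.tsv", sep="\t")
        with open(outdir / "fit_report.json") as fh:
            meta = json.load(fh)
        tfs = list(dict.fromkeys(acts["tf"]))
        times = meta["time_points_min"]
        mean = np.zeros((len(tfs), len(times)))
        sd = np.zeros_like(mean)
        tidx = {t: i for i, t in enumerate(times)}
        fidx = {tf: i for i, tf in enumerate(tfs)}
        for tf, tm, m, s in acts[["tf", "time_min", "mean", "sd"]
                                 ].itertuples(index=False):
            mean[fidx[tf], tidx[tm]] = m
            sd[fidx[tf], tidx[tm]] = s
        weight_mean = weight_sd = None
        gene_ids = []
        connectivity = None
        wpath = outdir / "weights.tsv"
        if wpath.exists():
            w = pd.read_csv(wpath, sep="\t")
            gene_ids = sorted(w["gene"].unique())
            gmap = {g: i for i, g in enumerate(gene_ids)}
            weight_mean = np.zeros((len(gene_ids), len(tfs)))
            weight_sd = np.zeros_like(weight_mean)
            connectivity = np.zeros_like(weight_mean, dtype=np.int8)
            for tf, gene, m, s in w[["tf", "gene", "mean", "sd"]
                                    ].itertuples(index=False):
                weight_mean[gmap[gene], fidx[tf]] = m
                weight_sd[gmap[gene], fidx[tf]] = s
                connectivity[gmap[gene], fidx[tf]] = 1
        return cls(
            tf_ids=tfs, time_points_min=times, activity_mean=mean,
            activity_sd=sd, condition=meta.get("condition", "condition"),
            gene_ids=gene_ids, weight_mean=weight_mean, weight_sd=weight_sd,
            noise_variance=meta.get("noise_variance", float("nan")),
            objective_trace=meta.get("objective_trace", []),
            converged=meta.get("converged", True),
            n_iterations=meta.get("iterations", 0),
            n_dropped_genes=meta.get("dropped_genes", 0),
            connectivity=connectivity,
            flipped=frozenset(meta.get("flipped", ())),
        )

    def plot_activities(self, tf_ids=None, z: float = 2.0, ax=None):
        """Plot mean profiles with +/- z sd error bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        t = np.asarray(self.time_points_min)
        for tf in tf_ids or self.tf_ids:
            f = self.tf_ids.index(tf)
            m, s = self.activity_mean[f], self.activity_sd[f]
            (line,) = ax.plot(t, m, label=tf)
            ax.fill_between(t, m - z * s, m + z * s, alpha=0.15,
                            color=line.get_color())
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity change (log2 scale)")
        ax.legend(fontsize="small", ncol=2)
        return ax
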