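"""Fitting the N-mixture model and summarizing its posterior."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from ..counts import CountTable
from .model import NMixtureModel, NMMSpec
from .sampler import nuts_sample

__all__ = ["Posterior", "fit_nmm", "posterior_abundance"]

_INTERVALS = (0.50, 0.80, 0.95)


@dataclass
class Posterior:
    """Posterior draws, pointwise log-likelihood and diagnostics.

    ``draws[name]`` has shape (chains, draws, *param_shape) on the
    constrained scale.  ``idata`` carries the same draws plus the
    per-unit log-likelihood for PSIS-LOO.  ``converged`` is False when
    any split R-hat reaches 1.01 or more than 1% of transitions
    diverged; estimates from a non-converged fit should not be trusted.
    """

    draws: dict[str, np.ndarray]
    idata: az.InferenceData
    unit_labels: list[tuple[str, int, int]]
    diagnostics: dict
    converged: bool
    model: NMixtureModel
    spec: NMMSpec

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chains*draws, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central intervals for the headline parameters."""
        rows = []
        skip = {"lam"}
        for name, d in self.draws.items():
            if name in skip:
                continue
            flat = d.reshape(-1, *d.shape[2:])
            flat2 = flat.reshape(flat.shape[0], -1)
            for k in range(flat2.shape[1]):
                idx = np.unravel_index(k, d.shape[2:]) if d.ndim > 2 else ()
                label = name + ("".join(f"[{i}]" for i in idx) if idx else "")
                x = flat2[:, k]
                row = {"param": label, "mean": x.mean(), "sd": x.std(ddof=1)}
                for lev in _INTERVALS:
                    lo, hi = np.quantile(x, [(1 - lev) / 2, (1 + lev) / 2])
                    row[f"lo{int(lev * 100)}"] = lo
                    row[f"hi{int(lev * 100)}"] = hi
                rows.append(row)
        return pd.DataFrame(rows)

    @property
    def max_rhat(self) -> float:
        return self.diagnostics["max_rhat"]

    @property
    def min_ess(self) -> float:
        return self.diagnostics["min_ess_bulk"]


def _diag_stats(arrays: dict[str, np.ndarray]) -> tuple[float, float]:
    """Max split R-hat and min bulk ESS over every scalar component."""
    max_rhat, min_ess = 0.0, np.inf
    for name, d in arrays.items():
        da = xr.DataArray(d, dims=["chain", "draw"] + [f"{name}_d{k}" for k in range(d.ndim - 2)])
        r = az.rhat(da.to_dataset(name=name))[name].values
        e = az.ess(da.to_dataset(name=name), method="bulk")[name].values
        max_rhat = max(max_rhat, float(np.nanmax(r)))
        min_ess = min(min_ess, float(np.nanmin(e)))
    return max_rhat, min_ess


def fit_nmm(counts: CountTable, spec: NMMSpec) -> Posterior:
    """Fit the model by NUTS on the marginalized posterior.

    Runs ``spec.chains`` chains of ``spec.iterations`` iterations each
    (the first ``spec.warmup`` adapt step size and metric and are
    discarded).  A non-converged fit is re-run with a fresh derived
    seed up to ``spec.max_restarts`` times; the returned posterior
    carries a non-convergence flag rather than raising, so
    model-comparison loops can inspect partial results.
    """
    from dataclasses import replace

    seed = spec.seed
    attempt_spec = spec
    best = None
    for attempt in range(spec.max_restarts + 1):
        post = _fit_once(counts, attempt_spec, seed)
        if post.converged:
            return post
        if best is None or post.max_rhat < best.max_rhat:
            best = post
        # escalate adaptation on retry (the standard response to a failed
        # R-hat check): finer integration and a longer warmup, fresh seed
        new_warmup = int(attempt_spec.warmup * 1.4)
        attempt_spec = replace(
            attempt_spec,
            target_accept=min(attempt_spec.target_accept + 0.02, 0.97),
            warmup=new_warmup,
            iterations=new_warmup + (spec.iterations - spec.warmup),
        )
        # derived restart seed, kept well below 2^31
        seed = (seed + 7919 * (attempt + 1)) % (2**31 - 1)
    return best


def _fit_once(counts: CountTable, spec: NMMSpec, seed: int) -> Posterior:
    model = NMixtureModel(counts, spec)
    n_keep = spec.iterations - spec.warmup
    if n_keep <= 0:
        raise ValueError("iterations must exceed warmup")
    n_samples = n_keep * max(spec.thin, 1)

    if spec.metric == "auto":
        # dense covariance adaptation pays off at moderate dimension but is
        # too noisy to estimate for large spatial-basis models
        dense = model.dim <= 150
    else:
        dense = spec.metric == "dense"

    seeds = np.random.SeedSequence(seed).spawn(spec.chains + 1)
    chains = []
    if spec.shared_adaptation:
        # one exploratory chain adapts step size and metric; its posterior
        # draws give a common covariance metric for all sampling chains
        rng0 = np.random.default_rng(seeds[-1])
        n_metric = min(max(600, spec.warmup // 2), 1000)
        pilot = nuts_sample(
            model.logp_and_grad,
            model.initial_point(rng0),
            n_warmup=spec.warmup,
            n_samples=n_metric,
            seed=rng0,
            target_accept=spec.target_accept,
            dense_metric=dense,
        )
        X = pilot.draws
        n = X.shape[0]
        if dense:
            shared = (n / (n + 5.0)) * np.cov(X.T) + (5.0 / (n + 5.0)) * np.eye(model.dim)
        else:
            shared = (n * X.var(axis=0, ddof=1) + 5.0) / (n + 5.0)
        starts = X[np.linspace(0, n - 1, spec.chains).astype(int)]
        for c in range(spec.chains):
            rng = np.random.default_rng(seeds[c])
            chains.append(
                nuts_sample(
                    model.logp_and_grad,
                    starts[c],
                    n_warmup=200,
                    n_samples=n_samples,
                    seed=rng,
                    target_accept=spec.target_accept,
                    init_inv_metric=shared,
                    adapt_metric=False,
                )
            )
    else:
        for c in range(spec.chains):
            rng = np.random.default_rng(seeds[c])
            theta0 = model.initial_point(rng)
            chains.append(
                nuts_sample(
                    model.logp_and_grad,
                    theta0,
                    n_warmup=spec.warmup,
                    n_samples=n_samples,
                    seed=rng,
                    target_accept=spec.target_accept,
                    dense_metric=dense,
                )
            )

    thin = max(spec.thin, 1)
    sl = slice(thin - 1, None, thin)
    unc = np.stack([c.draws[sl] for c in chains])            # (C, n_keep, dim)
    divergent = np.stack([c.divergent[sl] for c in chains])  # (C, n_keep)
    lp = np.stack([c.logp[sl] for c in chains])
    # divergence health is judged on every transition, not the retained ones
    div_frac_all = float(np.mean([c.divergent.mean() for c in chains]))

    # constrained draws + pointwise log-likelihood in one forward pass
    C, n, _ = unc.shape
    first = model.constrain(unc[0, 0])
    draws: dict[str, np.ndarray] = {
        k: np.empty((C, n) + np.shape(v)) for k, v in first.items()
    }
    pointwise = np.empty((C, n, model.n_units))
    for c in range(C):
        for d in range(n):
            con = model.constrain(unc[c, d])
            for k, v in con.items():
                draws[k][c, d] = v
            pointwise[c, d] = model.pointwise_loglik(unc[c, d])

    # diagnostics over the model's reported parameters (lam is a
    # deterministic function of them)
    diag_arrays = {k: v for k, v in draws.items() if k != "lam"}
    max_rhat, min_ess = _diag_stats(diag_arrays)
    div_frac = div_frac_all
    converged = (max_rhat < 1.01) and (div_frac <= 0.01)
    if not converged:
        warnings.warn(
            f"non-converged fit: max R-hat {max_rhat:.4f}, "
            f"divergent fraction {div_frac:.3%}",
            stacklevel=2,
        )

    posterior_vars = {
        k: v for k, v in draws.items() if k != "lam"
    }
    posterior_vars["lam"] = draws["lam"]
    idata = az.from_dict(
        posterior=posterior_vars,
        log_likelihood={"y": pointwise},
        sample_stats={"lp": lp, "diverging": divergent},
    )
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess_bulk": min_ess,
        "divergent_fraction": div_frac,
        "step_sizes": [c.step_size for c in chains],
        "accept_mean": [c.accept_mean for c in chains],
        "treedepth_mean": [c.treedepth_mean for c in chains],
    }
    return Posterior(
        draws=draws,
        idata=idata,
        unit_labels=model.unit_labels(),
        diagnostics=diagnostics,
        converged=converged,
        model=model,
        spec=spec,
    )


def _interval_rows(x: np.ndarray, base: dict) -> dict:
    row = dict(base)
    row["mean"] = float(x.mean())
    row["median"] = float(np.median(x))
    for lev in _INTERVALS:
        lo, hi = np.quantile(x, [(1 - lev) / 2, (1 + lev) / 2])
        row[f"lo{int(lev * 100)}"] = float(lo)
        row[f"hi{int(lev * 100)}"] = float(hi)
    return row


def posterior_abundance(posterior: Posterior) -> dict[str, pd.DataFrame]:
    """Species-year abundance and detection summaries.

    Returns frames for the yearly total expected abundance
    (sum_i lambda_sit), the per-site mean abundance, and the community
    (p_t) and species (p_st) detection-rate curves, each with posterior
    mean, median and 50/80/95% central intervals.
    """
    if not posterior.converged:
        warnings.warn("summarizing a non-converged posterior", stacklevel=2)
    lam = posterior.stacked("lam")     # (draws, S, R, T)
    p_st = posterior.stacked("p_st")   # (draws, S, T)
    p_t = posterior.stacked("p_t")     # (draws, T)
    species = posterior.model.counts.species
    years = posterior.model.counts.years

    total_rows, site_rows, pst_rows, pt_rows = [], [], [], []
    for t, year in enumerate(years):
        pt_rows.append(_interval_rows(p_t[:, t], {"year": year}))
        for s, sp in enumerate(species):
            base = {"species": sp, "year": year}
            total_rows.append(_interval_rows(lam[:, s, :, t].sum(axis=1), base))
            site_rows.append(_interval_rows(lam[:, s, :, t].mean(axis=1), base))
            pst_rows.append(_interval_rows(p_st[:, s, t], base))
    return {
        "abundance_total": pd.DataFrame(total_rows),
        "abundance_site_mean": pd.DataFrame(site_rows),
        "detection_community": pd.DataFrame(pt_rows),
        "detection_species": pd.DataFrame(pst_rows),
    }
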