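"""Model comparison by PSIS-LOO expected log predictive density.

The observation unit is the site-year count vector — the unit over
which the latent abundance is marginalized — so "leave one out" leaves
out one site-year of one species.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np
import pandas as pd

from .fit import Posterior

__all__ = ["loo_compare"]

_PARETO_K_WARN = 0.7
_PARETO_FRAC_WARN = 0.05


def loo_compare(
    posteriors: list[Posterior], names: list[str] | None = None
) -> pd.DataFrame:
    """PSIS-LOO comparison table, best model first.

    Columns: effective number of parameters (p_loo), ELPD LOO and its
    SE, the ELPD difference to the best model with the SE of the
    pointwise differences, and a Pareto-k health flag (True when more
    than 5% of units exceed k = 0.7, indicating unreliable importance
    sampling for those units).
    """
    if names is None:
        names = [f"model{k + 1}" for k in range(len(posteriors))]
    units = posteriors[0].unit_labels
    for p in posteriors[1:]:
        if p.unit_labels != units:
            raise ValueError("models must share identical observation units")

    loos = []
    for p in posteriors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loos.append(az.loo(p.idata, pointwise=True))
    elpd = np.array([float(l.elpd_loo) for l in loos])
    best = int(np.argmax(elpd))
    best_pw = np.asarray(loos[best].loo_i)

    rows = []
    for name, l in zip(names, loos):
        pw = np.asarray(l.loo_i)
        diff = pw - best_pw
        k = np.asarray(l.pareto_k)
        frac_bad = float(np.mean(k > _PARETO_K_WARN))
        if frac_bad > _PARETO_FRAC_WARN:
            warnings.warn(
                f"{name}: {frac_bad:.1%} of units have Pareto k > "
                f"{_PARETO_K_WARN}; LOO may be unreliable",
                stacklevel=2,
            )
        rows.append(
            {
                "model": name,
                "eff_n_par": float(l.p_loo),
                "elpd_loo": float(l.elpd_loo),
                "se": float(l.se),
                "delpd_loo": float(np.sum(diff)),
                "se_delpd": float(np.sqrt(len(diff) * np.var(diff, ddof=1)))
                if len(diff) > 1
                else 0.0,
                "pareto_k_warn": frac_bad > _PARETO_FRAC_WARN,
            }
        )
    table = pd.DataFrame(rows).sort_values("elpd_loo", ascending=False)
    return table.reset_index(drop=True)
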