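"""Model comparison via Pareto-smoothed importance-sampling LOO-CV.

Each candidate cognitive model yields a hierarchical regression fit with a
matrix of per-observation log-likelihoods over posterior draws.  Leave-one-out
expected log predictive density (elpd_loo) is estimated by PSIS, reported on
the LOOIC scale (``-2 * elpd_loo``; smaller is better) together with
``delta_looic``, the gap to the best model, and the per-observation Pareto-k
tail diagnostics.  The smoothing itself is delegated to arviz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LooResult", "psis_loo", "compare"]


@dataclass
class LooResult:
    model: str
    elpd_loo: float
    looic: float
    pareto_k: np.ndarray
    n_obs: int
    delta_looic: float = 0.0

    @property
    def n_bad_k(self) -> int:
        """Observations whose importance ratios have unreliable tails."""
        return int((self.pareto_k > 0.7).sum())


def psis_loo(pointwise_loglik: np.ndarray, model: str = "model") -> LooResult:
    """PSIS-LOO from a (chains, draws, n_obs) or (draws, n_obs) log-lik array."""
    import arviz as az

    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, ...]
    if ll.ndim != 3:
        raise ValueError("pointwise log-likelihood must be (chains, draws, n_obs)")
    if not np.isfinite(ll).all():
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    if ll.shape[0] * ll.shape[1] < 100:
        raise ValueError("need at least 100 posterior draws for PSIS")

    # az.loo requires a posterior group to size the draw dimension.
    idata = az.from_dict(
        posterior={"_draw": np.zeros(ll.shape[:2])},
        log_likelihood={"y": ll},
    )
    res = az.loo(idata, pointwise=True, scale="log")
    elpd = float(res.elpd_loo)
    return LooResult(
        model=model,
        elpd_loo=elpd,
        looic=-2.0 * elpd,
        pareto_k=np.asarray(res.pareto_k),
        n_obs=ll.shape[2],
    )


def compare(results: list[LooResult]) -> pd.DataFrame:
    """Rank models by LOOIC (ascending) and attach delta_looic.

    Ties for best are broken by declaration order.  All results must score the
    same observations.
    """
    if not results:
        raise ValueError("nothing to compare")
    n_set = {r.n_obs for r in results}
    if len(n_set) > 1:
        raise ValueError(f"mismatched observation counts: {sorted(n_set)}")
    best = min(r.looic for r in results)
    rows = []
    for order, r in enumerate(results):
        r.delta_looic = r.looic - best
        rows.append(
            {
                "model": r.model,
                "looic": r.looic,
                "delta_looic": r.delta_looic,
                "elpd_loo": r.elpd_loo,
                "n_bad_pareto_k": r.n_bad_k,
                "_order": order,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["looic", "_order"], kind="stable")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return table
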