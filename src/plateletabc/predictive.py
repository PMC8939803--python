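"""Posterior predictive checks: bands and the energy score.

Does the inferred posterior actually reproduce the subject's deposition
series?  Draw parameter samples from the posterior, simulate one series
per draw, and compare the predictive ensemble to the observation: a 95%
pointwise predictive band with its median, and the (strictly proper)
energy score

    ES = 2 * sum_i ||x_i - x0||^beta - sum_{i,j} ||x_i - x_j||^beta

computed exactly in this unnormalised double-sum form (all ordered pairs,
no 1/m factors), so comparisons are only meaningful at a fixed ensemble
size; a conventional normalised variant ((2/m) and (1/m^2) factors) is
available behind a flag.
"""

from __future__ import annotations

import numpy as np

from .inference import PosteriorSamples
from .simulator import DepositionParams, DeviceConfig, DepositionTimeSeries, simulate

__all__ = ["posterior_predictive", "credible_band", "energy_score"]


def posterior_predictive(
    samples: PosteriorSamples,
    config: DeviceConfig,
    n_draws: int = 500,
    seed: int | None = None,
    resample: bool = False,
) -> list[DepositionTimeSeries]:
    """One forward simulation per posterior parameter draw.

    Draws ``n_draws`` parameter vectors from the posterior cloud (without
    replacement unless ``resample``; drawing more than the cloud holds
    requires ``resample=True``).  Each simulation runs on an independent
    stream spawned from ``seed``, so the ensemble is reproducible.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    Z = len(samples)
    if n_draws > Z and not resample:
        raise ValueError(
            f"n_draws={n_draws} exceeds the {Z} posterior samples; "
            "pass resample=True to draw with replacement"
        )
    ss = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    idx = pick_rng.choice(Z, size=n_draws, replace=resample or n_draws > Z)
    streams = ss.spawn(n_draws)
    out = []
    for j, (i, stream) in enumerate(zip(idx, streams)):
        try:
            out.append(
                simulate(
                    DepositionParams.from_array(samples.samples[i]),
                    config,
                    np.random.default_rng(stream),
                )
            )
        except Exception as err:
            raise RuntimeError(f"simulation failed for predictive draw {j}") from err
    return out


def _stack(ensemble: list[DepositionTimeSeries]) -> np.ndarray:
    """(m, 3, n_times) array in observable order (clusters, size, platelets)."""
    if not ensemble:
        raise ValueError("empty predictive ensemble")
    return np.stack(
        [np.vstack([ts.n_clusters, ts.mean_cluster_size, ts.n_platelet]) for ts in ensemble]
    )


def credible_band(
    ensemble: list[DepositionTimeSeries], level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise predictive band (lower, median, upper), each (3, n_times).

    Empirical quantiles at (1-level)/2, 0.5 and 1-(1-level)/2 use numpy's
    default linear interpolation.
    """
    arr = _stack(ensemble)
    a = (1.0 - level) / 2.0
    lower, median, upper = np.quantile(arr, [a, 0.5, 1.0 - a], axis=0)
    return lower, median, upper


OBSERVABLE_NAMES = ("n_clusters", "mean_cluster_size", "n_platelet")


def energy_score(
    ensemble: list[DepositionTimeSeries],
    observed: DepositionTimeSeries,
    beta: float = 1.0,
    normalized: bool = False,
) -> dict[str, float]:
    """Energy score of the predictive ensemble against the observation.

    Returns one score per observable (raw units, as their magnitudes are
    naturally reported separately) plus a ``pooled`` score over the full
    flattened series, z-scored per coordinate with the ensemble statistics
    so that no single observable dominates the pooled norm.
    """
    if not 0 < beta < 2:
        raise ValueError("beta must lie in (0, 2) for a strictly proper score")
    arr = _stack(ensemble)  # (m, 3, T)
    obs = np.vstack([observed.n_clusters, observed.mean_cluster_size, observed.n_platelet])
    if arr.shape[1:] != obs.shape:
        raise ValueError("ensemble and observation have mismatched shapes")

    def score(X: np.ndarray, x0: np.ndarray) -> float:
        # X: (m, d); x0: (d,)
        m = len(X)
        term1 = np.linalg.norm(X - x0, axis=1) ** beta
        diff = X[:, None, :] - X[None, :, :]
        term2 = np.linalg.norm(diff, axis=2) ** beta
        if normalized:
            return float(2.0 / m * term1.sum() - term2.sum() / m**2)
        return float(2.0 * term1.sum() - term2.sum())

    out = {
        name: score(arr[:, k, :], obs[k]) for k, name in enumerate(OBSERVABLE_NAMES)
    }
    flat = arr.reshape(len(ensemble), -1)
    mu, sd = flat.mean(axis=0), flat.std(axis=0)
    sd[sd == 0] = 1.0
    out["pooled"] = score((flat - mu) / sd, (obs.ravel() - mu) / sd)
    return out
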