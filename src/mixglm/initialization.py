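"""Initial hard partitions for the EM algorithm.

Six strategies are provided, mirroring the common practice for mixtures of
regressions: the true simulated labels, MAP under the true data-generating
parameters, random short-EM restarts, k-means, PAM (k-medoids), and a
full-covariance Gaussian mixture.  The clustering strategies operate on the
raw joint (X, y) rows, unstandardised.  Every strategy is deterministic
given (data, seed); a partition with an empty cluster is retried once with a
fresh seed and then raises.
"""

from __future__ import annotations

import numpy as np

from .data import RegressionData
from .exceptions import ConfigurationError, EmptyClusterError
from .families import Family

__all__ = ["STRATEGIES", "initial_partition"]

STRATEGIES = (
    "true_labels",
    "true_dgp_map",
    "short_em",
    "kmeans",
    "pam",
    "gmm_full",
)


def initial_partition(
    data: RegressionData,
    k: int,
    strategy: str,
    seed: int | None = None,
    family: Family | None = None,
    dgp=None,
    short_em_restarts: int = 1,
    short_em_iters: int = 5,
    kmeans_restarts: int = 10,
) -> np.ndarray:
    """Return 1-based hard labels of length n for the requested strategy.

    ``dgp`` (a MixtureGLMParams with the true parameters) is required for
    'true_dgp_map'; ``data.true_labels`` for 'true_labels'.  ``family`` is
    required by the EM-based strategies ('true_dgp_map', 'short_em').
    """
    if strategy not in STRATEGIES:
        raise ConfigurationError(
            f"unknown initialization strategy {strategy!r}; choose from {STRATEGIES}"
        )
    if strategy == "true_labels":
        if data.true_labels is None:
            raise ConfigurationError("true_labels initialization requires labels")
        labels = np.asarray(data.true_labels, dtype=int)
        _check_partition(labels, k)
        return labels

    if strategy == "true_dgp_map":
        if dgp is None:
            raise ConfigurationError("true_dgp_map requires the true parameters")
        from .model import MixtureGLM, map_classify

        model = MixtureGLM.from_data(data, k=k, family=dgp.family)
        labels = map_classify(model.e_step(dgp))
        _check_partition(labels, k)
        return labels

    rng = np.random.default_rng(seed)
    for attempt in range(2):
        if strategy == "short_em":
            labels = _short_em(data, k, family, rng,
                               short_em_restarts, short_em_iters)
        elif strategy == "kmeans":
            labels = _kmeans(data, k, rng, kmeans_restarts)
        elif strategy == "pam":
            labels = _pam_labels(data, k)
        else:  # gmm_full
            labels = _gmm_full(data, k, rng)
        counts = np.bincount(labels, minlength=k + 1)[1:]
        if np.all(counts > 0):
            return labels
    raise EmptyClusterError(
        f"strategy {strategy!r} produced an empty cluster twice"
    )


def _check_partition(labels: np.ndarray, k: int) -> None:
    if labels.min() < 1 or labels.max() > k:
        raise ConfigurationError(f"labels must lie in 1..{k}")


def _joint(data: RegressionData) -> np.ndarray:
    return np.column_stack([data.X, data.y])


def _short_em(data, k, family, rng, restarts, iters):
    """S short EM runs of H iterations from random multinomial hard starts;
    keep the run with the highest observed-data log-likelihood."""
    if family is None:
        raise ConfigurationError("short_em requires the model family")
    from .model import MixtureGLM

    model = MixtureGLM.from_data(data, k=k, family=family)
    best_ll, best_labels = -np.inf, None
    for _ in range(max(1, restarts)):
        labels = _random_partition(data.n, k, rng)
        try:
            res = model.fit(init=labels, max_iter=max(1, iters), tol=0.0)
        except Exception:
            continue
        if res.llf > best_ll:
            best_ll, best_labels = res.llf, res.map_labels
    if best_labels is None:
        raise EmptyClusterError("all short-EM restarts failed")
    return best_labels


def _random_partition(n, k, rng, max_tries=100):
    for _ in range(max_tries):
        labels = rng.integers(1, k + 1, size=n)
        if np.bincount(labels, minlength=k + 1)[1:].min() > 0:
            return labels
    raise EmptyClusterError("could not draw a random partition without empty clusters")


def _kmeans(data, k, rng, restarts):
    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=k,
        n_init=max(1, restarts),
        random_state=int(rng.integers(2**31 - 1)),
    )
    return km.fit_predict(_joint(data)) + 1


def _gmm_full(data, k, rng):
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        init_params="kmeans",
        n_init=1,
        random_state=int(rng.integers(2**31 - 1)),
        reg_covar=1e-6,
    )
    return gm.fit_predict(_joint(data)) + 1


def _pam_labels(data, k):
    Z = _joint(data)
    D = _euclidean_matrix(Z)
    medoids = pam(D, k)
    return np.argmin(D[:, medoids], axis=1) + 1


def _euclidean_matrix(Z):
    sq = np.sum(Z**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T
    np.maximum(D2, 0.0, out=D2)
    return np.sqrt(D2)


def pam(D: np.ndarray, k: int, max_swaps: int = 200) -> np.ndarray:
    """Partitioning-around-medoids on a precomputed dissimilarity matrix.

    Classic BUILD (greedy seeding) + SWAP (steepest-descent exchange) scheme;
    deterministic.  Returns the indices of the k medoids.
    """
    n = D.shape[0]
    # BUILD: first medoid minimises total dissimilarity; the rest maximise
    # the decrease in cost
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, D[:, new])
    # SWAP
    medoids = np.asarray(medoids)
    for _ in range(max_swaps):
        dist_to_med = D[:, medoids]
        order = np.argsort(dist_to_med, axis=1)
        d1 = dist_to_med[np.arange(n), order[:, 0]]
        d2 = dist_to_med[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        nearest_idx = order[:, 0]
        best_delta, best_pair = 0.0, None
        nonmed = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            affected = nearest_idx == mi
            for h in nonmed:
                dh = D[:, h]
                # points losing medoid mi move to min(d2, dh); others may gain h
                new_cost = np.where(affected, np.minimum(d2, dh), np.minimum(d1, dh))
                delta = float(np.sum(new_cost - d1))
                if delta < best_delta - 1e-12:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is None:
            break
        medoids = medoids.copy()
        medoids[best_pair[0]] = best_pair[1]
    return np.sort(medoids)
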