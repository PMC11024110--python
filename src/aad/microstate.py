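"""EEG microstate segmentation and the four per-state parameters.

Spontaneous EEG can be described as a sequence of quasi-stable scalp
topographies ("microstates", ~80-120 ms each).  The standard analysis:

1. compute the global field power GFP(t), the spatial standard deviation
   of the potentials across electrodes at each sample;
2. take the topographies at local GFP maxima (moments of high
   signal-to-noise and stable topography);
3. cluster those peak maps into K prototype topographies — here with a
   polarity-invariant ("modified") k-means, AAHC, PCA or ICA;
4. backfit: label every sample with its best-correlated prototype,
   ignoring polarity;
5. summarize each state by mean GFP, occurrence (runs per second),
   mean duration (ms) and coverage (fraction of samples).

Fit quality is the global explained variance (GEV): the GFP^2-weighted
mean squared spatial correlation between each sample and its assigned
prototype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_preprocess import Window

__all__ = [
    "GFPSeries",
    "MicrostatePrototypes",
    "MicrostateSegmentation",
    "MicrostateFeatures",
    "compute_gfp",
    "find_gfp_peaks",
    "fit_prototypes",
    "compute_gev",
    "scan_n_states",
    "backfit",
    "microstate_features",
    "prototypes_from_recording",
    "gev_elbow",
]

METHODS = ("KMEANS", "AAHC", "PCA", "ICA")


@dataclass
class GFPSeries:
    values: np.ndarray  # per-sample GFP, microvolts, >= 0
    sfreq: float


@dataclass
class MicrostatePrototypes:
    maps: np.ndarray  # K x n_channels, unit L2 norm, zero channel mean
    method: str
    gev_total: float = np.nan
    gev_per_state: np.ndarray | None = None
    n_init: int = 1
    max_iter: int = 0
    seed: int | None = None

    @property
    def K(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateSegmentation:
    labels: np.ndarray    # per-sample state index in {0..K-1}
    polarity: np.ndarray  # per-sample sign in {-1, +1}
    sfreq: float


@dataclass
class MicrostateFeatures:
    """Per-state summaries; arrays are indexed by state 0..K-1."""

    mean_gfp: np.ndarray    # microvolts
    occurrence: np.ndarray  # runs per second
    duration: np.ndarray    # mean run length, ms
    coverage: np.ndarray    # fraction of samples


# ---------------------------------------------------------------------------
# GFP and peaks

def compute_gfp(window: Window | np.ndarray, sfreq: float | None = None) -> GFPSeries:
    """GFP(t) = sqrt( sum_i (x_i(t) - x̄(t))^2 / N ) across the N electrodes."""
    if isinstance(window, Window):
        data, sfreq = window.data, window.sfreq
    else:
        data = np.asarray(window, dtype=float)
        if sfreq is None:
            raise ValueError("sfreq required when passing a bare array")
    if data.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    values = data.std(axis=0, ddof=0)
    return GFPSeries(values=values, sfreq=float(sfreq))


def find_gfp_peaks(gfp: GFPSeries, min_distance_ms: float = 0.0) -> np.ndarray:
    """Indices of strict local maxima of GFP, >= min_distance_ms apart.

    Endpoints are never peaks.  When two candidate peaks are closer than the
    minimum distance the larger one wins (scipy's convention).
    """
    v = gfp.values
    if v.size < 3:
        raise ValueError("series too short for peak finding")
    from scipy.signal import find_peaks

    dist = max(1, int(round(min_distance_ms * 1e-3 * gfp.sfreq)))
    peaks, _ = find_peaks(v, distance=dist)
    return peaks


# ---------------------------------------------------------------------------
# prototype fitting

def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Mean-center each map across channels and scale to unit L2 norm."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _dominant_eigvec(x: np.ndarray) -> np.ndarray:
    """First principal direction of the rows of x (polarity-blind mean map)."""
    # eigh on the small channel-space covariance; x rows are maps
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def _gev_of_assignment(maps_n: np.ndarray, protos: np.ndarray,
                       labels: np.ndarray, gfp: np.ndarray) -> float:
    corr = np.einsum("ij,ij->i", maps_n, protos[labels])
    denom = np.sum(gfp ** 2)
    if denom == 0:
        return 0.0
    return float(np.sum(gfp ** 2 * corr ** 2) / denom)


def _kmeans_mod(maps_n: np.ndarray, gfp: np.ndarray, K: int, n_init: int,
                max_iter: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Polarity-invariant k-means maximizing squared spatial correlation.

    Returns (prototypes, converged); the best of ``n_init`` restarts by GEV.
    """
    n = maps_n.shape[0]
    best: tuple[float, np.ndarray, bool] | None = None
    for _ in range(n_init):
        protos = maps_n[rng.choice(n, size=K, replace=False)].copy()
        labels = np.full(n, -1)
        converged = False
        for _ in range(max_iter):
            c = maps_n @ protos.T
            new_labels = np.argmax(c ** 2, axis=1)
            if np.array_equal(new_labels, labels):
                converged = True
                break
            labels = new_labels
            for k in range(K):
                members = maps_n[labels == k]
                if len(members) == 0:
                    protos[k] = maps_n[rng.integers(n)]
                else:
                    protos[k] = _dominant_eigvec(members)
        gev = _gev_of_assignment(maps_n, protos, labels, gfp)
        if best is None or gev > best[0]:
            best = (gev, protos.copy(), converged)
    assert best is not None
    if not best[2]:
        warnings.warn("modified k-means did not converge; returning best-so-far")
    return best[1], best[2]


def _aahc(maps_n: np.ndarray, gfp: np.ndarray, K: int) -> np.ndarray:
    """Atomize-and-agglomerate hierarchical clustering down to K prototypes.

    Repeatedly dissolves the cluster contributing least GEV and reassigns its
    members to their best-correlated surviving cluster.
    """
    clusters: list[list[int]] = [[i] for i in range(maps_n.shape[0])]
    protos = maps_n.copy()

    def contribution(members: list[int], proto: np.ndarray) -> float:
        c = maps_n[members] @ proto
        return float(np.sum(gfp[members] ** 2 * c ** 2))

    while len(clusters) > K:
        scores = [contribution(m, protos[i]) for i, m in enumerate(clusters)]
        worst = int(np.argmin(scores))
        orphans = clusters.pop(worst)
        protos = np.delete(protos, worst, axis=0)
        corr = maps_n[orphans] @ protos.T
        dest = np.argmax(corr ** 2, axis=1)
        for o, d in zip(orphans, dest):
            clusters[d].append(o)
        touched = set(dest.tolist())
        for d in touched:
            protos[d] = _dominant_eigvec(maps_n[clusters[d]])
    return protos


def fit_prototypes(peak_maps: np.ndarray, K: int, method: str = "KMEANS",
                   n_init: int = 10, max_iter: int = 500,
                   seed: int | None = None) -> MicrostatePrototypes:
    """Cluster GFP-peak topographies into K unit-norm prototype maps.

    ``peak_maps`` is (n_peaks x n_channels), raw (un-normalized) topographies;
    their GFP is used as the weighting in the GEV restart criterion.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    peak_maps = np.asarray(peak_maps, dtype=float)
    n_peaks = peak_maps.shape[0]
    if not 1 <= K <= n_peaks:
        raise ValueError("need 1 <= K <= number of peak maps")
    gfp = peak_maps.std(axis=1, ddof=0)
    maps_n = _normalize_maps(peak_maps)
    rng = np.random.default_rng(seed)

    if method == "KMEANS":
        protos, _ = _kmeans_mod(maps_n, gfp, K, n_init, max_iter, rng)
    elif method == "AAHC":
        protos = _aahc(maps_n, gfp, K)
    elif method == "PCA":
        from sklearn.decomposition import PCA

        protos = PCA(n_components=K, random_state=seed).fit(maps_n).components_
    else:  # ICA
        from sklearn.decomposition import FastICA

        ica = FastICA(n_components=K, random_state=seed, max_iter=max_iter,
                      whiten="unit-variance")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny inputs
            ica.fit(maps_n)
        protos = ica.mixing_.T
    protos = _normalize_maps(protos)

    # GEV of the fitted prototypes over the peak ensemble
    labels = np.argmax((maps_n @ protos.T) ** 2, axis=1)
    corr = np.einsum("ij,ij->i", maps_n, protos[labels])
    denom = np.sum(gfp ** 2)
    per_state = np.array([
        np.sum(gfp[labels == k] ** 2 * corr[labels == k] ** 2) / denom if denom else 0.0
        for k in range(K)
    ])
    return MicrostatePrototypes(
        maps=protos, method=method, gev_total=float(per_state.sum()),
        gev_per_state=per_state, n_init=n_init, max_iter=max_iter, seed=seed,
    )


# ---------------------------------------------------------------------------
# backfitting, GEV, features

def _spatial_corr(data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels: (n_samples x K)."""
    x = data - data.mean(axis=0, keepdims=True)  # center across channels
    xn = np.linalg.norm(x, axis=0)
    xn_safe = np.where(xn == 0, 1.0, xn)
    m = maps - maps.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(m, axis=1)
    mn[mn == 0] = 1.0
    return (x.T @ m.T) / (xn_safe[:, None] * mn[None, :])


def backfit(data: Window | np.ndarray, prototypes: MicrostatePrototypes,
            sfreq: float | None = None,
            min_duration_ms: float = 0.0) -> MicrostateSegmentation:
    """Label every sample with its best |spatial correlation| prototype.

    Polarity-invariant: the winning sign is reported separately.  Ties break
    toward the lowest state index.  Zero-variance samples inherit the previous
    sample's label (state 0 at the start) with a warning.  ``min_duration_ms``
    optionally reassigns runs shorter than that to the neighboring state with
    the higher correlation (off by default).
    """
    if isinstance(data, Window):
        arr, sfreq = data.data, data.sfreq
    else:
        arr = np.asarray(data, dtype=float)
        if sfreq is None:
            raise ValueError("sfreq required when passing a bare array")
    corr = _spatial_corr(arr, prototypes.maps)
    labels = np.argmax(np.abs(corr), axis=1)
    polarity = np.where(corr[np.arange(len(labels)), labels] >= 0, 1, -1)

    flat = arr.std(axis=0) == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance samples; carried previous label")
        for i in np.flatnonzero(flat):
            labels[i] = labels[i - 1] if i > 0 else 0
            polarity[i] = polarity[i - 1] if i > 0 else 1

    if min_duration_ms > 0:
        min_len = int(round(min_duration_ms * 1e-3 * sfreq))
        labels = _suppress_short_runs(labels, np.abs(corr), min_len)
    return MicrostateSegmentation(labels=labels, polarity=polarity, sfreq=float(sfreq))


def _suppress_short_runs(labels: np.ndarray, acorr: np.ndarray, min_len: int) -> np.ndarray:
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        for start, length, k in _runs(labels):
            if length >= min_len:
                continue
            left = labels[start - 1] if start > 0 else None
            right = labels[start + length] if start + length < len(labels) else None
            cands = [c for c in (left, right) if c is not None and c != k]
            if not cands:
                continue
            seg = slice(start, start + length)
            best = max(cands, key=lambda c: acorr[seg, c].mean())
            labels[seg] = best
            changed = True
    return labels


def compute_gev(data: Window | np.ndarray, prototypes: MicrostatePrototypes,
                seg: MicrostateSegmentation) -> float:
    """GEV = sum_t GFP(t)^2 corr^2(x(t), map_label(t)) / sum_t GFP(t)^2."""
    arr = data.data if isinstance(data, Window) else np.asarray(data, dtype=float)
    gfp = arr.std(axis=0, ddof=0)
    denom = np.sum(gfp ** 2)
    if denom == 0:
        raise ValueError("all-zero window: GEV undefined")
    corr = _spatial_corr(arr, prototypes.maps)
    c = corr[np.arange(arr.shape[1]), seg.labels]
    return float(np.sum(gfp ** 2 * c ** 2) / denom)


def scan_n_states(peak_maps: np.ndarray, data: Window | np.ndarray,
                  sfreq: float | None = None,
                  K_range: range | list[int] = range(2, 11),
                  methods: tuple[str, ...] = ("KMEANS",),
                  n_init: int = 10, max_iter: int = 500,
                  seed: int | None = None, n_reruns: int = 10) -> dict:
    """GEV of the backfitted segmentation for each (method, K).

    Each cell keeps the best of ``n_reruns`` refits (seeded deterministically
    from ``seed``).  Returns ``{"gev": {method: {K: gev}}, "best_K": {method: K}}``.
    """
    arr = data.data if isinstance(data, Window) else np.asarray(data, dtype=float)
    if sfreq is None and isinstance(data, Window):
        sfreq = data.sfreq
    table: dict[str, dict[int, float]] = {}
    ss = np.random.SeedSequence(seed)
    for method in methods:
        table[method.upper()] = {}
        for K in K_range:
            best = 0.0
            for sub in ss.spawn(n_reruns):
                sub_seed = int(sub.generate_state(1)[0] % (2 ** 31))
                protos = fit_prototypes(peak_maps, K, method=method, n_init=n_init,
                                        max_iter=max_iter, seed=sub_seed)
                seg = backfit(arr, protos, sfreq=sfreq)
                best = max(best, compute_gev(arr, protos, seg))
            table[method.upper()][K] = best
    best_K = {m: max(kv, key=kv.get) for m, kv in table.items()}
    return {"gev": table, "best_K": best_K}


def gev_elbow(gev_by_K: dict[int, float]) -> int:
    """Pick the state count at the GEV curve's elbow.

    The elbow is the K with the greatest drop in marginal explained
    variance: argmax_K [gain(K) - gain(K+1)] where gain(K) = GEV(K) -
    GEV(K-1).  With a planted K, gains are sizable up to K and collapse
    beyond it, so the drop peaks exactly at the planted count.
    """
    ks = sorted(gev_by_K)
    if len(ks) < 3:
        return ks[-1]
    gain = {k: gev_by_K[k] - gev_by_K[k - 1] for k in ks[1:]}
    drops = {k: gain[k] - gain[k + 1] for k in ks[1:-1]}
    return max(drops, key=drops.get)


def prototypes_from_recording(rec, K: int = 4, method: str = "KMEANS",
                              min_distance_ms: float = 10.0,
                              max_peaks: int = 5000, n_init: int = 10,
                              max_iter: int = 500,
                              seed: int | None = None) -> MicrostatePrototypes:
    """Fit prototypes from the GFP-peak topographies of a whole recording.

    Peaks are pooled across all trials; if more than ``max_peaks`` are found
    a seeded random subsample keeps the clustering tractable.
    """
    gfp = compute_gfp(rec.data, sfreq=rec.sfreq)
    peaks = find_gfp_peaks(gfp, min_distance_ms=min_distance_ms)
    if len(peaks) > max_peaks:
        rng = np.random.default_rng(seed)
        peaks = np.sort(rng.choice(peaks, size=max_peaks, replace=False))
    peak_maps = rec.data[:, peaks].T
    return fit_prototypes(peak_maps, K, method=method, n_init=n_init,
                          max_iter=max_iter, seed=seed)


def _runs(labels: np.ndarray):
    """Yield (start, length, state) for each maximal run of equal labels."""
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            yield start, i - start, int(labels[start])
            start = i


def microstate_features(seg: MicrostateSegmentation, gfp: GFPSeries,
                        K: int | None = None) -> MicrostateFeatures:
    """Mean GFP, occurrence (1/s), mean duration (ms) and coverage per state.

    States absent from the window get 0 for all four parameters.
    """
    labels = seg.labels
    if K is None:
        K = int(labels.max()) + 1
    n = len(labels)
    window_s = n / seg.sfreq
    mean_gfp = np.zeros(K)
    occurrence = np.zeros(K)
    duration = np.zeros(K)
    coverage = np.zeros(K)
    run_counts = np.zeros(K)
    run_samples = np.zeros(K)
    for start, length, k in _runs(labels):
        run_counts[k] += 1
        run_samples[k] += length
    for k in range(K):
        mask = labels == k
        if not mask.any():
            continue
        mean_gfp[k] = gfp.values[mask].mean()
        coverage[k] = mask.sum() / n
        occurrence[k] = run_counts[k] / window_s
        duration[k] = (run_samples[k] / run_counts[k]) / seg.sfreq * 1e3
    return MicrostateFeatures(mean_gfp=mean_gfp, occurrence=occurrence,
                              duration=duration, coverage=coverage)
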