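"""Recurrence plots and recurrence quantification analysis (RQA).

A scalar series is delay-embedded into points
``x_i = (s_i, s_{i+tau}, ..., s_{i+(m-1)tau})``; the recurrence plot is the
binary matrix ``R_ij = Θ(ε - ||x_i - x_j||_∞)`` (Θ(0) = 1, so a distance of
exactly ε counts).  Eight summary statistics are computed:

==========  ==============================================================
RR          recurrence rate: fraction of recurrent cells (full matrix,
            line of identity included)
DET         determinism: fraction of recurrence points lying on diagonal
            lines of length >= l_min (LOI and Theiler band excluded)
L_MAX       longest diagonal line
L_MEAN      mean diagonal line length over lines >= l_min
ENTR        Shannon entropy (nats) of the diagonal line-length
            distribution over lines >= l_min
TT          trapping time: mean vertical line length over lines >= v_min
            (full matrix)
V_MAX       longest vertical line
RPDE        recurrence period density entropy: normalized entropy of the
            distribution of return times, in [0, 1]
==========  ==============================================================

Degenerate cases (no lines reaching the minimum length, single return
time, T_max <= 1) yield 0 for the affected statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "RecurrencePlot",
    "RQAFeatures",
    "FEATURE_NAMES",
    "embed",
    "recurrence_matrix",
    "diagonal_histogram",
    "vertical_histogram",
    "recurrence_times",
    "rqa_features",
    "auto_epsilon",
    "rqa_from_series",
    "save_rp_csv",
    "save_rp_png",
]

FEATURE_NAMES = ("RR", "DET", "L_MEAN", "L_MAX", "ENTR", "TT", "V_MAX", "RPDE")


@dataclass
class EmbeddingConfig:
    m: int = 1            # embedding dimension
    tau: int = 1          # delay, samples
    epsilon: float = 0.1  # recurrence threshold, series units
    norm: str = "CHEBYSHEV"
    theiler: int = 0      # diagonals with |i-j| > theiler enter line stats
    l_min: int = 2
    v_min: int = 2

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("need m >= 1 and tau >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.l_min < 2 or self.v_min < 2:
            raise ValueError("l_min and v_min must be >= 2")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")
        if self.norm.upper() != "CHEBYSHEV":
            raise ValueError("only the Chebyshev (maximum) norm is supported")


@dataclass
class RecurrencePlot:
    matrix: np.ndarray  # N x N uint8
    config: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RQAFeatures:
    rr: float
    det: float
    l_mean: float
    l_max: float
    entr: float
    tt: float
    v_max: float
    rpde: float

    def as_dict(self) -> dict[str, float]:
        return {"RR": self.rr, "DET": self.det, "L_MEAN": self.l_mean,
                "L_MAX": self.l_max, "ENTR": self.entr, "TT": self.tt,
                "V_MAX": self.v_max, "RPDE": self.rpde}


def embed(series: np.ndarray, m: int = 1, tau: int = 1) -> np.ndarray:
    """Time-delay embedding: N = len - (m-1)*tau points in R^m."""
    series = np.asarray(series, dtype=float).ravel()
    n = len(series) - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for this (m, tau)")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return series[idx]


def _cheb_dists(traj: np.ndarray) -> np.ndarray:
    return np.abs(traj[:, None, :] - traj[None, :, :]).max(axis=2)


def recurrence_matrix(traj: np.ndarray, config: EmbeddingConfig) -> RecurrencePlot:
    """Thresholded Chebyshev-distance matrix; distance exactly ε is recurrent."""
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    if traj.shape[0] < 2:
        raise ValueError("need at least 2 trajectory points")
    mat = (_cheb_dists(traj) <= config.epsilon).astype(np.uint8)
    return RecurrencePlot(matrix=mat, config=config)


def _run_lengths(bits: np.ndarray) -> list[int]:
    """Lengths of maximal runs of ones in a 1-D 0/1 array."""
    out, run = [], 0
    for b in bits:
        if b:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def diagonal_histogram(rp: RecurrencePlot) -> Counter:
    """Counts of maximal diagonal line lengths over diagonals |i-j| > theiler.

    The line of identity is always excluded; ``theiler`` widens the excluded
    band around it.
    """
    m, n = rp.matrix, rp.n_points
    hist: Counter = Counter()
    for off in range(rp.config.theiler + 1, n):
        for diag in (np.diagonal(m, off), np.diagonal(m, -off)):
            for length in _run_lengths(diag):
                hist[length] += 1
    return hist


def vertical_histogram(rp: RecurrencePlot) -> Counter:
    """Counts of maximal vertical line lengths (full matrix, LOI included)."""
    hist: Counter = Counter()
    for j in range(rp.n_points):
        for length in _run_lengths(rp.matrix[:, j]):
            hist[length] += 1
    return hist


def recurrence_times(rp: RecurrencePlot) -> Counter:
    """Histogram of return times per column (type-II: runs collapsed).

    For each column the recurrent rows are grouped into maximal runs; the
    return times are the gaps between successive run starts.
    """
    hist: Counter = Counter()
    for j in range(rp.n_points):
        rows = np.flatnonzero(rp.matrix[:, j])
        if len(rows) < 2:
            continue
        starts = rows[np.flatnonzero(np.diff(rows, prepend=rows[0] - 2) > 1)]
        for gap in np.diff(starts):
            hist[int(gap)] += 1
    return hist


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def rqa_features(rp: RecurrencePlot) -> RQAFeatures:
    """The eight RQA statistics of a recurrence plot (see module docstring)."""
    cfg = rp.config
    n = rp.n_points
    rr = float(rp.matrix.sum()) / n ** 2

    dhist = diagonal_histogram(rp)
    lengths = np.array(sorted(dhist))
    counts = np.array([dhist[int(l)] for l in lengths])
    total_pts = float((lengths * counts).sum()) if len(lengths) else 0.0
    sel = lengths >= cfg.l_min
    if total_pts > 0 and sel.any():
        det = float((lengths[sel] * counts[sel]).sum()) / total_pts
        l_mean = float((lengths[sel] * counts[sel]).sum() / counts[sel].sum())
        entr = _entropy(counts[sel].astype(float))
    else:
        det = l_mean = entr = 0.0
    l_max = float(lengths.max()) if len(lengths) else 0.0

    vhist = vertical_histogram(rp)
    vlengths = np.array(sorted(vhist))
    vcounts = np.array([vhist[int(v)] for v in vlengths])
    vsel = vlengths >= cfg.v_min
    tt = (float((vlengths[vsel] * vcounts[vsel]).sum() / vcounts[vsel].sum())
          if vsel.any() else 0.0)
    v_max = float(vlengths.max()) if len(vlengths) else 0.0

    thist = recurrence_times(rp)
    if thist:
        t_max = max(thist)
        if t_max > 1:
            tcounts = np.array([thist[t] for t in sorted(thist)], dtype=float)
            rpde = _entropy(tcounts) / np.log(t_max)
        else:
            rpde = 0.0
    else:
        rpde = 0.0
    return RQAFeatures(rr=rr, det=det, l_mean=l_mean, l_max=l_max,
                       entr=entr, tt=tt, v_max=v_max, rpde=rpde)


def auto_epsilon(traj: np.ndarray, strategy: str = "TARGET_RR",
                 value: float = 0.1) -> float:
    """Choose the recurrence threshold ε.

    ``TARGET_RR``: smallest pairwise distance achieving RR >= value (exact,
    from the sorted distance spectrum).  ``STD_FRACTION``: value × the
    standard deviation of the first embedding coordinate.
    """
    if not 0 < value <= 1:
        raise ValueError("value must be in (0, 1]")
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    strategy = strategy.upper()
    if strategy == "STD_FRACTION":
        sd = traj[:, 0].std()
        if sd == 0:
            raise ValueError("zero-variance trajectory: STD_FRACTION undefined")
        return float(value * sd)
    if strategy != "TARGET_RR":
        raise ValueError(f"unknown strategy {strategy!r}")
    d = np.sort(_cheb_dists(traj).ravel())
    k = int(np.ceil(value * len(d)))
    eps = float(d[k - 1])
    # Θ(0)=1 would make ε=0 valid, but EmbeddingConfig requires ε>0;
    # a tiny positive floor keeps constant series usable.
    return max(eps, np.finfo(float).tiny)


def rqa_from_series(series: np.ndarray, cfg: EmbeddingConfig | None = None,
                    eps_strategy: str | None = "TARGET_RR",
                    eps_value: float = 0.1) -> RQAFeatures:
    """Convenience: embed, auto-threshold (optional) and quantify a series."""
    cfg = cfg or EmbeddingConfig()
    traj = embed(series, cfg.m, cfg.tau)
    if eps_strategy is not None:
        from dataclasses import replace

        cfg = replace(cfg, epsilon=auto_epsilon(traj, eps_strategy, eps_value))
    return rqa_features(recurrence_matrix(traj, cfg))


def save_rp_csv(rp: RecurrencePlot, path) -> None:
    """Dense 0/1 CSV dump of the recurrence matrix."""
    np.savetxt(path, rp.matrix, fmt="%d", delimiter=",")


def save_rp_png(rp: RecurrencePlot, path, dpi: int = 100) -> None:
    """Debug image of the recurrence plot (origin at lower left)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rp.matrix, cmap="binary", origin="lower", interpolation="nearest")
    ax.set_xlabel("j")
    ax.set_ylabel("i")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
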