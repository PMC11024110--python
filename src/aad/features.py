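"""Feature assembly (microstate, recurrence, and their combination) and
statistical screening.

Three feature modes per analysis window:

* ``MS_ONLY`` — the four microstate parameters for each of the K states
  (mean GFP, occurrence, duration, coverage): 4K columns.
* ``RQA_ONLY`` — the eight recurrence statistics of the window's GFP
  series: 8 columns.
* ``MULTIVARIATE`` — the eight recurrence statistics of every microstate
  parameter series: the raw GFP(t) series plus, for each state, the
  occurrence/duration/coverage series recomputed over consecutive
  sub-windows.  With K=4 that is 8 x (1 + 3x4) = 104 columns; the
  combination found optimal for attention decoding, RR of the mean-GFP
  series, is always among them.

Screening follows the two-step recipe: a Kolmogorov-Smirnov normality
check per feature (EEG features are typically non-normal), then a
two-sided Mann-Whitney U test between the attend-speaker-1 and
attend-speaker-2 windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import Window
from .microstate import (MicrostatePrototypes, backfit, compute_gfp,
                         microstate_features)
from .rqa import EmbeddingConfig, rqa_from_series

__all__ = ["FeatureMatrix", "ScreeningResult", "ms_parameter_series",
           "build_features", "screen_features"]

MS_PARAMS = ("MEAN_GFP", "OCCURRENCE", "DURATION", "COVERAGE")


@dataclass
class FeatureMatrix:
    """Windows x features table with per-row class labels and trial ids."""

    df: pd.DataFrame
    labels: pd.Series
    trial_ids: pd.Series
    window_length_s: float

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        n = len(self.df)
        if len(self.labels) != n or len(self.trial_ids) != n:
            raise ValueError("labels/trial_ids must align with rows")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Integer classes: SPK1 -> 0 (positive), SPK2 -> 1."""
        return (self.labels.to_numpy() == "SPK2").astype(int)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            df=self.df.loc[mask].reset_index(drop=True),
            labels=self.labels.loc[mask].reset_index(drop=True),
            trial_ids=self.trial_ids.loc[mask].reset_index(drop=True),
            window_length_s=self.window_length_s,
        )

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "trial_id", self.trial_ids.to_numpy())
        out.insert(1, "label", self.labels.to_numpy())
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window_length_s: float = float("nan")) -> "FeatureMatrix":
        raw = pd.read_csv(path)
        return cls(df=raw.drop(columns=["trial_id", "label"]),
                   labels=raw["label"], trial_ids=raw["trial_id"],
                   window_length_s=window_length_s)


@dataclass
class ScreeningResult:
    table: pd.DataFrame  # index: feature; columns: normality_p, group_p, significant, degenerate
    alpha: float

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def ms_parameter_series(window: Window, prototypes: MicrostatePrototypes,
                        param: str, subwindow_s: float = 0.25) -> dict[str, np.ndarray]:
    """Scalar series feeding the recurrence analysis of one MS parameter.

    ``MEAN_GFP`` returns the raw GFP(t) sequence of the window (one series,
    key ``"gfp"``).  The per-state parameters are recomputed on consecutive
    non-overlapping sub-windows of ``subwindow_s`` seconds, one series per
    state (keys ``"<param>[k]"``).
    """
    param = param.upper()
    if param not in MS_PARAMS:
        raise ValueError(f"param must be one of {MS_PARAMS}")
    gfp = compute_gfp(window)
    if param == "MEAN_GFP":
        return {"gfp": gfp.values.copy()}

    sub = int(round(subwindow_s * window.sfreq))
    if sub < 2:
        raise ValueError("sub-window must cover at least 2 samples")
    n_sub = window.n_samples // sub
    if n_sub < 4:
        raise ValueError("fewer than 4 sub-windows: series too short for RQA")
    seg = backfit(window, prototypes)
    K = prototypes.K
    out = {f"{param.lower()}[{k}]": np.empty(n_sub) for k in range(K)}
    for i in range(n_sub):
        sl = slice(i * sub, (i + 1) * sub)
        sub_seg = replace(seg, labels=seg.labels[sl], polarity=seg.polarity[sl])
        sub_gfp = replace(gfp, values=gfp.values[sl])
        mf = microstate_features(sub_seg, sub_gfp, K=K)
        vals = {"OCCURRENCE": mf.occurrence, "DURATION": mf.duration,
                "COVERAGE": mf.coverage}[param]
        for k in range(K):
            out[f"{param.lower()}[{k}]"][i] = vals[k]
    return out


def _rqa_row(series: np.ndarray, cfg: EmbeddingConfig, eps_strategy, eps_value) -> dict:
    feats = rqa_from_series(series, cfg, eps_strategy, eps_value)
    return feats.as_dict()


def build_features(windows: list[Window], prototypes: MicrostatePrototypes,
                   mode: str = "MULTIVARIATE",
                   rqa_cfg: EmbeddingConfig | None = None,
                   selection: list[str] | str = "ALL",
                   subwindow_s: float = 0.25,
                   eps_strategy: str = "TARGET_RR",
                   eps_value: float = 0.1) -> FeatureMatrix:
    """Assemble the per-window feature table for one of the three modes.

    Windows whose features come out non-finite are dropped with a warning.
    ``selection`` keeps a named subset of the assembled columns.
    """
    mode = mode.upper()
    if mode not in ("MS_ONLY", "RQA_ONLY", "MULTIVARIATE"):
        raise ValueError(f"unknown mode {mode!r}")
    if not windows:
        raise ValueError("no windows given")
    cfg = rqa_cfg or EmbeddingConfig()
    K = prototypes.K

    rows, labels, trial_ids = [], [], []
    for w in windows:
        row: dict[str, float] = {}
        if mode == "MS_ONLY":
            seg = backfit(w, prototypes)
            gfp = compute_gfp(w)
            mf = microstate_features(seg, gfp, K=K)
            for k in range(K):
                row[f"mean_gfp[{k}]"] = mf.mean_gfp[k]
                row[f"occurrence[{k}]"] = mf.occurrence[k]
                row[f"duration[{k}]"] = mf.duration[k]
                row[f"coverage[{k}]"] = mf.coverage[k]
        elif mode == "RQA_ONLY":
            gfp = compute_gfp(w)
            for name, val in _rqa_row(gfp.values, cfg, eps_strategy, eps_value).items():
                row[f"{name}(gfp)"] = val
        else:  # MULTIVARIATE
            series_map: dict[str, np.ndarray] = {}
            series_map.update(ms_parameter_series(w, prototypes, "MEAN_GFP"))
            for param in ("OCCURRENCE", "DURATION", "COVERAGE"):
                series_map.update(
                    ms_parameter_series(w, prototypes, param, subwindow_s))
            for sname, series in series_map.items():
                for fname, val in _rqa_row(series, cfg, eps_strategy,
                                           eps_value).items():
                    row[f"{fname}({sname})"] = val
        rows.append(row)
        labels.append(w.label)
        trial_ids.append(w.trial_index)

    df = pd.DataFrame(rows)
    if isinstance(selection, (list, tuple)):
        unknown = set(selection) - set(df.columns)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        df = df[list(selection)]
    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} windows with "
                      "non-finite features")
    return FeatureMatrix(
        df=df.loc[finite].reset_index(drop=True),
        labels=pd.Series(labels)[finite].reset_index(drop=True),
        trial_ids=pd.Series(trial_ids)[finite].reset_index(drop=True),
        window_length_s=windows[0].length_s,
    )


def screen_features(fm: FeatureMatrix, alpha: float = 0.05,
                    fdr: bool = False) -> ScreeningResult:
    """KS normality check plus two-sided Mann-Whitney U per feature.

    ``significant`` means group p < alpha (optionally Benjamini-Hochberg
    adjusted when ``fdr`` is set).  Constant features are flagged degenerate
    with p = 1.
    """
    y = fm.labels.to_numpy()
    g1 = fm.df[y == "SPK1"]
    g2 = fm.df[y == "SPK2"]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need >= 3 windows per class for screening")
    records = []
    for col in fm.df.columns:
        x = fm.df[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            records.append((col, 1.0, 1.0, True))
            continue
        z = (x - x.mean()) / x.std()
        norm_p = stats.kstest(z, "norm").pvalue
        group_p = stats.mannwhitneyu(g1[col], g2[col],
                                     alternative="two-sided").pvalue
        records.append((col, norm_p, group_p, False))
    table = pd.DataFrame(records, columns=["feature", "normality_p",
                                           "group_p", "degenerate"])
    table = table.set_index("feature")
    pvals = table["group_p"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        table["significant"] = reject & ~table["degenerate"]
    else:
        table["significant"] = (pvals < alpha) & ~table["degenerate"]
    return ScreeningResult(table=table, alpha=alpha)
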