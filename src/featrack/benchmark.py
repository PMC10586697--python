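"""Link-level benchmarking against ground truth.

Tracking output is scored per identity link: links present in the ground
truth but missing from the reconstruction are false negatives, links present
in the reconstruction but absent from the ground truth are false positives,
and the F1-score 2TP / (2TP + FN + FP) summarises both.  To remove the
user-chosen threshold P from comparisons, the threshold is swept over a
logarithmic grid and each run is represented by its maximum F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .simulate import GroundTruthDataset
from .tracker import (LinkSet, PreparedTracking, TrackerConfig, assemble_tracks,
                      bridge_gaps, links_for_threshold, prepare_tracking)


@dataclass
class LinkComparison:
    """Counts of correct/incorrect links and the derived F1."""

    TP: int
    FP: int
    FN: int

    @property
    def f1(self) -> float:
        denom = 2 * self.TP + self.FN + self.FP
        return 2 * self.TP / denom if denom > 0 else 0.0

    @property
    def errors(self) -> int:
        return self.FP + self.FN


def default_p_grid(lo: float = 1e-4, hi: float = 1.0, n: int = 13) -> np.ndarray:
    """Logarithmically spaced threshold grid (defaults span four decades)."""
    return np.geomspace(lo, hi, n)


def _expand_gaps(pred: LinkSet, gt: LinkSet) -> tuple:
    """Resolve gap links into the consecutive-frame links they imply.

    A bridge over k missing frames stands for k+1 consecutive links.  If the
    ground truth contains a path of that length between the bridged
    endpoints, the bridge contributes those k+1 links (they score as true
    positives); otherwise it contributes k+1 unmatched placeholder links
    (scored as false positives).
    """
    df = pred.df
    gaps = df[df["kind"] == "gap"]
    if gaps.empty:
        return set(map(tuple, df[["frame_from", "id_from", "frame_to", "id_to"]]
                       .itertuples(index=False, name=None))), 0
    succ = {}
    for row in gt.df.itertuples(index=False):
        succ[(row.frame_from, row.id_from)] = (row.frame_to, row.id_to)
    keys = set(map(tuple, df[df["kind"] != "gap"]
                   [["frame_from", "id_from", "frame_to", "id_to"]]
                   .itertuples(index=False, name=None)))
    extra_fp = 0
    for row in gaps.itertuples(index=False):
        span = row.frame_to - row.frame_from
        node = (row.frame_from, row.id_from)
        path = []
        for _ in range(span):
            nxt = succ.get(node)
            if nxt is None:
                break
            path.append((node[0], node[1], nxt[0], nxt[1]))
            node = nxt
        if len(path) == span and node == (row.frame_to, row.id_to):
            keys.update(path)
        else:
            extra_fp += span
    return keys, extra_fp


def compare_links(pred: LinkSet, gt: LinkSet) -> LinkComparison:
    """Exact set comparison of predicted and true identity links.

    Gap links are first expanded to the consecutive-frame links they imply,
    so interpolation is scored fairly.  The ground truth is restricted to
    the frame range the prediction covers is the caller's responsibility;
    normally both cover the full dataset.
    """
    gt_keys = set(map(tuple, gt.df[["frame_from", "id_from", "frame_to", "id_to"]]
                      .itertuples(index=False, name=None)))
    pred_keys, extra_fp = _expand_gaps(pred, gt)
    tp = len(pred_keys & gt_keys)
    fp = len(pred_keys - gt_keys) + extra_fp
    fn = len(gt_keys - pred_keys)
    return LinkComparison(TP=tp, FP=fp, FN=fn)


@dataclass
class SweepResult:
    """Per-threshold comparisons and the maximising threshold."""

    P_grid: np.ndarray
    comparisons: list
    mean_trackability: float

    @property
    def f1(self) -> np.ndarray:
        return np.array([c.f1 for c in self.comparisons])

    @property
    def argmax_P(self) -> float:
        # deterministic tie-break toward the smaller threshold
        return float(self.P_grid[int(np.argmax(self.f1))])

    @property
    def max_f1(self) -> float:
        return float(self.f1.max())

    @property
    def best(self) -> LinkComparison:
        return self.comparisons[int(np.argmax(self.f1))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "P": self.P_grid,
            "TP": [c.TP for c in self.comparisons],
            "FP": [c.FP for c in self.comparisons],
            "FN": [c.FN for c in self.comparisons],
            "f1": self.f1,
        })


def _links_with_gaps(prepared: PreparedTracking, P: float) -> LinkSet:
    links = links_for_threshold(prepared, P)
    if prepared.config.max_gap >= 1:
        tracks = assemble_tracks(prepared.tables, links, prepared.spec)
        gaps = bridge_gaps(tracks, prepared.tables, prepared, links)
        if len(gaps):
            links = links.concat(gaps)
    return links


def sweep_threshold(dataset: GroundTruthDataset, config: TrackerConfig,
                    P_grid=None, prepared: PreparedTracking | None = None) -> SweepResult:
    """Track at every threshold of the grid and compare against ground truth.

    The training statistics and candidate scores do not depend on P, so they
    are computed once and only the assignment stage is repeated.
    """
    P_grid = default_p_grid() if P_grid is None else np.asarray(P_grid, dtype=float)
    if P_grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    if prepared is None:
        prepared = prepare_tracking(dataset.frames, dataset.spec, config)
    comparisons = []
    for P in P_grid:
        links = _links_with_gaps(prepared, float(P))
        comparisons.append(compare_links(links, dataset.gt_links))
    mean_r = float(np.mean([m.r for m in prepared.models()]))
    return SweepResult(P_grid, comparisons, mean_r)


def feature_ablation(dataset: GroundTruthDataset, config: TrackerConfig,
                     feature_sets: dict, P_grid=None) -> pd.DataFrame:
    """Sweep the threshold once per feature set and tabulate the results.

    ``feature_sets`` maps a label to a tuple of feature names (each must
    include both centroid coordinates).  Returns one row per label with the
    maximum F1, the error count at that threshold and the mean trackability.
    """
    if len(feature_sets) < 2:
        raise ValueError("need at least two feature sets to compare")
    rows = []
    for label, names in feature_sets.items():
        cfg = TrackerConfig(P=config.P, F=config.F, features_used=tuple(names),
                            max_gap=config.max_gap, min_train=config.min_train,
                            gate=config.gate)
        sweep = sweep_threshold(dataset, cfg, P_grid)
        rows.append({"feature_set": label, "max_f1": sweep.max_f1,
                     "errors": sweep.best.errors, "argmax_P": sweep.argmax_P,
                     "mean_trackability": sweep.mean_trackability})
    return pd.DataFrame(rows)


def fold_reduction(ablation: pd.DataFrame, baseline: str = "centroids",
                   full: str = "all") -> float:
    """Error fold-reduction of the full feature set over the baseline.

    When the full set makes zero errors the ratio is floored by treating the
    denominator as a single error — a conservative lower bound on the true
    (infinite) fold change.
    """
    e0 = int(ablation.set_index("feature_set").loc[baseline, "errors"])
    e1 = int(ablation.set_index("feature_set").loc[full, "errors"])
    return e0 / max(e1, 1)


def trackability_accuracy_report(runs) -> dict:
    """Rank correlation between mean trackability and maximum F1 across runs.

    ``runs`` is a sequence of (mean trackability, max F1) pairs.  With a
    constant predictor the correlation is undefined and reported as NaN.
    """
    runs = np.asarray(list(runs), dtype=float)
    if runs.shape[0] < 3:
        raise ValueError("need at least three runs for a correlation")
    r, x = runs[:, 0], runs[:, 1]
    if np.allclose(r, r[0]) or np.allclose(x, x[0]):
        rho, p = float("nan"), float("nan")
    else:
        rho, p = spearmanr(r, x)
    return {"spearman_rho": float(rho), "p_value": float(p),
            "n_runs": int(runs.shape[0]),
            "table": pd.DataFrame({"mean_trackability": r, "max_f1": x})}
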