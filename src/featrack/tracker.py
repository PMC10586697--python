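"""Two-stage feature-assisted tracking.

Stage 1 (training): a nearest-neighbour pass on centroids proposes putative
links; the fraction F with the smallest centroid displacement — the links
most likely to be correct — train the Gaussian displacement model of each
frame pair.  Stage 2 (assignment): every cross-frame pair is scored by its
Mahalanobis distance in the whitened feature space and links are accepted
greedily in ascending score order, one-to-one, up to the adaptive threshold
beta_t derived from the user's static threshold P.  Tracks interrupted by
transient missed detections are re-joined by gap bridging with the random
walk covariance inflated by the gap length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2
from ._kernels import greedy_one_to_one
from .features import POSITION_NAMES, FeatureSpec, FeatureTable, wrap_half_open
from .model import (DisplacementModel, InsufficientTrainingError, TrackabilityReport,
                    adaptive_threshold, build_trackability_report,
                    compute_displacements, fit_displacement_model,
                    normalize_displacement, select_training_links, trackability)

LINK_COLUMNS = ["frame_from", "id_from", "frame_to", "id_to", "score", "kind"]
INTERPOLATED_ID = -1


class LinkSet:
    """A one-to-one set of identity links between frames.

    Backed by a DataFrame with columns ``frame_from, id_from, frame_to,
    id_to, score, kind``; no object may appear twice as a source or twice
    as a target.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True)
        for c in ("frame_from", "id_from", "frame_to", "id_to"):
            df[c] = df[c].astype(np.int64)
        self.df = df[LINK_COLUMNS + [c for c in df.columns if c not in LINK_COLUMNS]]
        if validate and len(df):
            if (df["frame_to"] <= df["frame_from"]).any():
                raise ValueError("links must point forward in time")
            if df.duplicated(["frame_from", "id_from"]).any():
                raise ValueError("an object appears twice as a link source")
            if df.duplicated(["frame_to", "id_to"]).any():
                raise ValueError("an object appears twice as a link target")

    @classmethod
    def empty(cls) -> "LinkSet":
        return cls(pd.DataFrame({c: [] for c in LINK_COLUMNS}), validate=False)

    @classmethod
    def from_arrays(cls, frame_from, id_from, frame_to, id_to, score, kind) -> "LinkSet":
        n = len(id_from)
        return cls(pd.DataFrame({
            "frame_from": frame_from if np.ndim(frame_from) else np.full(n, frame_from),
            "id_from": id_from,
            "frame_to": frame_to if np.ndim(frame_to) else np.full(n, frame_to),
            "id_to": id_to,
            "score": score,
            "kind": kind if not isinstance(kind, str) else [kind] * n,
        }))

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> set:
        """Set of (frame_from, id_from, frame_to, id_to) tuples."""
        return set(map(tuple, self.df[["frame_from", "id_from", "frame_to", "id_to"]]
                       .itertuples(index=False, name=None)))

    def concat(self, other: "LinkSet") -> "LinkSet":
        return LinkSet(pd.concat([self.df, other.df], ignore_index=True))

    def sorted(self) -> "LinkSet":
        df = self.df.sort_values(["frame_from", "id_from"], kind="mergesort")
        return LinkSet(df, validate=False)


@dataclass
class TrackerConfig:
    """User-facing tracking settings.

    P is the static threshold converted per frame into the adaptive
    Mahalanobis cutoff beta_t; F the fraction of nearest-neighbour links kept
    for training; ``features_used`` the subset of the spec's features to track
    with (must include both centroid coordinates); ``max_gap`` the longest
    missed-detection gap that may be bridged.
    """

    P: float = 0.05
    F: float = 0.5
    features_used: tuple | None = None
    max_gap: int = 2
    min_train: int | None = None  # default max(50, 5N)
    gate: float = 1.0
    drop_bits: float = 1.0
    median_window: int = 21
    training_pass: str = "standardized"  # or "centroid"
    refine_iterations: int = 2

    def __post_init__(self):
        if not (self.P > 0):
            raise ValueError("P must be > 0")
        if not (0 < self.F <= 1):
            raise ValueError("F must lie in (0, 1]")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.training_pass not in ("standardized", "centroid"):
            raise ValueError("training_pass must be 'standardized' or 'centroid'")
        if self.refine_iterations < 0:
            raise ValueError("refine_iterations must be >= 0")
        if self.features_used is not None:
            self.features_used = tuple(self.features_used)
            for p in POSITION_NAMES:
                if p not in self.features_used:
                    raise ValueError("features_used must include both centroid coordinates")

    def resolve_features(self, spec: FeatureSpec) -> tuple:
        return self.features_used if self.features_used is not None else spec.names

    def resolve_min_train(self, n_features: int) -> int:
        return self.min_train if self.min_train is not None else max(50, 5 * n_features)


# ---------------------------------------------------------------------------
# stage 1: nearest-neighbour training pass
# ---------------------------------------------------------------------------

def _centroid_distances(table_t: FeatureTable, table_t1: FeatureTable,
                        spec: FeatureSpec) -> np.ndarray:
    """(n, m) matrix of centroid distances, minimum-image if periodic."""
    pi_ = spec.position_indices
    if len(pi_) != 2:
        raise ValueError("both centroid coordinates must be present")
    a = table_t.X[:, pi_]
    b = table_t1.X[:, pi_]
    d = b[None, :, :] - a[:, None, :]
    if spec.periodic:
        for ax in range(2):
            d[..., ax] = wrap_half_open(d[..., ax], spec.domain_size[ax])
    return np.sqrt((d ** 2).sum(axis=2))


def _greedy_distance_match(table_t: FeatureTable, table_t1: FeatureTable,
                           dist: np.ndarray) -> LinkSet:
    n, m = dist.shape
    ii, jj = np.unravel_index(np.arange(n * m), (n, m))
    order = np.lexsort((table_t1.ids[jj], table_t.ids[ii], dist.ravel()))
    accept = greedy_one_to_one(ii[order], jj[order], n, m, min(n, m))
    sel = order[accept]
    return LinkSet.from_arrays(table_t.frame, table_t.ids[ii[sel]],
                               table_t1.frame, table_t1.ids[jj[sel]],
                               dist.ravel()[sel], "training")


def nearest_neighbour_pass(table_t: FeatureTable, table_t1: FeatureTable,
                           spec: FeatureSpec) -> LinkSet:
    """Greedy mutually exclusive matching on centroid distance.

    Repeatedly accepts the globally smallest remaining centroid distance with
    both endpoints unused, so every object of the smaller frame gets matched.
    Ties are broken by (id_from, id_to).  Scores are the centroid distances.
    """
    if table_t.n_o == 0 or table_t1.n_o == 0:
        raise ValueError("nearest-neighbour pass needs two non-empty frames")
    return _greedy_distance_match(table_t, table_t1,
                                  _centroid_distances(table_t, table_t1, spec))


def standardized_nn_pass(table_t: FeatureTable, table_t1: FeatureTable,
                         spec: FeatureSpec) -> LinkSet:
    """Nearest-neighbour matching in per-feature standardized space.

    Like :func:`nearest_neighbour_pass` but the distance is Euclidean over
    *all* tracked features, each divided by its pooled frame-wide standard
    deviation.  When objects move further than their spacing between frames,
    centroid proximity alone pairs almost nothing correctly, while conserved
    features (length, intensity, orientation) still single out the right
    partner; this standardized distance keeps the preliminary pass usable in
    that regime without any fitted model.  Scores are standardized distances.
    """
    if table_t.n_o == 0 or table_t1.n_o == 0:
        raise ValueError("nearest-neighbour pass needs two non-empty frames")
    sd = np.vstack([table_t.X, table_t1.X]).std(axis=0)
    sd[sd == 0] = 1.0
    d = table_t1.X[None, :, :] - table_t.X[:, None, :]
    d = spec.wrap_differences(d) / sd
    return _greedy_distance_match(table_t, table_t1, np.sqrt((d ** 2).sum(axis=2)))


# ---------------------------------------------------------------------------
# stage 2: model-based scoring and assignment
# ---------------------------------------------------------------------------

@dataclass
class CandidateLinks:
    """Cross-frame candidate links sorted ascending by Mahalanobis norm."""

    frame_from: int
    frame_to: int
    ids_from: np.ndarray
    ids_to: np.ndarray
    rows_from: np.ndarray
    rows_to: np.ndarray
    norms: np.ndarray
    n_from: int
    n_to: int

    def __len__(self):
        return len(self.norms)


_CHUNK = 2_000_000  # max candidate matrix entries held at once


def score_candidates(table_t: FeatureTable, table_t1: FeatureTable,
                     model: DisplacementModel, spec: FeatureSpec,
                     gate: float = 1.0, gate_norm: float | None = None) -> CandidateLinks:
    """Mahalanobis norms of all cross-frame pairs within the gate.

    Pairs with norm <= ``gate * model.beta`` (or an absolute ``gate_norm``
    when given) are returned sorted ascending by norm, ties broken by
    (id_from, id_to).  Computation is dense all-pairs, chunked over rows of
    the earlier frame to bound memory.
    """
    limit = float(gate_norm) if gate_norm is not None else float(gate) * float(model.beta)
    n, m = table_t.n_o, table_t1.n_o
    keep_i, keep_j, keep_norm = [], [], []
    if n and m:
        rows_per_chunk = max(1, _CHUNK // max(1, m * spec.n_features))
        for lo in range(0, n, rows_per_chunk):
            hi = min(n, lo + rows_per_chunk)
            d = table_t1.X[None, :, :] - table_t.X[lo:hi, None, :]
            d = spec.wrap_differences(d)
            _, norms = normalize_displacement(d.reshape(-1, spec.n_features), model)
            norms = norms.reshape(hi - lo, m)
            ii, jj = np.nonzero(norms <= limit)
            keep_i.append(ii + lo)
            keep_j.append(jj)
            keep_norm.append(norms[ii, jj])
    ii = np.concatenate(keep_i) if keep_i else np.empty(0, dtype=int)
    jj = np.concatenate(keep_j) if keep_j else np.empty(0, dtype=int)
    norms = np.concatenate(keep_norm) if keep_norm else np.empty(0)
    order = np.lexsort((table_t1.ids[jj], table_t.ids[ii], norms))
    return CandidateLinks(table_t.frame, table_t1.frame,
                          table_t.ids[ii[order]], table_t1.ids[jj[order]],
                          ii[order], jj[order], norms[order], n, m)


def assign_links(candidates: CandidateLinks, beta: float) -> LinkSet:
    """Greedy one-to-one acceptance of candidates with norm <= beta."""
    k = int(np.searchsorted(candidates.norms, beta, side="right"))
    accept = greedy_one_to_one(candidates.rows_from[:k], candidates.rows_to[:k],
                               candidates.n_from, candidates.n_to,
                               min(candidates.n_from, candidates.n_to))
    return LinkSet.from_arrays(candidates.frame_from, candidates.ids_from[:k][accept],
                               candidates.frame_to, candidates.ids_to[:k][accept],
                               candidates.norms[:k][accept], "primary")


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreparedPair:
    """Fitted model and pre-scored candidates for one frame pair."""

    index: int          # position of the earlier frame in the table list
    model: DisplacementModel
    candidates: CandidateLinks


@dataclass
class PreparedTracking:
    """Threshold-independent tracking state, reusable across values of P.

    Training statistics, trackability and the candidate scores do not depend
    on the static threshold P, so a threshold sweep only repeats the greedy
    assignment stage.
    """

    spec: FeatureSpec
    sub_spec: FeatureSpec
    tables: list
    sub_tables: list
    pairs: dict  # index -> PreparedPair
    config: TrackerConfig

    def models(self):
        return [p.model for p in self.pairs.values()]


def prepare_tracking(tables, spec: FeatureSpec, config: TrackerConfig) -> PreparedTracking:
    """Run the training stage on every consecutive frame pair.

    Per pair: nearest-neighbour pass, training-link selection with fraction F,
    displacement-model fit (pooling neighbouring pairs when a pair alone has
    fewer than max(50, 5N) training links), trackability, and candidate
    scoring up to the largest admissible threshold.  Pairs touching an empty
    frame are skipped and appear as gaps in the report.
    """
    if len(tables) < 2:
        raise ValueError("need at least two frames to track")
    tables = sorted(tables, key=lambda t: t.frame)
    names = config.resolve_features(spec)
    sub_spec = spec.subset(names)
    sub_tables = [t.subset_features(spec, names) for t in tables]
    n_feat = sub_spec.n_features
    min_train = config.resolve_min_train(n_feat)
    cap = math.sqrt(float(chi2.ppf(0.999, df=n_feat)))
    pass_fn = (standardized_nn_pass if config.training_pass == "standardized"
               else nearest_neighbour_pass)

    # per-pair training displacements from the preliminary pass
    disp: dict[int, np.ndarray] = {}
    for i in range(len(tables) - 1):
        t0, t1 = sub_tables[i], sub_tables[i + 1]
        if t0.n_o == 0 or t1.n_o == 0:
            continue
        putative = pass_fn(t0, t1, sub_spec)
        training = select_training_links(putative, config.F)
        disp[i] = compute_displacements(t0, t1, training, sub_spec)

    models = _fit_pooled(disp, tables, sub_tables, n_feat, min_train, config)
    # refinement: re-derive training links from the fitted model itself.
    # The gate is deliberately looser than the final acceptance cap: the
    # one-to-one competition, not the radius, should pick the training set,
    # otherwise a low-biased initial covariance can lock itself in by
    # excluding the very links that would widen it.
    refine_gate = 3.0 * cap
    for _ in range(config.refine_iterations):
        new_disp: dict[int, np.ndarray] = {}
        for i, m in models.items():
            cands = score_candidates(sub_tables[i], sub_tables[i + 1], m,
                                     sub_spec, gate_norm=refine_gate)
            accept = greedy_one_to_one(cands.rows_from, cands.rows_to,
                                       cands.n_from, cands.n_to,
                                       min(cands.n_from, cands.n_to))
            d = sub_tables[i + 1].X[cands.rows_to[accept]] - \
                sub_tables[i].X[cands.rows_from[accept]]
            if len(d):
                new_disp[i] = sub_spec.wrap_differences(d)
        if new_disp:
            models = _fit_pooled(new_disp, tables, sub_tables, n_feat,
                                 min_train, config)

    pairs: dict[int, PreparedPair] = {}
    for i, m in models.items():
        cands = score_candidates(sub_tables[i], sub_tables[i + 1], m, sub_spec,
                                 gate_norm=config.gate * cap)
        pairs[i] = PreparedPair(i, m, cands)
    return PreparedTracking(spec, sub_spec, tables, sub_tables, pairs, config)


def _fit_pooled(disp: dict, tables, sub_tables, n_feat: int, min_train: int,
                config: TrackerConfig) -> dict:
    """Fit per-pair models, pooling neighbouring pairs when data are sparse."""
    models: dict[int, "DisplacementModel"] = {}
    for i, d in disp.items():
        pooled = d
        half = 0
        while pooled.shape[0] < min_train:
            half += 1
            lo, hi = i - half, i + half
            if lo < min(disp) and hi > max(disp):
                break
            pooled = np.vstack([disp[k] for k in sorted(disp) if lo <= k <= hi])
        if pooled.shape[0] < n_feat + 1:
            raise InsufficientTrainingError(
                f"frame pair {tables[i].frame}-{tables[i + 1].frame}: "
                f"{pooled.shape[0]} training links even after pooling")
        m = fit_displacement_model(pooled, sub_tables[i + 1], sub_tables[i].n_o,
                                   frame_pair=(tables[i].frame, tables[i + 1].frame))
        m.r = trackability(m.sigma_x, m.sigma_delta, m.n_o)
        m.beta = adaptive_threshold(m, config.P)
        models[i] = m
    return models


def links_for_threshold(prepared: PreparedTracking, P: float) -> LinkSet:
    """Primary links for a static threshold P, reusing prepared statistics."""
    out = []
    for pp in prepared.pairs.values():
        beta = adaptive_threshold(pp.model, P) * prepared.config.gate
        out.append(assign_links(pp.candidates, beta).df)
    if not out:
        return LinkSet.empty()
    return LinkSet(pd.concat(out, ignore_index=True))


# ---------------------------------------------------------------------------
# track assembly and gap bridging
# ---------------------------------------------------------------------------

class TrackSet:
    """Assembled trajectories: one row per (track, frame).

    Gap-bridged frames carry linearly interpolated feature values, the
    object id ``-1`` and ``interpolated=True``; frames within each track are
    strictly increasing and contiguous.
    """

    def __init__(self, df: pd.DataFrame, feature_names):
        self.df = df.reset_index(drop=True)
        self.feature_names = tuple(feature_names)

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    def track(self, track_id: int) -> pd.DataFrame:
        return self.df[self.df["track_id"] == track_id]

    def spans(self) -> pd.DataFrame:
        g = self.df.groupby("track_id")["frame"]
        return pd.DataFrame({"start_frame": g.min(), "end_frame": g.max()})


def _interp_features(x0, x1, frac, spec: FeatureSpec):
    """Wrap-aware linear interpolation between two raw feature vectors."""
    step = spec.wrap_differences(x1 - x0)
    x = x0 + frac * step
    for j, (k, p) in enumerate(zip(spec.kinds, spec.circular_period)):
        if k == "circular":
            x[j] = x[j] % p
    if spec.periodic:
        for ax, j in enumerate(spec.position_indices):
            x[j] = x[j] % spec.domain_size[ax]
    return x


def assemble_tracks(tables, links: LinkSet, spec: FeatureSpec) -> TrackSet:
    """Follow links into trajectories; gap links get interpolated entries.

    Track ids are assigned in order of (start frame, first object id).
    """
    tables = sorted(tables, key=lambda t: t.frame)
    lookup = {t.frame: (t, t.row_of()) for t in tables}
    succ: dict[tuple, tuple] = {}
    has_pred: set = set()
    for row in links.df.itertuples(index=False):
        succ[(row.frame_from, row.id_from)] = (row.frame_to, row.id_to)
        has_pred.add((row.frame_to, row.id_to))

    starts = []
    for t in tables:
        for oid in t.ids:
            if (t.frame, int(oid)) not in has_pred:
                starts.append((t.frame, int(oid)))
    starts.sort()

    rows = []
    for tid, (frame, oid) in enumerate(starts):
        node = (frame, oid)
        while True:
            tab, rowmap = lookup[node[0]]
            x = tab.X[rowmap[node[1]]]
            rows.append((tid, node[0], node[1], False, *x))
            nxt = succ.get(node)
            if nxt is None:
                break
            gap = nxt[0] - node[0] - 1
            if gap > 0:
                x1 = lookup[nxt[0]][0].X[lookup[nxt[0]][1][nxt[1]]]
                for g in range(1, gap + 1):
                    xi = _interp_features(x, x1, g / (gap + 1), spec)
                    rows.append((tid, node[0] + g, INTERPOLATED_ID, True, *xi))
            node = nxt
    df = pd.DataFrame(rows, columns=["track_id", "frame", "object_id",
                                     "interpolated", *spec.names])
    return TrackSet(df, spec.names)


def bridge_gaps(tracks: TrackSet, tables, prepared: PreparedTracking,
                links: LinkSet) -> LinkSet:
    """Join track ends to later track starts across short detection gaps.

    A candidate join over a gap of k missing frames is scored against the
    random-walk model of the end frame with mean (k+1)*mu and covariance
    (k+1)*sigma_delta, and accepted greedily under the adaptive threshold
    recomputed with that inflated covariance.  Returns the accepted gap
    links (kind ``"gap"``).
    """
    config = prepared.config
    if config.max_gap < 1 or tracks.df.empty:
        return LinkSet.empty()
    spans = tracks.spans()
    obs = tracks.df[~tracks.df["interpolated"]]
    first_frame = min(t.frame for t in tables)
    last_frame = max(t.frame for t in tables)
    frame_index = {t.frame: i for i, t in enumerate(sorted(tables, key=lambda t: t.frame))}

    ends = spans[spans["end_frame"] < last_frame]
    starts = spans[spans["start_frame"] > first_frame]
    if ends.empty or starts.empty:
        return LinkSet.empty()

    end_rows = obs.merge(ends.reset_index(), left_on=["track_id", "frame"],
                         right_on=["track_id", "end_frame"])
    start_rows = obs.merge(starts.reset_index(), left_on=["track_id", "frame"],
                           right_on=["track_id", "start_frame"])
    sub_names = prepared.sub_spec.names
    cands = []
    for e in end_rows.itertuples(index=False):
        pp = prepared.pairs.get(frame_index.get(e.frame))
        if pp is None:
            continue
        m = pp.model
        for s in start_rows.itertuples(index=False):
            k = s.frame - e.frame - 1
            if not (1 <= k <= config.max_gap):
                continue
            dx = np.array([getattr(s, n) for n in sub_names]) - \
                np.array([getattr(e, n) for n in sub_names])
            dx = prepared.sub_spec.wrap_differences(dx)
            infl = DisplacementModel(m.frame_pair, (k + 1) * m.mu,
                                     (k + 1) * m.sigma_delta, m.sigma_x,
                                     m.n_o, m.n_train)
            _, norm = normalize_displacement(dx, infl)
            beta_k = adaptive_threshold(infl, config.P) * config.gate
            if norm <= beta_k:
                cands.append((norm, e.frame, int(e.object_id), s.frame,
                              int(s.object_id)))
    if not cands:
        return LinkSet.empty()
    cands.sort()
    used_src, used_dst, accepted = set(), set(), []
    for norm, f0, i0, f1, i1 in cands:
        if (f0, i0) in used_src or (f1, i1) in used_dst:
            continue
        used_src.add((f0, i0))
        used_dst.add((f1, i1))
        accepted.append((f0, i0, f1, i1, norm, "gap"))
    return LinkSet(pd.DataFrame(accepted, columns=LINK_COLUMNS))


def track_dataset(tables, spec: FeatureSpec, config: TrackerConfig | None = None):
    """Run the complete tracking pipeline on a list of frame tables.

    Returns ``(tracks, links, report)``: assembled trajectories (gap frames
    interpolated), the accepted link set (primary + gap links) and the
    per-frame trackability report.
    """
    config = config or TrackerConfig()
    prepared = prepare_tracking(tables, spec, config)
    links = links_for_threshold(prepared, config.P)
    tracks = assemble_tracks(tables, links, spec)
    gap_links = bridge_gaps(tracks, tables, prepared, links)
    if len(gap_links):
        links = links.concat(gap_links)
        tracks = assemble_tracks(tables, links, spec)
    report = build_trackability_report(prepared.models(), config.drop_bits,
                                       config.median_window)
    return tracks, links.sorted(), report


def select_time_window(report: TrackabilityReport, frame_range=None) -> tuple:
    """Contiguous frame range excluding flagged frames.

    With ``frame_range`` given, that manual override is returned (after
    checking it is non-empty); otherwise the longest contiguous run of
    unflagged frames, earliest on ties.
    """
    if frame_range is not None:
        lo, hi = int(frame_range[0]), int(frame_range[1])
        if hi < lo:
            raise ValueError("empty time window selection")
        return lo, hi
    ok = ~np.isin(report.frames, report.flags)
    best, cur = None, None
    for f, good in zip(report.frames, ok):
        if good:
            cur = (f, f) if cur is None else (cur[0], f)
            if best is None or cur[1] - cur[0] > best[1] - best[0]:
                best = cur
        else:
            cur = None
    if best is None:
        raise ValueError("empty time window selection: every frame is flagged")
    return int(best[0]), int(best[1])
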