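"""Division detection: assigning daughter cells to mother cells.

A division shows up in tracking output as a track that starts mid-movie next
to an existing track whose length dropped sharply (the mother continues as
one daughter; the other daughter founds the new track).  Candidate
mother/daughter pairs are scored with the same whitened-feature machinery as
frame-to-frame linking, but against a division-specific displacement model
in which the expected transforms of division are removed first: the daughter
length is compared against half the mother length, its position against the
mother centroid and its intensity against the mother intensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSpec, wrap_half_open
from .model import (DisplacementModel, adaptive_threshold,
                    fit_displacement_model, normalize_displacement,
                    regularize_covariance)
from .tracker import TrackSet

LINEAGE_COLUMNS = ["child_track_id", "parent_track_id", "division_frame"]


@dataclass
class DivisionConfig:
    """Tunable contract of the division detector.

    ``length_drop`` is the minimum fractional length decrease of a candidate
    mother between the frames flanking the division; ``radius_factor`` times
    the mother length bounds the daughter's centroid offset; ``P_div`` plays
    the role of the tracking threshold P for daughter assignment.
    """

    length_drop: float = 0.2
    radius_factor: float = 1.5
    F_div: float = 1.0
    # divisions are rare and already pre-gated by the length-drop and radius
    # predicates, and the greedy one-to-one competition resolves ambiguity;
    # the threshold only needs to reject gross outliers, so one expected
    # spurious competitor per event (rather than the tracking default 0.05)
    # keeps the bulk of the true chi-distributed scores inside the gate
    P_div: float = 1.0
    features: tuple = ("x", "y", "length", "intensity")


@dataclass
class DivisionCandidate:
    child_track: int
    mother_track: int
    frame: int
    displacement: np.ndarray   # position (2), length-vs-half, intensity delta
    offset: float              # centroid offset magnitude (ranks training set)


class LineageSet:
    """Parent/child records forming a forest over track ids."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        if len(df):
            if df["child_track_id"].duplicated().any():
                raise ValueError("a child track has more than one parent")
            self._check_acyclic()

    def _check_acyclic(self):
        parent = dict(zip(self.df["child_track_id"], self.df["parent_track_id"]))
        for start in parent:
            seen = set()
            node = start
            while node in parent:
                if node in seen:
                    raise ValueError("lineage contains a cycle")
                seen.add(node)
                node = parent[node]

    def __len__(self):
        return len(self.df)

    def generations(self) -> dict:
        """Generation number per track (roots are generation 0)."""
        parent = dict(zip(self.df["child_track_id"], self.df["parent_track_id"]))
        gen: dict = {}

        def depth(node):
            if node not in parent:
                return 0
            if node not in gen:
                gen[node] = depth(parent[node]) + 1
            return gen[node]

        for c in parent:
            depth(c)
        return gen


def _track_entry(obs: pd.DataFrame, track: int, frame: int):
    sel = obs[(obs["track_id"] == track) & (obs["frame"] == frame)]
    return None if sel.empty else sel.iloc[0]


def candidate_division_events(tracks: TrackSet, spec: FeatureSpec,
                              config: DivisionConfig | None = None) -> list:
    """Enumerate plausible (new track, mother track, frame) triples.

    For every track starting at frame t past the start of the movie, mothers
    are tracks observed at both t-1 and t whose length drops by at least
    ``length_drop`` between those frames, with centroids within
    ``radius_factor`` times the mother's length of the new track's first
    centroid.
    """
    config = config or DivisionConfig()
    obs = tracks.df[~tracks.df["interpolated"]]
    if obs.empty:
        return []
    first_frame = int(obs["frame"].min())
    starts = obs.loc[obs.groupby("track_id")["frame"].idxmin()]
    li = "length"
    out = []
    for child in starts.itertuples(index=False):
        t = int(child.frame)
        if t <= first_frame:
            continue
        prev = obs[obs["frame"] == t - 1]
        curr = obs[obs["frame"] == t]
        for mother in prev.itertuples(index=False):
            if mother.track_id == child.track_id:
                continue
            now = _track_entry(curr, mother.track_id, t)
            if now is None:
                continue
            m_len = getattr(mother, li)
            if getattr(now, li) > (1 - config.length_drop) * m_len:
                continue
            dpos = np.array([child.x - mother.x, child.y - mother.y])
            if spec.periodic:
                for ax in range(2):
                    dpos[ax] = wrap_half_open(dpos[ax], spec.domain_size[ax])
            offset = float(np.hypot(*dpos))
            if offset > config.radius_factor * m_len:
                continue
            disp = _division_displacement(child, mother, dpos, config)
            out.append(DivisionCandidate(int(child.track_id), int(mother.track_id),
                                         t, disp, offset))
    out.sort(key=lambda c: (c.frame, c.child_track, c.mother_track))
    return out


def _division_displacement(child, mother, dpos, config: DivisionConfig) -> np.ndarray:
    parts = []
    for name in config.features:
        if name == "x":
            parts.append(dpos[0])
        elif name == "y":
            parts.append(dpos[1])
        elif name == "length":
            parts.append(getattr(child, name) - getattr(mother, name) / 2.0)
        else:
            parts.append(getattr(child, name) - getattr(mother, name))
    return np.array(parts, dtype=float)


def _cloud_covariance(tracks: TrackSet, config: DivisionConfig) -> np.ndarray:
    """Frame-wide covariance of the raw division features over all objects."""
    obs = tracks.df[~tracks.df["interpolated"]]
    X = obs[list(config.features)].to_numpy(dtype=float)
    return regularize_covariance(np.cov(X, rowvar=False, ddof=1))


def fit_division_model(candidates, tracks: TrackSet,
                       config: DivisionConfig | None = None,
                       fallback_sigma: np.ndarray | None = None) -> DisplacementModel:
    """Fit the mother-to-daughter displacement statistics.

    Displacement statistics come from the ``F_div`` fraction of candidates
    with the smallest centroid offsets (the analogue of the training-link
    fraction); the cloud covariance comes from the frame-wide spread of the
    raw division features.  With no candidates (or too few), a configured
    diagonal prior covariance replaces the fit, with a warning.
    """
    config = config or DivisionConfig()
    n_feat = len(config.features)
    sigma_x = _cloud_covariance(tracks, config)
    disp = np.array([c.displacement for c in candidates]) if candidates else \
        np.empty((0, n_feat))
    if disp.shape[0] >= n_feat + 1:
        order = np.argsort([c.offset for c in candidates], kind="stable")
        k = math.ceil(config.F_div * len(candidates))
        sel = disp[order[:k]]
        if sel.shape[0] >= n_feat + 1:
            mu = sel.mean(axis=0)
            sigma = regularize_covariance(np.cov(sel, rowvar=False, ddof=1))
            return DisplacementModel(("division", "division"), mu, sigma,
                                     sigma_x, max(1, len(candidates)), sel.shape[0])
    if fallback_sigma is None:
        raise ValueError("too few division candidates and no fallback prior given")
    warnings.warn("too few division candidates; falling back to prior covariance")
    sigma = regularize_covariance(np.diag(np.diag(np.atleast_2d(fallback_sigma))) * 4.0)
    return DisplacementModel(("division", "division"), np.zeros(n_feat), sigma,
                             sigma_x, max(1, len(candidates)), 0)


def assign_daughters(candidates, model: DisplacementModel,
                     P_div: float = 0.05) -> LineageSet:
    """Greedy ascending-score assignment of new tracks to mothers.

    Each new track gains at most one parent and each mother at most one new
    child per frame, under the adaptive threshold computed from ``P_div``
    with the division model.  The effective object count is the mean number
    of candidate mothers per new track.
    """
    if not candidates:
        return LineageSet(pd.DataFrame(columns=LINEAGE_COLUMNS))
    n_children = len({c.child_track for c in candidates})
    n_eff = max(1, round(len(candidates) / max(1, n_children)))
    beta_model = DisplacementModel(model.frame_pair, model.mu, model.sigma_delta,
                                   model.sigma_x, n_eff, model.n_train)
    beta = adaptive_threshold(beta_model, P_div)
    disp = np.array([c.displacement for c in candidates])
    _, norms = normalize_displacement(disp, model)
    order = np.argsort(norms, kind="stable")
    used_children, used_mother_frames = set(), set()
    rows = []
    for k in order:
        if norms[k] > beta:
            break
        c = candidates[k]
        if c.child_track in used_children:
            continue
        if (c.mother_track, c.frame) in used_mother_frames:
            continue
        used_children.add(c.child_track)
        used_mother_frames.add((c.mother_track, c.frame))
        rows.append((c.child_track, c.mother_track, c.frame))
    rows.sort()
    return LineageSet(pd.DataFrame(rows, columns=LINEAGE_COLUMNS))


def detect_divisions(tracks: TrackSet, spec: FeatureSpec,
                     config: DivisionConfig | None = None,
                     fallback_sigma: np.ndarray | None = None) -> LineageSet:
    """Full division-detection pipeline on assembled tracks."""
    config = config or DivisionConfig()
    cands = candidate_division_events(tracks, spec, config)
    if not cands:
        return LineageSet(pd.DataFrame(columns=LINEAGE_COLUMNS))
    model = fit_division_model(cands, tracks, config, fallback_sigma)
    return assign_daughters(cands, model, config.P_div)
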