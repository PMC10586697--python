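"""Feature specifications and per-frame observation tables.

Objects detected in each frame are described by an N-dimensional feature
vector (centroid coordinates, orientation, length, intensity, ...).  A
:class:`FeatureSpec` records the order, kind and geometry of those features:
circular features (e.g. nematic orientation, defined modulo pi) are
differenced with wrap-around, and centroid coordinates may live on a
doubly-periodic domain, in which case displacements use the minimum-image
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LINEAR = "linear"
CIRCULAR = "circular"

#: conventional names of the centroid coordinate features
POSITION_NAMES = ("x", "y")


def wrap_half_open(d: np.ndarray, period: float) -> np.ndarray:
    """Wrap differences into the interval (-period/2, period/2]."""
    return d - period * np.ceil(d / period - 0.5)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered description of the features measured for every object.

    Parameters
    ----------
    names
        Unique feature labels, in the column order of the feature tables.
    kinds
        Per-feature flag, ``"linear"`` or ``"circular"``.
    circular_period
        Period (radians) for each circular feature; ``None`` for linear ones.
        Use pi for nematic orientations and 2*pi for polar ones.
    units
        Free-text unit labels (optional, purely descriptive).
    domain_size
        ``(width, height)`` of the spatial domain, required iff ``periodic``.
    periodic
        Whether the centroid coordinates live on a doubly periodic domain.
    """

    names: tuple
    kinds: tuple
    circular_period: tuple
    units: tuple | None = None
    domain_size: tuple | None = None
    periodic: bool = False

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "circular_period", tuple(self.circular_period))
        if self.units is not None:
            object.__setattr__(self, "units", tuple(self.units))
        if self.domain_size is not None:
            object.__setattr__(self, "domain_size", tuple(float(v) for v in self.domain_size))
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not (len(self.kinds) == len(names) and len(self.circular_period) == len(names)):
            raise ValueError("kinds and circular_period must match names in length")
        for k, p, nm in zip(self.kinds, self.circular_period, names):
            if k not in (LINEAR, CIRCULAR):
                raise ValueError(f"unknown feature kind {k!r} for {nm!r}")
            if k == CIRCULAR and not (p is not None and p > 0):
                raise ValueError(f"circular feature {nm!r} needs a period > 0")
        if self.periodic != (self.domain_size is not None):
            raise ValueError("domain_size must be given iff periodic is set")

    # -- basic introspection -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def position_indices(self) -> tuple:
        """Indices of the centroid coordinate features present in the spec."""
        return tuple(self.names.index(n) for n in POSITION_NAMES if n in self.names)

    def subset(self, names) -> "FeatureSpec":
        """Restrict the spec to a subset of features (order preserved as given)."""
        idx = [self.index(n) for n in names]
        return FeatureSpec(
            names=tuple(self.names[i] for i in idx),
            kinds=tuple(self.kinds[i] for i in idx),
            circular_period=tuple(self.circular_period[i] for i in idx),
            units=None if self.units is None else tuple(self.units[i] for i in idx),
            domain_size=self.domain_size,
            periodic=self.periodic,
        )

    # -- geometry ------------------------------------------------------------
    def wrap_differences(self, d: np.ndarray) -> np.ndarray:
        """Wrap raw feature differences feature-by-feature.

        Circular features are wrapped into (-period/2, period/2]; periodic
        centroid coordinates use the minimum-image convention.  ``d`` has the
        features on its last axis; a wrapped copy is returned.
        """
        d = np.array(d, dtype=float, copy=True)
        for j, (k, p) in enumerate(zip(self.kinds, self.circular_period)):
            if k == CIRCULAR:
                d[..., j] = wrap_half_open(d[..., j], p)
        if self.periodic:
            for ax, j in enumerate(self.position_indices):
                d[..., j] = wrap_half_open(d[..., j], self.domain_size[ax])
        return d

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "names": list(self.names),
            "kinds": list(self.kinds),
            "circular_period": [None if p is None else float(p) for p in self.circular_period],
        }
        if self.units is not None:
            out["units"] = list(self.units)
        if self.periodic:
            out["domain_size"] = list(self.domain_size)
            out["periodic"] = True
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        known = {"names", "kinds", "circular_period", "units", "domain_size", "periodic"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown FeatureSpec keys: {sorted(unknown)}")
        return cls(
            names=tuple(d["names"]),
            kinds=tuple(d["kinds"]),
            circular_period=tuple(d["circular_period"]),
            units=None if d.get("units") is None else tuple(d["units"]),
            domain_size=None if d.get("domain_size") is None else tuple(d["domain_size"]),
            periodic=bool(d.get("periodic", False)),
        )


@dataclass
class FeatureTable:
    """Observations of a single frame: object ids and feature vectors."""

    frame: int
    ids: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.ids.ndim != 1 or self.X.shape[0] != self.ids.shape[0]:
            raise ValueError("ids and feature matrix row counts differ")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate object ids in frame {self.frame}")

    @property
    def n_o(self) -> int:
        """Number of objects present in the frame."""
        return len(self.ids)

    def row_of(self) -> dict:
        """Mapping object id -> row index."""
        return {int(i): j for j, i in enumerate(self.ids)}

    def subset_features(self, spec: FeatureSpec, names) -> "FeatureTable":
        idx = [spec.index(n) for n in names]
        return FeatureTable(self.frame, self.ids, self.X[:, idx])
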