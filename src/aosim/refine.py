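"""Combinatorial pattern refinement.

Mimics the data tuning performed by the glomerulus/mitral-cell stage of the
olfactory bulb: the continuous three-channel G_max response of the receptor
array is segmented into nine conductance regions, and each channel's value
is assigned to its region, producing a 9 × 3 black-and-white pattern (rows =
conductance regions from low to high, columns = channels in the fixed order
hOR51E1, hOR51E2, hOR52D1).  Each column carries exactly one active pixel,
so a pattern is a 27-bit one-hot-per-column code — the input representation
of the recognition network.

Region boundaries are equal-width over the observed response range and
shared across channels by default; explicit boundaries can be supplied to
override this.  Bins are half-open [low, high) with the final bin closed,
and values outside the range are clamped to the edge regions (logged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .synth import (
    AffinityProfile,
    ResponseRecord,
    composition_label,
    sample_responses,
)

__all__ = [
    "RegionScheme",
    "OdorPattern",
    "PatternDataset",
    "make_region_scheme",
    "refine",
    "build_datasets",
    "SINGLE_CLASSES",
    "MIXED_CLASSES",
]

logger = logging.getLogger(__name__)

N_REGIONS = 9
N_CHANNELS = 3

#: the four single-odorant classes
SINGLE_CLASSES = (
    {"PA": 1.0},
    {"BA": 1.0},
    {"VA": 1.0},
    {"HA": 1.0},
)

#: default nine mixture classes: all six equimolar two-odorant mixtures plus
#: the first three equimolar three-odorant mixtures in composition order
MIXED_CLASSES = (
    {"PA": 0.5, "BA": 0.5},
    {"PA": 0.5, "VA": 0.5},
    {"PA": 0.5, "HA": 0.5},
    {"BA": 0.5, "VA": 0.5},
    {"BA": 0.5, "HA": 0.5},
    {"VA": 0.5, "HA": 0.5},
    {"PA": 1 / 3, "BA": 1 / 3, "VA": 1 / 3},
    {"PA": 1 / 3, "BA": 1 / 3, "HA": 1 / 3},
    {"PA": 1 / 3, "VA": 1 / 3, "HA": 1 / 3},
)


@dataclass(frozen=True)
class RegionScheme:
    """Partition of a conductance range into ``n_regions`` ordered regions.

    ``boundaries`` holds the ``n_regions - 1`` interior thresholds (μS),
    strictly increasing and interior to ``range`` = (low, high).
    """

    boundaries: tuple
    range: tuple
    n_regions: int = N_REGIONS

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        lo, hi = self.range
        if len(b) != self.n_regions - 1:
            raise ValueError(
                f"n_regions={self.n_regions} requires {self.n_regions - 1} boundaries, got {len(b)}"
            )
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if not (lo < b[0] and b[-1] < hi):
            raise ValueError("boundaries must be interior to the range")

    def assign(self, gmax) -> np.ndarray:
        """Region index (0-based, 0 = lowest conductance) of each value.

        Bins are [low, b1), [b1, b2), …, [b8, high]; values outside the
        range are clamped into the edge regions with a logged warning.
        """
        g = np.atleast_1d(np.asarray(gmax, dtype=float))
        lo, hi = self.range
        if np.any((g < lo) | (g > hi)):
            logger.warning(
                "conductance outside scheme range [%g, %g]; clamping to edge regions", lo, hi
            )
        idx = np.searchsorted(np.asarray(self.boundaries), g, side="right")
        return idx if np.ndim(gmax) else int(idx[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_regions": self.n_regions,
                "boundaries_uS": list(self.boundaries),
                "range_uS": list(self.range),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegionScheme":
        d = json.loads(text)
        return cls(
            boundaries=tuple(d["boundaries_uS"]),
            range=tuple(d["range_uS"]),
            n_regions=int(d["n_regions"]),
        )


def make_region_scheme(responses, n_regions: int = N_REGIONS, margin_frac: float = 0.0) -> RegionScheme:
    """Equal-width region boundaries spanning the observed response range.

    The range is [min − ε, max + ε] with ε = ``margin_frac`` × span, shared
    across channels.  All input values are guaranteed to map into exactly
    one region.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    g = np.array([r.gmax for r in responses], dtype=float)
    if g.size == 0:
        raise ValueError("responses must be non-empty")
    lo, hi = float(g.min()), float(g.max())
    if hi <= lo:
        raise ValueError("degenerate response range: all gmax values equal")
    eps = margin_frac * (hi - lo)
    lo, hi = lo - eps, hi + eps
    edges = np.linspace(lo, hi, n_regions + 1)
    return RegionScheme(boundaries=tuple(edges[1:-1].tolist()), range=(lo, hi), n_regions=n_regions)


@dataclass(frozen=True)
class OdorPattern:
    """A 9 × 3 binary combinatorial odor pattern with its class label.

    ``grid[r, c] = 1`` iff channel ``c`` fell in conductance region ``r``
    (row 0 = lowest region); every column sums to exactly 1.  Flattened
    row-major, the grid is the 27-wide network input.
    """

    grid: np.ndarray
    label: str

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=int)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2 or g.shape[1] != N_CHANNELS:
            raise ValueError(f"grid must be n_regions x {N_CHANNELS}")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("grid entries must be 0/1")
        if not np.all(g.sum(axis=0) == 1):
            raise ValueError("each column must contain exactly one active region")

    def flatten(self) -> np.ndarray:
        """Row-major 0/1 vector of length n_regions × 3."""
        return self.grid.reshape(-1)

    @classmethod
    def from_flat(cls, flat, label: str, n_regions: int = N_REGIONS) -> "OdorPattern":
        return cls(grid=np.asarray(flat, dtype=int).reshape(n_regions, N_CHANNELS), label=label)

    def to_art(self) -> str:
        """Plain-text art: one line per region, '1'/'0' per channel."""
        return "\n".join("".join(str(v) for v in row) for row in self.grid)

    def to_record(self) -> dict:
        return {"label": self.label, "grid": self.flatten().tolist()}

    @classmethod
    def from_record(cls, d: dict) -> "OdorPattern":
        flat = np.asarray(d["grid"], dtype=int)
        return cls.from_flat(flat, d["label"], n_regions=len(flat) // N_CHANNELS)


def refine(records, scheme: RegionScheme) -> OdorPattern:
    """Map one channel-triple of responses onto a binary odor pattern.

    ``records`` must hold exactly one :class:`ResponseRecord` per channel
    of the fixed channel order; the pattern's label is the composition's
    canonical class label.
    """
    from .synth import CHANNELS

    by_channel = {r.channel: r for r in records}
    if len(records) != len(CHANNELS) or set(by_channel) != set(CHANNELS):
        raise ValueError(f"need exactly one record per channel {CHANNELS}")
    labels = {composition_label(r.composition) for r in records}
    if len(labels) > 1:
        raise ValueError(f"records mix compositions: {sorted(labels)}")
    grid = np.zeros((scheme.n_regions, N_CHANNELS), dtype=int)
    for c, ch in enumerate(CHANNELS):
        region = scheme.assign(by_channel[ch].gmax)
        grid[region, c] = 1
    return OdorPattern(grid=grid, label=labels.pop())


@dataclass
class PatternDataset:
    """A labelled collection of odor patterns with a train/inference tag."""

    patterns: list
    class_names: tuple
    split: str

    def __post_init__(self) -> None:
        if self.split not in ("train", "inference"):
            raise ValueError("split must be 'train' or 'inference'")
        names = set(self.class_names)
        seen = {p.label for p in self.patterns}
        if not seen <= names:
            raise ValueError(f"labels outside class list: {sorted(seen - names)}")
        if seen != names:
            raise ValueError(f"classes with no patterns: {sorted(names - seen)}")

    def __len__(self) -> int:
        return len(self.patterns)

    def inputs(self) -> np.ndarray:
        """Pattern matrix, one flattened pattern per row."""
        return np.stack([p.flatten() for p in self.patterns]).astype(float)

    def targets(self) -> np.ndarray:
        """Class index per pattern (position in ``class_names``)."""
        idx = {name: i for i, name in enumerate(self.class_names)}
        return np.array([idx[p.label] for p in self.patterns], dtype=int)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                json.dumps({"class_names": list(self.class_names), "split": self.split}) + "\n"
            )
            for p in self.patterns:
                fh.write(json.dumps(p.to_record()) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "PatternDataset":
        with open(path) as fh:
            header = json.loads(fh.readline())
            patterns = [OdorPattern.from_record(json.loads(line)) for line in fh if line.strip()]
        return cls(
            patterns=patterns,
            class_names=tuple(header["class_names"]),
            split=header["split"],
        )


def _per_class_counts(total: int, n_classes: int) -> list:
    """Split ``total`` into per-class counts differing by at most one."""
    base, extra = divmod(total, n_classes)
    return [base + (1 if i < extra else 0) for i in range(n_classes)]


def build_datasets(
    profile: AffinityProfile,
    class_specs,
    n_train: int,
    n_infer: int,
    total_concentration: float = 3.0,
    seed: int | None = 0,
    scheme: RegionScheme | None = None,
):
    """Generate matched train/inference pattern datasets.

    For each class composition, replicate responses are sampled (seeded,
    train and inference from independent substreams), the region scheme is
    fitted on the pooled training responses (unless one is supplied), and
    every channel triple is refined into a 9 × 3 pattern.  Total pattern
    counts match the requested sizes with per-class counts differing by at
    most one.

    Returns ``(scheme, train_dataset, inference_dataset)``.
    """
    class_specs = list(class_specs)
    if not class_specs:
        raise ValueError("need at least one class")
    names = tuple(composition_label(c) for c in class_specs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate class compositions")
    root = np.random.SeedSequence(seed)
    train_ss, infer_ss = root.spawn(2)

    def sample_split(counts, seedseq, prefix):
        groups = []
        for comp, n, child in zip(class_specs, counts, seedseq.spawn(len(class_specs))):
            recs = sample_responses(
                profile,
                comp,
                total_concentration=total_concentration,
                n_replicates=n,
                seed=child,
                sample_prefix=prefix,
            )
            groups.append(recs)
        return groups

    train_groups = sample_split(_per_class_counts(n_train, len(names)), train_ss, "tr")
    infer_groups = sample_split(_per_class_counts(n_infer, len(names)), infer_ss, "inf")

    if scheme is None:
        pooled = [r for g in train_groups for r in g]
        scheme = make_region_scheme(pooled)

    def to_patterns(groups, split):
        pats = []
        for recs in groups:
            for i in range(0, len(recs), N_CHANNELS):
                pats.append(refine(recs[i : i + N_CHANNELS], scheme))
        return PatternDataset(patterns=pats, class_names=names, split=split)

    return scheme, to_patterns(train_groups, "train"), to_patterns(infer_groups, "inference")
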