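"""Linkage counting, cluster sizing and damage-type classification.

The cluster analysis has three steps:

1. *Linkages*: every unordered pair of events separated by at most the
   linkage distance L_c counts as one linkage; their total is
   N_link(L_c) and each pair defines a candidate complex-damage *site*
   centred at the pair midpoint.
2. *Cluster size*: N_cl of a site is the number of events (including
   the linked pair itself) within L_c of the site centre.
3. *Classification*: N_cl is binned into damage-type classes.  The
   BD scheme spans simple DSB (or 2BD) through DSB/BD/BD (4BD) in bins
   of width 9 — the mean number of events needed to add one base
   damage to a site; the SB scheme spans simple DSB through DSB++
   in bins of width 12 = round(9 × 1.3) — the events needed to add one
   strand break, deduced from the BD spacing and the BD/SSB yield
   ratio of 1.3.

Distance comparisons are closed (≤ L_c) everywhere.  The KD-tree
search is exact and contractually equal to a brute-force all-pairs
scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .events import EventSet

__all__ = [
    "AnalysisParams",
    "Site",
    "LinkageResult",
    "Bin",
    "ClassificationScheme",
    "ClassFractions",
    "BD_SCHEME",
    "SB_SCHEME",
    "BP_TO_NM",
    "BD_SSB_RATIO",
    "EVENTS_PER_EXTRA_BD",
    "MEAN_NCL_SIMPLE_DSB",
    "events_per_extra_strand_break",
    "count_linkages",
    "compute_ncl",
    "classify_site",
    "class_fractions",
]

#: base-pair to nm conversion: 10 bp = 3.4 nm
BP_TO_NM = 0.34

#: assumed induction-yield ratio of base damage to single-strand breaks
BD_SSB_RATIO = 1.3

#: mean cluster size of a simple DSB (or 2BD) site
MEAN_NCL_SIMPLE_DSB = 6

#: mean number of events needed to induce one additional BD at a site
EVENTS_PER_EXTRA_BD = 9


def events_per_extra_strand_break(
    events_per_extra_bd: int = EVENTS_PER_EXTRA_BD,
    bd_ssb_ratio: float = BD_SSB_RATIO,
) -> int:
    """Mean events needed for one additional strand break at a DSB site.

    A strand break is ``bd_ssb_ratio`` times harder to induce than a
    base damage, so the per-lesion event cost scales accordingly:
    round(9 × 1.3) = 12.
    """
    return round(events_per_extra_bd * bd_ssb_ratio)


@dataclass(frozen=True)
class AnalysisParams:
    """Linkage-sampling parameters.

    ``lc_bp`` is the maximum inter-lesion distance in base pairs (10 bp
    for the standard DSB/cBD definition; 5 bp and 3 bp are used for
    detection-loss and sensitivity analyses).  ``bp_to_nm`` converts it
    to the geometric search radius ``lc_nm``.
    """

    lc_bp: float = 10.0
    bp_to_nm: float = BP_TO_NM

    def __post_init__(self) -> None:
        if not self.lc_bp > 0:
            raise ValueError("lc_bp must be > 0")
        if not self.bp_to_nm > 0:
            raise ValueError("bp_to_nm must be > 0")

    @property
    def lc_nm(self) -> float:
        return self.lc_bp * self.bp_to_nm


@dataclass(frozen=True)
class Site:
    """A candidate complex-damage locus: a linked event pair.

    ``n_cl`` counts all events within ``lc_nm`` of the pair midpoint,
    the linked pair included, hence ``n_cl >= 2``.
    """

    event_indices: tuple[int, int]
    center: np.ndarray
    n_cl: int


@dataclass(frozen=True)
class LinkageResult:
    """All linkages of an event set at one L_c.

    Column-oriented: ``pairs`` is an (m, 2) index array, ``centers`` the
    (m, 3) midpoints in nm and ``n_cl`` the per-site cluster sizes.
    """

    pairs: np.ndarray
    centers: np.ndarray
    n_cl: np.ndarray
    lc_bp: float
    lc_nm: float
    pairing: str = "all_pairs"

    @property
    def n_link(self) -> int:
        return len(self.pairs)

    @property
    def sites(self) -> list[Site]:
        return [
            Site((int(i), int(j)), self.centers[k].copy(), int(self.n_cl[k]))
            for k, (i, j) in enumerate(self.pairs)
        ]


@dataclass(frozen=True)
class Bin:
    """Half-open integer cluster-size bin [lower, upper) with its labels.

    ``label`` names the strand-break stream class (DSB, DSB/BD, ... or
    DSB, DSB+, DSB++); ``bd_label`` the base-damage stream class
    (BD/BD, BD/BD/BD, ...) where the scheme defines one.
    """

    lower: int
    upper: int
    label: str
    bd_label: str | None = None

    def __contains__(self, n_cl: int) -> bool:
        return self.lower <= n_cl < self.upper


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered, contiguous cluster-size bins mapping N_cl to a damage type."""

    name: str
    bins: tuple[Bin, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.bins, self.bins[1:]):
            if a.upper != b.lower:
                raise ValueError(f"bins of scheme {self.name} are not contiguous")

    @property
    def lower_edge(self) -> int:
        return self.bins[0].lower

    @property
    def top_edge(self) -> int:
        return self.bins[-1].upper

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bins)

    @property
    def bd_labels(self) -> tuple[str, ...]:
        return tuple(b.bd_label for b in self.bins if b.bd_label is not None)


def _make_scheme(name: str, width: int, labels: Sequence[str],
                 bd_labels: Sequence[str | None]) -> ClassificationScheme:
    bins = []
    lo = 2
    for label, bd_label in zip(labels, bd_labels):
        bins.append(Bin(lo, lo + width, label, bd_label))
        lo += width
    return ClassificationScheme(name, tuple(bins))


#: DSB ± base damage (and pure-BD cluster) scheme: bins of width 9
BD_SCHEME = _make_scheme(
    "BD_SCHEME",
    EVENTS_PER_EXTRA_BD,
    ("DSB", "DSB/BD", "DSB/BD/BD"),
    ("BD/BD", "BD/BD/BD", "BD/BD/BD/BD"),
)

#: DSB ± strand break scheme: bins of width 12 = round(9 × 1.3)
SB_SCHEME = _make_scheme(
    "SB_SCHEME",
    events_per_extra_strand_break(),
    ("DSB", "DSB+", "DSB++"),
    (None, None, None),
)


@dataclass(frozen=True)
class ClassFractions:
    """Per-class site fractions f(N_cl) under one scheme.

    ``fractions`` covers the scheme's in-range bins; sites with N_cl at
    or above the top bin edge are reported in ``overflow_fraction`` so
    that the total is exactly 1 whenever sites exist.  ``counts`` holds
    the raw per-bin site counts (overflow under ``"overflow"``).
    """

    scheme: str
    n_sites: int
    fractions: Mapping[str, float]
    overflow_fraction: float
    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_sites == 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def count_linkages(
    es: EventSet,
    params: AnalysisParams | None = None,
    pairing: str = "all_pairs",
) -> LinkageResult:
    """Count linkages: event pairs separated by at most ``lc_nm``.

    By default every unordered in-range pair is one linkage (events may
    belong to several linkages); ``pairing="unique"`` instead greedily
    matches each event into at most one pair, shortest distances first,
    for sensitivity analysis.  Each linkage becomes a site centred at
    the pair midpoint with its cluster size N_cl attached.

    The result is independent of event ordering and of rigid-body
    transforms of the coordinates.
    """
    if params is None:
        params = AnalysisParams()
    if pairing not in ("all_pairs", "unique"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    lc = params.lc_nm
    if es.n_event < 2:
        empty = np.empty((0, 2), dtype=np.intp)
        return LinkageResult(empty, np.empty((0, 3)), np.empty(0, dtype=np.intp),
                             params.lc_bp, lc, pairing)
    tree = cKDTree(es.coords)
    pairs = tree.query_pairs(r=lc, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
    if pairing == "unique" and len(pairs):
        d = np.linalg.norm(es.coords[pairs[:, 0]] - es.coords[pairs[:, 1]], axis=1)
        keep = []
        used: set[int] = set()
        for k in np.argsort(d, kind="stable"):
            i, j = int(pairs[k, 0]), int(pairs[k, 1])
            if i not in used and j not in used:
                used.update((i, j))
                keep.append(k)
        pairs = pairs[sorted(keep)]
    centers = 0.5 * (es.coords[pairs[:, 0]] + es.coords[pairs[:, 1]])
    if len(centers):
        neighborhoods = tree.query_ball_point(centers, r=lc)
        n_cl = np.fromiter((len(nb) for nb in neighborhoods), dtype=np.intp,
                           count=len(neighborhoods))
    else:
        n_cl = np.empty(0, dtype=np.intp)
    return LinkageResult(pairs, centers, n_cl, params.lc_bp, lc, pairing)


def compute_ncl(site: Site, es: EventSet, params: AnalysisParams | None = None) -> int:
    """Cluster size of a site: events within ``lc_nm`` of its centre.

    The linked pair itself lies within ``lc_nm/2`` of the midpoint, so
    the count is always at least 2.  The boundary is closed: an event at
    exactly ``lc_nm`` from the centre is counted.
    """
    if params is None:
        params = AnalysisParams()
    d = np.linalg.norm(es.coords - np.asarray(site.center, dtype=float), axis=1)
    return int(np.count_nonzero(d <= params.lc_nm))


def classify_site(n_cl: int, scheme: ClassificationScheme = BD_SCHEME,
                  stream: str = "sb") -> str:
    """Damage-type label of a cluster of size ``n_cl`` under a scheme.

    ``stream="sb"`` returns the strand-break family label (DSB, DSB/BD,
    ...); ``stream="bd"`` the base-damage family label (BD/BD, ...)
    where the scheme defines one.  Cluster sizes at or above the top
    bin edge are clamped to the most complex label (they are tallied as
    overflow by :func:`class_fractions`).
    """
    if n_cl < scheme.lower_edge:
        raise ValueError(
            f"n_cl = {n_cl} is below {scheme.lower_edge}: not a complex-damage site"
        )
    if stream not in ("sb", "bd"):
        raise ValueError(f"unknown stream {stream!r}")
    for b in scheme.bins:
        if n_cl in b:
            chosen = b
            break
    else:
        chosen = scheme.bins[-1]  # overflow clamp
    if stream == "bd":
        if chosen.bd_label is None:
            raise ValueError(f"scheme {scheme.name} has no base-damage stream")
        return chosen.bd_label
    return chosen.label


def class_fractions(lr: LinkageResult,
                    scheme: ClassificationScheme = BD_SCHEME) -> ClassFractions:
    """Per-class fractions f(N_cl) of the sites of a linkage result.

    Normalization is per site: each linkage contributes once.  With no
    sites, all fractions are zero and ``empty`` is set.
    """
    n = lr.n_link
    if n == 0:
        return ClassFractions(
            scheme.name, 0,
            {b.label: 0.0 for b in scheme.bins}, 0.0,
            {**{b.label: 0 for b in scheme.bins}, "overflow": 0},
        )
    ncl = lr.n_cl
    counts = {b.label: int(np.count_nonzero((ncl >= b.lower) & (ncl < b.upper)))
              for b in scheme.bins}
    overflow = int(np.count_nonzero(ncl >= scheme.top_edge))
    counts["overflow"] = overflow
    fractions = {label: c / n for label, c in counts.items() if label != "overflow"}
    return ClassFractions(scheme.name, n, fractions, overflow / n, counts)
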