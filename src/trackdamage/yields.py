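"""DNA-damage yield model.

Yields in Gy⁻¹Da⁻¹ follow from two track statistics — the event count
N_event and the linkage count N_link(L_c) — normalized by the deposited
energy E_dep (keV):

    Y_SSB = k_SSB · N_event / E_dep         Y_DSB = k_DSB · N_link(10) / E_dep
    Y_BD  = k_BD  · N_event / E_dep         Y_cBD = k_cBD · N_link(L_c) / E_dep

The strand-break coefficients k_SSB = 5.66×10⁻¹² and
k_DSB = 1.61×10⁻¹³ keV·Gy⁻¹·Da⁻¹ were calibrated against experimental
220 kVp X-ray yields; the base-damage coefficients derive from the
assumed BD/SSB induction ratio of 1.3: k_BD = 1.3·k_SSB and
k_cBD = 1.3²·k_DSB (two independent base damages per cBD site).

Complex yields are split over damage-type classes with the cluster
fractions f(N_cl), and two experimental-detection corrections are
modelled: a per-lesion labelling efficiency η (Y_BD·η, Y_cBD·η², and
generally η per base damage in a class), and the probe-size detection
loss Y*_cBD = Y_cBD(10 bp) − Y_cBD(5 bp) for aldehyde-reactive-probe
imaging, where two base damages closer than 5 bp cannot be resolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

from .cluster import BD_SSB_RATIO, ClassFractions, LinkageResult
from .events import EventSet

__all__ = [
    "Coefficients",
    "DetectionModel",
    "YieldReport",
    "UndefinedYieldError",
    "yield_ssb",
    "yield_dsb",
    "yield_bd",
    "yield_cbd",
    "split_by_class",
    "bd_multiplicity",
    "apply_detection",
    "detection_loss",
]

K_SSB_DEFAULT = 5.66e-12  # keV Gy^-1 Da^-1
K_DSB_DEFAULT = 1.61e-13  # keV Gy^-1 Da^-1


class UndefinedYieldError(ZeroDivisionError):
    """Yield undefined because the event set deposited no energy."""


@dataclass(frozen=True)
class Coefficients:
    """Yield coefficients in keV·Gy⁻¹·Da⁻¹.

    ``k_bd`` and ``k_cbd`` default to the ratio-derived values
    ``k_ssb × 1.3`` and ``k_dsb × 1.3²`` and are stored at full
    precision (7.358e−12 and 2.7209e−13, i.e. 7.36e−12 and 2.72e−13 to
    three significant figures).
    """

    k_ssb: float = K_SSB_DEFAULT
    k_dsb: float = K_DSB_DEFAULT
    k_bd: float | None = None
    k_cbd: float | None = None

    def __post_init__(self) -> None:
        if self.k_bd is None:
            object.__setattr__(self, "k_bd", self.k_ssb * BD_SSB_RATIO)
        if self.k_cbd is None:
            object.__setattr__(self, "k_cbd", self.k_dsb * BD_SSB_RATIO**2)
        for name in ("k_ssb", "k_dsb", "k_bd", "k_cbd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DetectionModel:
    """Experimental detection corrections.

    ``eta`` is the per-base-damage labelling efficiency; a class
    containing k base damages is detected with probability η^k.
    ``mode="per_lesion"`` applies that generalization to every class;
    ``mode="parent_only"`` applies strictly Y_BD·η and Y_cBD·η² and
    leaves class yields untouched.  ``arp_loss`` enables the
    probe-size detection loss Y*_cBD = Y_cBD(10 bp) − Y_cBD(5 bp).
    """

    eta: float = 1.0
    arp_loss: bool = False
    mode: str = "per_lesion"

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta!r}")
        if self.mode not in ("per_lesion", "parent_only"):
            raise ValueError(f"unknown detection mode {self.mode!r}")


@dataclass(frozen=True)
class YieldReport:
    """Structured result of a full analysis run.

    ``yields`` holds the parent yields (``y_ssb``, ``y_dsb``, ``y_bd``,
    ``y_cbd`` and, with the probe-loss correction on, ``y_cbd_star``)
    and per-class splits; ``fractions`` the f(N_cl) tables;
    ``ratios`` the derived yield ratios; ``detection`` the corrected
    yields when a detection model was applied.  ``empty`` flags a run
    on an event set with no events.
    """

    params: Mapping[str, Any]
    counts: Mapping[str, Any]
    yields: Mapping[str, Any]
    fractions: Mapping[str, Any] = field(default_factory=dict)
    ratios: Mapping[str, Any] = field(default_factory=dict)
    detection: Mapping[str, Any] | None = None
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "params": _plain(self.params),
            "counts": _plain(self.counts),
            "yields": _plain(self.yields),
            "fractions": _plain(self.fractions),
            "ratios": _plain(self.ratios),
            "detection": _plain(self.detection) if self.detection is not None else None,
            "empty": self.empty,
        }

    def to_json(self) -> str:
        """Canonical JSON: sorted keys, no timestamps, diffable."""
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _plain(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# yield equations
# ---------------------------------------------------------------------------

def _per_energy(count: int, es: EventSet, k: float, what: str) -> float:
    if count == 0:
        return 0.0
    if es.e_dep_keV <= 0.0:
        raise UndefinedYieldError(f"{what}: E_dep is zero, yield undefined")
    return k * count / es.e_dep_keV


def yield_ssb(es: EventSet, c: Coefficients | None = None) -> float:
    """Single-strand-break yield k_SSB · N_event / E_dep (Gy⁻¹Da⁻¹)."""
    c = c or Coefficients()
    return _per_energy(es.n_event, es, c.k_ssb, "yield_ssb")


def yield_bd(es: EventSet, c: Coefficients | None = None) -> float:
    """Isolated base-damage yield k_BD · N_event / E_dep (Gy⁻¹Da⁻¹)."""
    c = c or Coefficients()
    return _per_energy(es.n_event, es, c.k_bd, "yield_bd")


def yield_dsb(lr: LinkageResult, es: EventSet, c: Coefficients | None = None) -> float:
    """Double-strand-break yield k_DSB · N_link(10 bp) / E_dep (Gy⁻¹Da⁻¹).

    The DSB definition fixes the linkage distance at 10 bp; a linkage
    result sampled at any other L_c is rejected.
    """
    if lr.lc_bp != 10.0:
        raise ValueError(
            f"DSB yield is defined at L_c = 10 bp; got a linkage result at {lr.lc_bp} bp"
        )
    c = c or Coefficients()
    return _per_energy(lr.n_link, es, c.k_dsb, "yield_dsb")


def yield_cbd(lr: LinkageResult, es: EventSet, c: Coefficients | None = None) -> float:
    """Complex base-damage yield k_cBD · N_link(L_c) / E_dep (Gy⁻¹Da⁻¹).

    Unlike the DSB case, the cBD linkage distance is a free parameter
    (the experimental detection technique sets it); the result carries
    whatever L_c the linkage result was sampled at.
    """
    c = c or Coefficients()
    return _per_energy(lr.n_link, es, c.k_cbd, "yield_cbd")


def split_by_class(parent_yield: float, cf: ClassFractions,
                   stream: str = "sb") -> dict[str, float]:
    """Split a parent yield over damage classes by their fractions.

    Overflow sites (N_cl at or above the top bin edge) are folded into
    the most complex class so the split always sums to the parent.
    ``stream="bd"`` relabels the bins with the base-damage family names
    (BD/BD, BD/BD/BD, ...) for splitting Y_cBD.
    """
    from .cluster import BD_SCHEME, SB_SCHEME  # label lookup only

    scheme = {BD_SCHEME.name: BD_SCHEME, SB_SCHEME.name: SB_SCHEME}[cf.scheme]
    if stream == "bd":
        labels = scheme.bd_labels
        if len(labels) != len(scheme.bins):
            raise ValueError(f"scheme {cf.scheme} has no base-damage stream")
    elif stream == "sb":
        labels = scheme.labels
    else:
        raise ValueError(f"unknown stream {stream!r}")
    out = {
        label: parent_yield * cf.fractions[b.label]
        for label, b in zip(labels, scheme.bins)
    }
    out[labels[-1]] += parent_yield * cf.overflow_fraction
    return out


# ---------------------------------------------------------------------------
# detection corrections
# ---------------------------------------------------------------------------

def bd_multiplicity(label: str) -> int:
    """Number of base-damage lesions in a damage-class label.

    Counts the ``BD`` tokens: DSB → 0, DSB/BD → 1, BD/BD/BD → 3.
    Strand-break-only labels (DSB+, DSB++) carry no base damage.
    """
    return sum(1 for tok in label.split("/") if tok == "BD")


def apply_detection(r: YieldReport, d: DetectionModel) -> YieldReport:
    """Attach detection-corrected yields to a report.

    Base-damage yields are thinned by the labelling efficiency:
    Y_BD·η, Y_cBD·η² and, in per-lesion mode, every class yield by η^k
    with k its base-damage multiplicity.  Strand-break yields are not
    affected.  With η = 1 the corrected yields equal the uncorrected
    ones on every field.
    """
    if not isinstance(d, DetectionModel):
        d = DetectionModel(**d) if isinstance(d, Mapping) else DetectionModel(d)
    eta = d.eta
    corrected: dict[str, Any] = {}
    for key, val in r.yields.items():
        if isinstance(val, Mapping):
            if d.mode == "per_lesion":
                corrected[key] = {
                    label: y * eta ** bd_multiplicity(label) for label, y in val.items()
                }
            else:
                corrected[key] = dict(val)
        elif key in ("y_bd",):
            corrected[key] = val * eta
        elif key in ("y_cbd", "y_cbd_star"):
            corrected[key] = val * eta**2
        else:
            corrected[key] = val
    return replace(
        r,
        detection={"eta": eta, "arp_loss": d.arp_loss, "mode": d.mode,
                   "corrected": corrected},
    )


def detection_loss(y_cbd_10: float, y_cbd_5: float) -> float:
    """Probe-size detection loss Y*_cBD = Y_cBD(10 bp) − Y_cBD(5 bp).

    Complex base damage whose two lesions sit within 5 bp is hidden
    under a single ~10 bp-diameter probe; what remains detectable is
    the difference of the 10 bp and 5 bp yields.  Both yields must come
    from the same event set; since linkages only grow with L_c,
    ``y_cbd_5 > y_cbd_10`` is impossible on one event set and is
    rejected as a provenance mismatch.
    """
    for name, y in (("y_cbd_10", y_cbd_10), ("y_cbd_5", y_cbd_5)):
        if y < 0:
            raise ValueError(f"{name} must be >= 0")
    if y_cbd_5 > y_cbd_10 * (1.0 + 1e-12):
        raise ValueError(
            "y_cbd_5 exceeds y_cbd_10: the two yields cannot come from the "
            "same event set (linkage count is monotone in L_c)"
        )
    return max(y_cbd_10 - y_cbd_5, 0.0)
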