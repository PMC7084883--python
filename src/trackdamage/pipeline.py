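"""End-to-end analysis pipeline and report generation.

``run_analysis`` orchestrates the whole method on one event set —
read (or synthesize) events, count linkages at each requested L_c,
size and classify the clusters, evaluate the yield equations, split
the complex yields over damage classes, derive the summary ratios and
apply the detection corrections — and returns a :class:`YieldReport`.
The report is deterministic given the input file (or the generator
seed) and serializes to canonical, diffable JSON.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cluster import (
    BD_SCHEME,
    SB_SCHEME,
    AnalysisParams,
    ClassFractions,
    class_fractions,
    count_linkages,
)
from .events import EventSet, read_events
from .synth import TrackParams, generate_track
from .yields import (
    Coefficients,
    DetectionModel,
    YieldReport,
    apply_detection,
    detection_loss,
    split_by_class,
    yield_bd,
    yield_cbd,
    yield_dsb,
    yield_ssb,
)

__all__ = ["RunConfig", "run_analysis", "cdsb_ratio", "fraction_table"]

#: the linkage distance defining DSBs and used for the classification pass
PRIMARY_LC_BP = 10.0
#: the probe-resolution distance of the ARP detection-loss correction
ARP_LC_BP = 5.0


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_path`` (an event-table TSV) and ``track``
    (synthetic-track parameters) must be given.  ``lc_bp`` lists the
    linkage distances to sample; 10 bp is always included, and 5 bp is
    added automatically when the ARP detection loss is enabled.
    """

    input_path: str | os.PathLike | None = None
    track: TrackParams | None = None
    lc_bp: tuple[float, ...] = (PRIMARY_LC_BP,)
    bp_to_nm: float = 0.34
    pairing: str = "all_pairs"
    coefficients: Coefficients = field(default_factory=Coefficients)
    detection: DetectionModel = field(default_factory=DetectionModel)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.track is None):
            raise ValueError("exactly one of input_path and track must be given")
        lcs = list(dict.fromkeys(float(lc) for lc in self.lc_bp))
        if PRIMARY_LC_BP not in lcs:
            lcs.insert(0, PRIMARY_LC_BP)
        if self.detection.arp_loss and ARP_LC_BP not in lcs:
            lcs.append(ARP_LC_BP)
        object.__setattr__(self, "lc_bp", tuple(sorted(lcs, reverse=True)))


def cdsb_ratio(fractions: Mapping[str, float]) -> float:
    """Complex-DSB share: 100 × (DSB+ + DSB++) / (DSB + DSB+ + DSB++).

    ``fractions`` maps the strand-break classes to fractions,
    percentages or yields (any common scale cancels).  A zero
    denominator — no DSBs of any complexity — leaves the ratio
    undefined.
    """
    try:
        simple, plus, plusplus = (
            fractions["DSB"], fractions["DSB+"], fractions["DSB++"]
        )
    except KeyError as exc:
        raise KeyError(f"fractions table is missing class {exc}") from None
    total = simple + plus + plusplus
    if total == 0:
        raise ZeroDivisionError("no DSB yield in any complexity class: cDSB/DSB undefined")
    return 100.0 * (plus + plusplus) / total


def _load_events(cfg: RunConfig) -> EventSet:
    if cfg.input_path is not None:
        return read_events(cfg.input_path)
    return generate_track(cfg.track)


def run_analysis(cfg: RunConfig) -> YieldReport:
    """Run the full pipeline described in the module docstring."""
    try:
        es = _load_events(cfg)
    except Exception as exc:
        raise type(exc)(f"[load events] {exc}") from exc

    c = cfg.coefficients
    d = cfg.detection

    params_block: dict = {
        "lc_bp": list(cfg.lc_bp),
        "bp_to_nm": cfg.bp_to_nm,
        "pairing": cfg.pairing,
        "coefficients": {"k_ssb": c.k_ssb, "k_dsb": c.k_dsb,
                         "k_bd": c.k_bd, "k_cbd": c.k_cbd},
    }
    if cfg.track is not None:
        params_block["track"] = {
            "n_events": cfg.track.n_events,
            "mean_free_path_nm": cfg.track.mean_free_path_nm,
            "edep_mean_eV": cfg.track.edep_mean_eV,
            "edep_sd_eV": cfg.track.edep_sd_eV,
            "p_ionization": cfg.track.p_ionization,
            "seed": cfg.track.seed,
        }
    else:
        params_block["input_path"] = str(cfg.input_path)

    try:
        linkages = {
            lc: count_linkages(es, AnalysisParams(lc, cfg.bp_to_nm), cfg.pairing)
            for lc in cfg.lc_bp
        }
    except Exception as exc:
        raise type(exc)(f"[count linkages] {exc}") from exc

    lr10 = linkages[PRIMARY_LC_BP]
    counts = {
        "n_event": es.n_event,
        "e_dep_keV": es.e_dep_keV,
        "n_link": {f"{lc:g}bp": linkages[lc].n_link for lc in cfg.lc_bp},
    }

    if es.n_event == 0:
        zeros = {"y_ssb": 0.0, "y_dsb": 0.0, "y_bd": 0.0, "y_cbd": 0.0}
        report = YieldReport(params_block, counts, zeros, {}, {}, empty=True)
        return apply_detection(report, d)

    try:
        cf_bd = class_fractions(lr10, BD_SCHEME)
        cf_sb = class_fractions(lr10, SB_SCHEME)
    except Exception as exc:
        raise type(exc)(f"[classify clusters] {exc}") from exc

    try:
        y_ssb = yield_ssb(es, c)
        y_dsb = yield_dsb(lr10, es, c)
        y_bd = yield_bd(es, c)
        y_cbd = yield_cbd(lr10, es, c)
        yields: dict = {
            "y_ssb": y_ssb,
            "y_dsb": y_dsb,
            "y_bd": y_bd,
            "y_cbd": y_cbd,
            "dsb_classes": split_by_class(y_dsb, cf_bd, stream="sb"),
            "cbd_classes": split_by_class(y_cbd, cf_bd, stream="bd"),
            "sb_classes": split_by_class(y_dsb, cf_sb, stream="sb"),
        }
        if d.arp_loss:
            y_cbd_5 = yield_cbd(linkages[ARP_LC_BP], es, c)
            yields["y_cbd_5bp"] = y_cbd_5
            yields["y_cbd_star"] = detection_loss(y_cbd, y_cbd_5)
    except Exception as exc:
        raise type(exc)(f"[yield model] {exc}") from exc

    fractions = {
        BD_SCHEME.name: _fractions_block(cf_bd),
        SB_SCHEME.name: _fractions_block(cf_sb),
    }

    ratios: dict = {
        "bd_ssb": y_bd / y_ssb if y_ssb else None,
        "cbd_bd": y_cbd / y_bd if y_bd else None,
        "dsb_ssb": y_dsb / y_ssb if y_ssb else None,
    }
    sb_yields = yields["sb_classes"]
    try:
        ratios["cdsb_dsb"] = cdsb_ratio(sb_yields)
    except ZeroDivisionError:
        ratios["cdsb_dsb"] = None

    report = YieldReport(params_block, counts, yields, fractions, ratios)
    return apply_detection(report, d)


def _fractions_block(cf: ClassFractions) -> dict:
    return {
        "n_sites": cf.n_sites,
        "f": dict(cf.fractions),
        "overflow_fraction": cf.overflow_fraction,
        "counts": dict(cf.counts),
        "empty": cf.empty,
    }


def fraction_table(report: YieldReport) -> str:
    """Render the per-class table as TSV.

    Columns: scheme, stream, label, n_sites, fraction, yield.  One row
    per damage class of each scheme/stream, plus the overflow row.
    """
    rows = ["scheme\tstream\tlabel\tn_sites\tfraction\tyield"]
    stream_of = {"dsb_classes": ("BD_SCHEME", "sb"), "cbd_classes": ("BD_SCHEME", "bd"),
                 "sb_classes": ("SB_SCHEME", "sb")}
    schemes = {s.name: s for s in (BD_SCHEME, SB_SCHEME)}
    for key, (scheme_name, stream) in stream_of.items():
        split = report.yields.get(key)
        if split is None:
            continue
        frac = report.fractions.get(scheme_name, {})
        scheme = schemes[scheme_name]
        labels = scheme.bd_labels if stream == "bd" else scheme.labels
        for label, b in zip(labels, scheme.bins):
            f = frac.get("f", {}).get(b.label, 0.0)
            n = frac.get("counts", {}).get(b.label, 0)
            rows.append(
                f"{scheme_name}\t{stream}\t{label}\t{n}\t{f:.6f}\t{split[label]:.6e}"
            )
        rows.append(
            f"{scheme_name}\t{stream}\toverflow\t"
            f"{frac.get('counts', {}).get('overflow', 0)}\t"
            f"{frac.get('overflow_fraction', 0.0):.6f}\t"
        )
    return "\n".join(rows) + "\n"
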