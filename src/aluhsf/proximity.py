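"""Antisense probe signals versus Alu-harbored HSF sites.

Probe signals with a significant detection p-value are related to the
nearest HSF site inside an antisense-oriented Alu of the same gene's genic
region.  Distances are edge-to-edge gaps between the half-open intervals
(0 when they overlap); a site within 5 kb counts as proximal.  Side labels
are taken in the antisense transcript's frame — the transcript runs
opposite the host gene, so for a '+' host a site at higher coordinates than
the signal lies *upstream* of the antisense transcript.  A host-gene-frame
labelling is available via ``frame="host"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedHit

DEFAULT_PROXIMITY_THRESHOLD = 5000
DEFAULT_DETECTION_ALPHA = 0.05

UPSTREAM = "upstream_of_antisense"
DOWNSTREAM = "downstream_of_antisense"


@dataclass
class AntisenseSignal:
    """One exon-array probe interval with its detection p-value."""

    signal_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    detection_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_p <= 1.0:
            raise ValueError(f"{self.signal_id}: detection_p outside [0, 1]")
        if self.start >= self.end:
            raise ValueError(f"{self.signal_id}: empty interval")


@dataclass
class ProximityRecord:
    """Distance relation between a signal and its nearest antisense-Alu site."""

    signal_id: str
    site: ClassifiedHit
    gap: int
    side: str
    within_threshold: bool


def filter_detected(
    signals: Iterable[AntisenseSignal], alpha: float = DEFAULT_DETECTION_ALPHA
) -> list[AntisenseSignal]:
    """Keep signals with detection p strictly below ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return [s for s in signals if s.detection_p < alpha]


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 if they overlap or abut."""
    return max(a_start - b_end, b_start - a_end, 0)


def nearest_site(
    signal: AntisenseSignal,
    sites: Sequence[ClassifiedHit],
    host_strand: str,
    threshold: int = DEFAULT_PROXIMITY_THRESHOLD,
    frame: str = "antisense",
) -> ProximityRecord | None:
    """The closest site to a signal, with its side and 5-kb flag.

    ``sites`` must all belong to the signal's gene.  Ties in gap go to the
    smaller site start.  In the default antisense-transcript frame, for a
    '+' host gene a site at higher coordinates than the signal is upstream
    of the antisense transcript; ``frame="host"`` labels sides in the host
    gene's own reading direction instead.  Overlapping pairs are sided by
    midpoint comparison (ties upstream).  Returns None when no sites.
    """
    if frame not in ("antisense", "host"):
        raise ValueError(f"unknown frame {frame!r}")
    if host_strand not in ("+", "-"):
        raise ValueError("host strand must be '+' or '-'")
    best: ClassifiedHit | None = None
    best_gap = -1
    for site in sites:
        if site.gene_id != signal.gene_id:
            raise ValueError(
                f"site of gene {site.gene_id} offered to signal of {signal.gene_id}"
            )
        gap = interval_gap(signal.start, signal.end, site.hit.start, site.hit.end)
        if best is None or gap < best_gap or (gap == best_gap and site.hit.start < best.hit.start):
            best, best_gap = site, gap
    if best is None:
        return None

    if best.hit.start >= signal.end:
        site_higher = True
    elif best.hit.end <= signal.start:
        site_higher = False
    else:  # overlap: compare midpoints, ties count as higher
        site_higher = (best.hit.start + best.hit.end) >= (signal.start + signal.end)

    # antisense transcript runs opposite the host gene
    if frame == "antisense":
        upstream = site_higher if host_strand == "+" else not site_higher
    else:
        upstream = not site_higher if host_strand == "+" else site_higher
    return ProximityRecord(
        signal_id=signal.signal_id,
        site=best,
        gap=best_gap,
        side=UPSTREAM if upstream else DOWNSTREAM,
        within_threshold=best_gap <= threshold,
    )


@dataclass
class ProximitySummary:
    n_records: int
    n_within: int
    n_upstream: int
    n_downstream: int
    histogram: pd.DataFrame  # bin_start, count over within-threshold gaps


def proximity_summary(
    records: Iterable[ProximityRecord], bin_width: int = 500
) -> ProximitySummary:
    """Counts of proximal signals, split by side, plus a gap histogram.

    Side counts and the histogram cover within-threshold records only.
    """
    records = list(records)
    within = [r for r in records if r.within_threshold]
    n_up = sum(1 for r in within if r.side == UPSTREAM)
    if within:
        gaps = np.array([r.gap for r in within])
        bins = gaps // bin_width
        idx, counts = np.unique(bins, return_counts=True)
        hist = pd.DataFrame(
            {"bin_start": idx * bin_width, "count": counts}
        )
    else:
        hist = pd.DataFrame(columns=["bin_start", "count"])
    return ProximitySummary(
        n_records=len(records),
        n_within=len(within),
        n_upstream=n_up,
        n_downstream=len(within) - n_up,
        histogram=hist,
    )


def records_to_frame(records: Iterable[ProximityRecord]) -> pd.DataFrame:
    rows = [
        {
            "signal_id": r.signal_id,
            "gene_id": r.site.gene_id,
            "site_start": r.site.hit.start,
            "site_end": r.site.hit.end,
            "site_alu": r.site.alu_id,
            "gap": r.gap,
            "side": r.side,
            "within_threshold": r.within_threshold,
        }
        for r in records
    ]
    cols = [
        "signal_id", "gene_id", "site_start", "site_end",
        "site_alu", "gap", "side", "within_threshold",
    ]
    return pd.DataFrame(rows, columns=cols)


def signals_from_frame(df: pd.DataFrame) -> list[AntisenseSignal]:
    """Build signal records from a table with the generator's signal columns."""
    return [
        AntisenseSignal(
            signal_id=r.signal_id,
            gene_id=r.gene_id,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            detection_p=float(r.detection_p),
        )
        for r in df.itertuples()
    ]
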