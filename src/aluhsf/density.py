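"""Per-gene Alu and HSF-site densities and group comparisons.

Upstream densities are counts per kilobase; genic densities are counts per
10 kb, which brings the much longer genic stretches onto a scale comparable
with the 5-kb upstream windows.  The gene is the sampling unit: densities
are computed per gene region, then compared between expression classes with
a two-tailed t-test (Welch by default — the unequal-variance form is the
safer reading of an unspecified "two tailed t-test"; the pooled form is
available behind a flag).  Raw p-values are reported; Benjamini-Hochberg
adjustment is optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AluElement, RegionSpec
from .classify import ClassifiedHit

METRICS = ("alu_density", "hsf_density_alu", "hsf_density_nonalu", "hsf_density_total")

#: Region-kind scaling: upstream per kb, genic per 10 kb.
SCALE_BASES = {"upstream5kb": 1000.0, "genic": 10000.0}


@dataclass
class DensityRecord:
    gene_id: str
    region_kind: str
    metric: str
    value: float


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def region_density(n_features: int, region: RegionSpec, metric: str) -> DensityRecord:
    """Density of a feature count over one region, with the region-kind scaling."""
    if region.length <= 0:
        raise ValueError(f"zero-length region {region.gene_id}:{region.kind}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    scale = SCALE_BASES.get(region.kind, 1000.0)
    value = n_features / (region.length / scale)
    return DensityRecord(region.gene_id, region.kind, metric, value)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
    equal_var: bool = False,
) -> GroupComparison:
    """Two-tailed two-sample t-test (Welch unless ``equal_var``)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(group_a, group_b, len(a), len(b), float(t), float(p))


def density_table(
    regions: Iterable[RegionSpec],
    hosted_alus: Iterable[AluElement],
    classified: Iterable[ClassifiedHit],
    gene_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene density records for every metric and region.

    Every gene region appears (zero counts give zero density), so class
    means are averaged over the gene number in each class.
    """
    alu_counts: dict[tuple[str, str], int] = {}
    for alu in hosted_alus:
        key = (alu.host_gene, alu.region_kind)
        alu_counts[key] = alu_counts.get(key, 0) + 1

    hit_counts: dict[tuple[str, str, str], int] = {}
    for c in classified:
        bucket = "alu" if c.in_alu else "nonalu"
        for b in (bucket, "total"):
            key = (c.gene_id, c.region_kind, b)
            hit_counts[key] = hit_counts.get(key, 0) + 1

    rows = []
    for region in regions:
        gid, kind = region.gene_id, region.kind
        counts = {
            "alu_density": alu_counts.get((gid, kind), 0),
            "hsf_density_alu": hit_counts.get((gid, kind, "alu"), 0),
            "hsf_density_nonalu": hit_counts.get((gid, kind, "nonalu"), 0),
            "hsf_density_total": hit_counts.get((gid, kind, "total"), 0),
        }
        for metric, n in counts.items():
            rec = region_density(n, region, metric)
            rows.append(
                {
                    "gene_id": gid,
                    "expression_class": gene_classes[gid],
                    "region_kind": kind,
                    "metric": metric,
                    "value": rec.value,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "expression_class", "region_kind", "metric", "value"]
    )


#: Class pairs mirroring the Alu-density comparison table.
DEFAULT_COMPARISONS = (
    ("up", "random"),
    ("down", "random"),
    ("down", "up"),
)


def class_comparisons(
    densities: pd.DataFrame,
    metric: str = "alu_density",
    pairs: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    equal_var: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pairwise class comparisons of a density metric, per region kind.

    One row per (comparison, region kind) with the Welch t statistic and
    two-tailed p.  ``adjust`` applies Benjamini-Hochberg across the rows.
    """
    sub = densities[densities["metric"] == metric]
    rows = []
    for kind in sorted(sub["region_kind"].unique()):
        for a, b in pairs:
            va = sub[(sub["region_kind"] == kind) & (sub["expression_class"] == a)]["value"]
            vb = sub[(sub["region_kind"] == kind) & (sub["expression_class"] == b)]["value"]
            if len(va) < 2 or len(vb) < 2:
                continue
            cmp_ = compare_groups(va, vb, a, b, equal_var=equal_var)
            rows.append(
                {
                    "metric": metric,
                    "region_kind": kind,
                    "comparison": f"{a}_vs_{b}",
                    "n_a": cmp_.n_a,
                    "n_b": cmp_.n_b,
                    "mean_a": float(np.mean(va)),
                    "mean_b": float(np.mean(vb)),
                    "t_statistic": cmp_.t_statistic,
                    "p_value": cmp_.p_value,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "metric", "region_kind", "comparison", "n_a", "n_b",
            "mean_a", "mean_b", "t_statistic", "p_value",
        ],
    )
    if adjust and len(df):
        df["p_adjusted"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
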