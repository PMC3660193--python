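"""Readers/writers for the package's TSV dialects and SNP-assay QC arithmetic.

All tables are plain TSV with a header naming units; readers validate
strictly and report the offending line number.  The genotype dialects live
in :mod:`meiomap.simulate` (``write_genotypes`` / ``read_genotypes``) and
are re-exported here for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import read_genotypes, write_genotypes  # noqa: F401  (re-export)
from .twopoint import GeneticMap

__all__ = [
    "AssayQcSummary",
    "qc_summary",
    "read_map",
    "write_map",
    "read_anchors",
    "write_anchors",
    "read_genotypes",
    "write_genotypes",
]

MAP_COLUMNS = ["lg", "marker", "position_cM", "role",
               "nearest_framework", "attach_dist_cM", "attach_lod"]


@dataclass(frozen=True)
class AssayQcSummary:
    """Array-conversion bookkeeping for one genotyped population."""

    n_total_assayed: int
    n_polymorphic: int
    n_poor: int
    n_monomorphic: int
    conversion_rate: float  # percent, 1 decimal
    poor_rate: float  # percent, 1 decimal


def qc_summary(n_polymorphic: int, n_poor: int, n_total: int) -> AssayQcSummary:
    """Conversion rate = 100 * polymorphic / total assayed; similarly the
    poorly-performing rate.  Loci neither polymorphic nor poor are counted
    monomorphic."""
    if n_total <= 0:
        raise ValueError("total assayed loci must be positive")
    if min(n_polymorphic, n_poor) < 0 or n_polymorphic + n_poor > n_total:
        raise ValueError("component counts inconsistent with the total")
    return AssayQcSummary(
        n_total_assayed=n_total,
        n_polymorphic=n_polymorphic,
        n_poor=n_poor,
        n_monomorphic=n_total - n_polymorphic - n_poor,
        conversion_rate=round(100.0 * n_polymorphic / n_total, 1),
        poor_rate=round(100.0 * n_poor / n_total, 1),
    )


def write_map(gmap: GeneticMap, path) -> None:
    out = pd.DataFrame(
        {
            "lg": gmap.table["lg"],
            "marker": gmap.table["marker"],
            "position_cM": gmap.table["position"],
            "role": gmap.table["role"],
            "nearest_framework": gmap.table["nearest_framework"],
            "attach_dist_cM": gmap.table["attach_dist_cM"],
            "attach_lod": gmap.table["attach_lod"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_map(path) -> GeneticMap:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in MAP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    if table["marker"].duplicated().any():
        dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
        line = int(table.index[table["marker"] == dup][1]) + 2
        raise ValueError(f"{path}: line {line}: duplicate marker id {dup!r}")
    fw = table[table["role"] == "framework"]
    for lg, grp in fw.groupby("lg"):
        pos = grp["position_cM"].to_numpy()
        if (pos[1:] < pos[:-1]).any():
            bad = int(grp.index[1:][pos[1:] < pos[:-1]][0]) + 2
            raise ValueError(f"{path}: line {bad}: positions not sorted within {lg}")
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": table["marker"].astype(str),
                "lg": table["lg"].astype(str),
                "position": table["position_cM"].astype(float),
                "role": table["role"].astype(str),
                "nearest_framework": table["nearest_framework"].fillna(""),
                "attach_dist_cM": table["attach_dist_cM"],
                "attach_lod": table["attach_lod"],
            }
        )
    )


def write_anchors(anchors: pd.DataFrame, path) -> None:
    anchors.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_anchors(path, maps: list[str] | None = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    need = ["marker", "lg"] + [f"pos_{m}" for m in (maps or [])]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    return table
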