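"""Targeted analysis of cancer-associated regions in a normalized profile.

For single-gene targets (one 500 kb bin at the default grid) the statistic is
that bin's z-score and effect size ("ratio"); for larger chromosomal regions
the z-scores and effect sizes of all overlapping usable bins are combined to
their medians.  Results are reported against two z cut-offs: an exploratory
3.0 (inclusive) and a stringent 5.0 (strict), matching how such hit counts
are conventionally printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .intervals import read_bed
from .wisecondor import NormalizedProfile

Z_CUT_LOW = 3.0
Z_CUT_HIGH = 5.0

_CYTOBAND_RE = re.compile(r"^\d{1,2}[pq]\d")


@dataclass(frozen=True)
class TargetRegion:
    name: str
    chrom: str
    start: int
    end: int
    kind: str = "gene"   # "gene" | "region"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


@dataclass
class TargetResult:
    name: str
    z: float
    ratio: float          # effect size, proportion
    n_bins: int
    evaluable: bool = True

    @property
    def hit_low(self) -> bool:
        return self.evaluable and self.z >= Z_CUT_LOW

    @property
    def hit_high(self) -> bool:
        return self.evaluable and self.z > Z_CUT_HIGH


def load_target_regions(path=None) -> list[TargetRegion]:
    """Load target regions from BED4 (default: the packaged list).

    The packaged list carries the recurrently altered gastro-oesophageal
    cancer genes and cytoband regions named in the study's printed results; it
    is a reconstruction, not the authoritative original list, and is fully
    user-replaceable.
    """
    if path is None:
        path = resources.files("cfcna.data") / "targets_grch37.bed"
    df = read_bed(path)
    regions = []
    for r in df.itertuples():
        kind = "region" if _CYTOBAND_RE.match(str(r.name)) else "gene"
        regions.append(TargetRegion(name=str(r.name), chrom=str(r.chrom),
                                    start=int(r.start), end=int(r.end),
                                    kind=kind))
    return regions


def score_target(profile: NormalizedProfile,
                 region: TargetRegion) -> TargetResult:
    """z and ratio of a target: the containing bin for a gene, the median
    over overlapping usable bins for a region.  Targets overlapping no usable
    bin are marked not evaluable."""
    grid = profile.grid
    on = ((grid.chrom == region.chrom) & (grid.start < region.end)
          & (grid.end > region.start) & profile.usable)
    idx = np.flatnonzero(on)
    if len(idx) == 0:
        return TargetResult(name=region.name, z=float("nan"),
                            ratio=float("nan"), n_bins=0, evaluable=False)
    if region.kind == "gene" and len(idx) == 1:
        return TargetResult(name=region.name, z=float(profile.z[idx[0]]),
                            ratio=float(profile.e[idx[0]]), n_bins=1)
    return TargetResult(name=region.name,
                        z=float(np.median(profile.z[idx])),
                        ratio=float(np.median(profile.e[idx])),
                        n_bins=len(idx))


def run_targeted(profile: NormalizedProfile,
                 regions: list[TargetRegion]) -> list[TargetResult]:
    """Score all regions; report sorted by z descending (hit flags at the 3.0
    and 5.0 cuts live on each result)."""
    if not regions:
        raise ValueError("no target regions supplied")
    results = [score_target(profile, r) for r in regions]
    results.sort(key=lambda r: (-(r.z if np.isfinite(r.z) else -np.inf),
                                r.name))
    return results


def count_targeted_hits(results: pd.DataFrame, z_cut: float,
                        inclusive: bool | None = None) -> tuple[int, int]:
    """(n_calls, n_patients) above a z cut from a per-patient result table.

    ``results`` needs columns ``patient`` and ``z``.  The exploratory 3.0 cut
    is inclusive (z >= cut) and the stringent 5.0 cut strict (z > cut), the
    convention under which printed hit counts at both cuts are consistent;
    override with ``inclusive``.
    """
    if inclusive is None:
        inclusive = z_cut < Z_CUT_HIGH
    z = results["z"].to_numpy(float)
    mask = z >= z_cut if inclusive else z > z_cut
    return int(mask.sum()), int(results.loc[mask, "patient"].nunique())


def results_to_frame(patient: str, results: list[TargetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(patient, r.name, r.z, r.ratio, r.n_bins, r.evaluable,
          r.hit_low, r.hit_high) for r in results],
        columns=["patient", "region", "z", "ratio", "n_bins", "evaluable",
                 "hit_3.0", "hit_5.0"])
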