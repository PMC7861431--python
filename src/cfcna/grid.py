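"""Fixed-width genomic bin grids and bin-level read-count matrices.

Shallow whole-genome cfDNA analysis counts reads in fixed windows ("bins",
500 kb by default) over the 22 autosomes.  :class:`BinGrid` is the immutable
partition; :class:`BinCountMatrix` holds raw integer counts for one or more
samples on that partition.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# GRCh37/hg19 autosome lengths in base pairs.
GRCH37_AUTOSOMES: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}

DEFAULT_BIN_WIDTH = 500_000


@dataclass(frozen=True)
class BinGrid:
    """An ordered, non-overlapping partition of autosomes into fixed-width bins.

    All bins on a chromosome except the last have length exactly ``bin_width``;
    the final bin is truncated at the chromosome end.
    """

    chrom: np.ndarray          # str labels, one per bin
    start: np.ndarray          # int64
    end: np.ndarray            # int64
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.chrom) == 0:
            raise ValueError("empty bin grid")
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end length mismatch")
        if np.any(self.end <= self.start):
            raise ValueError("bins must satisfy end > start")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in grid order (first appearance)."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chromosome)

    @property
    def width(self) -> np.ndarray:
        return self.end - self.start

    @classmethod
    def from_chrom_lengths(cls, lengths: dict[str, int],
                           bin_width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        chroms, starts, ends = [], [], []
        for name, length in lengths.items():
            edges = np.arange(0, length, bin_width, dtype=np.int64)
            chroms.extend([name] * len(edges))
            starts.append(edges)
            ends.append(np.minimum(edges + bin_width, length))
        return cls(
            chrom=np.asarray(chroms, dtype=object),
            start=np.concatenate(starts),
            end=np.concatenate(ends),
            bin_width=bin_width,
        )

    @classmethod
    def grch37(cls, bin_width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        """The full GRCh37 autosomal grid (~5,800 bins at 500 kb)."""
        return cls.from_chrom_lengths(GRCH37_AUTOSOMES, bin_width)

    @classmethod
    def desk(cls, bin_width: int = 100_000) -> "BinGrid":
        """A reduced 22-autosome grid (3-6 Mb per chromosome, ~1,000 bins).

        Keeps simulations and test suites fast while preserving the
        multi-chromosome structure reference-bin selection relies on.
        """
        lengths = {
            str(i + 1): int((6_000_000 - 3_000_000 * i / 21) // bin_width) * bin_width
            for i in range(22)
        }
        return cls.from_chrom_lengths(lengths, bin_width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start,
                             "end": self.end})

    def overlap_fraction(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Per-bin fraction of each bin covered by [start, end) on chromosome."""
        ov = np.zeros(self.n_bins)
        on = self.chrom == chromosome
        lo = np.maximum(self.start, start)
        hi = np.minimum(self.end, end)
        frac = np.clip(hi - lo, 0, None) / self.width
        ov[on] = frac[on]
        return ov


@dataclass
class BinCountMatrix:
    """Raw per-bin read counts: one row per grid bin, one column per sample."""

    grid: BinGrid
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.counts) != self.grid.n_bins:
            raise ValueError(
                f"count rows ({len(self.counts)}) != grid bins ({self.grid.n_bins})"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.grid.to_frame()
        out = pd.concat([out, self.counts.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        grid = BinGrid(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            bin_width=int((df["end"] - df["start"]).max()),
        )
        counts = df.drop(columns=["chrom", "start", "end"])
        return cls(grid=grid, counts=counts)
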