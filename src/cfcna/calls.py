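"""Copy-number alteration call records shared by both callers."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GAIN = "gain"
LOSS = "loss"

# status flags a call may carry
FLAG_BLACKLISTED = "blacklisted"
FLAG_LIKELY_GERMLINE = "likely-germline"
FLAG_CANCER_ASSOCIATED = "cancer-associated"
FLAG_TISSUE_VERIFIED = "tissue-verified"
FLAG_AMPLIFICATION = "amplification"


@dataclass
class CnaCall:
    """One called segment (0-based half-open coordinates).

    ``score`` is the signed Stouffer z for the within-sample caller and the
    segment mean log2 ratio for the HMM caller; ``effect_size`` is the mean
    relative coverage deviation (proportion) over member bins.
    """

    chrom: str
    start: int
    end: int
    direction: str            # "gain" | "loss"
    score: float
    effect_size: float
    n_bins: int
    caller: str               # "wc" | "hmm"
    flags: set = field(default_factory=set)
    genes: tuple = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if self.direction not in (GAIN, LOSS):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def calls_to_frame(calls: list[CnaCall]) -> pd.DataFrame:
    """BED-compatible table: chrom, start, end, direction, score,
    effect_size, n_bins, caller, flags, genes."""
    rows = [
        (c.chrom, c.start, c.end, c.direction, c.score, c.effect_size,
         c.n_bins, c.caller, ",".join(sorted(c.flags)), ",".join(c.genes))
        for c in calls
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "direction", "score", "effect_size",
        "n_bins", "caller", "flags", "genes"])


def write_calls_tsv(calls: list[CnaCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[CnaCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False)
    out = []
    for r in df.itertuples():
        flags = set(str(r.flags).split(",")) - {""} if r.flags else set()
        genes = tuple(str(r.genes).split(",")) if r.genes else ()
        out.append(CnaCall(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            direction=r.direction, score=float(r.score),
            effect_size=float(r.effect_size), n_bins=int(r.n_bins),
            caller=r.caller, flags=flags, genes=genes))
    return out
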