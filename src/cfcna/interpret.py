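"""Post-filtering and clinical interpretation of CNA calls.

Covers the filtering conventions of shallow-WGS cfDNA analysis (blacklist
overlap, exclusion of the GC-rich chromosome 19 and the sex chromosomes, the
1.5% minimal effect size), the copy-number arithmetic linking effect size and
ctDNA fraction, amplification and chromosomal-instability classification,
empirical confidence tiers, tissue concordance and per-patient/cohort
summaries.

Copy-number model: a segment at tumour copy number c in a sample with ctDNA
fraction f has effect size e = f (c - 2) / 2, hence the estimator
c = 2 + 2 e / f.  An amplification is a gain reaching >= 5 copies in the
tumour cells, i.e. e / f >= 1.5; when no fraction estimate exists the
fallback is e > 4.5% (5 copies at an assumed 3% fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .calls import (FLAG_AMPLIFICATION, FLAG_BLACKLISTED,
                    FLAG_CANCER_ASSOCIATED, FLAG_LIKELY_GERMLINE,
                    FLAG_TISSUE_VERIFIED, GAIN, LOSS, CnaCall)
from .hmm import TumourFractionEstimate
from .intervals import overlap_bp, read_bed

DEFAULT_EXCLUDED_CHROMOSOMES = frozenset({"19", "X", "Y"})
DEFAULT_ES_MIN = 0.015
DEFAULT_AMP_RATIO = 1.5
DEFAULT_FALLBACK_ES = 0.045
CIN_MIN_CHROMOSOMES = 10
GERMLINE_MAX_BINS = 3
GERMLINE_MIN_ES = 0.25
DEFAULT_BLACKLIST_OVERLAP = 0.5

GROUP_TP = "TP"   # CNAs in tissue and plasma
GROUP_T = "T"     # tissue only
GROUP_P = "P"     # plasma only
GROUP_N = "N"     # neither


@dataclass
class TissueCallSet:
    """Tissue CNA calls (e.g. from an array-CGH report) for one patient."""

    patient_id: str
    intervals: pd.DataFrame  # chrom, start, end, direction, amplification

    def __post_init__(self) -> None:
        if len(self.intervals):
            if (self.intervals["start"] < 0).any():
                raise ValueError("negative tissue interval coordinates")
            self.intervals = self.intervals.sort_values(
                ["chrom", "start"]).reset_index(drop=True)

    @property
    def has_calls(self) -> bool:
        return len(self.intervals) > 0


@dataclass
class PatientSummary:
    patient_id: str
    tissue: bool
    wc: bool
    hmm: bool
    ctdna_fraction: TumourFractionEstimate
    cin: bool
    targeted_hit: bool
    group: str = ""
    amplified_genes: tuple = ()

    def __post_init__(self) -> None:
        if not self.group:
            self.group = concordance_group(self.tissue, self.wc or self.hmm)

    @property
    def plasma(self) -> bool:
        return self.wc or self.hmm


def concordance_group(tissue: bool, plasma: bool) -> str:
    if tissue and plasma:
        return GROUP_TP
    if tissue:
        return GROUP_T
    if plasma:
        return GROUP_P
    return GROUP_N


def flag_likely_germline(calls: list[CnaCall],
                         max_bins: int = GERMLINE_MAX_BINS,
                         min_es: float = GERMLINE_MIN_ES) -> list[CnaCall]:
    """Flag (never delete) short, very strong calls as likely germline CNVs:
    <= 3 bins with |effect size| >= 25% is the review heuristic."""
    for c in calls:
        if c.n_bins <= max_bins and abs(c.effect_size) >= min_es:
            c.flags.add(FLAG_LIKELY_GERMLINE)
    return calls


def filter_calls(calls: list[CnaCall], blacklist: pd.DataFrame | None = None,
                 excluded_chromosomes=DEFAULT_EXCLUDED_CHROMOSOMES,
                 es_min: float = DEFAULT_ES_MIN,
                 max_blacklist_overlap: float = DEFAULT_BLACKLIST_OVERLAP
                 ) -> list[CnaCall]:
    """Remove excluded-chromosome calls, sub-threshold effect sizes, and
    calls mostly covered by the blacklist; survivors are flagged
    cancer-associated.  Order of the three filters does not matter."""
    out = []
    for c in calls:
        if str(c.chrom) in excluded_chromosomes:
            continue
        if abs(c.effect_size) < es_min:
            continue
        if blacklist is not None and len(blacklist):
            frac = overlap_bp(c.chrom, c.start, c.end, blacklist) / c.length
            if frac > max_blacklist_overlap:
                c.flags.add(FLAG_BLACKLISTED)
                continue
        c.flags.add(FLAG_CANCER_ASSOCIATED)
        out.append(c)
    return out


def estimate_copy_number(effect_size: float,
                         f: TumourFractionEstimate | float) -> float | None:
    """Tumour copy number implied by an effect size at ctDNA fraction f:
    c = 2 + 2 (e / f).  Returns None when the fraction is undefined or 0
    (not evaluable)."""
    if isinstance(f, TumourFractionEstimate):
        if not f.defined:
            return None
        f = f.f
    if f is None or f <= 0:
        return None
    return 2.0 + 2.0 * (effect_size / f)


def classify_amplification(effect_size: float,
                           f: TumourFractionEstimate | float | None,
                           fallback_es: float = DEFAULT_FALLBACK_ES,
                           amp_ratio: float = DEFAULT_AMP_RATIO) -> str:
    """"gain" | "amplification" | "loss".

    With a defined fraction, a gain is an amplification iff
    effect_size / f >= amp_ratio (1.5, i.e. tumour copy number >= 5; the
    boundary is classified as amplification so the rule coincides exactly
    with estimate_copy_number >= 5).  Without a fraction the fallback is
    effect_size > fallback_es (strictly above 4.5%).
    """
    if effect_size < 0:
        return LOSS
    if isinstance(f, TumourFractionEstimate):
        f = f.f if f.defined else None
    if f is not None and f > 0:
        # routed through the copy-number estimator so that the equivalence
        # amplification <=> estimated copy number >= 5 holds bit-for-bit
        return ("amplification"
                if estimate_copy_number(effect_size, f) >= 2.0 + 2.0 * amp_ratio
                else GAIN)
    return "amplification" if effect_size > fallback_es else GAIN


def classify_cin(calls: list[CnaCall],
                 min_chromosomes: int = CIN_MIN_CHROMOSOMES) -> bool:
    """Chromosomal instability: cancer-associated gains/losses on >= 10
    distinct chromosomes."""
    return len({c.chrom for c in calls}) >= min_chromosomes


def classify_confidence(call: CnaCall, caller: str | None = None) -> str:
    """Empirical confidence tier from length and effect size.

    For the z-score caller, every call > 30 Mb with effect > 3% and every
    call of 5-30 Mb with effect > 5% was tissue-verified in the study these
    thresholds derive from; the HMM caller supports a lower small-call bound
    of 2 Mb.  Everything else is "low".
    """
    caller = caller or call.caller
    length = call.length
    es = abs(call.effect_size)
    small_floor = 2e6 if caller == "hmm" else 5e6
    if length > 30e6 and es > 0.03:
        return "high"
    if small_floor < length <= 30e6 and es > 0.05:
        return "high"
    return "low"


def verify_against_tissue(plasma: list[CnaCall], tissue: TissueCallSet,
                          min_overlap_fraction: float = 0.0
                          ) -> tuple[list[CnaCall], str]:
    """Flag plasma calls verified by tissue and derive the patient group.

    A plasma call is tissue-verified iff it overlaps a tissue call of the
    same direction (any overlap by default; a minimum reciprocal fraction of
    the plasma call is configurable).  Group: TP / T / P / N from presence of
    tissue and plasma calls.
    """
    for c in plasma:
        for r in tissue.intervals.itertuples():
            if str(r.chrom) != str(c.chrom) or r.direction != c.direction:
                continue
            ov = max(0, min(c.end, int(r.end)) - max(c.start, int(r.start)))
            if ov > 0 and ov / c.length >= min_overlap_fraction:
                c.flags.add(FLAG_TISSUE_VERIFIED)
                break
    group = concordance_group(tissue.has_calls, len(plasma) > 0)
    return plasma, group


def load_actionable_genes(path=None) -> pd.DataFrame:
    """Actionable-gene intervals (BED4).  The packaged default
    {ERBB2, EGFR, FGFR2, VEGFA, KRAS, MET, CCND1, CDK6} is a stand-in list of
    recurrently actionable gastro-oesophageal amplification targets and is
    user-replaceable."""
    if path is None:
        path = resources.files("cfcna.data") / "actionable_genes_grch37.bed"
    return read_bed(path)


def annotate_actionable(calls: list[CnaCall],
                        genes: pd.DataFrame) -> list[CnaCall]:
    """Attach gene names to amplification-flagged calls overlapping a listed
    actionable gene; non-amplification calls are left unannotated."""
    if genes is None or not len(genes):
        return calls
    for c in calls:
        if FLAG_AMPLIFICATION not in c.flags:
            continue
        hit = [str(r.name) for r in genes.itertuples()
               if str(r.chrom) == str(c.chrom)
               and int(r.start) < c.end and int(r.end) > c.start]
        if hit:
            c.genes = tuple(sorted(set(c.genes) | set(hit)))
    return calls


def summarize_patient(patient_id: str, wc_calls: list[CnaCall],
                      hmm_calls: list[CnaCall],
                      fraction: TumourFractionEstimate,
                      tissue: TissueCallSet | None = None,
                      targeted_hit: bool = False,
                      fallback_es: float = DEFAULT_FALLBACK_ES
                      ) -> PatientSummary:
    """Assemble one patient's interpretation from filtered calls."""
    all_calls = wc_calls + hmm_calls
    for c in all_calls:
        if c.direction == GAIN and classify_amplification(
                c.effect_size, fraction, fallback_es) == "amplification":
            c.flags.add(FLAG_AMPLIFICATION)
    if tissue is not None:
        verify_against_tissue(all_calls, tissue)
    tissue_flag = tissue.has_calls if tissue is not None else False
    cin = classify_cin(wc_calls) or classify_cin(hmm_calls)
    genes: set[str] = set()
    for c in all_calls:
        genes |= set(c.genes)
    return PatientSummary(
        patient_id=patient_id, tissue=tissue_flag, wc=len(wc_calls) > 0,
        hmm=len(hmm_calls) > 0, ctdna_fraction=fraction, cin=cin,
        targeted_hit=targeted_hit, amplified_genes=tuple(sorted(genes)))


def summarize_cohort(summaries: list[PatientSummary]) -> dict:
    """Cohort-level counts and detection rates.

    Plasma positivity is taken from the per-caller call flags (a defined
    ctDNA fraction with no surviving calls does not count as plasma-positive).
    """
    if not summaries:
        raise ValueError("no patient summaries")
    n = len(summaries)
    tissue_pos = sum(s.tissue for s in summaries)
    wc_pos = sum(s.wc for s in summaries)
    hmm_pos = sum(s.hmm for s in summaries)
    plasma_pos = sum(s.plasma for s in summaries)
    groups = {g: sum(s.group == g for s in summaries)
              for g in (GROUP_TP, GROUP_T, GROUP_P, GROUP_N)}
    cin = sum(s.cin for s in summaries)
    cin_plasma = sum(s.cin and s.plasma for s in summaries)
    noncin_plasma = sum((not s.cin) and s.plasma for s in summaries)
    targeted_hits = sum(s.targeted_hit for s in summaries)
    return {
        "n_patients": n,
        "tissue_positive": tissue_pos,
        "wc_positive": wc_pos,
        "hmm_positive": hmm_pos,
        "plasma_positive": plasma_pos,
        "groups": groups,
        "cin": cin,
        "cin_and_plasma": cin_plasma,
        "noncin_and_plasma": noncin_plasma,
        "targeted_hits": targeted_hits,
        "plasma_detection_rate": plasma_pos / n,
        "tissue_concordance_rate": (groups[GROUP_TP] / tissue_pos
                                    if tissue_pos else float("nan")),
    }


def summaries_to_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    rows = [(s.group, s.patient_id, s.cin, s.tissue, s.wc, s.hmm,
             s.ctdna_fraction.f * 100 if s.ctdna_fraction.defined else 0.0,
             s.targeted_hit, ",".join(s.amplified_genes)) for s in summaries]
    return pd.DataFrame(rows, columns=[
        "group", "patient", "cin", "tissue", "wc", "hmm",
        "ctdna_fraction_pct", "targeted_hit", "amplified_genes"])
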