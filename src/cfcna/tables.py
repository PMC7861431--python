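"""Loaders for the packaged printed-table fixtures.

The study's per-patient results table (44 patients: concordance group, CIN,
tissue/plasma call flags per caller, ctDNA fraction, targeted hit) and its
targeted-analysis table (23 target hits with z-score, ratio and
whole-genome/tissue classes) are shipped as plain TSV transcriptions with a
row-count manifest; loaders validate the fixtures before returning them.
Percentages are stored as printed (e.g. 439 for 439%); loaders add
proportion-scale columns where useful.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .hmm import TumourFractionEstimate
from .interpret import PatientSummary, concordance_group

_GROUPS = {"TP", "T", "P", "N"}
_CLASSES = {"Amp", "Gain", "0"}


class FixtureError(RuntimeError):
    """A packaged fixture failed validation (corruption or bad edit)."""


def _data_path(name: str):
    return resources.files("cfcna.data") / name


def _expected_rows(name: str) -> int:
    manifest = json.loads(_data_path("manifest.json").read_text())
    return int(manifest[name]["rows"])


def load_table3() -> pd.DataFrame:
    """Targeted-analysis fixture: 23 rows of (patient, region, z, ratio,
    whole-genome and tissue classes).  ``ratio_pct`` is as printed;
    ``ratio`` is the proportion."""
    name = "table3_targeted.tsv"
    df = pd.read_csv(_data_path(name), sep="\t")
    if len(df) != _expected_rows(name):
        raise FixtureError(f"{name}: expected {_expected_rows(name)} rows, "
                           f"got {len(df)}")
    if (df["z"] < 3.0).any():
        raise FixtureError(f"{name}: all rows must have z >= 3.0")
    if (df["ratio_pct"] <= 0).any():
        raise FixtureError(f"{name}: ratios must be positive (gains only)")
    for col in ("wc_class", "ichor_class", "tissue_class"):
        bad = set(df[col].astype(str)) - _CLASSES
        if bad:
            raise FixtureError(f"{name}: invalid classes {bad} in {col}")
    df["ratio"] = df["ratio_pct"] / 100.0
    return df


def load_table2() -> pd.DataFrame:
    """Per-patient results fixture: 44 rows of (group, patient, CIN, tissue,
    wc, ichor, ctDNA fraction %, targeted hit)."""
    name = "table2_patient_summary.tsv"
    df = pd.read_csv(_data_path(name), sep="\t", keep_default_na=False)
    if len(df) != _expected_rows(name):
        raise FixtureError(f"{name}: expected {_expected_rows(name)} rows, "
                           f"got {len(df)}")
    bad = set(df["group"]) - _GROUPS
    if bad:
        raise FixtureError(f"{name}: invalid group codes {bad}")
    for col in ("cin", "tissue", "wc", "ichor", "targeted_hit"):
        df[col] = df[col].map({"yes": True, "no": False})
        if df[col].isna().any():
            raise FixtureError(f"{name}: non yes/no value in {col}")
    # internal consistency: the group code must equal the partition
    # recomputed from the tissue/plasma flags
    for r in df.itertuples():
        if concordance_group(r.tissue, r.wc or r.ichor) != r.group:
            raise FixtureError(
                f"{name}: group code {r.group} of {r.patient} inconsistent "
                "with tissue/plasma flags")
    return df


def table2_to_summaries(df: pd.DataFrame | None = None) -> list[PatientSummary]:
    """PatientSummary records from the per-patient fixture.

    The printed ctDNA fraction is stored verbatim; a nonzero fraction is a
    defined estimate.  (One patient carries a defined fraction with no
    plasma calls; plasma positivity is always taken from the call flags.)
    """
    if df is None:
        df = load_table2()
    out = []
    for r in df.itertuples():
        f_pct = float(r.ctdna_fraction_pct)
        est = TumourFractionEstimate(f=f_pct / 100.0, defined=f_pct > 0)
        out.append(PatientSummary(
            patient_id=str(r.patient), tissue=bool(r.tissue), wc=bool(r.wc),
            hmm=bool(r.ichor), ctdna_fraction=est, cin=bool(r.cin),
            targeted_hit=bool(r.targeted_hit), group=str(r.group)))
    return out
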