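"""Packaged reference datasets.

Two small tab-separated tables ship with the package:

* the catalog of 25 rare, predicted-damaging germline NBN coding variants
  observed among 4,183 pediatric B-ALL patients, with gnomAD allele
  fractions, CADD and REVEL scores, ClinVar designations, and case-carrier
  counts;
* the per-variant functional-screen classes (protein-stability class from the
  EGFP:mCherry reporter assay and mitomycin-C sensitivity class from the
  barcode-depletion screen) together with the reported final pathogenicity
  call for each of those variants.

Cohort-level summary constants (case and control totals, control carrier
count) accompany them for burden calculations against the gnomAD v2.1
non-cancer control cohort.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import VariantRecord, load_variant_table

__all__ = [
    "ball_variants_path",
    "load_ball_variants",
    "ball_screen_classes_path",
    "load_ball_screen_classes",
    "N_CASES",
    "N_CONTROLS",
    "CONTROL_CARRIERS",
]

#: Size of the B-ALL case cohort screened by targeted sequencing.
N_CASES = 4183
#: Size of the gnomAD v2.1 exome non-cancer control cohort.
N_CONTROLS = 118_479
#: Carriers of qualifying NBN variants among the controls.
CONTROL_CARRIERS = 208


def _data_path(name: str) -> Path:
    return Path(resources.files("nbnscreen").joinpath("data", name))  # type: ignore[arg-type]


def ball_variants_path() -> Path:
    """Path of the packaged B-ALL NBN variant catalog TSV."""
    return _data_path("ball_nbn_variants.tsv")


def load_ball_variants() -> list[VariantRecord]:
    """The 25-variant B-ALL catalog as validated records."""
    return load_variant_table(ball_variants_path())


def ball_screen_classes_path() -> Path:
    """Path of the packaged per-variant functional-screen class TSV."""
    return _data_path("ball_nbn_screen_classes.tsv")


def load_ball_screen_classes() -> pd.DataFrame:
    """Per-variant screen classes and reported final calls as a DataFrame."""
    return pd.read_csv(ball_screen_classes_path(), sep="\t")
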