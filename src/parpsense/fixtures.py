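"""Packaged study cohorts, transcribed verbatim from the published tables.

Four fixtures ship with the package:

``table1``
    Cohort-level clinical characteristics (a summary table, returned as a
    DataFrame by :func:`load_characteristics`).
``table2``
    The 41-patient olaparib cohort with every homologous-recombination
    variant and its curated class, PFS and censoring status.  For the 12
    patients carrying only VUS, the published second-hit scores, DANN and
    PROVEAN calls and Performance Status are merged in, so the full
    decision pipeline can run on this cohort directly.
``table3``
    The 12 olaparib-treated patients whose tumors carry only variants of
    unknown significance, with the published second-hit scores, DANN and
    PROVEAN calls and Performance Status.
``table5``
    The 8 niraparib-treated ovarian-cancer patients with VUS, with
    categorical second-hit, DANN and PROVEAN calls.

The published per-patient final predictions for the two VUS cohorts are
exposed as dictionaries so that a re-run of the classifier can be checked
against them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_cohort
from .models import Cohort

__all__ = [
    "FIXTURES",
    "load_fixture",
    "load_characteristics",
    "TABLE3_FINAL_PREDICTION",
    "TABLE5_FINAL_PREDICTION",
]

FIXTURES = ("table1", "table2", "table3", "table5")

#: Published final predictions for the olaparib VUS cohort.  "S or R"
#: (the two evidence models disagreed) is recorded as "U".
TABLE3_FINAL_PREDICTION = {
    "Ovarian #2": "S",
    "Ovarian #6": "S",
    "Ovarian #20": "S",
    "Ovarian #23": "U",
    "Breast #6": "S",
    "Breast #8": "S",
    "Digestive tract #1": "R",
    "Digestive tract #2": "R",
    "Digestive tract #5": "R",
    "Digestive tract #6": "R",
    "Digestive tract #7": "R",
    "Skin #1": "S",
}

#: Published final predictions for the niraparib VUS cohort.
TABLE5_FINAL_PREDICTION = {
    "Niraparib #1": "S",
    "Niraparib #2": "S",
    "Niraparib #3": "S",
    "Niraparib #4": "R",
    "Niraparib #5": "R",
    "Niraparib #6": "R",
    "Niraparib #7": "R",
    "Niraparib #8": "U",
}


def _data_path(name: str):
    return resources.files("parpsense") / "data" / name


def load_fixture(name: str) -> Cohort:
    """Load a packaged cohort fixture by name.

    ``table1`` is a summary table, not a per-patient cohort; request it
    through :func:`load_characteristics` instead.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    if name == "table1":
        raise ValueError(
            "table1 is a cohort-characteristics summary; use load_characteristics()"
        )
    with resources.as_file(_data_path(f"{name}_patients.tsv")) as ppath, resources.as_file(
        _data_path(f"{name}_variants.tsv")
    ) as vpath:
        return read_cohort(str(ppath), str(vpath), label=name)


def load_characteristics() -> pd.DataFrame:
    """The published cohort-characteristics summary as a DataFrame."""
    with resources.as_file(_data_path("table1_characteristics.tsv")) as path:
        return pd.read_csv(path, sep="\t")
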