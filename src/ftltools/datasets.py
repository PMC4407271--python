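"""Bundled published count tables from the FTL heterozygosity survey.

These small TSVs hold the printed summary data of the fluorescent-reporter
crossover study the package is built around: pooled tetrad class counts
per interval and background, adjacent-crossover-stratified map distances,
hot/cold-quartile marker genotype counts for three F2 populations, and the
per-accession F1 interval cM survey.  They serve as worked inputs and
validation anchors for the estimators.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .estimators import TetradCounts


__all__ = [
    "load_tetrad_counts",
    "tetrad_counts_as_objects",
    "load_adjacent_co_cm",
    "load_quartile_counts",
    "quartile_tables",
    "load_f1_interval_cm",
]

_QUARTILE_FILES = {
    "420": "f2_quartile_counts_420.tsv",
    "I2f": "f2_quartile_counts_I2f.tsv",
    "CEN3": "f2_quartile_counts_CEN3.tsv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("ftltools").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_tetrad_counts() -> pd.DataFrame:
    """PD/NPD/T counts per interval and genetic background.

    Columns: interval, background (Col/Col homozygous or Col/Ler hybrid),
    PD, NPD, T, and the published cM +/- SE for cross-checking.
    """
    return _read("tetrad_counts.tsv")


def tetrad_counts_as_objects() -> dict:
    """``{(interval, background): TetradCounts}`` from the bundled table."""
    df = load_tetrad_counts()
    return {(row.interval, row.background):
            TetradCounts(PD=int(row.PD), NPD=int(row.NPD), T=int(row.T))
            for row in df.itertuples()}


def load_adjacent_co_cm() -> pd.DataFrame:
    """Published per-interval map distances stratified by adjacent COs.

    ``cm_without``/``cm_with`` are Perkins cM among tetrads without/with a
    crossover in the adjacent interval (+/- SE columns), with the published
    without/with ratio per background.
    """
    return _read("adjacent_co_cm.tsv")


def load_quartile_counts(interval: str) -> pd.DataFrame:
    """Hot/cold-quartile HET/HOM marker counts for one F2 population.

    ``interval`` is one of ``"420"``, ``"I2f"``, ``"CEN3"``.  Columns:
    marker_bp, hot_het, hot_hom, cold_het, cold_hom, and the published
    FDR-adjusted p-value (NA where not published).
    """
    if interval not in _QUARTILE_FILES:
        raise KeyError(f"unknown F2 population {interval!r}; "
                       f"have {sorted(_QUARTILE_FILES)}")
    return _read(_QUARTILE_FILES[interval])


def quartile_tables(interval: str) -> dict:
    """Per-marker 2x2 quartile tables, ready for ``association_from_tables``."""
    df = load_quartile_counts(interval)
    return {int(r.marker_bp): np.array([[r.hot_het, r.hot_hom],
                                        [r.cold_het, r.cold_hom]])
            for r in df.itertuples()}


def load_f1_interval_cm() -> pd.DataFrame:
    """Per-accession F1 genetic distances for the five surveyed intervals.

    One row per accession crossed to the Col-0 reporter background, with
    per-interval cM, their sum (``total``; NA where not all five intervals
    were measured) and the published GLM p-value against Col-0.
    """
    df = _read("f1_interval_cm.tsv")
    return df
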