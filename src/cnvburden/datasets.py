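"""Bundled worked-example data from a published AVSD rare-CNV study.

These are the printed, cohort-level values of a whole-exome case-control
study of atrioventricular septal defect (150 cases, 100 controls): the
curated pathogenic-CNV table, the Down-syndrome critical region, and the
headline summary counts.  They serve as inputs for worked examples and
consistency checks of the pipeline's arithmetic (interval lengths, count
identities, percentage formatting); the underlying patient data are not
public, so none of the per-sample stages can be re-run on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .intervals import GenomicInterval, interval_length
from .io import read_region_bed

__all__ = [
    "load_pathogenic_cnvs",
    "ds_critical_region",
    "AVSD_COHORT_COUNTS",
]

# Printed cohort summary counts of the AVSD study.
AVSD_COHORT_COUNTS: dict[str, int] = {
    "n_cases": 150,
    "n_controls": 100,
    "n_rare_dup": 2394,
    "n_rare_del": 1861,
    "n_large_cnvs_gt_500kb": 122,
    "n_male_cases": 76,
    "n_complete_avsd": 125,
}


def _data_path(name: str):
    return resources.files("cnvburden.data") / name


def load_pathogenic_cnvs() -> pd.DataFrame:
    """The study's curated pathogenic-CNV calls, with computed region sizes.

    Returns a frame with columns SAMPLE, CHROM, START, END, CYTOBAND, TYPE
    plus a ``REGION_SIZE`` column computed as the half-open interval length
    (END - START) through the package's interval arithmetic.
    """
    with resources.as_file(_data_path("avsd_pathogenic_cnvs.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df["REGION_SIZE"] = [
        interval_length(GenomicInterval(r.CHROM, r.START, r.END))
        for r in df.itertuples()
    ]
    return df


def ds_critical_region() -> tuple[GenomicInterval, str]:
    """The ~34 kb Down-syndrome critical region on 21q22.13 (GRCh38)."""
    with resources.as_file(_data_path("ds_critical_region.bed")) as path:
        records = read_region_bed(path)
    return records[0]
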