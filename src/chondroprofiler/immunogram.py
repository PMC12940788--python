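"""Per-patient immunograms: six-axis radar summaries of immune context.

Each patient is summarized on six axes in [0, 1]:

1. mean density of immune-suppressive cell markers (Foxp3, CD163,
   CD68 [KP1]), both tumor regions, min-max normalized across the cohort;
2. presence of an IDH1 mutation (binary);
3. TMB status (binary: above the cohort median);
4. presence of PD-L1 expression (binary: ordinal score >= 1);
5. mean density of the remaining immune markers, both regions, normalized;
6. mean density of immune-checkpoint markers (TIM-3, LAG-3, Gal-9, PD-1),
   normalized.

Density axes use cohort min-max normalization, so they reach 0 and 1 at
the cohort extremes and are invariant to affine rescaling of raw
densities.
"""

from __future__ import annotations

import pandas as pd

from .immune import MarkerDensityTable, score_pdl1
from .synth import MARKERS, REGIONS

__all__ = ["AXIS_COLUMNS", "build_immunograms", "summarize_by_imp"]

SUPPRESSIVE_MARKERS = ("FOXP3", "CD163", "CD68_KP1")
ICP_MARKERS = ("TIM3", "LAG3", "GAL9", "PD1")
#: axis 5 covers every marker not on axis 1 or 6; PD-L1 density is excluded
#: because axis 4 already encodes PD-L1 expression
REST_MARKERS = tuple(
    m for m in MARKERS if m not in SUPPRESSIVE_MARKERS + ICP_MARKERS + ("PDL1",)
)
AXIS_COLUMNS = ("a1_suppressive", "a2_idh1", "a3_tmb", "a4_pdl1", "a5_rest", "a6_icp")


def _marker_mean(data: pd.DataFrame, markers) -> pd.Series:
    cols = [f"{m}_{r}" for m in markers for r in REGIONS]
    return data[cols].mean(axis=1)


def _minmax(x: pd.Series) -> pd.Series:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return pd.Series(0.0, index=x.index)
    return (x - lo) / (hi - lo)


def build_immunograms(
    table: MarkerDensityTable,
    idh1_flags: pd.Series,
    tmb: pd.Series,
) -> pd.DataFrame:
    """Immunogram axes for every patient of the cohort.

    ``idh1_flags`` (0/1) and ``tmb`` (mut/Mb) are indexed by sample and
    must cover every patient in the density table; a missing patient is
    an error naming it.
    """
    data = table.data.set_index("sample")
    for name, series in (("IDH1 flag", idh1_flags), ("TMB", tmb)):
        missing = [s for s in data.index if s not in series.index]
        if missing:
            raise KeyError(f"patient {missing[0]} missing from {name} input")
    idh1 = idh1_flags.reindex(data.index)
    tmb = tmb.reindex(data.index)
    out = pd.DataFrame(index=data.index)
    out["a1_suppressive"] = _minmax(_marker_mean(data, SUPPRESSIVE_MARKERS))
    out["a2_idh1"] = idh1.astype(int).astype(float)
    out["a3_tmb"] = (tmb > tmb.median()).astype(float)
    out["a4_pdl1"] = data["pdl1_percent"].map(lambda v: float(score_pdl1(v) >= 1))
    out["a5_rest"] = _minmax(_marker_mean(data, REST_MARKERS))
    out["a6_icp"] = _minmax(_marker_mean(data, ICP_MARKERS))
    return out


def summarize_by_imp(immunograms: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Arithmetic mean axis profile per immunophenotype.

    An empty group yields NaN axis means (flagged missing).
    """
    labels = pd.Series(labels).reindex(immunograms.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all patients")
    return immunograms.groupby(labels).mean()
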