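"""Rule-based fast-spiking (FS) classification and per-animal aggregation.

A cell is classified FS when at least two of three strict-inequality
conditions hold: AP half-width < 0.26 ms, AHP amplitude > 16.5 mV, and
adaptation ratio > 0.56 (the AHP entering the rule is the fAHP of the first
rheobase-evoked AP, the single-AP afterhyperpolarization this package
measures).  Cells failing the rule are non-FS (putative somatostatin-type
interneurons).  Missing features count as unmet conditions so that
non-fast-spiking cells, which often fail the 150 Hz analysis-sweep rule,
remain classifiable; a cell with all three features missing is
unclassifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ClassifierRule:
    aphw_max_ms: float = 0.26
    ahp_min_mV: float = 16.5
    ar_min: float = 0.56
    min_conditions: int = 2

    def __post_init__(self) -> None:
        if self.min_conditions not in (1, 2, 3):
            raise ValueError("min_conditions must be 1, 2 or 3")


DEFAULT_RULE = ClassifierRule()

FS = "FS"
NON_FS = "non-FS"


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_fs(aphw_ms, ahp_mV, ar, rule: ClassifierRule = DEFAULT_RULE,
                ) -> tuple[str | None, int]:
    """(class label, conditions met) for one cell; label None if unclassifiable.

    Comparisons are strict; a missing feature counts as an unmet condition.
    """
    if all(_is_missing(x) for x in (aphw_ms, ahp_mV, ar)):
        return None, 0
    met = 0
    if not _is_missing(aphw_ms) and aphw_ms < rule.aphw_max_ms:
        met += 1
    if not _is_missing(ahp_mV) and ahp_mV > rule.ahp_min_mV:
        met += 1
    if not _is_missing(ar) and ar > rule.ar_min:
        met += 1
    return (FS if met >= rule.min_conditions else NON_FS), met


def aggregate_fs_fraction(cells: pd.DataFrame, *,
                          group_col: str = "group_label",
                          animal_col: str = "animal_id",
                          class_col: str = "fs_class") -> pd.DataFrame:
    """Per-group FS percentage: fraction per animal, then mean ± SEM across
    animals.

    Returns one row per group with ``mean_pct``, ``sem_pct`` (NaN for a
    single animal, mirroring the undefined SEM) and ``n_animals``.
    Unclassifiable cells are excluded from the denominators.
    """
    df = cells[cells[class_col].isin([FS, NON_FS])]
    if df.empty:
        raise ValueError("no classified cells to aggregate")
    rows = []
    for group, gdf in df.groupby(group_col, sort=True):
        fracs = gdf.groupby(animal_col, sort=True)[class_col].apply(
            lambda s: (s == FS).mean())
        n = len(fracs)
        sem = float(fracs.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"group_label": group,
                     "mean_pct": 100.0 * float(fracs.mean()),
                     "sem_pct": 100.0 * sem if n > 1 else math.nan,
                     "n_animals": n})
    return pd.DataFrame(rows)
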