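"""Islet functional phenotypes from raw assay measurements.

Duplicate measurements are averaged before any ratio is taken; then

* insulin content = content-tube insulin / total islet protein,
* GSIS           = secretion at 11 mM glucose / secretion at 2.8 mM glucose,
* basal secretion = secretion at 2.8 mM glucose / insulin content.

Dilution factors (secretion 1:5, content 1:100 in the assay protocol) can be
applied before the ratios, but default to 1 because ELISA readouts are
normally reported already dilution-corrected; GSIS is a ratio of
same-dilution values so the factor cancels there either way — recorded
explicitly to prevent double-application.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class IsletAssay:
    """Duplicate raw measurements for one individual."""

    secretion_low: tuple[float, float]  # insulin at 2.8 mM glucose
    secretion_high: tuple[float, float]  # insulin at 11 mM glucose
    content_insulin: tuple[float, float]
    total_protein: tuple[float, float]
    dilution_secretion: float = 1.0
    dilution_content: float = 1.0

    def __post_init__(self) -> None:
        for pair in (
            self.secretion_low, self.secretion_high, self.content_insulin, self.total_protein
        ):
            if any(v < 0 for v in pair):
                raise ValidationError("assay measurements must be non-negative")


@dataclass(frozen=True)
class PhenotypeResult:
    gsis: float
    basal_secretion: float
    insulin_content: float

    @property
    def any_undefined(self) -> bool:
        return any(math.isnan(v) for v in (self.gsis, self.basal_secretion, self.insulin_content))


def _mean(pair: tuple[float, float]) -> float:
    return (pair[0] + pair[1]) / 2.0


def derive_phenotypes(assay: IsletAssay) -> PhenotypeResult:
    """Average duplicates, apply dilutions, compute the three ratios.

    A zero denominator yields NaN for the affected phenotype (flagged via
    warning, never silently dropped).
    """
    s_low = _mean(assay.secretion_low) * assay.dilution_secretion
    s_high = _mean(assay.secretion_high) * assay.dilution_secretion
    content = _mean(assay.content_insulin) * assay.dilution_content
    protein = _mean(assay.total_protein)

    if protein > 0:
        insulin_content = content / protein
    else:
        warnings.warn("zero total protein: insulin content undefined", stacklevel=2)
        insulin_content = float("nan")
    if s_low > 0:
        gsis = s_high / s_low
    else:
        warnings.warn("zero basal secretion: GSIS undefined", stacklevel=2)
        gsis = float("nan")
    if insulin_content > 0:
        basal = s_low / insulin_content
    else:
        warnings.warn("insulin content not positive: basal secretion undefined", stacklevel=2)
        basal = float("nan")
    return PhenotypeResult(gsis=gsis, basal_secretion=basal, insulin_content=insulin_content)


ASSAY_COLUMNS = (
    "secretion_low_1", "secretion_low_2",
    "secretion_high_1", "secretion_high_2",
    "content_insulin_1", "content_insulin_2",
    "total_protein_1", "total_protein_2",
)


def derive_phenotype_table(
    assays: pd.DataFrame,
    dilution_secretion: float = 1.0,
    dilution_content: float = 1.0,
) -> pd.DataFrame:
    """Vectorized derivation for a table of assays (one row per individual).

    Expects the duplicate columns of :data:`ASSAY_COLUMNS`.  Output columns:
    gsis (ratio), basal_secretion (per insulin-content unit), insulin_content
    (insulin per protein mass), plus a ``units`` column.
    """
    missing = [c for c in ASSAY_COLUMNS if c not in assays.columns]
    if missing:
        raise ValidationError(f"assay table is missing columns: {missing}")
    rows = {}
    for idx, row in assays.iterrows():
        res = derive_phenotypes(
            IsletAssay(
                secretion_low=(row.secretion_low_1, row.secretion_low_2),
                secretion_high=(row.secretion_high_1, row.secretion_high_2),
                content_insulin=(row.content_insulin_1, row.content_insulin_2),
                total_protein=(row.total_protein_1, row.total_protein_2),
                dilution_secretion=dilution_secretion,
                dilution_content=dilution_content,
            )
        )
        rows[idx] = {
            "gsis": res.gsis,
            "basal_secretion": res.basal_secretion,
            "insulin_content": res.insulin_content,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["units"] = "gsis: ratio; basal: secretion per content unit; content: insulin per ug protein"
    return out
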