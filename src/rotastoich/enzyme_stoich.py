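"""Extracellular enzyme C:N:P stoichiometry and vector analysis.

Five enzyme activities (μmol product g⁻¹ soil d⁻¹) summarize microbial
resource acquisition: BG (β-glucosidase, C), NAG (N-acetylglucosaminidase,
fungal N), LAP (leucine aminopeptidase, bacterial N), ALP (alkaline
phosphatase, P) and PPO (polyphenol oxidase, recalcitrant C).

The vector analysis maps the log activities to

    L = sqrt( [ln BG]^2 + [ln(NAG+LAP)]^2 )
    A = arctan( ln(NAG+LAP) / ln BG )   (degrees)

where larger L indicates stronger carbon limitation, and A below /
above 45° indicates nitrogen / phosphorus limitation respectively.  The
log formulation requires BG > 1 and NAG+LAP > 1; activities in (0, 1]
produce nonpositive logarithms that break the angle's interpretation and
are flagged (never silently clipped).

An alternative relative-proportion variant (``mode="relative"``, using
x = BG/(BG+ALP) and y = BG/(BG+NAG+LAP)) is available for sensitivity
analysis; the literal log formulation is the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EnzymeActivities",
    "EnzymeRatios",
    "StoichiometryResult",
    "enzyme_ratios",
    "vector_length",
    "vector_angle",
    "classify_limitation",
    "analyze",
    "stoichiometry_table",
]

ENZYMES = ("BG", "NAG", "LAP", "ALP", "PPO")


@dataclass(frozen=True)
class EnzymeActivities:
    """One sample's enzyme activities, μmol product g⁻¹ soil d⁻¹."""

    BG: float
    NAG: float
    LAP: float
    ALP: float
    PPO: float

    def __post_init__(self) -> None:
        for name in ENZYMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"activity {name} must be strictly positive")


@dataclass(frozen=True)
class EnzymeRatios:
    """The four acquisition-strategy ratios.

    ratio_cn   BG:(NAG+LAP) — C vs N acquisition investment
    ratio_nagl NAG:LAP      — fungal vs bacterial N cycling (>1 = fungal)
    ratio_cp   BG:ALP       — C vs P acquisition strategy
    ratio_cppo BG:PPO       — labile vs recalcitrant C decomposition
    """

    ratio_cn: float
    ratio_nagl: float
    ratio_cp: float
    ratio_cppo: float

    @property
    def fungal_dominated_n_cycling(self) -> bool:
        return self.ratio_nagl > 1.0


@dataclass(frozen=True)
class StoichiometryResult:
    ratios: EnzymeRatios
    vector_length: float
    vector_angle: float
    limitation: str | None
    flagged: bool
    mode: str = "literal"

    @property
    def c_limitation_score(self) -> float:
        return self.vector_length


def enzyme_ratios(e: EnzymeActivities) -> EnzymeRatios:
    """Plain activity quotients; all activities must be positive."""
    return EnzymeRatios(
        ratio_cn=e.BG / (e.NAG + e.LAP),
        ratio_nagl=e.NAG / e.LAP,
        ratio_cp=e.BG / e.ALP,
        ratio_cppo=e.BG / e.PPO,
    )


def _log_terms(e: EnzymeActivities) -> tuple[float, float, bool]:
    x = math.log(e.BG)
    y = math.log(e.NAG + e.LAP)
    # activities in (0, 1] give log <= 0: the point leaves the first
    # quadrant (or its boundary origin) and the angle loses its meaning
    flagged = x <= 0 or y <= 0
    if flagged:
        warnings.warn(
            "enzyme activity <= 1 gives a nonpositive logarithm; vector "
            "angle interpretation is unreliable (result flagged)",
            stacklevel=3,
        )
    return x, y, flagged


def vector_length(e: EnzymeActivities, mode: str = "literal") -> float:
    """Euclidean norm of the two log (or relative-proportion) terms."""
    if mode == "relative":
        x = e.BG / (e.BG + e.ALP)
        y = e.BG / (e.BG + e.NAG + e.LAP)
        return math.hypot(x, y)
    if mode != "literal":
        raise ValueError("mode must be 'literal' or 'relative'")
    x, y, _ = _log_terms(e)
    return math.hypot(x, y)


def vector_angle(e: EnzymeActivities, mode: str = "literal") -> float:
    """Vector angle in degrees.

    Literal mode: arctan(ln(NAG+LAP)/ln BG); by the limit convention
    ln BG = 0 with ln(NAG+LAP) > 0 maps to 90°.  Relative mode:
    atan2(x, y) on the proportion coordinates (angle measured from the
    N-acquisition axis, so >45° again indicates P limitation).
    """
    if mode == "relative":
        x = e.BG / (e.BG + e.ALP)
        y = e.BG / (e.BG + e.NAG + e.LAP)
        return math.degrees(math.atan2(x, y))
    if mode != "literal":
        raise ValueError("mode must be 'literal' or 'relative'")
    x, y, _ = _log_terms(e)
    if x == 0:
        return 90.0 if y > 0 else 0.0
    return math.degrees(math.atan(y / x))


def classify_limitation(angle: float, flagged: bool = False) -> str:
    """Nitrogen below 45°, phosphorus above, balanced at exactly 45°."""
    if flagged:
        raise ValueError("vector angle was flagged; classification refused")
    if angle < 45.0:
        return "nitrogen"
    if angle > 45.0:
        return "phosphorus"
    return "balanced"


def analyze(e: EnzymeActivities, mode: str = "literal") -> StoichiometryResult:
    """Ratios, vector traits and limitation label for one sample."""
    ratios = enzyme_ratios(e)
    if mode == "literal":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, flagged = _log_terms(e)
        if flagged:
            warnings.warn("vector analysis flagged: activity <= 1", stacklevel=2)
    else:
        flagged = False
    length = vector_length(e, mode)
    angle = vector_angle(e, mode)
    limitation = None if flagged else classify_limitation(angle)
    return StoichiometryResult(
        ratios=ratios,
        vector_length=length,
        vector_angle=angle,
        limitation=limitation,
        flagged=flagged,
        mode=mode,
    )


def stoichiometry_table(table: pd.DataFrame, mode: str = "literal") -> pd.DataFrame:
    """Per-row stoichiometry results for a soil table with enzyme columns."""
    missing = [c for c in ENZYMES if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing enzyme columns: {missing}")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, row in table.iterrows():
            res = analyze(EnzymeActivities(*(float(row[c]) for c in ENZYMES)), mode)
            rec = {}
            for key in ("treatment", "replicate"):
                if key in table.columns:
                    rec[key] = row[key]
            rec.update(
                ratio_cn=res.ratios.ratio_cn,
                ratio_nagl=res.ratios.ratio_nagl,
                ratio_cp=res.ratios.ratio_cp,
                ratio_cppo=res.ratios.ratio_cppo,
                vector_length=res.vector_length,
                vector_angle=res.vector_angle,
                limitation=res.limitation,
                flagged=res.flagged,
            )
            rows.append(rec)
    return pd.DataFrame(rows)
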