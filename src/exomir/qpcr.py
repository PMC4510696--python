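"""Quantitative PCR and reporter-assay arithmetic.

Implements the standard comparative-Ct machinery: technical-replicate Ct
averaging with a <=30-cycle QC gate, U6-referenced delta-Ct, fold change
2^-ddCt, dilution-series standard curves (OLS of mean Ct on log10 copies/ul),
curve inversion to absolute copy numbers, relative percent increase between
copy estimates, and luciferase/beta-galactosidase reporter normalization.
SEMs are propagated first-order (delta method).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

AVOGADRO = 6.02214076e23
CT_MAX = 30.0


def picomolar_to_copies_per_ul(pM: float) -> float:
    """Convert a pM oligonucleotide concentration to copies per microliter."""
    return pM * 1e-12 * AVOGADRO / 1e6


def summarize_replicates(values) -> tuple[float, float]:
    """(mean, SEM) of technical replicates."""
    x = np.asarray(values, float)
    sem = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(x.mean()), sem


@dataclass
class QPCRMeasurement:
    sample_id: str
    target_cts: list[float]
    reference_cts: list[float]
    condition: str = ""

    def __post_init__(self):
        if not self.target_cts or not self.reference_cts:
            raise ValueError("replicate Ct lists must be non-empty")
        for ct in list(self.target_cts) + list(self.reference_cts):
            if not 0 < ct <= CT_MAX:
                raise ValueError(f"Ct {ct} outside QC range (0, {CT_MAX}]")

    @property
    def delta_ct(self) -> float:
        """Mean target Ct minus mean reference (U6) Ct."""
        return float(np.mean(self.target_cts) - np.mean(self.reference_cts))


def ddct_fold_change(treated: QPCRMeasurement, control: QPCRMeasurement) -> tuple[float, float]:
    """(fold_change, ddct) with FC = 2^-ddCt; FC > 1 means enriched in
    ``treated`` (e.g. exosome over cell)."""
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct), ddct


@dataclass
class StandardCurve:
    slope: float  # Ct per log10(copies/ul)
    intercept: float
    r_squared: float
    dilution_table: list[tuple[float, float]] = field(default_factory=list)

    @property
    def efficiency(self) -> float | None:
        """Amplification efficiency 10^(-1/slope) - 1; None for a flat curve."""
        if self.slope == 0:
            return None
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, copies_per_ul: float) -> float:
        return self.intercept + self.slope * math.log10(copies_per_ul)


def fit_standard_curve(dilution_series: list[tuple[float, list[float]]]) -> StandardCurve:
    """OLS of mean Ct on log10(copies/ul) over a dilution series.

    ``dilution_series`` rows are (copies_per_ul, replicate Cts)."""
    if len({c for c, _ in dilution_series}) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if any(c <= 0 for c, _ in dilution_series):
        raise ValueError("concentrations must be positive")
    x = np.log10([c for c, _ in dilution_series])
    y = np.array([float(np.mean(cts)) for _, cts in dilution_series])
    if np.allclose(y, y[0]):
        return StandardCurve(0.0, float(y[0]), 1.0, list(zip(x.tolist(), y.tolist())))
    fit = stats.linregress(x, y)
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2),
                         list(zip(x.tolist(), y.tolist())))


def absolute_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies/ul = 10^((Ct - intercept)/slope)."""
    if curve.slope == 0:
        raise ValueError("flat standard curve cannot be inverted")
    if curve.dilution_table:
        cts = [t[1] for t in curve.dilution_table]
        if not (min(cts) <= ct <= max(cts)):
            warnings.warn(f"Ct {ct} outside the fitted dilution range; extrapolating")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass
class CopyEstimate:
    condition: str
    copies: float
    sem: float = 0.0

    def __post_init__(self):
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


def percent_increase(
    cp_condition: CopyEstimate | float, cp_baseline: CopyEstimate | float
) -> tuple[float, float]:
    """Relative change of absolute copy number vs baseline, in percent.

    Returns (percent, sem) where percent = (CP_cond - CP_base)/CP_base x 100
    and the SEM is first-order propagated from the two copy SEMs."""
    cond = cp_condition if isinstance(cp_condition, CopyEstimate) else CopyEstimate("cond", cp_condition)
    base = cp_baseline if isinstance(cp_baseline, CopyEstimate) else CopyEstimate("base", cp_baseline)
    if base.copies <= 0:
        raise ValueError("baseline copy number must be positive")
    pct = (cond.copies - base.copies) / base.copies * 100.0
    var = (100.0 / base.copies) ** 2 * cond.sem**2 \
        + (100.0 * cond.copies / base.copies**2) ** 2 * base.sem**2
    return pct, math.sqrt(var)


def reporter_normalize(
    luc: float, bgal: float, control_ratio: float
) -> tuple[float, float]:
    """Luciferase over beta-galactosidase, relative to the control construct.

    Returns (relative_expression, fold_repression = 1/relative)."""
    if luc <= 0 or bgal <= 0 or control_ratio <= 0:
        raise ValueError("signals and control ratio must be positive")
    rel = (luc / bgal) / control_ratio
    return rel, 1.0 / rel


def reporter_batch(
    luc_values, bgal_values, control_ratio: float
) -> dict[str, float]:
    """Technical-replicate reporter summary with delta-method SEM."""
    ratios = [reporter_normalize(l, b, control_ratio)[0]
              for l, b in zip(luc_values, bgal_values)]
    mean, sem = summarize_replicates(ratios)
    return {"relative": mean, "relative_sem": sem,
            "fold_repression": 1.0 / mean,
            "fold_repression_sem": sem / mean**2}
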