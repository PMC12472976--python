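"""DPPH radical scavenging arithmetic.

The DPPH assay reads the stable radical's absorbance at 516 nm before
(``A0``, control) and after (``A1``, sample) reaction; the scavenging
activity is ``((A0 − A1)/A0) · 100`` percent.  Values above 100 cannot
occur for non-negative absorbances; negative values (sample more
absorbing than the control) are reported as-is with a warning rather
than clamped, because they usually indicate a blank or turbidity problem
worth seeing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DpphMeasurement:
    """Control/sample absorbance pair at 516 nm for one labelled sample."""

    label: str
    a0: float
    a1: float

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError(f"{self.label}: control absorbance A0 must be > 0")
        if self.a1 < 0:
            raise ValueError(f"{self.label}: sample absorbance A1 must be >= 0")


def scavenging_percent(m: DpphMeasurement) -> float:
    """((A0 − A1)/A0) · 100; negative when A1 > A0 (warned, not clamped)."""
    value = (m.a0 - m.a1) / m.a0 * 100.0
    if value < 0:
        warnings.warn(f"{m.label}: negative scavenging ({value:.2f}%); "
                      "sample absorbs more than the control", stacklevel=2)
    return value


def batch_scavenging(path_or_frame: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Compute scavenging for a (label, a0, a1) table.

    Accepts a tab-separated file or a DataFrame; returns a table with a
    ``scavenging_percent`` column appended.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", comment="#")
    if not {"label", "a0", "a1"} <= set(df.columns):
        raise ValueError("need columns 'label', 'a0', 'a1'")
    df["scavenging_percent"] = [
        scavenging_percent(DpphMeasurement(str(r["label"]),
                                           float(r["a0"]), float(r["a1"])))
        for _, r in df.iterrows()
    ]
    return df


@dataclass(frozen=True)
class LinearStandardCurve:
    """Generic least-squares standard curve (e.g. Trolox equivalents).

    response = slope · concentration + intercept.  No default
    parameterisation is shipped; fit it from your own standards.
    """

    slope: float
    intercept: float
    r_squared: float

    @classmethod
    def fit(cls, concentrations, responses) -> "LinearStandardCurve":
        fit = stats.linregress(concentrations, responses)
        return cls(float(fit.slope), float(fit.intercept),
                   float(fit.rvalue) ** 2)

    def to_concentration(self, response: float) -> float:
        if self.slope == 0:
            raise ValueError("flat standard curve cannot be inverted")
        return (response - self.intercept) / self.slope
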