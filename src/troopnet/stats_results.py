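"""Uniform result record shared by every statistical test."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any


@dataclass
class TestResult:
    """Statistic, degrees of freedom, p-value and metadata for one test."""

    __test__ = False  # not a pytest class despite the name

    test_name: str
    statistic: float
    df: float | tuple | None
    p_value: float
    notes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def as_dict(self) -> dict[str, Any]:
        df = self.df
        if isinstance(df, tuple):
            df = ",".join(str(d) for d in df)
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": df,
            "p_value": self.p_value,
            **{f"note_{k}": v for k, v in self.notes.items()},
        }
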