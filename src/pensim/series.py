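"""Small year-indexed series container used throughout the projection engine.

Monetary and rate series in the model are indexed by calendar year over
irregular spans (wage history reaches decades before the forecast start).
``YearSeries`` wraps a contiguous float array with a start year so code can
ask for ``series[1998]`` or a closed year window without bookkeeping offsets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["YearSeries"]


class YearSeries:
    """A contiguous float array indexed by calendar year (inclusive span)."""

    __slots__ = ("start_year", "values")

    def __init__(self, start_year: int, values) -> None:
        self.start_year = int(start_year)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("YearSeries values must be one-dimensional")

    @property
    def end_year(self) -> int:
        return self.start_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def _pos(self, year: int) -> int:
        pos = int(year) - self.start_year
        if pos < 0 or pos >= len(self.values):
            raise KeyError(f"year {year} outside series span "
                           f"[{self.start_year}, {self.end_year}]")
        return pos

    def __getitem__(self, year) -> float:
        return float(self.values[self._pos(year)])

    def __setitem__(self, year, value) -> None:
        self.values[self._pos(year)] = value

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, year) -> bool:
        return self.start_year <= int(year) <= self.end_year

    def window(self, first_year: int, last_year: int) -> np.ndarray:
        """Values for the closed year range [first_year, last_year]."""
        if last_year < first_year:
            return np.empty(0)
        return self.values[self._pos(first_year):self._pos(last_year) + 1]

    def cumprod1p(self) -> "YearSeries":
        """Running product of (1 + value), same year indexing."""
        return YearSeries(self.start_year, np.cumprod(1.0 + self.values))

    def copy(self) -> "YearSeries":
        return YearSeries(self.start_year, self.values.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"YearSeries({self.start_year}..{self.end_year}, n={len(self)})"
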