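"""Species -> continuous trait tables (e.g. log body mass).

Species names are matched to tip labels exactly after trimming surrounding
whitespace and normalizing internal spaces to underscores, which reconciles
the two conventions used by published supertrees and trait compendia.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["TraitTable", "TraitError"]


class TraitError(ValueError):
    """Missing or invalid trait data."""


def _canonical(name: str) -> str:
    return "_".join(str(name).strip().split())


class TraitTable:
    """Mapping from species label to a single continuous trait value.

    Ranks (average ranks for ties) are derived on demand for whatever subset
    and order of species an analysis asks for.
    """

    def __init__(self, values: Mapping[str, float]):
        if not values:
            raise TraitError("empty trait table")
        self._values: dict[str, float] = {}
        for name, value in values.items():
            key = _canonical(name)
            value = float(value)
            if not np.isfinite(value):
                raise TraitError(f"non-finite trait value for {name!r}: {value}")
            if key in self._values:
                raise TraitError(f"duplicate species after name normalization: {key!r}")
            self._values[key] = value

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_file(cls, path, species_col=0, value_col=1) -> "TraitTable":
        """Read a two-column TSV/CSV (species, value); header row optional."""
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
        if df.shape[1] < 2:
            raise TraitError(f"{path}: expected at least two columns (species, value)")
        first = df.iloc[0, value_col]
        try:
            float(first)
        except (TypeError, ValueError):
            df = df.iloc[1:]  # header row
        if df.empty:
            raise TraitError(f"{path}: no data rows")
        return cls(dict(zip(df.iloc[:, species_col], df.iloc[:, value_col].astype(float))))

    @classmethod
    def from_series(cls, series: pd.Series) -> "TraitTable":
        return cls(series.to_dict())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self._values), "value": list(self._values.values())}
        )

    # -- access ---------------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, name: str) -> bool:
        return _canonical(name) in self._values

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[_canonical(name)]
        except KeyError:
            raise TraitError(f"no trait value for species {name!r}") from None

    def covered(self, labels: Iterable[str]) -> list[str]:
        """The subset of ``labels`` that has a trait value."""
        return [lbl for lbl in labels if lbl in self]

    def values_for(self, labels: Sequence[str]) -> np.ndarray:
        """Trait values aligned to ``labels``; errors name missing species."""
        missing = [lbl for lbl in labels if lbl not in self]
        if missing:
            raise TraitError(f"missing trait values for species: {missing}")
        return np.array([self[lbl] for lbl in labels], dtype=float)

    def ranks_for(self, labels: Sequence[str]) -> np.ndarray:
        """Average ranks (1..n, ties averaged) aligned to ``labels``."""
        return rankdata(self.values_for(labels))
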