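"""In-memory container for normalized NSE relaxation tables.

A :class:`RelaxationDataset` is a long-format table of
``(q [1/m], t [s], s, err)`` records plus a metadata mapping (temperature,
viscosities, population, diffusion spec, provenance).  All numeric content
is SI; unit conversion happens only at the file boundary
(:mod:`vesiclense.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["RelaxationDataset"]

#: allowed noise excursion of normalized S above 1
S_MAX = 1.2
#: minimum number of time points per q block for a weighted fit
MIN_POINTS_PER_Q = 4

COLUMNS = ("q", "t", "s", "err")


@dataclass
class RelaxationDataset:
    """Normalized relaxation records with 1-sigma uncertainties."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.table
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DomainError(f"missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)].astype(float).reset_index(drop=True)
        if not np.all(np.isfinite(df.to_numpy())):
            raise DomainError("non-finite values in relaxation table")
        if np.any(df["err"] <= 0):
            raise DomainError("uncertainties must be strictly positive")
        if np.any(df["s"] <= 0) or np.any(df["s"] > S_MAX):
            raise DomainError(f"normalized S must lie in (0, {S_MAX}]")
        df = df.sort_values(["q", "t"], kind="stable").reset_index(drop=True)
        counts = df.groupby("q").size()
        if (counts < MIN_POINTS_PER_Q).any():
            bad = counts[counts < MIN_POINTS_PER_Q].index.tolist()
            raise DomainError(
                f"q blocks {bad} have fewer than {MIN_POINTS_PER_Q} time points")
        self.table = df

    @property
    def q_values(self) -> np.ndarray:
        return self.table["q"].unique()

    @property
    def n_records(self) -> int:
        return len(self.table)

    def block(self, q: float) -> pd.DataFrame:
        """All records at one q value."""
        return self.table[self.table["q"] == q]

    def blocks(self):
        """Iterate ``(q, sub-table)`` in ascending q."""
        for q, sub in self.table.groupby("q", sort=True):
            yield float(q), sub

    @classmethod
    def from_arrays(cls, q, t, s, err, metadata: dict | None = None
                    ) -> "RelaxationDataset":
        df = pd.DataFrame({"q": q, "t": t, "s": s, "err": err})
        return cls(df, dict(metadata or {}))

    def equals_numeric(self, other: "RelaxationDataset", rtol=1e-12) -> bool:
        a, b = self.table.to_numpy(), other.table.to_numpy()
        return a.shape == b.shape and np.allclose(a, b, rtol=rtol, atol=0)
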