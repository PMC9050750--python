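"""Relative qPCR quantification (dCT) and Z-score matrix construction.

Relative mRNA amounts are computed with the dCT method against a
housekeeping gene (18S rRNA by default): RQ = 2^-(CT_gene - CT_hk) per
sample.  Heatmap rows are standardised per gene as Z = (x - mu)/sigma
with the population (divisor n) standard deviation.  Samples whose
housekeeping reaction produced no usable CT are discarded with a
warning, mirroring standard background-CT handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pump_model import ConfigurationError

__all__ = [
    "QpcrTable",
    "delta_ct_quantity",
    "delta_delta_ct",
    "zscore_matrix",
]

DEFAULT_HOUSEKEEPING = "18S rRNA"


class DegenerateRowError(ValueError):
    """A gene row has zero variance and cannot be Z-scored."""


@dataclass
class QpcrTable:
    """CT values per gene (rows) per sample (columns).

    ``ct`` is a genes x samples DataFrame; ``housekeeping`` names the
    reference gene; ``sample_groups`` maps sample -> condition label
    (e.g. CT vs dP); ``background_ct`` optionally marks CTs at or above
    a threshold as background (default: only missing values count).
    """

    ct: pd.DataFrame
    housekeeping: str = DEFAULT_HOUSEKEEPING
    sample_groups: dict[str, str] = field(default_factory=dict)
    background_ct: float | None = None

    def __post_init__(self):
        if self.housekeeping not in self.ct.index:
            raise ConfigurationError(
                f"housekeeping gene {self.housekeeping!r} absent from the CT table"
            )

    def _usable_samples(self) -> list[str]:
        hk = self.ct.loc[self.housekeeping]
        bad = hk.isna()
        if self.background_ct is not None:
            bad |= hk >= self.background_ct
        dropped = list(self.ct.columns[bad])
        if dropped:
            warnings.warn(
                f"discarding {len(dropped)} sample(s) with background housekeeping CT: "
                f"{dropped}", stacklevel=3,
            )
        return list(self.ct.columns[~bad])


def delta_ct_quantity(table: QpcrTable) -> pd.DataFrame:
    """Relative amounts RQ = 2^-(CT_gene - CT_hk), genes x samples.

    The housekeeping row is identically 1.  Samples with a missing (or
    above-threshold) housekeeping CT are dropped with a warning.
    """
    cols = table._usable_samples()
    ct = table.ct[cols]
    dct = ct.subtract(ct.loc[table.housekeeping], axis=1)
    return 2.0 ** (-dct)


def delta_delta_ct(table: QpcrTable, group_ref: str, group_test: str) -> pd.Series:
    """Per-gene fold change 2^-ddCT of ``group_test`` over ``group_ref``.

    ddCT is the difference of group-mean dCTs; a convenience wrapper
    over the per-sample dCT quantities for two-condition contrasts.
    """
    cols = table._usable_samples()
    groups = {c: table.sample_groups.get(c) for c in cols}
    ref = [c for c, g in groups.items() if g == group_ref]
    test = [c for c, g in groups.items() if g == group_test]
    if not ref or not test:
        raise ConfigurationError(f"groups {group_ref!r}/{group_test!r} not found among samples")
    ct = table.ct[cols]
    dct = ct.subtract(ct.loc[table.housekeeping], axis=1)
    ddct = dct[test].mean(axis=1) - dct[ref].mean(axis=1)
    return 2.0 ** (-ddct)


def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z = (x - mu)/sigma with population (divisor n) SD.

    Raises :class:`DegenerateRowError` naming the first constant gene
    row; every returned row has mean 0 and population SD 1.
    """
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    zero = np.nonzero(sd[:, 0] == 0)[0]
    if zero.size:
        raise DegenerateRowError(
            f"gene {values.index[zero[0]]!r} has zero variance across samples"
        )
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)
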