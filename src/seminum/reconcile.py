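"""Per-name comparison of harmonized TPL and COL statuses.

Only names with a status from both providers are compared (a name one
provider did not find contributes no conflict).  Identical statuses count as
agreement; differing statuses are kept as discrepancy records and tallied in
a cross-tabulation indexed by (TPL status, COL status), off-diagonal cells
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import pandas as pd

from .names import CanonicalName
from .verification import NameCollection, Status


@dataclass(frozen=True)
class DiscrepancyRecord:
    name: CanonicalName
    status_tpl: Status
    status_col: Status

    def __post_init__(self) -> None:
        if self.status_tpl == self.status_col:
            raise ValueError("a discrepancy requires differing statuses")
        if Status.NA in (self.status_tpl, self.status_col):
            raise ValueError("NA statuses are excluded from comparison")


def compare_status(
    name: CanonicalName, status_tpl: Status, status_col: Status
) -> DiscrepancyRecord | None:
    """Return ``None`` on agreement, else the saved discrepancy."""
    if status_tpl == status_col:
        return None
    return DiscrepancyRecord(name, status_tpl, status_col)


def collect_discrepancies(
    coll: NameCollection, provider_a: str = "TPL", provider_b: str = "COL"
) -> tuple[list[DiscrepancyRecord], int]:
    """All discrepancies plus the agreement count over dual-status names."""
    discrepancies: list[DiscrepancyRecord] = []
    agreements = 0
    a = {r.query_name.key: r for r in coll.by_provider(provider_a)}
    b = {r.query_name.key: r for r in coll.by_provider(provider_b)}
    for key, ra in a.items():
        rb = b.get(key)
        if rb is None or ra.status is Status.NA or rb.status is Status.NA:
            continue
        rec = compare_status(ra.query_name, ra.status, rb.status)
        if rec is None:
            agreements += 1
        else:
            discrepancies.append(rec)
    return discrepancies, agreements


def discrepancy_crosstab(
    coll: NameCollection, provider_a: str = "TPL", provider_b: str = "COL"
) -> pd.DataFrame:
    """Cross-tabulate discrepancy counts, rows = TPL status, cols = COL status.

    Only off-diagonal (conflicting) combinations appear; the cell sum equals
    the number of discrepancy records.
    """
    discrepancies, _ = collect_discrepancies(coll, provider_a, provider_b)
    if not discrepancies:
        return pd.DataFrame(dtype=int).rename_axis(
            index=f"status_{provider_a.lower()}", columns=f"status_{provider_b.lower()}"
        )
    df = pd.DataFrame(
        {
            f"status_{provider_a.lower()}": [d.status_tpl.value for d in discrepancies],
            f"status_{provider_b.lower()}": [d.status_col.value for d in discrepancies],
        }
    )
    return pd.crosstab(df[f"status_{provider_a.lower()}"], df[f"status_{provider_b.lower()}"])


DISCREPANCY_HEADER = "name,status_tpl,status_col"


def write_discrepancies(discrepancies: list[DiscrepancyRecord], fh: TextIO) -> None:
    import csv

    w = csv.writer(fh)
    w.writerow(DISCREPANCY_HEADER.split(","))
    for d in discrepancies:
        w.writerow([d.name.text, d.status_tpl.value, d.status_col.value])
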