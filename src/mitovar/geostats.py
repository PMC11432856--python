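"""Geographic association of mitochondrial groups.

Wild beet (Beta vulgaris ssp. maritima / adanensis) collection sites
fall on either the Atlantic or the Mediterranean coast, and the
mitochondrial clades split into two large phylogenetic groups
(clades 1, 2, 4A-4D versus clades 3, 4E-4H).  This module builds the
coast x group 2x2 contingency table and tests the association with a
two-sided Fisher exact test computed in log-space (minimum-likelihood
rule: the p-value sums the hypergeometric probabilities of all tables
with the observed margins that are no more probable than the observed
table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln

GROUP_A = "group_A"  # clades 1, 2, 4A-4D (Mediterranean-overrepresented)
GROUP_B = "group_B"  # clades 3, 4E-4H (Atlantic-overrepresented)

DEFAULT_GROUP_MAP: dict[str, str] = {
    "1": GROUP_A,
    "2": GROUP_A,
    "4A": GROUP_A,
    "4B": GROUP_A,
    "4C": GROUP_A,
    "4D": GROUP_A,
    "3": GROUP_B,
    "4E": GROUP_B,
    "4F": GROUP_B,
    "4G": GROUP_B,
    "4H": GROUP_B,
}

COASTS = ("Atlantic", "Mediterranean")

#: Published per-clade tallies of the 296 wild beet accessions by coast
#: of collection (clades 1..4H).  Used as worked-example input for the
#: contingency construction and the association test.
WILD_BEET_CLADE_COUNTS: dict[str, dict[str, int]] = {
    "Atlantic": {
        "1": 5, "2": 3, "3": 25, "4A": 2, "4B": 2, "4C": 0,
        "4D": 0, "4E": 107, "4F": 17, "4G": 4, "4H": 0,
    },
    "Mediterranean": {
        "1": 7, "2": 1, "3": 32, "4A": 0, "4B": 4, "4C": 49,
        "4D": 9, "4E": 18, "4F": 3, "4G": 3, "4H": 5,
    },
}


def assign_group(clade: str, group_map: Mapping[str, str] | None = None) -> str:
    """Map a clade label to its large mitochondrial group."""
    gm = DEFAULT_GROUP_MAP if group_map is None else group_map
    try:
        return gm[clade]
    except KeyError:
        raise KeyError(f"clade {clade!r} has no group mapping") from None


@dataclass(frozen=True)
class Contingency2x2:
    """Coast x mitochondrial-group counts.

    Layout: rows (Atlantic, Mediterranean), columns (group_A, group_B):
    ``[[a, b], [c, d]]``.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = COASTS
    col_labels: tuple[str, str] = (GROUP_A, GROUP_B)
    excluded_n: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency_from_clade_counts(
    counts: Mapping[str, Mapping[str, int]] | None = None,
    group_map: Mapping[str, str] | None = None,
) -> Contingency2x2:
    """Sum per-clade, per-coast counts into the 2x2 group table."""
    counts = WILD_BEET_CLADE_COUNTS if counts is None else counts
    cells = {coast: {GROUP_A: 0, GROUP_B: 0} for coast in COASTS}
    for coast in COASTS:
        for clade, n in counts[coast].items():
            cells[coast][assign_group(clade, group_map)] += n
    return Contingency2x2(
        a=cells["Atlantic"][GROUP_A],
        b=cells["Atlantic"][GROUP_B],
        c=cells["Mediterranean"][GROUP_A],
        d=cells["Mediterranean"][GROUP_B],
    )


def build_contingency(
    records: Iterable[tuple[str, str, str]],
    group_map: Mapping[str, str] | None = None,
) -> Contingency2x2:
    """Cross-classify (accession, coast, clade) records.

    Records whose coast is not Atlantic/Mediterranean or whose clade has
    no group mapping are excluded and counted in ``excluded_n``.
    """
    gm = DEFAULT_GROUP_MAP if group_map is None else group_map
    cells = {coast: {GROUP_A: 0, GROUP_B: 0} for coast in COASTS}
    excluded = 0
    for _acc, coast, clade in records:
        if coast not in COASTS or clade not in gm:
            excluded += 1
            continue
        cells[coast][gm[clade]] += 1
    return Contingency2x2(
        a=cells["Atlantic"][GROUP_A],
        b=cells["Atlantic"][GROUP_B],
        c=cells["Mediterranean"][GROUP_A],
        d=cells["Mediterranean"][GROUP_B],
        excluded_n=excluded,
    )


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def fisher_exact(
    t: Contingency2x2,
    alternative: str = "two-sided",
    tie_rel_tol: float = 1e-7,
) -> float:
    """Two-sided Fisher exact p-value, computed in log-space.

    With margins fixed, cell ``a`` follows a hypergeometric law; the
    two-sided p-value sums the probabilities of all tables whose
    probability does not exceed the observed one (within a relative
    tolerance for float ties).  A zero margin makes the table
    degenerate; by convention p = 1 with a warning.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    if t.total == 0:
        raise ValueError("empty table")
    r1, r2 = t.row_totals
    c1, _c2 = t.col_totals
    n = t.total
    if 0 in (r1, r2, *t.col_totals):
        warnings.warn("degenerate table (zero margin): p = 1", stacklevel=2)
        return 1.0
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    log_denom = _log_binom(n, c1)
    logp = np.array(
        [_log_binom(r1, k) + _log_binom(r2, c1 - k) - log_denom for k in ks]
    )
    log_obs = logp[t.a - k_lo]
    keep = logp <= log_obs + math.log1p(tie_rel_tol)
    sel = logp[keep]
    m = sel.max()
    p = float(np.exp(m) * np.exp(sel - m).sum())
    return min(p, 1.0)


@dataclass
class GeoReport:
    table: Contingency2x2
    p_value: float

    def to_dict(self) -> dict:
        return {
            "table": self.table.table.tolist(),
            "row_labels": list(self.table.row_labels),
            "col_labels": list(self.table.col_labels),
            "row_totals": list(self.table.row_totals),
            "col_totals": list(self.table.col_totals),
            "total": self.table.total,
            "excluded_n": self.table.excluded_n,
            "p_value": self.p_value,
        }


def geographic_association(
    records: Iterable[tuple[str, str, str]],
    group_map: Mapping[str, str] | None = None,
) -> GeoReport:
    """Contingency table plus Fisher exact p for a cohort of records."""
    table = build_contingency(records, group_map)
    return GeoReport(table=table, p_value=fisher_exact(table))
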